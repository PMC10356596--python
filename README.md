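# octrend

Trend detection and time-of-emergence analysis for **multiband ocean-colour
time series**.

Satellite ocean-colour sensors measure remote-sensing reflectance R_rs
(sr⁻¹) in several visible wavebands at once. Because the reflectance
spectrum carries more signal than any derived scalar product (such as
chlorophyll-a), and some wavebands are less noisy, treating all bands
jointly can reveal long-term change that no single variable shows. The
obstacles are serial autocorrelation in the annual series (which shrinks
the effective sample size) and strong correlation between wavebands (which
couples the uncertainties of their trends). `octrend` implements the
statistical machinery that addresses both, for gridded (latitude ×
longitude × year × waveband) cubes:

* **Cochrane–Orcutt prewhitening** — the residual lag-1 coefficient ρ̂ is
  estimated per grid cell and removed by quasi-differencing
  (y_t ← y_t − ρ̂ y_{t−1}, applied to response and design alike), at most
  twice, while the residual autocorrelation remains significant.
* **Multivariate trend regression** — per-band OLS slopes **b** on a
  common design [1, t], with cross-band slope covariance
  C = Σ̂ · [(XᵀX)⁻¹]_(slope,slope), Σ̂ the residual cross-band covariance
  (denominator n − 2).
* **The SNR statistic** —

  SNR = ‖**b**‖ / √(ûᵀ C û),   û = **b**/‖**b**‖,

  the magnitude of the multiband trend vector divided by its uncertainty
  projected along the trend direction; the multivariate analogue of a
  z-score, reducing to b/√C for a single band. Thresholds map to two-sided
  normal confidence levels (2 ↔ 95.45%, 1.645 ↔ 90%, 2.576 ↔ 99%).
* **Area-weighted summaries** — cos(latitude)-weighted fractions of ocean
  with significant trends, and conditional overlap of significance masks
  against their independence baseline.
* **Time of emergence** — for a control/forced simulation pair,
  ToE = 2σ/‖**b**‖ per cell, with ‖**b**‖ from the full forced run and σ
  the control-run interannual variability projected onto the forced trend
  direction; plus the area-weighted ToE distribution and median.
* **A synthetic-data generator** — linear per-band trends plus stationary
  multivariate AR(1) noise with cross-waveband correlation,
  latitude-dependent amplitude and missing-data masks, so the whole
  pipeline is testable without any satellite download.

Ingest helpers aggregate monthly cubes into July–June years, rebin
spatially with cosine weighting, and linearly interpolate model reflectance
spectra to sensor band centres. Everything reads and writes NetCDF.

## Worked example

Plant a trend of population SNR 4 in the left half of a synthetic global
grid and run the full pipeline:

```python
import numpy as np
from octrend import SynthConfig, run_pipeline

cfg = SynthConfig(n_lat=10, n_lon=20, n_years=20, seed=42)
u = cfg.intercepts / np.linalg.norm(cfg.intercepts)   # trend direction
t = np.arange(20.0) - 9.5
kappa = 1 / np.dot(t, t)                              # design factor
sig_stat = cfg.noise_cov / (1 - cfg.ar1_coeff**2)     # stationary noise cov
scale = 4.0 * np.sqrt(u @ (sig_stat * kappa) @ u)     # ||b|| for SNR = 4
trends = np.zeros((10, 20, 10))
trends[:, :10] = scale * u
cfg.trends = trends

print(run_pipeline(synth=cfg).to_text())
```

```
n_analysed = 200
significant_fraction_snr_gt_1.645 = 0.7
significant_fraction_snr_gt_2.0 = 0.61
significant_fraction_snr_gt_2.576 = 0.52
cells_with_0_prewhiten_iterations = 168
cells_with_1_prewhiten_iterations = 32
cells_with_2_prewhiten_iterations = 0
```

Half the area carries a planted trend, and at threshold 2 the detector
flags 61% of the (cosine-weighted) area: essentially all planted cells
plus false positives among the null cells at the test's finite-sample
rate. Fractions shrink as the threshold rises, and the prewhitening
iteration counts show how often significant lag-1 autocorrelation was
found and removed.

The same steps are available from the shell:

```sh
octrend simulate --config scene.yaml --out cube.nc
octrend detect cube.nc --outdir out/
octrend toe control.nc forced.nc --outdir toe_out/
```

## Limitations

See `docs/methods.md` for the model assumptions, default parameter choices
and the known finite-sample behaviour of the SNR test (the normal
threshold↔confidence mapping is asymptotic; at 20 years the null
exceedance rate of SNR > 2 is materially above 4.55%).
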