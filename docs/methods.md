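# Methods

This note documents the statistical model behind `octrend`, the default
parameter choices and why they were made, what the synthetic generator does
and does not emulate, and the numerical conventions and known limitations a
user should be aware of before interpreting output.

## The detection model

Each grid cell carries an annual multiband reflectance series
y_t ∈ R^p (p wavebands, t = 1…n years), modelled as

    y_t = a + b t + e_t,        e_t = ρ e_{t−1} + η_t,

with η_t zero-mean multivariate noise of cross-band covariance Σ. The
analysis proceeds in three stages per cell.

**1. Prewhitening (Cochrane–Orcutt).** The lag-1 coefficient ρ̂ is
estimated from residuals of the per-band linear trend fit — never the raw
series, which would conflate trend with autocorrelation. One ρ̂ per cell is
the default: residuals are standardised per band and pooled, on the view
that the iteration decision is made once per location. A per-band mode
(`mode="band"`) estimates and applies a separate coefficient for each
waveband. Significance uses the two-sided Bartlett large-sample bound
|ρ̂| > z_{1−α/2}/√n at α = 0.05. While significant, response and both
design columns are quasi-differenced (x_t ← x_t − ρ̂ x_{t−1}), losing one
time step, at most twice; the transform leaves the slope parameter's
meaning unchanged. Cells still significant after two passes are retained
and flagged non-converged rather than dropped. A ρ̂ with |ρ̂| ≥ 1 blocks
the transform for that iteration and flags the cell.

**2. Multivariate regression.** All bands share the design X = [1, t]
(t centred at its mean for conditioning; the slope is unaffected). The
slope vector is the band-wise OLS estimate; its covariance is

    C = Σ̂ · [(XᵀX)⁻¹]_{slope,slope},    Σ̂ = RᵀR/(n−2),

with R the residual matrix. The n−2 denominator matches the two-parameter
fit's degrees of freedom. Rows with any masked band are dropped whole
(complete-case), so Σ̂ is estimated on a common sample; cells with fewer
than 15 usable years (configurable) are skipped.

**3. The SNR statistic.** SNR = ‖b‖ / √(ûᵀCû) with û = b/‖b‖; zero when
b = 0, and an infinite sentinel when the projected uncertainty is at
floating-point rounding level of the trend itself (noiseless input).
Threshold ↔ confidence conversions use the two-sided standard normal
mapping, confidence = 2Φ(θ) − 1.

### Finite-sample behaviour of the SNR test (important caveat)

The normal mapping (SNR > 2 ↔ 95.45%) is asymptotic. Two finite-sample
effects inflate the null exceedance rate at n = 20 years:

* the denominator uses the *estimated* residual covariance with n−2 = 18
  degrees of freedom, so even in the univariate case the statistic is
  t₁₈-distributed under the null, giving P(SNR > 2) = 0.061 rather than
  0.0455;
* with p bands the trend direction û is itself estimated from the data, and
  in the limit of mutually independent bands the statistic behaves like a
  chi distribution with p degrees of freedom (null rate ≈ 0.93 at p = 10).
  Strong cross-band correlation — the realistic regime for reflectance —
  collapses the effective dimension back toward 1; at the generator's
  default correlation of 0.9 the measured null rate is ≈ 0.09–0.10.

Separately, the significance-gated Cochrane–Orcutt correction has limited
power at n = 20: ρ̂ from detrended residuals is biased low (measured mean
≈ 0.34 for a true ρ = 0.6), so the transform triggers in only a minority
of truly autocorrelated cells and under-corrects where it does. The
package therefore reports prewhitened null rates that remain above the
white-noise rate under strong AR(1) noise; prewhitening reduces, but does
not remove, the inflation at this record length. These are properties of
the method itself, reproduced faithfully; the acceptance script reports
the measured rates so they can be inspected rather than assumed.

## Time of emergence

For a control/forced pair, the forced run is regressed over its *full*
length with the same prewhitening as the observational pipeline. Where the
forced trend is significant (SNR above the threshold, default 2), the cell
emerges at

    ToE = 2σ/‖b‖,

where σ is the control run's interannual standard deviation. The formula
is scalar; for multiband reflectance σ is taken as the standard deviation
(denominator n−1) of the control annual means *projected onto the forced
unit trend vector* û — the natural multivariate analogue, consistent with
how the SNR projects the trend covariance. A per-band scalar mode is
available by running single-band slices (`band_toe_maps`). Optional linear
detrending of the control series is off by default, since control drift is
expected to be negligible; a flag enables it. Non-significant cells carry
a NaN sentinel plus an `emerged = False` flag, distinct from cells that
could not be analysed at all (`valid = False`). The ToE cumulative
distribution weights cells by cos(latitude) over all analysable cells;
sentinel cells count toward the area but never emerge, so the curve is
bounded by the emerged-area fraction, and the area-weighted median is NaN
when less than half the area ever emerges (at exactly half, the lower
quantile convention applies).

## The synthetic generator

The generator draws, per cell, exactly the model the detector assumes:
y_t = a + b t + e_t with e_t = ρ e_{t−1} + η_t, η_t ~ N(0, Σ), and e_0
drawn from the stationary distribution (covariance Σ/(1−ρ²)) so there is
no burn-in transient. Cells are independent, each seeded from a
deterministic substream of (seed, lat index, lon index), making scenes
bit-reproducible and individual cells reconstructible.

Defaults, chosen once to represent a 20-year, 10-band global study:

| parameter | default | rationale |
|---|---|---|
| grid | 10 × 20 cells | desk-scale stand-in for a 2° global grid |
| n_years | 20 | two decades of annual means |
| band_centers | 412…678 nm (10 bands) | the standard ocean-colour band set |
| intercepts | 8.0→0.7 ×10⁻³ sr⁻¹ | typical oligotrophic reflectance spectrum, blue-high |
| innovation sd | 2% of each band's intercept | weak interannual variability of large-area annual means |
| cross-band correlation | 0.9 | reflectance anomalies are strongly correlated across bands; this sets the (low) effective dimension |
| ρ (AR 1) | 0.5 | produces significant lag-1 autocorrelation in roughly half the cells at n = 20, the regime the iteration rules are designed for |
| lat_variance_profile | none (optional 1 + k·|sin lat|) | mimics quiet subtropics / noisy high latitudes when enabled |
| missing_fraction | 0 | coverage gaps are opt-in; masking is completely at random, applied to whole (cell, year) entries across bands |

Climate pairs share the noise model; the control member has no imposed
trend, the forced member adds a linear ramp (scalar, per-band, or
per-cell), and the two use distinct substreams so a zero ramp yields
exchangeable — not identical — members. Both runs must be ≥ 30 years.

**What the generator does not emulate:** realistic reflectance spectral
shapes beyond second-order statistics, seasonal cycles (series are
annual), spatial correlation between cells, regime shifts or
heavier-than-Gaussian tails (the noise is Gaussian; the distribution of
real interannual reflectance anomalies is not established), and
instrument artefacts such as drift or inter-sensor offsets. Passing tests
therefore demonstrate the statistical machinery is correct under its own
assumptions — not that those assumptions hold for any particular sensor
record.

## Ingest conventions

* **Annual aggregation:** 12-month windows starting in July by default
  (configurable), labelled by the starting month's calendar year. Monthly
  values are combined unweighted (not day-weighted). A year needs at least
  9 of 12 months (configurable) per cell/band, else it is masked; only
  windows fully inside the record are emitted.
* **Spatial rebinning:** integer block factors only (lat and lon factors
  may differ); coarse cells are cos(latitude)-weighted means of unmasked
  fine cells and are masked only when every contributor is masked, which
  maximises coverage in the spirit of level-3 compositing.
* **Spectral interpolation:** piecewise linear, exact at grid nodes, with
  a hard error on any band centre outside the wavelength span — no silent
  extrapolation.
* **Coordinates:** cell-centre latitudes/longitudes, longitude in
  [−180, 180); NetCDF I/O uses the classic format with CF-style coordinate
  variables, a NaN fill plus an explicit mask variable, and the generator
  configuration serialised into a global attribute for provenance.

## Numerical choices and degenerate inputs

* Time regressors are mean-centred before fitting; slopes are unchanged.
* PSD checks on noise covariances tolerate eigenvalues down to −1e−10
  relative; the covariance factor clips tiny negative eigenvalues to zero,
  so exactly singular (including zero) covariances are valid generator
  inputs.
* A residual series with no variance after centring yields ρ̂ = NaN
  ("insufficient signal"), which is treated as non-significant.
* `snr` returns +inf when ûᵀCû ≤ (10⁻¹² ‖b‖)², flagging noiseless fits
  rather than overflowing.
* Fractions in text reports are printed to two significant digits; the
  JSON report keeps full precision.

## Problem sizes used in the shipped checks

The test suite and acceptance script run entirely on generated data at
sizes chosen to make Monte-Carlo error small relative to each tolerance:
2000-cell null scenes for calibration rates; 20 000 replicate fits for the
slope-covariance and slope-recovery checks (with a 6000-draw residual
bootstrap, rescaled by √(n/(n−2)), as the nonparametric cross-check); and
an 8 × 12 grid with 106 forced / 100 control years for time-of-emergence
recovery against the generator's closed form 2σ/‖b‖.

## Known limitations

* No higher-order AR models and no Prais–Winsten rescue of the first
  observation; each Cochrane–Orcutt pass simply drops one time step.
* No spatial autocorrelation correction: cells are tested independently,
  so neighbouring false positives cluster.
* The threshold↔confidence mapping is asymptotic-normal by design (see
  caveat above); users needing calibrated finite-sample p-values should
  simulate the null with the generator at their record length.
* The univariate comparison path consumes chlorophyll-like inputs as
  given; no retrieval algorithm is included.
* A thin reader for pre-gridded level-3-style NetCDF is provided, but no
  download client and no native-resolution (4 km) processing.
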