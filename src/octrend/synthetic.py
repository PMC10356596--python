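"""Synthetic multiband time-series generator.

Generates reflectance cubes with the statistical structure the trend
analysis assumes: a per-band linear trend plus stationary multivariate AR(1)
interannual noise with cross-waveband correlation, an optional
latitude-dependent noise amplitude, and a missing-data mask.  Century-scale
control/forced pairs for the emergence analysis share the same noise model;
the forced member simply adds a linear per-band ramp.

The generative model per grid cell is the exact inverse of the regression
model fitted downstream:

    y_t = a + b * t + e_t,      e_t = rho * e_{t-1} + eta_t,
    eta_t ~ N(0, Sigma),        e_0 ~ N(0, Sigma / (1 - rho^2)),

so the series is stationary from the first year (no burn-in transient).
Every cell draws from its own deterministic substream of the global seed,
making cells independent and individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .cube import MODIS_BANDS, SpectralCube
from .errors import ConfigurationError

__all__ = [
    "SynthConfig",
    "default_config",
    "banded_noise_cov",
    "sin_lat_profile",
    "generate_cell_series",
    "generate_scene",
    "generate_climate_pair",
]


def banded_noise_cov(stds, corr: float = 0.9) -> np.ndarray:
    """Innovation covariance with a common cross-band correlation.

    Ocean-colour reflectance anomalies are strongly correlated between
    wavebands, which is what makes the effective dimension of the
    measurement much smaller than the number of bands; ``corr`` controls
    that structure.  ``stds`` are the per-band innovation standard
    deviations (sr^-1).
    """
    s = np.asarray(stds, dtype=float)
    p = s.size
    R = np.full((p, p), float(corr))
    np.fill_diagonal(R, 1.0)
    return np.outer(s, s) * R


def sin_lat_profile(k: float = 0.5) -> Callable[[np.ndarray], np.ndarray]:
    """Noise-amplitude factor 1 + k*|sin(lat)|.

    Mimics the observed pattern of weak interannual variability in the
    subtropics and strong variability at high latitudes.
    """

    def profile(lat: np.ndarray) -> np.ndarray:
        return 1.0 + k * np.abs(np.sin(np.deg2rad(lat)))

    return profile


# Typical oligotrophic R_rs spectrum (sr^-1) at the 10 MODIS bands: high in
# the blue, decaying toward the red.
_DEFAULT_INTERCEPTS = np.array(
    [8.0, 7.0, 6.0, 5.5, 4.0, 3.5, 3.3, 1.0, 0.8, 0.7]
) * 1e-3


@dataclass
class SynthConfig:
    """Full parameterisation of the synthetic generator.

    ``trends`` may be a per-band vector (uniform over the grid) or a full
    (n_lat, n_lon, n_bands) array.  ``lat_variance_profile`` multiplies the
    noise *standard deviation* as a function of latitude.
    """

    n_lat: int = 10
    n_lon: int = 20
    n_years: int = 20
    band_centers: np.ndarray = field(default_factory=lambda: np.array(MODIS_BANDS))
    intercepts: np.ndarray = field(default_factory=lambda: _DEFAULT_INTERCEPTS.copy())
    trends: np.ndarray | None = None
    noise_cov: np.ndarray | None = None
    ar1_coeff: float = 0.5
    lat_variance_profile: Callable[[np.ndarray], np.ndarray] | None = None
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.band_centers = np.asarray(self.band_centers, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if self.trends is None:
            self.trends = np.zeros(self.band_centers.size)
        self.trends = np.asarray(self.trends, dtype=float)
        if self.noise_cov is None:
            # default: innovation sd = 2% of the band intercept, corr 0.9
            self.noise_cov = banded_noise_cov(0.02 * np.abs(self.intercepts), 0.9)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        p = self.band_centers.size
        if self.band_centers.size > 1 and not np.all(np.diff(self.band_centers) > 0):
            raise ConfigurationError("band_centers must be strictly increasing")
        if self.intercepts.shape != (p,):
            raise ConfigurationError("intercepts must have one entry per band")
        if self.trends.shape not in ((p,), (self.n_lat, self.n_lon, p)):
            raise ConfigurationError(
                "trends must be per-band or (n_lat, n_lon, n_bands)"
            )
        _check_cov(self.noise_cov, p)
        if not abs(self.ar1_coeff) < 1:
            raise ConfigurationError("|ar1_coeff| must be < 1")
        if self.n_years < 3:
            raise ConfigurationError("n_years must be >= 3")
        if not 0 <= self.missing_fraction < 1:
            raise ConfigurationError("missing_fraction must be in [0, 1)")

    @property
    def n_bands(self) -> int:
        return self.band_centers.size

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Regular global cell-centre grid for (n_lat, n_lon)."""
        dlat = 180.0 / self.n_lat
        dlon = 360.0 / self.n_lon
        lat = -90.0 + dlat * (np.arange(self.n_lat) + 0.5)
        lon = -180.0 + dlon * (np.arange(self.n_lon) + 0.5)
        return lat, lon

    def cell_trends(self, i: int, j: int) -> np.ndarray:
        if self.trends.ndim == 3:
            return self.trends[i, j]
        return self.trends

    def to_dict(self) -> dict:
        """Plain-text-serialisable echo of the configuration (provenance)."""
        prof = self.lat_variance_profile
        return {
            "n_lat": self.n_lat,
            "n_lon": self.n_lon,
            "n_years": self.n_years,
            "band_centers": self.band_centers.tolist(),
            "intercepts": self.intercepts.tolist(),
            "trends": self.trends.tolist(),
            "noise_cov": self.noise_cov.tolist(),
            "ar1_coeff": self.ar1_coeff,
            "lat_variance_profile": "none" if prof is None else getattr(prof, "__name__", "custom"),
            "missing_fraction": self.missing_fraction,
            "seed": self.seed,
        }


def default_config(**overrides) -> SynthConfig:
    """The 20-year, 10-band study configuration with optional overrides."""
    return SynthConfig(**overrides)


def _check_cov(cov: np.ndarray, p: int) -> None:
    if cov.shape != (p, p):
        raise ConfigurationError(f"noise covariance must be {p}x{p}")
    if not np.allclose(cov, cov.T, atol=1e-12):
        raise ConfigurationError("noise covariance must be symmetric")
    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-10 * max(1.0, w.max()):
        raise ConfigurationError("noise covariance must be positive semi-definite")


def _cov_factor(cov: np.ndarray) -> np.ndarray:
    """Factor L with L L' = cov, valid for semi-definite cov (zero allowed)."""
    w, V = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def generate_cell_series(
    intercepts,
    trends,
    noise_cov,
    ar1_coeff: float,
    n_years: int,
    seed,
) -> np.ndarray:
    """Draw one cell's (n_years, n_bands) series of trend + AR(1) noise.

    ``seed`` may be an integer or a :class:`numpy.random.SeedSequence` /
    :class:`numpy.random.Generator`; the output is reproducible for a fixed
    seed.  The AR(1) error starts from its stationary distribution, whose
    covariance is ``noise_cov / (1 - ar1_coeff**2)``.
    """
    a = np.asarray(intercepts, dtype=float)
    b = np.asarray(trends, dtype=float)
    cov = np.asarray(noise_cov, dtype=float)
    p = a.size
    _check_cov(cov, p)
    if not abs(ar1_coeff) < 1:
        raise ConfigurationError("|ar1_coeff| must be < 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    L = _cov_factor(cov)
    eta = rng.standard_normal((n_years, p)) @ L.T
    eps = np.empty((n_years, p))
    eps[0] = eta[0] / np.sqrt(1.0 - ar1_coeff**2)
    for t in range(1, n_years):
        eps[t] = ar1_coeff * eps[t - 1] + eta[t]
    t_axis = np.arange(n_years)[:, None]
    return a + b * t_axis + eps


def _cell_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def generate_scene(config: SynthConfig) -> SpectralCube:
    """Generate a full synthetic scene from a :class:`SynthConfig`.

    Cells are independent, each drawn from a substream keyed on
    (seed, lat index, lon index).  The latitude profile scales the noise
    standard deviation; ``missing_fraction`` of (cell, year) entries are
    masked completely at random across all bands, emulating satellite
    coverage gaps.
    """
    lat, lon = config.grid()
    amp = np.ones(config.n_lat)
    if config.lat_variance_profile is not None:
        amp = np.asarray(config.lat_variance_profile(lat), dtype=float)
    values = np.empty((config.n_lat, config.n_lon, config.n_years, config.n_bands))
    for i in range(config.n_lat):
        cov_i = config.noise_cov * amp[i] ** 2
        for j in range(config.n_lon):
            values[i, j] = generate_cell_series(
                config.intercepts,
                config.cell_trends(i, j),
                cov_i,
                config.ar1_coeff,
                config.n_years,
                _cell_rng(config.seed, i, j),
            )
    mask = np.zeros(values.shape, dtype=bool)
    if config.missing_fraction > 0:
        mask_rng = _cell_rng(config.seed, 0, 0, 0)
        gaps = mask_rng.random((config.n_lat, config.n_lon, config.n_years))
        mask |= (gaps < config.missing_fraction)[..., None]
    cube = SpectralCube(
        values=values,
        lat=lat,
        lon=lon,
        time=np.arange(config.n_years),
        band=config.band_centers,
        mask=mask,
    )
    cube.attrs["source"] = "octrend synthetic generator"
    return cube


def generate_climate_pair(
    config: SynthConfig,
    trend_ramp,
    n_years_control: int,
    n_years_forced: int,
    seed: int | None = None,
) -> tuple[SpectralCube, SpectralCube]:
    """Generate a (control, forced) pair of century-scale cubes.

    The control member has no imposed trend; the forced member shares the
    noise model and adds the linear ``trend_ramp`` (sr^-1 yr^-1), given as a
    scalar, a per-band vector, or a full (n_lat, n_lon, n_bands) field.
    Both are reproducible from ``seed`` (defaults to ``config.seed``) but use
    distinct substreams, so a zero ramp gives statistically exchangeable —
    not identical — members.
    """
    if n_years_control < 30 or n_years_forced < 30:
        raise ConfigurationError("control and forced runs need at least 30 years")
    seed = config.seed if seed is None else seed
    ramp = np.asarray(trend_ramp, dtype=float)
    if ramp.ndim == 0:
        ramp = np.full(config.n_bands, float(ramp))
    if ramp.shape not in ((config.n_bands,), (config.n_lat, config.n_lon, config.n_bands)):
        raise ConfigurationError("trend_ramp must be scalar, per-band or per-cell")
    lat, lon = config.grid()
    amp = np.ones(config.n_lat)
    if config.lat_variance_profile is not None:
        amp = np.asarray(config.lat_variance_profile(lat), dtype=float)

    def _member(member_key: int, n_years: int, trends: np.ndarray) -> SpectralCube:
        values = np.empty((config.n_lat, config.n_lon, n_years, config.n_bands))
        for i in range(config.n_lat):
            cov_i = config.noise_cov * amp[i] ** 2
            for j in range(config.n_lon):
                values[i, j] = generate_cell_series(
                    config.intercepts,
                    trends[i, j] if trends.ndim == 3 else trends,
                    cov_i,
                    config.ar1_coeff,
                    n_years,
                    _cell_rng(seed, member_key, i, j),
                )
        return SpectralCube(
            values=values,
            lat=lat,
            lon=lon,
            time=np.arange(n_years),
            band=config.band_centers,
        )

    control = _member(1, n_years_control, np.zeros(config.n_bands))
    forced = _member(2, n_years_forced, ramp)
    control.attrs["run"] = "control"
    forced.attrs["run"] = "forced"
    return control, forced
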