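"""Cochrane–Orcutt prewhitening of per-cell time series.

Serial (lag-1) autocorrelation inflates the apparent significance of a
trend by shrinking the effective sample size.  The Cochrane–Orcutt
procedure removes it by quasi-differencing: estimate the residual lag-1
coefficient rho, replace y_t by y_t - rho*y_{t-1} and transform every
design column the same way (losing the first time step), and repeat while
the residual autocorrelation remains significant.  At most two iterations
are applied to any cell; the slope of the transformed regression retains
its interpretation as the original trend.

rho is estimated from residuals of the per-band linear trend fit — not the
raw series — so trend is not conflated with autocorrelation.  By default a
single rho per cell is estimated by pooling residuals across bands after
per-band standardisation (``mode="cell"``); ``mode="band"`` estimates and
applies a separate rho per band.  Significance uses the two-sided Bartlett
large-sample bound |rho| > z_{1-alpha/2}/sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientDataError

__all__ = [
    "lag1_autocorr",
    "autocorr_significant",
    "cochrane_orcutt",
    "PrewhitenResult",
]


def lag1_autocorr(residuals) -> float:
    """Sample lag-1 autocorrelation of a residual series (mean-centred).

    Returns NaN for a degenerate series (no variance after centring);
    raises for fewer than 3 points.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 3:
        raise InsufficientDataError("need at least 3 residuals for lag-1 autocorrelation")
    c = r - r.mean()
    denom = np.dot(c, c)
    if denom <= 0:
        return np.nan
    return float(np.dot(c[:-1], c[1:]) / denom)


def autocorr_significant(rho_hat: float, n: int, alpha: float = 0.05) -> bool:
    """Two-sided Bartlett test: is |rho_hat| > z_{1-alpha/2}/sqrt(n)?"""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n < 3:
        raise InsufficientDataError("need n >= 3")
    if not np.isfinite(rho_hat):
        return False
    return abs(rho_hat) > stats.norm.ppf(1 - alpha / 2) / np.sqrt(n)


@dataclass
class PrewhitenResult:
    """Outcome of the Cochrane–Orcutt iteration for one grid cell.

    ``y`` and ``design`` are the transformed response (years x bands) and
    design matrix (years x 2, intercept and time columns); their length
    shrinks by one row per iteration.  ``converged`` is False when residual
    autocorrelation is still significant after the final iteration or a
    |rho| >= 1 estimate blocked a transform.
    """

    y: np.ndarray
    design: np.ndarray
    rho_estimates: list = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = True


def _trend_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _pooled_rho(resid: np.ndarray) -> float:
    """One rho from multiband residuals: standardise per band, then pool."""
    c = resid - resid.mean(axis=0)
    sd = c.std(axis=0)
    keep = sd > 0
    if not keep.any():
        return np.nan
    z = c[:, keep] / sd[keep]
    denom = np.sum(z * z)
    return float(np.sum(z[:-1] * z[1:]) / denom)


def cochrane_orcutt(
    Y,
    t,
    max_iter: int = 2,
    alpha: float = 0.05,
    mode: str = "cell",
) -> PrewhitenResult:
    """Iteratively prewhiten a (years x bands) series against regressor ``t``.

    Parameters
    ----------
    Y
        Response, shape (n_years,) or (n_years, n_bands); no masked rows.
    t
        Time regressor, same length as Y.
    max_iter
        Maximum quasi-differencing passes (default 2).
    alpha
        Level of the Bartlett residual-autocorrelation test.
    mode
        ``"cell"``: one pooled rho per cell (default); ``"band"``: a
        separate rho per band, each band quasi-differenced with its own
        coefficient and its own copy of the design.

    Returns a :class:`PrewhitenResult`.  In ``"band"`` mode ``design`` has
    shape (years, 2, bands) — one transformed design per band.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T  # (n, p)
    t = np.asarray(t, dtype=float)
    n, p = Y.shape
    if n < 4:
        raise InsufficientDataError("Cochrane-Orcutt needs at least 4 time steps")
    if np.isnan(Y).any():
        raise ValueError("masked rows must be dropped before prewhitening")
    X = np.column_stack([np.ones(n), t])

    if mode == "cell":
        return _co_common(Y, X, max_iter, alpha)
    if mode == "band":
        return _co_per_band(Y, X, max_iter, alpha)
    raise ValueError(f"unknown mode {mode!r}")


def _co_common(Y, X, max_iter, alpha):
    rhos: list = []
    converged = True
    it = 0
    while True:
        resid = _trend_residuals(Y, X)
        rho = _pooled_rho(resid)
        significant = autocorr_significant(rho, len(Y), alpha) if np.isfinite(rho) else False
        if not significant or it >= max_iter:
            converged = not significant
            break
        if abs(rho) >= 1:  # cannot quasi-difference; flag and stop
            converged = False
            break
        rhos.append(rho)
        Y = Y[1:] - rho * Y[:-1]
        X = X[1:] - rho * X[:-1]
        it += 1
    return PrewhitenResult(y=Y, design=X, rho_estimates=rhos, n_iterations=it, converged=converged)


def _co_per_band(Y, X, max_iter, alpha):
    n, p = Y.shape
    ys, designs, all_rhos = [], [], []
    n_it_max = 0
    converged = True
    for j in range(p):
        res_j = _co_common(Y[:, [j]], X, max_iter, alpha)
        ys.append(res_j.y[:, 0])
        designs.append(res_j.design)
        all_rhos.append(res_j.rho_estimates)
        n_it_max = max(n_it_max, res_j.n_iterations)
        converged &= res_j.converged
    # truncate every band to the shortest transformed length so the cell
    # keeps a rectangular response
    m = min(len(y) for y in ys)
    y_out = np.column_stack([y[-m:] for y in ys])
    design_out = np.stack([d[-m:] for d in designs], axis=-1)  # (m, 2, p)
    return PrewhitenResult(
        y=y_out,
        design=design_out,
        rho_estimates=all_rhos,
        n_iterations=n_it_max,
        converged=converged,
    )
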