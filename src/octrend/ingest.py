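"""Reading, temporal/spatial aggregation and spectral interpolation.

Covers the preprocessing that turns gridded monthly level-3 style input
into the annual, coarse-resolution cubes the trend analysis consumes:

* :func:`aggregate_annual` — July–June (or any start month) annual means;
* :func:`rebin_spatial` — block-average to coarser resolution with
  cosine-of-latitude weighting;
* :func:`interpolate_spectrum` — linear interpolation of model reflectance
  spectra to sensor band centres;
* :func:`read_cube` / :func:`write_cube` — NetCDF round trip.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import interp1d

from .cube import SpectralCube
from .errors import ExtrapolationError, FormatError, GeometryError, InsufficientDataError

__all__ = [
    "aggregate_annual",
    "rebin_spatial",
    "interpolate_spectrum",
    "interpolate_cube_spectrum",
    "read_cube",
    "write_cube",
]


def aggregate_annual(
    cube: SpectralCube, year_start_month: int = 7, min_months: int = 9
) -> SpectralCube:
    """Aggregate a monthly cube into 12-month years starting at a given month.

    Each output year is the unweighted mean of the available (unmasked)
    monthly values in the window [start month, start month + 11]; a year is
    masked per cell/band when fewer than ``min_months`` months contribute.
    The output year label is the calendar year of the starting month, so the
    July 2002 – June 2003 window is labelled 2002.
    """
    times = pd.DatetimeIndex(cube.time)
    years = times.year.to_numpy()
    months = times.month.to_numpy()
    # label = calendar year of the window's starting month
    labels = np.where(months >= year_start_month, years, years - 1)

    # keep only labels whose full 12-month window lies inside the record
    start = times.min()
    end = times.max()
    out_labels = []
    for lab in np.unique(labels):
        w0 = pd.Timestamp(year=lab, month=year_start_month, day=1)
        w1 = w0 + pd.DateOffset(months=11)
        if w0 >= start.replace(day=1) and w1 <= end.replace(day=1):
            out_labels.append(lab)
    if not out_labels:
        raise InsufficientDataError("no complete 12-month aggregation year in record")
    out_labels = np.asarray(out_labels)

    n_lat, n_lon, _, n_band = cube.shape
    values = np.full((n_lat, n_lon, out_labels.size, n_band), np.nan)
    counts = np.zeros((n_lat, n_lon, out_labels.size, n_band), dtype=int)
    for k, lab in enumerate(out_labels):
        sel = labels == lab
        chunk = cube.values[:, :, sel, :]
        good = ~np.isnan(chunk)
        cnt = good.sum(axis=2)
        counts[:, :, k, :] = cnt
        sums = np.where(good, chunk, 0.0).sum(axis=2)
        values[:, :, k, :] = np.divide(sums, cnt, out=np.full(cnt.shape, np.nan),
                                       where=cnt > 0)
    mask = counts < min_months
    values[mask] = np.nan
    return SpectralCube(
        values=values,
        lat=cube.lat,
        lon=cube.lon,
        time=out_labels,
        band=cube.band,
        mask=mask,
        attrs={**cube.attrs, "aggregation": f"annual, start month {year_start_month}"},
    )


def rebin_spatial(cube: SpectralCube, factor) -> SpectralCube:
    """Block-average a cube to a coarser grid by an integer factor.

    Each coarse cell is the cosine-of-latitude-weighted mean of its unmasked
    fine cells; it is masked only when every contributor is masked.  The
    coarse grid must nest exactly (grid dimensions divisible by the factor);
    ``factor`` may be a single integer or a (lat, lon) pair.
    """
    try:
        f_lat, f_lon = (int(factor[0]), int(factor[1]))
    except TypeError:
        f_lat = f_lon = int(factor)
    if f_lat < 1 or f_lon < 1:
        raise GeometryError("rebin factor must be a positive integer")
    n_lat, n_lon, n_time, n_band = cube.shape
    if n_lat % f_lat or n_lon % f_lon:
        raise GeometryError(
            f"grid {n_lat}x{n_lon} does not nest into blocks of {f_lat}x{f_lon}"
        )
    w = np.cos(np.deg2rad(cube.lat))[:, None, None, None]
    vals = cube.values
    good = ~cube.mask
    wv = np.where(good, w * np.nan_to_num(vals), 0.0)
    ww = np.where(good, w * np.ones_like(vals), 0.0)

    def blocks(a):
        return a.reshape(n_lat // f_lat, f_lat, n_lon // f_lon, f_lon, n_time, n_band)

    num = blocks(wv).sum(axis=(1, 3))
    den = blocks(ww).sum(axis=(1, 3))
    out_mask = den == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(out_mask, np.nan, num / np.where(den == 0, 1.0, den))
    lat = cube.lat.reshape(-1, f_lat).mean(axis=1)
    lon = cube.lon.reshape(-1, f_lon).mean(axis=1)
    return SpectralCube(
        values=out,
        lat=lat,
        lon=lon,
        time=cube.time,
        band=cube.band,
        mask=out_mask,
        attrs=dict(cube.attrs),
    )


def interpolate_spectrum(values, wavelengths, band_centers) -> np.ndarray:
    """Linearly interpolate spectra to sensor band centres.

    ``values`` has wavelength on its last axis (a single spectrum or any
    stack of spectra, e.g. a model cube at 25-nm resolution from
    400–700 nm).  Interpolation is piecewise linear and exact at grid
    nodes; a band centre outside the wavelength span raises — there is no
    silent extrapolation.
    """
    wl = np.asarray(wavelengths, dtype=float)
    bc = np.asarray(band_centers, dtype=float)
    if bc.min() < wl.min() or bc.max() > wl.max():
        raise ExtrapolationError(
            f"band centres {bc.min()}–{bc.max()} nm outside wavelength span "
            f"{wl.min()}–{wl.max()} nm"
        )
    f = interp1d(wl, np.asarray(values, dtype=float), axis=-1, assume_sorted=True)
    return f(bc)


def interpolate_cube_spectrum(cube: SpectralCube, band_centers) -> SpectralCube:
    """Interpolate a model cube's wavelength axis to sensor band centres."""
    out = interpolate_spectrum(cube.values, cube.band, band_centers)
    return SpectralCube(
        values=out,
        lat=cube.lat,
        lon=cube.lon,
        time=cube.time,
        band=np.asarray(band_centers, dtype=float),
        attrs=dict(cube.attrs),
    )


def write_cube(cube: SpectralCube, path) -> None:
    """Write a cube to NetCDF (classic format, CF-style coordinates)."""
    ds = cube.to_dataset()
    ds.to_netcdf(path, engine="scipy", format="NETCDF3_CLASSIC")


def read_cube(path, var: str = "rrs") -> SpectralCube:
    """Read a cube written by :func:`write_cube` (or any conforming file)."""
    try:
        ds = xr.open_dataset(path, engine="scipy")
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read NetCDF file {path}: {exc}") from exc
    with ds:
        return SpectralCube.from_dataset(ds.load(), var=var)
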