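"""The in-memory container for gridded multiband reflectance time series.

A :class:`SpectralCube` holds remote-sensing reflectance R_rs (sr^-1) on a
regular latitude-longitude grid, indexed (lat, lon, time, band).  Missing
observations are carried both as NaN in ``values`` and as ``True`` in the
boolean ``mask``; the two are kept consistent by the constructor.

Cubes convert losslessly to and from :class:`xarray.Dataset`, which is also
the on-disk representation (NetCDF, written with CF-style coordinate
variables by :mod:`octrend.ingest`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .errors import FormatError

__all__ = ["SpectralCube", "MODIS_BANDS"]

#: Centre wavelengths (nm) of the 10 MODIS-Aqua ocean-colour wavebands.
MODIS_BANDS = (412.0, 443.0, 469.0, 488.0, 531.0, 547.0, 555.0, 645.0, 667.0, 678.0)

_DIMS = ("lat", "lon", "time", "band")


@dataclass
class SpectralCube:
    """Gridded (lat, lon, time, band) reflectance with a missing-data mask.

    Parameters
    ----------
    values
        Reflectance (sr^-1), shape (n_lat, n_lon, n_time, n_bands); NaN where
        masked.
    lat, lon
        Cell-centre coordinates in degrees; lat must lie in [-90, 90].
    time
        Time coordinate: integer year labels for annual cubes, or
        ``datetime64`` month stamps for monthly cubes.
    band
        Band-centre wavelengths in nm, strictly increasing.
    mask
        Boolean missing-data indicator, same shape as ``values``.  If omitted
        it is derived from NaNs in ``values``.
    attrs
        Free-form provenance attributes propagated to NetCDF.
    """

    values: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    time: np.ndarray
    band: np.ndarray
    mask: np.ndarray | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.time = np.asarray(self.time)
        self.band = np.asarray(self.band, dtype=float)
        expected = (self.lat.size, self.lon.size, self.time.size, self.band.size)
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match coordinates {expected}"
            )
        if self.lat.size and (self.lat.min() < -90 or self.lat.max() > 90):
            raise ValueError("latitudes must lie in [-90, 90]")
        if self.band.size > 1 and not np.all(np.diff(self.band) > 0):
            raise ValueError("band centres must be strictly increasing")
        if self.mask is None:
            self.mask = np.isnan(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")
            self.values = np.where(self.mask, np.nan, self.values)

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.band.size

    def series(self, i: int, j: int) -> np.ndarray:
        """Return the (time, band) series of cell (i, j), NaN where masked."""
        return self.values[i, j]

    def select_bands(self, bands) -> "SpectralCube":
        """Subset to the given band centres (nm)."""
        idx = [int(np.argmin(np.abs(self.band - b))) for b in np.atleast_1d(bands)]
        return SpectralCube(
            values=self.values[..., idx],
            lat=self.lat,
            lon=self.lon,
            time=self.time,
            band=self.band[idx],
            mask=self.mask[..., idx],
            attrs=dict(self.attrs),
        )

    # -- xarray interchange ---------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        coords = {"lat": self.lat, "lon": self.lon, "time": self.time, "band": self.band}
        ds = xr.Dataset(
            {
                "rrs": (_DIMS, self.values),
                "mask": (_DIMS, self.mask.astype(np.int8)),
            },
            coords=coords,
            attrs=dict(self.attrs),
        )
        ds["rrs"].attrs["units"] = "sr-1"
        ds["rrs"].attrs["long_name"] = "remote-sensing reflectance"
        ds["lat"].attrs.update(units="degrees_north", standard_name="latitude")
        ds["lon"].attrs.update(units="degrees_east", standard_name="longitude")
        ds["band"].attrs.update(units="nm", long_name="band centre wavelength")
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset, var: str = "rrs") -> "SpectralCube":
        for coord in _DIMS:
            if coord not in ds.coords:
                raise FormatError(f"dataset lacks required coordinate '{coord}'")
        if var not in ds:
            raise FormatError(f"dataset lacks data variable '{var}'")
        da = ds[var].transpose(*_DIMS)
        values = np.asarray(da.values, dtype=float)
        if "mask" in ds:
            mask = np.asarray(ds["mask"].transpose(*_DIMS).values).astype(bool)
        else:
            mask = np.isnan(values)
        return cls(
            values=values,
            lat=np.asarray(ds["lat"].values, dtype=float),
            lon=np.asarray(ds["lon"].values, dtype=float),
            time=np.asarray(ds["time"].values),
            band=np.asarray(ds["band"].values, dtype=float),
            mask=mask,
            attrs=dict(ds.attrs),
        )
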