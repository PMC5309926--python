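"""Analysis grid, 5-year period scheme and gridded-field container.

The analysis domain is the North-East Atlantic and North Sea box 45–64° N,
20° W–8° E.  All kriged fields (log abundance and SST) live on a fixed
0.5° × 0.5° grid whose cell centres sit at the quarter-degree points
(45.25 … 63.75° N, −19.75 … 7.75° E); the domain edges are cell boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

#: km per degree of latitude used for all displacement arithmetic
#: (10° of latitude ≈ 1,110 km).
KM_PER_DEG_LAT = 111.0


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon analysis grid with half-open cells ``[lo, hi)``."""

    lat_min: float = 45.0
    lat_max: float = 64.0
    lon_min: float = -20.0
    lon_max: float = 8.0
    cell: float = 0.5

    @property
    def lat_centers(self) -> np.ndarray:
        n = int(round((self.lat_max - self.lat_min) / self.cell))
        return self.lat_min + self.cell * (np.arange(n) + 0.5)

    @property
    def lon_centers(self) -> np.ndarray:
        n = int(round((self.lon_max - self.lon_min) / self.cell))
        return self.lon_min + self.cell * (np.arange(n) + 0.5)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.lat_centers), len(self.lon_centers)

    @property
    def center_lat(self) -> float:
        return 0.5 * (self.lat_min + self.lat_max)

    @property
    def center_lon(self) -> float:
        return 0.5 * (self.lon_min + self.lon_max)

    def contains(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the (half-open) domain box."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        return (
            (lat >= self.lat_min)
            & (lat < self.lat_max)
            & (lon >= self.lon_min)
            & (lon < self.lon_max)
        )

    def project(self, lat, lon) -> tuple[np.ndarray, np.ndarray]:
        """Local equirectangular projection about the domain centre, in km.

        1° latitude = 111.0 km; 1° longitude = 111.0·cos(centre latitude) km.
        Adequate at this domain extent (< 20° of latitude).
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        kx = KM_PER_DEG_LAT * np.cos(np.deg2rad(self.center_lat))
        return (lon - self.center_lon) * kx, (lat - self.center_lat) * KM_PER_DEG_LAT

    def cell_xy_km(self) -> np.ndarray:
        """Projected (x, y) of every cell centre, shape (nlat·nlon, 2), C order."""
        glat, glon = np.meshgrid(self.lat_centers, self.lon_centers, indexing="ij")
        x, y = self.project(glat.ravel(), glon.ravel())
        return np.column_stack([x, y])


@dataclass(frozen=True, order=True)
class PeriodIndex:
    """One 5-year analysis period, e.g. 1954–1958."""

    start_year: int
    end_year: int

    @property
    def label(self) -> str:
        return f"{self.start_year}-{self.end_year}"

    @property
    def mid_year(self) -> float:
        return 0.5 * (self.start_year + self.end_year + 1)

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @classmethod
    def from_label(cls, label: str) -> "PeriodIndex":
        a, b = label.split("-")
        return cls(int(a), int(b))


def standard_periods(start: int = 1954, end: int = 2013, length: int = 5) -> list[PeriodIndex]:
    """The twelve 5-year periods 1954–1958, 1959–1963, …, 2009–2013."""
    return [PeriodIndex(y, y + length - 1) for y in range(start, end, length)]


def period_of_year(year: int, periods: Iterable[PeriodIndex]) -> PeriodIndex | None:
    for p in periods:
        if p.start_year <= year <= p.end_year:
            return p
    return None


@dataclass
class PeriodGrid:
    """A kriged field (log abundance or SST in °C) for one period on the grid.

    ``values`` has shape ``grid.shape`` (lat rows south→north, lon columns
    west→east); missing cells are NaN.  ``months_used`` records how many
    monthly fields contributed when the grid is a 5-yearly mean.
    """

    grid: GridSpec
    values: np.ndarray
    period: PeriodIndex | None = None
    month: int | None = None
    months_used: int = 1
    kind: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: period, lat, lon, value."""
        glat, glon = np.meshgrid(self.grid.lat_centers, self.grid.lon_centers, indexing="ij")
        return pd.DataFrame(
            {
                "period": self.period.label if self.period else "",
                "lat": glat.ravel(),
                "lon": glon.ravel(),
                "value": self.values.ravel(),
            }
        )

    def to_dataarray(self):
        """xarray export (dims lat, lon) for NetCDF serialization."""
        import xarray as xr

        da = xr.DataArray(
            self.values,
            coords={"lat": self.grid.lat_centers, "lon": self.grid.lon_centers},
            dims=("lat", "lon"),
            name=self.kind or "value",
        )
        if self.period is not None:
            da = da.assign_attrs(period=self.period.label)
        return da


def grids_to_frame(grids: dict[PeriodIndex, PeriodGrid]) -> pd.DataFrame:
    """Stack per-period grids into one long table (period, lat, lon, value)."""
    return pd.concat([g.to_frame() for _, g in sorted(grids.items())], ignore_index=True)


def frame_to_grids(df: pd.DataFrame, grid: GridSpec, kind: str = "") -> dict[PeriodIndex, PeriodGrid]:
    """Inverse of :func:`grids_to_frame`; NaN-safe round trip."""
    out: dict[PeriodIndex, PeriodGrid] = {}
    nlat, nlon = grid.shape
    lat_idx = {round(v, 4): i for i, v in enumerate(grid.lat_centers)}
    lon_idx = {round(v, 4): i for i, v in enumerate(grid.lon_centers)}
    for label, sub in df.groupby("period", sort=True):
        values = np.full((nlat, nlon), np.nan)
        ii = sub["lat"].round(4).map(lat_idx).to_numpy()
        jj = sub["lon"].round(4).map(lon_idx).to_numpy()
        values[ii, jj] = sub["value"].to_numpy()
        out[PeriodIndex.from_label(str(label))] = PeriodGrid(
            grid=grid, values=values, period=PeriodIndex.from_label(str(label)), kind=kind
        )
    return out
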