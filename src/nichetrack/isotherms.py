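"""Isotherm latitude tracking from kriged SST fields.

For each 0.5° longitude column of a 5-yearly SST field a polynomial (cubic
by default) of SST on latitude is fitted and solved for the latitudes where
it equals the target temperature (11, 12 or 13 °C by default).  Because a
polynomial can cross a level several times, only crossings where the fitted
SST decreases northwards are kept — the physically meaningful thermal front
— and the median of the remaining candidates is taken.  The per-period mean
isotherm latitude is the arithmetic mean over longitudes with a crossing;
its change through time is the velocity of climate change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import PeriodGrid, PeriodIndex


@dataclass
class IsothermTrack:
    """Per-longitude latitude of one isotherm in one period (NaN = missing)."""

    temp: float
    period: PeriodIndex | None
    lons: np.ndarray
    lats: np.ndarray

    @property
    def mean_latitude(self) -> float:
        return mean_isotherm_latitude(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temp": self.temp,
                "period": self.period.label if self.period else "",
                "longitude": self.lons,
                "latitude": self.lats,
            }
        )


def _column_crossing(
    lat: np.ndarray, sst: np.ndarray, temp: float, degree: int
) -> float:
    """Crossing latitude for one longitude column, NaN if none."""
    valid = np.isfinite(sst)
    n = int(valid.sum())
    if n < 2:
        return np.nan
    deg = min(degree, n - 1)
    x, y = lat[valid], sst[valid]
    poly = np.polynomial.Polynomial.fit(x, y, deg)
    roots = (poly - temp).roots()
    real = roots[np.abs(roots.imag) < 1e-8].real
    span_lo, span_hi = x.min(), x.max()
    real = real[(real >= span_lo) & (real <= span_hi)]
    if real.size == 0:
        return np.nan
    deriv = poly.deriv()
    falling = real[deriv(real) < 0]  # SST decreasing northwards
    if falling.size == 0:
        return np.nan
    return float(np.median(falling))


def isotherm_latitude(
    sst_grid: PeriodGrid, temp: float, degree: int = 3
) -> IsothermTrack:
    """Locate the `temp` isotherm at each longitude column of an SST field.

    Columns with fewer than ``degree + 3`` valid cells fall back to a lower
    polynomial degree; columns with no admissible crossing are missing.
    Raises when every column is missing (isotherm outside the domain).
    """
    lat = sst_grid.grid.lat_centers
    lons = sst_grid.grid.lon_centers
    lats = np.empty(len(lons))
    for j in range(len(lons)):
        col = sst_grid.values[:, j]
        deg = degree if np.isfinite(col).sum() >= 6 else degree - 1
        lats[j] = _column_crossing(lat, col, temp, max(deg, 1))
    if not np.any(np.isfinite(lats)):
        raise ValueError(
            f"isotherm {temp} degC not found at any longitude in period "
            f"{sst_grid.period.label if sst_grid.period else '?'}"
        )
    return IsothermTrack(temp=temp, period=sst_grid.period, lons=lons, lats=lats)


def mean_isotherm_latitude(track: IsothermTrack) -> float:
    """Arithmetic mean of the non-missing per-longitude isotherm latitudes."""
    finite = np.isfinite(track.lats)
    if not finite.any():
        raise ValueError("isotherm track has no non-missing columns")
    return float(np.mean(track.lats[finite]))


def isotherm_tracks(
    sst_fields: dict[PeriodIndex, PeriodGrid],
    temps: tuple[float, ...] = (11.0, 12.0, 13.0),
    degree: int = 3,
) -> dict[float, dict[PeriodIndex, IsothermTrack]]:
    """All isotherm tracks: temperature → period → track."""
    return {
        temp: {
            period: isotherm_latitude(field, temp, degree=degree)
            for period, field in sorted(sst_fields.items())
        }
        for temp in temps
    }
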