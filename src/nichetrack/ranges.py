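"""Range metrics: percent north of an isotherm, median range latitude,
population index, displacements and per-decade velocities.

All mass-weighted statistics operate on the kriged log(n+1) abundance field,
so they are invariant to positive rescaling of the transformed values (and
hence to the logarithm base).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import KM_PER_DEG_LAT, PeriodGrid, PeriodIndex
from .isotherms import IsothermTrack


def percent_north(field: PeriodGrid, track: IsothermTrack) -> float:
    """Percentage of the field's mass north of the isotherm track.

    Column by column (0.5° longitude), cells wholly north of the isotherm
    latitude count fully; the cell containing the isotherm is split linearly
    by the fraction of the cell north of it.  Columns where the isotherm is
    missing are excluded from both numerator and denominator.
    """
    lat = field.grid.lat_centers
    half = field.grid.cell / 2.0
    values = field.values
    north_mass = 0.0
    total_mass = 0.0
    any_col = False
    for j, iso_lat in enumerate(track.lats):
        if not np.isfinite(iso_lat):
            continue
        col = values[:, j]
        ok = np.isfinite(col)
        if not ok.any():
            continue
        any_col = True
        frac_north = np.clip((lat + half - iso_lat) / field.grid.cell, 0.0, 1.0)
        north_mass += float(np.sum(col[ok] * frac_north[ok]))
        total_mass += float(np.sum(col[ok]))
    if not any_col:
        raise ValueError("percent_north: no usable longitude columns")
    if total_mass <= 0:
        raise ValueError("percent_north: total field mass is zero")
    return 100.0 * north_mass / total_mass


def zscore_series(x) -> np.ndarray:
    """(x − mean) / sd with the sample sd (n − 1 denominator)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("zscore_series needs at least 2 values")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("zscore_series: constant series (sd = 0)")
    return (x - np.mean(x)) / sd


def median_range_latitude(field: PeriodGrid) -> float:
    """Latitude splitting the field's mass into equal southern/northern halves.

    Row totals are accumulated south→north and the 50% point is located by
    linear interpolation within the crossing row's cell.
    """
    row_mass = np.nansum(np.where(np.isfinite(field.values), field.values, 0.0), axis=1)
    total = row_mass.sum()
    if total <= 0:
        raise ValueError("median_range_latitude: total field mass is zero")
    half = field.grid.cell / 2.0
    cum = np.cumsum(row_mass)
    target = 0.5 * total
    i = int(np.searchsorted(cum, target))
    cum_before = cum[i - 1] if i > 0 else 0.0
    lat_lo = field.grid.lat_centers[i] - half
    if row_mass[i] <= 0:  # pragma: no cover - searchsorted lands on massive rows
        return float(lat_lo)
    return float(lat_lo + field.grid.cell * (target - cum_before) / row_mass[i])


def population_index(field: PeriodGrid) -> float:
    """Mean of the kriged values over non-missing cells (the population series)."""
    ok = np.isfinite(field.values)
    if not ok.any():
        raise ValueError("population_index: field entirely missing")
    return float(np.mean(field.values[ok]))


def displacement_km(lat_start: float, lat_end: float) -> float:
    """Northward displacement in km (1° latitude = 111.0 km)."""
    return (lat_end - lat_start) * KM_PER_DEG_LAT


def per_decade_velocity(displacement: float, start: PeriodIndex, end: PeriodIndex) -> float:
    """Displacement rate in km per decade over the inclusive calendar span.

    The divisor is the inclusive span of the endpoint periods in decades:
    1984–1988 → 2004–2008 spans (2008 − 1984 + 1)/10 = 2.5 decades.
    """
    decades = (end.end_year - start.start_year + 1) / 10.0
    if decades <= 0:
        raise ValueError("per_decade_velocity: end period must follow start period")
    return displacement / decades


@dataclass
class RangeTrajectory:
    """Per-period range series for one taxon.

    ``percent_north``/``percent_north_z`` map isotherm temperature → series
    over the periods; z-scores are computed over the periods used.
    """

    taxon: str
    periods: list[PeriodIndex]
    percent_north: dict[float, np.ndarray]
    percent_north_z: dict[float, np.ndarray] = field(default_factory=dict)
    median_latitude: np.ndarray = field(default_factory=lambda: np.array([]))
    population_index: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for temp in sorted(self.percent_north):
            pn = self.percent_north[temp]
            pz = self.percent_north_z.get(temp, np.full_like(pn, np.nan))
            for k, p in enumerate(self.periods):
                rows.append(
                    {
                        "taxon": self.taxon,
                        "period": p.label,
                        "isotherm_temp": temp,
                        "percent_north": pn[k],
                        "percent_north_z": pz[k],
                        "median_latitude": self.median_latitude[k],
                        "population_index": self.population_index[k],
                    }
                )
        return pd.DataFrame(rows)


def range_trajectory(
    taxon: str,
    fields: dict[PeriodIndex, PeriodGrid],
    tracks: dict[float, dict[PeriodIndex, IsothermTrack]],
) -> RangeTrajectory:
    """Assemble the full per-period range series for one taxon."""
    periods = sorted(fields)
    pn = {
        temp: np.array([percent_north(fields[p], by_period[p]) for p in periods])
        for temp, by_period in tracks.items()
    }
    pz = {temp: zscore_series(series) for temp, series in pn.items()}
    med = np.array([median_range_latitude(fields[p]) for p in periods])
    pop = np.array([population_index(fields[p]) for p in periods])
    return RangeTrajectory(
        taxon=taxon,
        periods=periods,
        percent_north=pn,
        percent_north_z=pz,
        median_latitude=med,
        population_index=pop,
    )
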