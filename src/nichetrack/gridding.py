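"""From tow samples to 5-yearly kriged fields.

The workflow follows the standard treatment of Continuous Plankton Recorder
(CPR) style data: samples are pooled into 5-year × calendar-month sets (the
spatial structure is only assumed stable within a 5-year window), counts are
log(n+1) transformed, vertically migrating genera are restricted to samples
taken between 18:00 and 06:00 local solar time, each monthly set is kriged to
the 0.5° analysis grid, and the monthly estimates are averaged cell-wise into
a 5-yearly field.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .grids import GridSpec, PeriodGrid, PeriodIndex, period_of_year, standard_periods
from .kriging import VariogramModel, OrdinaryKriging, dedupe_points, fit_variogram

log = logging.getLogger(__name__)

#: minimum samples in a (period, month, taxon) bucket before kriging is attempted
MIN_SAMPLES_PER_BUCKET = 30

REQUIRED_TOW_COLUMNS = ("taxon", "latitude", "longitude", "datetime_utc", "count")


def read_tows(path) -> pd.DataFrame:
    """Read the tow-sample CSV (taxon, latitude, longitude, datetime_utc, count)."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_TOW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tow table missing columns: {missing}")
    df["datetime_utc"] = pd.to_datetime(df["datetime_utc"], utc=True)
    return df


def filter_domain(samples: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Keep samples inside the analysis box."""
    mask = grid.contains(samples["latitude"].to_numpy(), samples["longitude"].to_numpy())
    return samples.loc[mask]


def assign_periods(
    samples: pd.DataFrame, periods: Iterable[PeriodIndex] | None = None
) -> dict[tuple[PeriodIndex, int], pd.DataFrame]:
    """Partition samples into (5-year period, calendar month) buckets.

    Samples dated outside the period scheme (before 1954 or after 2013 with
    the standard scheme) are silently excluded, with a log record.
    """
    periods = list(periods) if periods is not None else standard_periods()
    dt = pd.to_datetime(samples["datetime_utc"], utc=True)
    years = dt.dt.year.to_numpy()
    months = dt.dt.month.to_numpy()
    out: dict[tuple[PeriodIndex, int], pd.DataFrame] = {}
    n_dropped = 0
    pmap = {y: period_of_year(y, periods) for y in np.unique(years)}
    plabels = np.array([pmap[y].label if pmap[y] else "" for y in years])
    for (label, month), sub in samples.groupby([plabels, months], sort=True):
        if label == "":
            n_dropped += len(sub)
            continue
        out[(PeriodIndex.from_label(label), int(month))] = sub
    if n_dropped:
        log.info("assign_periods: excluded %d samples outside the period scheme", n_dropped)
    return out


def local_solar_hour(datetime_utc: pd.Series, longitude: np.ndarray) -> np.ndarray:
    """Local solar hour = UTC hour + longitude / 15, wrapped to [0, 24)."""
    dt = pd.to_datetime(datetime_utc, utc=True)
    hour_utc = dt.dt.hour + dt.dt.minute / 60.0 + dt.dt.second / 3600.0
    return np.mod(hour_utc.to_numpy() + np.asarray(longitude, dtype=float) / 15.0, 24.0)


def night_filter(samples: pd.DataFrame, taxon: str, diel_set: set[str]) -> pd.DataFrame:
    """Keep only 18:00–06:00 local-solar-time samples for diel migrators.

    Near-surface abundance of vertically migrating genera (e.g. *Metridia*,
    *Pleuromamma*) is only representative at night; other taxa pass through
    unchanged.
    """
    if taxon not in diel_set:
        return samples
    h = local_solar_hour(samples["datetime_utc"], samples["longitude"].to_numpy())
    return samples.loc[(h >= 18.0) | (h < 6.0)]


def log_transform(count, base: float | None = None):
    """log(n+1) abundance transform (natural log by default).

    The choice of base rescales every transformed value by a constant and so
    cannot change percent-north, median-latitude or correlation outcomes.
    """
    count = np.asarray(count, dtype=float)
    if np.any(count < 0):
        raise ValueError("counts must be non-negative")
    out = np.log1p(count)
    if base is not None:
        out = out / np.log(base)
    return out


def krige_field(
    lat: np.ndarray,
    lon: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    grid: GridSpec,
    period: PeriodIndex | None = None,
    month: int | None = None,
    kind: str = "",
) -> PeriodGrid:
    """Ordinary-kriging estimate at every cell centre of the analysis grid."""
    x, y = grid.project(np.asarray(lat, float), np.asarray(lon, float))
    est = OrdinaryKriging(model).fit(np.column_stack([x, y]), values).predict(grid.cell_xy_km())
    return PeriodGrid(
        grid=grid,
        values=est.reshape(grid.shape),
        period=period,
        month=month,
        kind=kind,
    )


def krige_bucket(
    bucket: pd.DataFrame,
    grid: GridSpec,
    value_column: str,
    period: PeriodIndex,
    month: int,
    min_samples: int = MIN_SAMPLES_PER_BUCKET,
    kind: str = "",
) -> PeriodGrid | None:
    """Fit a variogram to one (period, month) bucket and krige it.

    Returns None (with a log record) when the bucket has fewer than
    ``min_samples`` rows or the variogram cannot be fitted; a spatially
    constant bucket short-circuits to a constant field.
    """
    if len(bucket) < min_samples:
        log.warning(
            "skipping %s month %d: %d samples < %d", period.label, month, len(bucket), min_samples
        )
        return None
    lat = bucket["latitude"].to_numpy(float)
    lon = bucket["longitude"].to_numpy(float)
    vals = bucket[value_column].to_numpy(float)
    x, y = grid.project(lat, lon)
    xy, v = dedupe_points(np.column_stack([x, y]), vals)
    if np.ptp(v) < 1e-12:
        return PeriodGrid(
            grid=grid,
            values=np.full(grid.shape, float(v[0])),
            period=period,
            month=month,
            kind=kind,
        )
    try:
        model = fit_variogram(xy, v)
    except ValueError as err:
        log.warning("skipping %s month %d: %s", period.label, month, err)
        return None
    est = OrdinaryKriging(model).fit(xy, v).predict(grid.cell_xy_km())
    return PeriodGrid(
        grid=grid, values=est.reshape(grid.shape), period=period, month=month, kind=kind
    )


def period_mean_field(monthly_grids: list[PeriodGrid]) -> PeriodGrid:
    """Cell-wise mean of the available monthly fields for one period."""
    if not monthly_grids:
        raise ValueError("period_mean_field: no monthly grids supplied")
    periods = {g.period for g in monthly_grids}
    if len(periods) != 1:
        raise ValueError("period_mean_field: grids from different periods")
    stack = np.stack([g.values for g in monthly_grids])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    g0 = monthly_grids[0]
    return PeriodGrid(
        grid=g0.grid,
        values=mean,
        period=g0.period,
        months_used=len(monthly_grids),
        kind=g0.kind,
    )


def grid_taxon(
    tows: pd.DataFrame,
    taxon: str,
    grid: GridSpec,
    periods: Iterable[PeriodIndex] | None = None,
    diel_set: set[str] | None = None,
    min_samples: int = MIN_SAMPLES_PER_BUCKET,
    log_base: float | None = None,
    keep_monthly: bool = False,
) -> tuple[dict[PeriodIndex, PeriodGrid], dict[tuple[PeriodIndex, int], PeriodGrid]]:
    """Full gridding chain for one taxon.

    Domain filter → night filter (if diel) → log(n+1) → per-(period, month)
    kriging → 5-yearly cell-wise mean.  Returns (period fields, monthly
    fields); the monthly dict is empty unless ``keep_monthly``.
    """
    periods = list(periods) if periods is not None else standard_periods()
    sub = tows.loc[tows["taxon"] == taxon]
    sub = filter_domain(sub, grid)
    sub = night_filter(sub, taxon, diel_set or set())
    sub = sub.assign(log_abundance=log_transform(sub["count"].to_numpy(), base=log_base))
    buckets = assign_periods(sub, periods)
    monthly: dict[tuple[PeriodIndex, int], PeriodGrid] = {}
    by_period: dict[PeriodIndex, list[PeriodGrid]] = {p: [] for p in periods}
    for (period, month), bucket in buckets.items():
        pg = krige_bucket(
            bucket, grid, "log_abundance", period, month, min_samples=min_samples, kind=taxon
        )
        if pg is None:
            continue
        by_period[period].append(pg)
        if keep_monthly:
            monthly[(period, month)] = pg
    fields = {
        p: period_mean_field(gs) for p, gs in by_period.items() if gs
    }
    return fields, monthly


def read_sst(path) -> pd.DataFrame:
    """Read long-format SST (time, lat, lon, sst); time is YYYY-MM."""
    df = pd.read_csv(path)
    missing = [c for c in ("time", "lat", "lon", "sst") if c not in df.columns]
    if missing:
        raise ValueError(f"SST table missing columns: {missing}")
    return df


def grid_sst(
    sst: pd.DataFrame,
    grid: GridSpec,
    periods: Iterable[PeriodIndex] | None = None,
) -> dict[PeriodIndex, PeriodGrid]:
    """Krige monthly SST sets to the analysis grid and average into 5-yearly fields.

    Input is a long table (time YYYY-MM, lat, lon, sst) on the native source
    grid (e.g. 1° × 1°).  Within a (period, month) set the five yearly values
    at each source cell are duplicates in space and are averaged before the
    variogram fit / kriging.
    """
    periods = list(periods) if periods is not None else standard_periods()
    t = pd.PeriodIndex(sst["time"], freq="M")
    years = t.year.to_numpy()
    months = t.month.to_numpy()
    pmap = {y: period_of_year(int(y), periods) for y in np.unique(years)}
    plabels = np.array([pmap[y].label if pmap[y] else "" for y in years])
    by_period: dict[PeriodIndex, list[PeriodGrid]] = {p: [] for p in periods}
    for (label, month), sub in sst.groupby([plabels, months], sort=True):
        if label == "":
            continue
        period = PeriodIndex.from_label(label)
        # the five yearly values at each source cell are spatial duplicates:
        # average them up front
        bucket = (
            sub.groupby(["lat", "lon"], as_index=False)["sst"]
            .mean()
            .rename(columns={"lat": "latitude", "lon": "longitude"})
        )
        pg = krige_bucket(
            bucket, grid, "sst", period, int(month), min_samples=10, kind="sst"
        )
        if pg is not None:
            by_period[period].append(pg)
    return {p: period_mean_field(gs) for p, gs in by_period.items() if gs}
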