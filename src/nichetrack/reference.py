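"""Packaged reference tables and fleet-level summaries.

``reference_taxon_movements.csv`` holds published range-shift estimates for
35 North-East Atlantic plankton taxa over 1954–2013: the number of isotherms
(of 11, 12, 13 °C) with a significant negative percent-north correlation,
the northward movement (km) of the range median latitude in the cooling
(1959–1963 → 1984–1988) and warming (1984–1988 → 2004–2008) periods, the
sign of any significant abundance–SST correlation, and the population mean
and s.d. over the twelve 5-year periods.  Groups: DIA diatoms, DIN
dinoflagellates, CEU *Calanus*/*Euchaeta*/*Undeuchaeta*, MP
*Metridia*/*Pleuromamma*.  ``reference_isotherm_movements.csv`` holds the
corresponding mean-latitude shifts of the three isotherms.

These tables let the fleet-summary statistics (mean poleward velocity,
counts of large movers, largest between-taxon contrast) be recomputed
without the multi-decade survey archives.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .grids import PeriodIndex
from .ranges import per_decade_velocity

COOLING_PAIR = (PeriodIndex(1959, 1963), PeriodIndex(1984, 1988))
WARMING_PAIR = (PeriodIndex(1984, 1988), PeriodIndex(2004, 2008))


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("nichetrack.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_reference_movements() -> pd.DataFrame:
    df = _read_packaged("reference_taxon_movements.csv")
    df["sst_correlation_sign"] = df["sst_correlation_sign"].fillna("none")
    df["verdict"] = np.select(
        [df["n_isotherms_negative"] == 3, df["n_isotherms_negative"] == 0],
        ["plastic_all3", "conservative"],
        default="plastic_partial",
    )
    return df


def load_reference_isotherm_movements() -> pd.DataFrame:
    return _read_packaged("reference_isotherm_movements.csv")


def summarize_groups(report: pd.DataFrame) -> dict:
    """Fleet-level movement summary from a per-taxon report.

    Expects columns ``taxon``, ``verdict``, ``movement_cooling_km``,
    ``movement_warming_km``.  Means are reported in km and km per decade
    (warming span 2.5 decades); counts are taxa moving more than 100 km
    south/north in the warming period.  Empty verdict groups are absent
    from the result, not zero.
    """
    if report.empty:
        raise ValueError("empty report")
    warm = report["movement_warming_km"].to_numpy(dtype=float)
    net = report["movement_cooling_km"].to_numpy(dtype=float) + warm

    def stats(mask: np.ndarray) -> dict:
        vals = warm[mask]
        return {
            "n_taxa": int(mask.sum()),
            "mean_warming_km": float(np.mean(vals)),
            "mean_warming_km_per_decade": per_decade_velocity(
                float(np.mean(vals)), *WARMING_PAIR
            ),
        }

    out: dict = {"all": stats(np.ones(len(warm), dtype=bool))}
    for verdict in ("conservative", "plastic_all3"):
        mask = (report["verdict"] == verdict).to_numpy()
        if mask.any():
            out[verdict] = stats(mask)
    out["n_moving_south_gt100km"] = int(np.sum(warm < -100.0))
    out["n_moving_north_gt100km"] = int(np.sum(warm > 100.0))
    out["max_pairwise_difference_km"] = float(warm.max() - warm.min())
    out["net_movement_km"] = {
        t: float(v) for t, v in zip(report["taxon"], net) if np.isfinite(v)
    }
    return out
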