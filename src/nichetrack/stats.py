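"""Statistical layer: autocorrelation-adjusted correlation tests, niche
plasticity classification, abundance–SST correlations and phenology.

Correlations between two short, serially correlated time series (here:
percent north of an isotherm vs the isotherm's mean latitude over twelve
5-year periods) overstate their significance if the nominal sample size is
used.  The effective sample size is re-estimated with the Chelton-style
adjustment in its standard modern (Pyper–Peterson 1998) cross-correlation
form:

    1 / n_eff = (1/n) · Σ_{j=−J..J} ρ_x(j) · ρ_y(j),   J = ⌊n/5⌋

with sample autocorrelations ρ at lag j, and n_eff clipped to (2, n].  The
t test for the Pearson correlation then uses n_eff − 2 degrees of freedom.

A taxon shows *niche plasticity* when the proportion of its population north
of an isotherm falls significantly as the isotherm moves north (one-sided
negative correlation); *niche conservatism* when no isotherm shows such a
correlation (the range simply tracks the moving thermal envelope).

Seasonal timing of peak abundance is the abundance-weighted mean month
S_p = Σ M·x_M / Σ x_M, restricted to the dominant peak for bimodal profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .grids import PeriodIndex
from .ranges import displacement_km


# ---------------------------------------------------------------------------
# effective degrees of freedom

def _autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        raise ValueError("constant series has no autocorrelation")
    n = len(x)
    return np.array([np.dot(x[: n - j], x[j:]) / denom for j in range(1, max_lag + 1)])


def effective_dof(x, y, max_lag: int | None = None) -> float:
    """Effective sample size for the correlation of two autocorrelated series.

    Truncates the lag sum at J = ⌊n/5⌋ by default.  Returns a value in
    (2, n]; white-noise pairs give n_eff ≈ n, positively autocorrelated
    pairs give smaller values (e.g. two AR(1) series with φ = 0.5 give
    n_eff/n → 0.6 for large n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 observations")
    J = int(n // 5) if max_lag is None else int(max_lag)
    rx = _autocorr(x, J)
    ry = _autocorr(y, J)
    inv = (1.0 + 2.0 * float(np.dot(rx, ry))) / n
    n_eff = 1.0 / inv if inv > 0 else float(n)
    return float(min(float(n), max(n_eff, 2.0 + 1e-9)))


# ---------------------------------------------------------------------------
# plasticity test and classification

@dataclass(frozen=True)
class PlasticityResult:
    """One-sided test for a negative percent-north vs isotherm-latitude link."""

    taxon: str
    isotherm_temp: float
    r: float
    n: int
    n_eff: float
    p_one_sided: float
    significant_negative: bool


def _pearson_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Pearson r, t statistic and df using the Chelton-adjusted sample size."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate (constant) series")
    r = float(np.corrcoef(x, y)[0, 1])
    n_eff = effective_dof(x, y)
    df = n_eff - 2.0
    denom = 1.0 - r * r
    if denom <= 0:
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt(df / denom)
    return r, t, n_eff


def plasticity_test(
    percent_z, isotherm_lat, alpha: float = 0.05, taxon: str = "", isotherm_temp: float = np.nan
) -> PlasticityResult:
    """Test for a significant *negative* correlation (niche plasticity).

    The hypothesis is directional, so the p-value is the one-sided lower
    tail of the t distribution with n_eff − 2 degrees of freedom.
    """
    x = np.asarray(percent_z, dtype=float)
    y = np.asarray(isotherm_lat, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need equal-length series of at least 5 periods")
    r, t, n_eff = _pearson_t(x, y)
    p = float(sps.t.cdf(t, n_eff - 2.0))
    return PlasticityResult(
        taxon=taxon,
        isotherm_temp=float(isotherm_temp),
        r=r,
        n=len(x),
        n_eff=n_eff,
        p_one_sided=p,
        significant_negative=bool(p < alpha and r < 0),
    )


@dataclass(frozen=True)
class TaxonClassification:
    """Verdict and movement summary for one taxon (one report row)."""

    taxon: str
    verdict: str  # plastic_all3 | plastic_partial | conservative
    n_significant: int
    movement_cooling_km: float
    movement_warming_km: float
    sst_correlation_sign: str  # '+', '-', 'none'
    abundance_mean: float
    abundance_sd: float


def classify_taxon(
    results: dict[float, PlasticityResult],
    periods: list[PeriodIndex],
    median_latitude: np.ndarray,
    population: np.ndarray,
    cooling: tuple[PeriodIndex, PeriodIndex],
    warming: tuple[PeriodIndex, PeriodIndex],
    sst_sign: str = "none",
) -> TaxonClassification:
    """Combine the three per-isotherm tests with movement and abundance stats.

    Movements are the northward displacement of the range median latitude
    over the cooling pair (1959–1963 → 1984–1988) and the warming pair
    (1984–1988 → 2004–2008).
    """
    if len(results) != 3:
        raise ValueError("expected plasticity results for exactly three isotherms")
    idx = {p: i for i, p in enumerate(periods)}
    needed = {cooling[0], cooling[1], warming[0], warming[1]}
    missing = sorted(p.label for p in needed if p not in idx)
    if missing:
        raise ValueError(f"missing periods in trajectory: {missing}")
    n_sig = sum(r.significant_negative for r in results.values())
    verdict = (
        "plastic_all3" if n_sig == 3 else "conservative" if n_sig == 0 else "plastic_partial"
    )
    move_cool = displacement_km(median_latitude[idx[cooling[0]]], median_latitude[idx[cooling[1]]])
    move_warm = displacement_km(median_latitude[idx[warming[0]]], median_latitude[idx[warming[1]]])
    taxon = next(iter(results.values())).taxon
    return TaxonClassification(
        taxon=taxon,
        verdict=verdict,
        n_significant=n_sig,
        movement_cooling_km=move_cool,
        movement_warming_km=move_warm,
        sst_correlation_sign=sst_sign,
        abundance_mean=float(np.mean(population)),
        abundance_sd=float(np.std(population, ddof=1)),
    )


def abundance_sst_correlation(
    pop,
    sst,
    warming_window: slice | None = None,
    alpha: float = 0.05,
) -> str:
    """Sign of a significant population–SST correlation, else 'none'.

    Pearson r with the Chelton-adjusted sample size, two-sided, tested over
    the full series and (if given) the warming-window subseries; the sign of
    the most significant window is returned when either rejects.
    """
    pop = np.asarray(pop, dtype=float)
    sst = np.asarray(sst, dtype=float)
    if pop.shape != sst.shape or len(pop) < 5:
        raise ValueError("need equal-length series of at least 5 periods")
    windows = [slice(None)]
    if warming_window is not None:
        windows.append(warming_window)
    best: tuple[float, float] | None = None  # (p, r)
    for w in windows:
        x, y = pop[w], sst[w]
        if len(x) < 5:
            continue
        r, t, n_eff = _pearson_t(x, y)
        p = 2.0 * float(sps.t.sf(abs(t), n_eff - 2.0))
        if best is None or p < best[0]:
            best = (p, r)
    if best is None or best[0] >= alpha:
        return "none"
    return "+" if best[1] > 0 else "-"


# ---------------------------------------------------------------------------
# phenology

@dataclass(frozen=True)
class SeasonalProfile:
    """Mean abundance per calendar month over one window of years."""

    taxon: str
    window: str
    x_m: np.ndarray  # length 12, month 1..12

    @property
    def seasonal_peak(self) -> float:
        return seasonal_peak(self.x_m)


def _circular_gap(a: int, b: int) -> int:
    d = abs(a - b)
    return min(d, 12 - d)


def seasonal_peak(x_m) -> float:
    """Abundance-weighted mean month S_p = Σ M·x_M / Σ x_M (fractional months).

    Profiles with two well-separated peaks of comparable height (both spring
    and autumn blooms) are reduced to the most populous peak: when a second
    local maximum at least 3 months away (circularly) reaches 60% of the
    global maximum, the weighted mean is restricted to months within ±3
    (circular) of the global maximum, and the result is wrapped back into
    [1, 12].
    """
    x = np.asarray(x_m, dtype=float)
    if x.shape != (12,):
        raise ValueError("expected 12 monthly values")
    if np.any(x < 0):
        raise ValueError("monthly abundances must be non-negative")
    if not np.any(x > 0):
        raise ValueError("all-zero seasonal profile")
    months = np.arange(1, 13)
    peaks = [
        m
        for m in range(12)
        if x[m] > 0
        and x[m] >= x[(m - 1) % 12]
        and x[m] >= x[(m + 1) % 12]
        and (x[m] > x[(m - 1) % 12] or x[m] > x[(m + 1) % 12])
    ]
    major = int(np.argmax(x))
    bimodal = any(
        _circular_gap(m + 1, major + 1) >= 3 and x[m] >= 0.6 * x[major]
        for m in peaks
        if m != major
    )
    if not bimodal:
        return float(np.dot(months, x) / x.sum())
    # dominant-peak window, unwrapped around the major month
    offsets = np.arange(-3, 4)
    win_months = major + 1 + offsets
    win_x = x[(major + offsets) % 12]
    sp = float(np.dot(win_months, win_x) / win_x.sum())
    return float((sp - 1.0) % 12.0 + 1.0)


def phenological_shift(profile_start: SeasonalProfile, profile_end: SeasonalProfile) -> float:
    """Change in seasonal peak timing, in months (negative = earlier)."""
    return profile_end.seasonal_peak - profile_start.seasonal_peak


def phenology_vs_range(shifts, movements) -> tuple[float, float]:
    """Cross-taxon Pearson correlation of range movement vs phenological shift.

    Ordinary degrees of freedom (taxa are exchangeable units, not a time
    series).  Returns (r, two-sided p).  Requires at least 4 taxa and
    non-degenerate variance in both variables.
    """
    shifts = np.asarray(shifts, dtype=float)
    movements = np.asarray(movements, dtype=float)
    if len(shifts) != len(movements) or len(shifts) < 4:
        raise ValueError("need at least 4 taxa")
    if np.std(shifts) == 0 or np.std(movements) == 0:
        raise ValueError("degenerate group: zero variance")
    res = sps.pearsonr(shifts, movements)
    return float(res.statistic), float(res.pvalue)
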