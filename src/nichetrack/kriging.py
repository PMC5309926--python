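"""Empirical variograms, automatic model selection and ordinary kriging.

Ordinary kriging (OK) is the best linear unbiased spatial predictor under an
intrinsically stationary model described by a semivariogram γ(h).  The OK
weights at a prediction point solve the augmented linear system

    [ Γ  1 ] [ w ]   [ γ0 ]
    [ 1ᵀ 0 ] [ μ ] = [ 1  ]

where Γ_ij = γ(|s_i − s_j|), γ0_i = γ(|s_i − s0|) and μ is the Lagrange
multiplier enforcing Σw = 1 (unbiasedness).  The semivariogram is fitted to
the empirical (binned) variogram by weighted least squares with Cressie-style
weights N_j / h_j², and the model family (spherical, exponential, gaussian)
is selected automatically by minimal weighted SSE — mirroring the common
automatic-fitting workflow in geostatistics packages.

All distances are in km (see :meth:`nichetrack.grids.GridSpec.project`).
Model ranges use the *practical range* convention for exponential and
gaussian families, so fitted ranges are comparable across families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform

log = logging.getLogger(__name__)

FAMILIES = ("spherical", "exponential", "gaussian")


def _gamma(family: str, h: np.ndarray, nugget: float, psill: float, rng: float) -> np.ndarray:
    """Semivariogram value at lag h ≥ 0; γ(0) = 0 exactly for every family."""
    h = np.asarray(h, dtype=float)
    if family == "spherical":
        hr = np.minimum(h / rng, 1.0)
        struct = psill * (1.5 * hr - 0.5 * hr**3)
    elif family == "exponential":
        struct = psill * (1.0 - np.exp(-3.0 * h / rng))
    elif family == "gaussian":
        struct = psill * (1.0 - np.exp(-3.0 * (h / rng) ** 2))
    else:  # pragma: no cover - guarded by FAMILIES
        raise ValueError(f"unknown variogram family {family!r}")
    out = np.where(h > 0, nugget + struct, 0.0)
    return out


@dataclass(frozen=True)
class VariogramModel:
    """A fitted semivariogram model.

    ``sill`` is the total sill (nugget + partial sill); ``range_km`` is the
    practical range; ``fit_score`` is the weighted SSE of the winning fit.
    """

    family: str
    nugget: float
    sill: float
    range_km: float
    fit_score: float = float("nan")

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.sill < self.nugget or self.range_km <= 0:
            raise ValueError("require nugget >= 0, sill >= nugget, range > 0")

    @property
    def partial_sill(self) -> float:
        return self.sill - self.nugget

    def __call__(self, h) -> np.ndarray:
        return _gamma(self.family, h, self.nugget, self.partial_sill, self.range_km)


def empirical_variogram(
    xy: np.ndarray,
    values: np.ndarray,
    n_bins: int = 15,
    cutoff: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned empirical semivariogram.

    Returns (bin mean distance, semivariance, pair count) for non-empty bins.
    The default cutoff is one third of the bounding-box diagonal (the common
    gstat default); zero-distance pairs (duplicates) are excluded.
    """
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    d = pdist(xy)
    dv = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    if cutoff is None:
        span = xy.max(axis=0) - xy.min(axis=0)
        cutoff = float(np.hypot(*span)) / 3.0
    keep = (d > 0) & (d <= cutoff)
    d, dv = d[keep], dv[keep]
    if d.size == 0:
        return np.array([]), np.array([]), np.array([])
    edges = np.linspace(0.0, cutoff, n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        h = np.bincount(idx, weights=d, minlength=n_bins) / counts
        gamma = np.bincount(idx, weights=dv, minlength=n_bins) / counts
    nz = counts > 0
    return h[nz], gamma[nz], counts[nz]


def fit_variogram(
    xy: np.ndarray,
    values: np.ndarray,
    n_bins: int = 15,
    cutoff: float | None = None,
    families: tuple[str, ...] = FAMILIES,
) -> VariogramModel:
    """Fit candidate variogram families and return the best by weighted SSE.

    Requires at least 10 points and at least 5 non-empty distance bins;
    otherwise raises ``ValueError("insufficient data for variogram")``.
    Weights are N_j / h_j² (Cressie-style), emphasising short lags.
    """
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(xy) < 10:
        raise ValueError("insufficient data for variogram: need >= 10 points")
    h, gamma, counts = empirical_variogram(xy, values, n_bins=n_bins, cutoff=cutoff)
    if len(h) < 5:
        raise ValueError("insufficient data for variogram: need >= 5 distance bins")

    w = np.sqrt(counts / h**2)
    var = float(np.var(values))
    hmax = float(h.max())
    best: VariogramModel | None = None
    # Initial guesses: nugget from the shortest lag, structure to the sample
    # variance, range at half the largest binned lag.
    x0 = np.array([max(gamma[0], 1e-12), max(var - gamma[0], 0.1 * var, 1e-12), hmax / 2.0])
    lo = np.array([0.0, 0.0, hmax / 100.0])
    hi = np.array([5.0 * var + 1e-12, 5.0 * var + 1e-12, 10.0 * hmax])
    for family in families:
        def resid(p, fam=family):
            return w * (_gamma(fam, h, p[0], p[1], p[2]) - gamma)

        try:
            sol = least_squares(resid, np.clip(x0, lo, hi), bounds=(lo, hi), method="trf")
        except Exception:  # pragma: no cover - optimizer failure fallback
            continue
        score = float(np.sum(sol.fun**2))
        nug, psill, rng = (float(v) for v in sol.x)
        # Floor the fitted nugget at 0.1% of the sill: a zero-nugget model
        # (especially gaussian) makes the kriging system ill-conditioned and
        # can produce wild extrapolation at the grid edges.
        nug = max(nug, 1e-3 * (nug + psill))
        model = VariogramModel(family, nug, nug + psill, rng, score)
        if best is None or score < best.fit_score:
            best = model
    if best is None:  # pragma: no cover
        raise RuntimeError("variogram fitting failed for all families")
    return best


def dedupe_points(xy: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average values at duplicate coordinates (keeps the OK system nonsingular)."""
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    key = np.round(xy, 6)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    if len(uniq) == len(xy):
        return xy, values
    log.warning("kriging: averaged %d duplicate locations", len(xy) - len(uniq))
    sums = np.zeros(len(uniq))
    counts = np.zeros(len(uniq))
    np.add.at(sums, inv, values)
    np.add.at(counts, inv, 1.0)
    return uniq.astype(float), sums / counts


class OrdinaryKriging:
    """Ordinary kriging interpolator with a fitted variogram model.

    >>> ok = OrdinaryKriging(model).fit(xy, values)
    >>> estimates = ok.predict(grid_xy)
    """

    def __init__(self, model: VariogramModel):
        self.model = model

    def fit(self, xy: np.ndarray, values: np.ndarray) -> "OrdinaryKriging":
        xy, values = dedupe_points(np.atleast_2d(xy), values)
        if len(xy) < 1:
            raise ValueError("ordinary kriging needs at least one observation")
        self.xy_, self.values_ = xy, values
        n = len(xy)
        a = np.zeros((n + 1, n + 1))
        a[:n, :n] = self.model(squareform(pdist(xy))) if n > 1 else 0.0
        a[:n, n] = 1.0
        a[n, :n] = 1.0
        try:
            from scipy.linalg import lu_factor

            self._lu_ = lu_factor(a)
        except Exception:
            # Degenerate model (e.g. pure-zero variogram): fall back to the
            # sample-mean predictor via pseudo-inverse weights.
            self._lu_ = None
            self._pinv_ = np.linalg.pinv(a)
        return self

    def predict(self, xy_new: np.ndarray, return_weights: bool = False):
        """OK estimate at each new location; optionally also the weight matrix.

        Weights sum to one at every prediction point (unbiasedness constraint).
        """
        xy_new = np.atleast_2d(np.asarray(xy_new, dtype=float))
        n = len(self.xy_)
        b = np.empty((n + 1, len(xy_new)))
        b[:n] = self.model(cdist(self.xy_, xy_new))
        b[n] = 1.0
        if self._lu_ is not None:
            from scipy.linalg import lu_solve

            sol = lu_solve(self._lu_, b)
        else:
            sol = self._pinv_ @ b
        weights = sol[:n]
        est = self.values_ @ weights
        if return_weights:
            return est, weights
        return est


def krige_points(
    xy: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    xy_new: np.ndarray,
    return_weights: bool = False,
):
    """Functional wrapper: fit OK on (xy, values) and predict at xy_new."""
    ok = OrdinaryKriging(model).fit(xy, values)
    return ok.predict(xy_new, return_weights=return_weights)
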