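"""Adaptive landscape analysis over the jaw shape morphospace.

Each biomechanical trait yields a performance surface: a second-order
polynomial fitted by least squares over the (PC1, PC2) warp-grid trait
values, then standardized to zero mean and unit variance over a fixed
evaluation lattice so all surfaces contribute on equal footing.  A combined
landscape W = Σ wₙFₙ weights the standardized surfaces by relative fitness
contributions wₙ on the unit simplex.  For a clade, the optimal weights
maximize the log-likelihood Σ ln Ŵ(taxon), where Ŵ is W min-max rescaled
into (0, 1] over the lattice; weight vectors within 2 log-likelihood units
of the optimum form the support (confidence) set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = [
    "PerformanceSurface",
    "WeightSolution",
    "fit_surface",
    "evaluate_landscape",
    "simplex_grid",
    "optimize_weights",
    "compare_groups",
]

_RESCALE_EPS = 1e-6


def _design(points: np.ndarray) -> np.ndarray:
    x, y = points[:, 0], points[:, 1]
    return np.column_stack([np.ones_like(x), x, y, x**2, x * y, y**2])


@dataclass
class PerformanceSurface:
    """Quadratic performance surface F(x, y) with lattice standardization.

    ``coeffs`` are (β₀, β₁x, β₂y, β₃x², β₄xy, β₅y²); ``mean``/``sd`` are the
    moments of the raw quadratic over the evaluation lattice, so that
    ``evaluate`` returns values with mean 0 and variance 1 on that lattice.
    """

    coeffs: np.ndarray
    mean: float
    sd: float
    bounds: tuple[float, float, float, float]  # (x0, x1, y0, y1) of the lattice
    trait: str = ""
    negated: bool = False

    def raw(self, points: np.ndarray) -> np.ndarray:
        return _design(np.atleast_2d(points)) @ self.coeffs

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Standardized surface value at (x, y) points."""
        return (self.raw(points) - self.mean) / self.sd


def _lattice(bounds: tuple[float, float, float, float], n: int = 50) -> np.ndarray:
    xs = np.linspace(bounds[0], bounds[1], n)
    ys = np.linspace(bounds[2], bounds[3], n)
    X, Y = np.meshgrid(xs, ys)
    return np.column_stack([X.ravel(), Y.ravel()])


def fit_surface(
    points: np.ndarray,
    values: np.ndarray,
    bounds: tuple[float, float, float, float] | None = None,
    trait: str = "",
    negated: bool = False,
    lattice_n: int = 50,
) -> PerformanceSurface:
    """Least-squares fit of the 6-term quadratic to trait values at (PC1,
    PC2) points; missing values are dropped.  ``negated`` records that the
    raw trait was negated so that higher = better performance."""
    points = np.asarray(points, float)
    values = np.asarray(values, float)
    keep = np.isfinite(values) & np.all(np.isfinite(points), axis=1)
    points, values = points[keep], values[keep]
    if len(values) < 6:
        raise ValueError("need at least 6 points with values for a quadratic fit")
    X = _design(points)
    if np.linalg.matrix_rank(X) < 6:
        raise ValueError("rank-deficient design: points are degenerate (collinear?)")
    coeffs, *_ = np.linalg.lstsq(X, values, rcond=None)
    if bounds is None:
        bounds = (
            points[:, 0].min(), points[:, 0].max(),
            points[:, 1].min(), points[:, 1].max(),
        )
    grid_vals = _design(_lattice(bounds, lattice_n)) @ coeffs
    sd = float(grid_vals.std())
    if sd == 0:
        sd = 1.0  # constant surface standardizes to all-zero
    return PerformanceSurface(
        coeffs=coeffs,
        mean=float(grid_vals.mean()),
        sd=sd,
        bounds=bounds,
        trait=trait,
        negated=negated,
    )


def _check_simplex(w: np.ndarray, n: int) -> np.ndarray:
    w = np.asarray(w, float)
    if len(w) != n:
        raise ValueError("weight vector length does not match surface count")
    if np.any(w < -1e-9) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1")
    return w


def evaluate_landscape(
    surfaces: list[PerformanceSurface],
    w: np.ndarray,
    points: np.ndarray,
    lattice_n: int = 50,
) -> np.ndarray:
    """Rescaled combined landscape Ŵ at query points: W = Σ wₙFₙ on the
    standardized surfaces, min-max rescaled over the evaluation lattice into
    (ε, 1] with ε = 1e-6."""
    w = _check_simplex(w, len(surfaces))
    W, lo, hi = _combined(surfaces, w, points, lattice_n)
    if hi == lo:
        return np.full(len(np.atleast_2d(points)), 1.0)
    scaled = (np.clip(W, lo, hi) - lo) / (hi - lo)
    return _RESCALE_EPS + (1.0 - _RESCALE_EPS) * scaled


def _combined(
    surfaces: list[PerformanceSurface],
    w: np.ndarray,
    points: np.ndarray,
    lattice_n: int = 50,
) -> tuple[np.ndarray, float, float]:
    pts = np.atleast_2d(points)
    F = np.stack([s.evaluate(pts) for s in surfaces])
    W = w @ F
    lat = _lattice(surfaces[0].bounds, lattice_n)
    Flat = np.stack([s.evaluate(lat) for s in surfaces])
    Wlat = w @ Flat
    return W, float(Wlat.min()), float(Wlat.max())


def simplex_grid(n: int, step: float = 0.05) -> np.ndarray:
    """All weight vectors on the n-simplex lattice with the given increment
    (1771 candidates for n = 4, step 0.05)."""
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise ValueError("1/step must be an integer")
    out = []
    for bars in combinations(range(m + n - 1), n - 1):
        prev, counts = -1, []
        for b in bars:
            counts.append(b - prev - 1)
            prev = b
        counts.append(m + n - 1 - prev - 1)
        out.append(counts)
    return np.asarray(out, float) * step


@dataclass
class WeightSolution:
    """Optimal fitness weights for one group of taxa."""

    weights: np.ndarray
    lnl: float
    confidence_set: np.ndarray  # (m, n) weight vectors with ΔlnL <= 2
    z: float                    # group mean standardized landscape height at ŵ
    candidates: np.ndarray = field(repr=False, default=None)
    lnl_all: np.ndarray = field(repr=False, default=None)
    step: float = 0.05


def optimize_weights(
    surfaces: list[PerformanceSurface],
    group_points: np.ndarray,
    step: float = 0.05,
    lattice_n: int = 50,
    normalized: bool = False,
) -> WeightSolution:
    """Exhaustive simplex-lattice search for the weights maximizing
    Σ ln Ŵ(taxon) over the group's morphospace positions.

    With ``normalized=True`` the likelihood subtracts n·ln(mean lattice Ŵ),
    treating Ŵ as an unnormalized density of taxon positions over the
    morphospace; this variant is a consistent estimator when taxa really are
    distributed proportionally to the landscape, whereas the plain sum of
    ln Ŵ (the descriptive convention, default) measures only how high the
    group sits on each candidate landscape.
    """
    pts = np.atleast_2d(np.asarray(group_points, float))
    if len(pts) < 3:
        raise ValueError("need at least 3 group points")
    n = len(surfaces)
    cand = simplex_grid(n, step)
    # precompute standardized surface values once
    F_pts = np.stack([s.evaluate(pts) for s in surfaces])       # (n, npts)
    lat = _lattice(surfaces[0].bounds, lattice_n)
    F_lat = np.stack([s.evaluate(lat) for s in surfaces])       # (n, nlat)
    W_pts = cand @ F_pts                                        # (ncand, npts)
    W_lat = cand @ F_lat
    lo = W_lat.min(axis=1, keepdims=True)
    hi = W_lat.max(axis=1, keepdims=True)
    rng = np.where(hi > lo, hi - lo, 1.0)
    Wh = _RESCALE_EPS + (1.0 - _RESCALE_EPS) * (np.clip(W_pts, lo, hi) - lo) / rng
    lnl = np.log(Wh).sum(axis=1)
    if normalized:
        Wh_lat = _RESCALE_EPS + (1.0 - _RESCALE_EPS) * (W_lat - lo) / rng
        lnl = lnl - pts.shape[0] * np.log(Wh_lat.mean(axis=1))
    if not np.any(np.isfinite(lnl)):
        raise ValueError("all weight candidates give -inf likelihood (group outside lattice?)")
    best = int(np.argmax(lnl))
    conf = cand[lnl >= lnl[best] - 2.0]
    return WeightSolution(
        weights=cand[best],
        lnl=float(lnl[best]),
        confidence_set=conf,
        z=float(W_pts[best].mean()),
        candidates=cand,
        lnl_all=lnl,
        step=step,
    )


def compare_groups(sol_a: WeightSolution, sol_b: WeightSolution) -> dict:
    """Compare two groups' optimal regimes by confidence-set overlap.

    ``disjoint`` means the ΔlnL ≤ 2 support regions share no weight vector —
    evidence the groups are adapted to different regimes."""
    if sol_a.step != sol_b.step or sol_a.confidence_set.shape[1] != sol_b.confidence_set.shape[1]:
        raise ValueError("solutions computed on mismatched surfaces or step")
    set_a = {tuple(np.round(w, 9)) for w in sol_a.confidence_set}
    set_b = {tuple(np.round(w, 9)) for w in sol_b.confidence_set}
    inter = set_a & set_b
    return {
        "disjoint": len(inter) == 0,
        "overlap_fraction": len(inter) / min(len(set_a), len(set_b)),
    }
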