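"""Jaw outline geometry: canonicalization, resampling, Procrustes alignment,
elliptic Fourier analysis (EFA), PCA morphospace and theoretical warp grids.

An outline is a closed 2D polygon in a canonical anatomical frame: the
anterior tip of the jaw is the minimal-x point, dorsal is +y, and the jaw
joint lies at the posterior (maximal-x) end.  Vertices run counter-clockwise.

The EFA here operates on outlines resampled to equal arc-length spacing, so
harmonic coefficients are computed with the discrete Fourier transform of the
x(t) and y(t) coordinate series — the trapezoid-rule form of the elliptic
Fourier integrals over the closed chain.  With all available harmonics the
inverse transform reproduces the sampled outline to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

__all__ = [
    "Outline",
    "AlignedOutlineSet",
    "EFACoefficients",
    "Morphospace",
    "WarpModel",
    "canonicalize",
    "resample_outline",
    "procrustes_align",
    "efa",
    "inverse_efa",
    "build_morphospace",
    "reconstruct_at",
    "warp_grid",
    "self_intersects",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Outline:
    """A closed 2D polygon (implicitly closed; last vertex != first).

    Parameters
    ----------
    points : (k, 2) array of vertex coordinates in mm.
    id : identifier used in tables and trees.
    canonical : whether the outline is in the canonical anatomical frame
        (anterior = min x, dorsal = +y, joint posterior, CCW vertex order).
    """

    points: np.ndarray
    id: str = ""
    canonical: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (k, 2) array")
        scale = max(float(np.abs(pts).max(initial=0.0)), 1.0)
        tol = 1e-9 * scale
        if len(pts) >= 2 and np.hypot(*(pts[0] - pts[-1])) <= tol:
            pts = pts[:-1]  # drop explicit closure
        if len(pts) < 3:
            raise ValueError("an outline needs at least 3 distinct points")
        gaps = np.hypot(*(np.roll(pts, -1, axis=0) - pts).T)
        if (gaps <= tol).any():
            raise ValueError("consecutive duplicate points are not allowed")
        self.points = pts

    @property
    def k(self) -> int:
        return len(self.points)

    def perimeter(self) -> float:
        d = np.roll(self.points, -1, axis=0) - self.points
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class AlignedOutlineSet:
    """Result of generalized Procrustes alignment.

    ``coords`` has shape (n_shapes, k, 2); each shape is centred at the
    origin with unit centroid size.  ``consensus`` is the coordinate-wise
    mean shape.
    """

    coords: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    ids: list[str] = field(default_factory=list)

    @property
    def n_shapes(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]


@dataclass
class EFACoefficients:
    """Per-shape elliptic Fourier harmonic quadruples.

    ``coeffs`` has shape (n_shapes, H, 4) ordered (a_n, b_n, c_n, d_n) where
    the x(t) series is A0 + sum a_n cos + b_n sin and y(t) likewise with
    (c_n, d_n).  ``locus`` holds the per-shape (A0, C0) DC terms.
    """

    coeffs: np.ndarray
    locus: np.ndarray
    k: int  # semi-landmarks per shape, fixes the harmonic normalization

    @property
    def n_shapes(self) -> int:
        return self.coeffs.shape[0]

    @property
    def H(self) -> int:
        return self.coeffs.shape[1]

    def power(self) -> np.ndarray:
        """Per-shape, per-harmonic power (a²+b²+c²+d²)/2, shape (n, H)."""
        return 0.5 * np.sum(self.coeffs**2, axis=2)

    def cumulative_power(self) -> np.ndarray:
        """Per-shape cumulative power fraction over harmonics, shape (n, H)."""
        p = self.power()
        tot = p.sum(axis=1, keepdims=True)
        return np.cumsum(p, axis=1) / tot

    def matrix(self) -> np.ndarray:
        """Flatten to an (n_shapes, 4H) coefficient matrix."""
        return self.coeffs.reshape(self.n_shapes, -1)


@dataclass
class Morphospace:
    """PCA ordination of EFA coefficient vectors."""

    mean: np.ndarray            # (4H,) mean coefficient vector
    eigenvectors: np.ndarray    # (n_pc, 4H), rows are axes
    eigenvalues: np.ndarray     # (n_pc,)
    scores: np.ndarray          # (n_shapes, n_pc)
    variance_fractions: np.ndarray
    ids: list[str] = field(default_factory=list)
    H: int = 0
    k: int = 0

    @property
    def n_pc(self) -> int:
        return len(self.eigenvalues)


@dataclass
class WarpModel:
    """A theoretical jaw shape reconstructed at a lattice point of the
    PC1–PC2 morphospace."""

    i: int
    j: int
    pc1: float
    pc2: float
    outline: Outline
    valid: bool


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def anterior_index(points: np.ndarray) -> int:
    """Index of the anterior-most vertex: minimal x, ties broken ventral-most
    (minimal y)."""
    order = np.lexsort((points[:, 1], points[:, 0]))
    return int(order[0])


def canonicalize(points: np.ndarray, flip_x: bool = False, flip_y: bool = False) -> np.ndarray:
    """Put a polygon into the canonical frame: optional axis flips (when the
    source image had anterior to the right or dorsal down), counter-clockwise
    vertex order, and the vertex sequence rolled to start at the
    anterior-most point."""
    pts = np.asarray(points, dtype=float).copy()
    if flip_x:
        pts[:, 0] = -pts[:, 0]
    if flip_y:
        pts[:, 1] = -pts[:, 1]
    if signed_area(pts) < 0:
        pts = pts[::-1]
    return np.roll(pts, -anterior_index(pts), axis=0)


def self_intersects(outline: Outline | np.ndarray) -> bool:
    """True iff any two non-adjacent edges of the closed polygon intersect or
    touch (the outline is not a simple ring)."""
    pts = outline.points if isinstance(outline, Outline) else np.asarray(outline, float)
    ring = shapely.LineString(np.vstack([pts, pts[:1]]))
    return not ring.is_simple


# ---------------------------------------------------------------------------
# resampling and alignment
# ---------------------------------------------------------------------------


def resample_outline(outline: Outline, k: int) -> Outline:
    """Resample a closed outline to ``k`` points equally spaced by arc
    length, starting from the anterior-most point.

    The perimeter is preserved to within 1% for k >= 100 on smooth shapes.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    pts = outline.points
    start = anterior_index(pts)
    pts = np.roll(pts, -start, axis=0)
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*(np.diff(closed, axis=0).T))
    perim = seg.sum()
    if perim <= 0:
        raise ValueError("degenerate outline with zero perimeter")
    t = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, perim, k, endpoint=False)
    x = np.interp(targets, t, closed[:, 0])
    y = np.interp(targets, t, closed[:, 1])
    return Outline(np.column_stack([x, y]), id=outline.id, canonical=outline.canonical)


def _optimal_rotation(shape: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation matrix (no reflection) minimizing ||shape @ R - target||."""
    u, _, vt = np.linalg.svd(shape.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def procrustes_align(
    outlines: list[Outline], tol: float = 1e-8, max_iter: int = 100
) -> AlignedOutlineSet:
    """Full generalized Procrustes alignment: remove translation, scale and
    rotation by iterative superimposition onto the running consensus until
    the consensus change falls below ``tol``."""
    if not outlines:
        raise ValueError("no outlines to align")
    ks = {o.k for o in outlines}
    if len(ks) != 1:
        raise ValueError(f"outlines have mismatched point counts: {sorted(ks)}")
    coords = np.stack([o.points for o in outlines]).astype(float)
    cent = coords.mean(axis=1, keepdims=True)
    coords -= cent
    sizes = np.sqrt((coords**2).sum(axis=(1, 2)))
    coords /= sizes[:, None, None]

    consensus = coords[0]
    for _ in range(max_iter):
        for i in range(len(coords)):
            coords[i] = coords[i] @ _optimal_rotation(coords[i], consensus)
        new = coords.mean(axis=0)
        new /= np.sqrt((new**2).sum())
        if np.sqrt(((new - consensus) ** 2).sum()) < tol:
            consensus = new
            break
        consensus = new
    return AlignedOutlineSet(
        coords=coords,
        centroid_sizes=sizes,
        consensus=coords.mean(axis=0),  # coordinate-wise mean shape
        ids=[o.id for o in outlines],
    )


# ---------------------------------------------------------------------------
# elliptic Fourier analysis
# ---------------------------------------------------------------------------


def _efa_single(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Harmonic quadruples and (A0, C0) for one equally-spaced closed chain.

    Returns (H_max, 4) coefficients with H_max = floor(k/2); for even k the
    Nyquist harmonic carries the un-doubled DFT weight so that the inverse
    series evaluated at the sample parameters is exact.
    """
    k = len(points)
    fx = np.fft.rfft(points[:, 0])
    fy = np.fft.rfft(points[:, 1])
    h_max = k // 2
    a = 2.0 * fx[1 : h_max + 1].real / k
    b = -2.0 * fx[1 : h_max + 1].imag / k
    c = 2.0 * fy[1 : h_max + 1].real / k
    d = -2.0 * fy[1 : h_max + 1].imag / k
    if k % 2 == 0:  # Nyquist term appears once in the series
        a[-1] /= 2.0
        c[-1] /= 2.0
        b[-1] = 0.0
        d[-1] = 0.0
    locus = np.array([fx[0].real / k, fy[0].real / k])
    return np.column_stack([a, b, c, d]), locus


def efa(
    aligned: AlignedOutlineSet,
    power_target: float = 0.99,
    criterion: str = "mean",
) -> tuple[EFACoefficients, int]:
    """Elliptic Fourier transform of an aligned outline set with a calibrated
    harmonics search.

    H is the smallest harmonic count whose cumulative harmonic power reaches
    ``power_target`` — averaged over shapes (``criterion='mean'``, default)
    or required of every shape (``criterion='per_shape'``).  The returned
    coefficient set is truncated to H harmonics.
    """
    if not 0.0 < power_target <= 1.0:
        raise ValueError("power_target must be in (0, 1]")
    if aligned.n_shapes == 0:
        raise ValueError("empty aligned set")
    if criterion not in ("mean", "per_shape"):
        raise ValueError(f"unknown criterion {criterion!r}")
    full = _efa_full(aligned)
    cum = full.cumulative_power()
    profile = cum.mean(axis=0) if criterion == "mean" else cum.min(axis=0)
    h = int(np.searchsorted(profile, power_target - 1e-12) + 1)
    h = min(h, full.H)
    return EFACoefficients(full.coeffs[:, :h], full.locus, full.k), h


def _efa_full(aligned: AlignedOutlineSet) -> EFACoefficients:
    coeffs, loci = [], []
    for shape in aligned.coords:
        c, l = _efa_single(shape)
        coeffs.append(c)
        loci.append(l)
    return EFACoefficients(np.stack(coeffs), np.stack(loci), aligned.k)


def inverse_efa(
    coeffs: np.ndarray, k: int, locus: tuple[float, float] = (0.0, 0.0)
) -> np.ndarray:
    """Reconstruct a closed outline of ``k`` points from an (H, 4) harmonic
    coefficient block.  Exact inverse of :func:`efa` when all harmonics are
    retained and ``k`` matches the sampling used for the transform."""
    coeffs = np.asarray(coeffs, float)
    h = len(coeffs)
    t = np.arange(k) / k
    n = np.arange(1, h + 1)
    cos = np.cos(2 * np.pi * np.outer(t, n))
    sin = np.sin(2 * np.pi * np.outer(t, n))
    x = locus[0] + cos @ coeffs[:, 0] + sin @ coeffs[:, 1]
    y = locus[1] + cos @ coeffs[:, 2] + sin @ coeffs[:, 3]
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# morphospace
# ---------------------------------------------------------------------------


def build_morphospace(coefs: EFACoefficients, ids: list[str] | None = None) -> Morphospace:
    """PCA of the raw (unstandardized) EFA coefficient covariance.

    Axis signs are fixed deterministically: the shape with the largest
    absolute score on each axis scores positive.
    """
    mat = coefs.matrix()
    n = mat.shape[0]
    if n < 3:
        raise ValueError("need at least 3 shapes for a morphospace")
    mean = mat.mean(axis=0)
    centred = mat - mean
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    n_pc = int(min(n - 1, mat.shape[1]))
    u, s, vt = u[:, :n_pc], s[:n_pc], vt[:n_pc]
    eigenvalues = s**2 / (n - 1)
    scores = u * s
    # deterministic axis orientation
    for a in range(n_pc):
        imax = int(np.argmax(np.abs(scores[:, a])))
        if scores[imax, a] < 0:
            scores[:, a] *= -1
            vt[a] *= -1
    total_var = centred.var(axis=0, ddof=1).sum()
    return Morphospace(
        mean=mean,
        eigenvectors=vt,
        eigenvalues=eigenvalues,
        scores=scores,
        variance_fractions=eigenvalues / total_var,
        ids=list(ids) if ids is not None else [],
        H=coefs.H,
        k=coefs.k,
    )


def reconstruct_at(space: Morphospace, pc1: float, pc2: float, k: int | None = None) -> Outline:
    """Inverse-transform a (PC1, PC2) position into an outline (all other PC
    scores held at zero)."""
    k = k or space.k
    vec = space.mean + pc1 * space.eigenvectors[0] + pc2 * space.eigenvectors[1]
    pts = inverse_efa(vec.reshape(space.H, 4), k)
    return Outline(pts, id=f"warp({pc1:.3g},{pc2:.3g})", canonical=True)


def warp_grid(space: Morphospace, nx: int = 10, ny: int = 10, k: int | None = None) -> list[WarpModel]:
    """Reconstruct theoretical jaw shapes on a regular nx-by-ny lattice
    spanning the observed PC1 and PC2 ranges; models whose outlines
    self-intersect are flagged invalid (biologically impossible)."""
    if nx < 2 or ny < 2:
        raise ValueError("warp grid needs nx >= 2 and ny >= 2")
    if space.n_pc < 2:
        raise ValueError("morphospace has fewer than 2 PCs")
    xs = np.linspace(space.scores[:, 0].min(), space.scores[:, 0].max(), nx)
    ys = np.linspace(space.scores[:, 1].min(), space.scores[:, 1].max(), ny)
    models = []
    for j, y in enumerate(ys):
        for i, x in enumerate(xs):
            out = reconstruct_at(space, x, y, k)
            out.id = f"warp_{i}_{j}"
            models.append(WarpModel(i, j, float(x), float(y), out, not self_intersects(out)))
    return models
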