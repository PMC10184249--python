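"""Biomechanical traits of jaw outlines.

Two lever traits are measured directly on the outline geometry:

* aspect ratio AR = dorsoventral depth / anteroposterior length (1/AR is a
  proxy for jaw closing velocity), and
* mechanical advantage MA = in-lever / out-lever, with the in-lever running
  from the jaw joint to the dorsal-most point of the coronoid/adductor
  process and the out-lever from the joint to the anterior bite point.

Stiffness traits (tip deflection and strain energy) come from a simulated
cantilever bending test: the outline is extruded to a plate of thickness t,
rasterized into square bilinear (Q4) plane-stress finite elements, clamped
over small patches at the posterior-dorsal and posterior-ventral extremes,
and loaded ventrally at the anterior tip.  A Timoshenko beam closed form is
provided as an independent oracle for rectangular geometries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .outlines import Outline, WarpModel

__all__ = [
    "BiomechTraits",
    "SolverParams",
    "TraitGrid",
    "TRAIT_NAMES",
    "aspect_ratio",
    "mechanical_advantage",
    "cantilever_solve",
    "cantilever_beam_oracle",
    "compute_warp_traits",
    "trait_grid",
    "interpolate_bilinear",
]

TRAIT_NAMES = ("MA", "AR", "velocity", "deflection", "SE")


@dataclass
class BiomechTraits:
    """Trait bundle for one shape.  MA and AR are unitless and size-free;
    deflection is in mm and strain energy in N·mm (divide by 1000 for J)."""

    MA: float
    AR: float
    deflection: float = np.nan
    SE: float = np.nan
    deflection_raw: float = np.nan

    @property
    def velocity(self) -> float:
        return 1.0 / self.AR

    @property
    def SE_joules(self) -> float:
        return self.SE * 1e-3

    def as_dict(self) -> dict[str, float]:
        return {
            "MA": self.MA,
            "AR": self.AR,
            "velocity": self.velocity,
            "deflection": self.deflection,
            "SE": self.SE,
        }


@dataclass
class SolverParams:
    """Material, load and meshing parameters for the cantilever simulation.

    Defaults follow standard practice for bone-proxy linear static models:
    E = 20 GPa (= 20000 N/mm²), nu = 0.3, a 100 N ventral load, 10 mm
    extrusion thickness.  ``h`` is the element size in mm; when None it is
    set per shape to (anteroposterior extent)/150.  ``deflection_cap``
    mirrors a bench test with limited crosshead travel: the capped value is
    what downstream analyses consume; the raw value is also reported.
    """

    E: float = 20000.0
    nu: float = 0.3
    P: float = 100.0
    t: float = 10.0
    h: float | None = None
    kappa: float = 5.0 / 6.0
    deflection_cap: float = 10.0
    patch_radius: float | None = None

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not 0.0 <= self.nu < 0.5:
            raise ValueError("nu must lie in [0, 0.5)")
        if self.h is not None and self.h <= 0:
            raise ValueError("h must be positive")

    @property
    def G(self) -> float:
        return self.E / (2.0 * (1.0 + self.nu))


# ---------------------------------------------------------------------------
# lever traits
# ---------------------------------------------------------------------------


def _extents(pts: np.ndarray) -> tuple[float, float]:
    return float(np.ptp(pts[:, 0])), float(np.ptp(pts[:, 1]))


def aspect_ratio(outline: Outline) -> float:
    """Dorsoventral depth over anteroposterior length of the outline."""
    length, depth = _extents(outline.points)
    if length <= 0:
        raise ValueError("outline has zero anterior-posterior extent")
    return depth / length


def _pick(pts: np.ndarray, primary: np.ndarray, secondary: np.ndarray) -> np.ndarray:
    """Vertex maximizing `primary`, ties broken by maximizing `secondary`."""
    return pts[np.lexsort((-secondary, -primary))[0]]


def mechanical_advantage(outline: Outline) -> float:
    """In-lever/out-lever ratio of the jaw as a class III lever.

    The jaw joint is the posterior-most vertex (ties broken ventral-most);
    the in-lever runs to the dorsal-most vertex (ties posterior-most) and
    the out-lever to the anterior-most vertex (ties ventral-most).
    """
    pts = outline.points
    joint = _pick(pts, pts[:, 0], -pts[:, 1])
    dorsal = _pick(pts, pts[:, 1], pts[:, 0])
    anterior = _pick(pts, -pts[:, 0], -pts[:, 1])
    out_lever = float(np.hypot(*(joint - anterior)))
    if out_lever <= 0:
        raise ValueError("zero out-lever: joint and anterior bite point coincide")
    return float(np.hypot(*(joint - dorsal))) / out_lever


# ---------------------------------------------------------------------------
# plane-stress cantilever solver
# ---------------------------------------------------------------------------


def _q4_stiffness(E: float, nu: float, t: float) -> np.ndarray:
    """8x8 plane-stress stiffness of a square bilinear element (independent
    of element size), by 2x2 Gauss quadrature."""
    D = (E / (1 - nu**2)) * np.array(
        [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1 - nu) / 2.0]]
    )
    gp = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    ke = np.zeros((8, 8))
    for xi in gp:
        for eta in gp:
            dN = 0.25 * np.array(
                [
                    [-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)],
                    [-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)],
                ]
            )  # derivatives wrt xi, eta on [-1,1]^2; jacobian = h/2 * I
            B = np.zeros((3, 8))
            B[0, 0::2] = dN[0]
            B[1, 1::2] = dN[1]
            B[2, 0::2] = dN[1]
            B[2, 1::2] = dN[0]
            # (2/h) from dN/dx and (h/2)^2 from dA cancel to 1 for square cells
            ke += B.T @ D @ B
    return t * ke


def _posterior_extremes(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-dorsal and posterior-ventral extreme vertices, taken as the
    maximizers of x + y and x - y respectively."""
    pd_pt = pts[np.argmax(pts[:, 0] + pts[:, 1])]
    pv_pt = pts[np.argmax(pts[:, 0] - pts[:, 1])]
    return pd_pt, pv_pt


def cantilever_solve(
    outline: Outline, params: SolverParams | None = None
) -> tuple[float, float]:
    """Simulated cantilever bending test on an outline.

    Returns (deflection mm, strain_energy N·mm).  The deflection is the
    ventral displacement averaged over the loaded anterior patch, capped at
    ``params.deflection_cap`` (the raw value satisfies the work-energy
    identity SE = P·deflection_raw/2 exactly for this load case).
    """
    params = params or SolverParams()
    pts = outline.points
    length, depth = _extents(pts)
    h = params.h if params.h is not None else length / 150.0

    poly = shapely.Polygon(pts)
    if not poly.is_valid:
        raise ValueError("outline self-intersects; cannot mesh")

    minx, miny = pts[:, 0].min(), pts[:, 1].min()
    nx = max(int(np.ceil(length / h)), 1)
    ny = max(int(np.ceil(depth / h)), 1)
    cx = minx + (np.arange(nx) + 0.5) * h
    cy = miny + (np.arange(ny) + 0.5) * h
    CX, CY = np.meshgrid(cx, cy)  # (ny, nx)
    filled = shapely.contains_xy(poly, CX.ravel(), CY.ravel()).reshape(ny, nx)
    if not filled.any():
        raise ValueError("rasterization produced no filled elements; h too large")
    # keep the largest connected block so stray pixels cannot make K singular
    labels, nlab = ndimage.label(filled)
    if nlab > 1:
        filled = labels == (np.argmax(np.bincount(labels.ravel())[1:]) + 1)

    eidx = np.argwhere(filled)  # rows (iy, ix)
    n_nodes_x = nx + 1

    def node(ix: np.ndarray, iy: np.ndarray) -> np.ndarray:
        return iy * n_nodes_x + ix

    iy, ix = eidx[:, 0], eidx[:, 1]
    conn = np.stack(
        [node(ix, iy), node(ix + 1, iy), node(ix + 1, iy + 1), node(ix, iy + 1)], axis=1
    )
    active = np.unique(conn)
    remap = -np.ones((nx + 1) * (ny + 1), dtype=int)
    remap[active] = np.arange(len(active))
    conn = remap[conn]
    node_xy = np.column_stack(
        [minx + (active % n_nodes_x) * h, miny + (active // n_nodes_x) * h]
    )

    ke = _q4_stiffness(params.E, params.nu, params.t)
    dof = np.empty((len(conn), 8), dtype=int)
    dof[:, 0::2] = 2 * conn
    dof[:, 1::2] = 2 * conn + 1
    rows = np.repeat(dof, 8, axis=1).ravel()
    cols = np.tile(dof, (1, 8)).ravel()
    vals = np.tile(ke.ravel(), len(conn))
    ndof = 2 * len(active)
    K = sparse.coo_matrix((vals, (rows, cols)), shape=(ndof, ndof)).tocsc()

    pd_pt, pv_pt = _posterior_extremes(pts)
    ant_pt = pts[np.lexsort((pts[:, 1], pts[:, 0]))[0]]
    # constraint/load patches have a fixed physical radius (twice the default
    # element size) so refinement converges instead of shrinking toward
    # singular point constraints; coarse meshes widen to 2h to catch nodes.
    r_fixed = params.patch_radius if params.patch_radius is not None else 2.0 * length / 150.0
    r = max(r_fixed, 2.0 * h)

    def patch(point: np.ndarray) -> np.ndarray:
        d = np.hypot(*(node_xy - point).T)
        hit = np.where(d <= r)[0]
        # very thin regions can rasterize away from the patch radius: fall
        # back to the nearest active node so the contact is still applied
        return hit if len(hit) else np.array([int(np.argmin(d))])

    fixed_nodes = []
    for name, point in (("posterior-dorsal", pd_pt), ("posterior-ventral", pv_pt)):
        p = patch(point)
        if len(p) == 0:
            raise ValueError(f"no mesh nodes near the {name} constraint patch")
        fixed_nodes.append(p)
    fixed = np.unique(np.concatenate(fixed_nodes))
    loaded = np.setdiff1d(patch(ant_pt), fixed)
    if len(loaded) == 0:
        raise ValueError(
            "anterior load patch empty after removing constrained nodes: "
            "the shape's anterior tip overlaps its constraint patches"
        )

    f = np.zeros(ndof)
    f[2 * loaded + 1] = -params.P / len(loaded)

    fixed_dof = np.concatenate([2 * fixed, 2 * fixed + 1])
    free = np.setdiff1d(np.arange(ndof), fixed_dof)
    u = np.zeros(ndof)
    u_free = spsolve(K[np.ix_(free, free)], f[free])
    if not np.all(np.isfinite(u_free)):
        raise ValueError("singular stiffness system: constraints insufficient after rasterization")
    u[free] = u_free

    deflection_raw = float(-u[2 * loaded + 1].mean())
    strain_energy = float(0.5 * f @ u)
    return min(deflection_raw, params.deflection_cap), strain_energy


def cantilever_beam_oracle(L: float, d: float, params: SolverParams | None = None) -> float:
    """Timoshenko tip deflection of a rectangular cantilever: bending term
    PL³/(3EI) plus shear term PL/(κGA), with I = t·d³/12 and A = t·d."""
    if L <= 0 or d <= 0:
        raise ValueError("L and d must be positive")
    params = params or SolverParams()
    I = params.t * d**3 / 12.0
    A = params.t * d
    return params.P * L**3 / (3.0 * params.E * I) + params.P * L / (
        params.kappa * params.G * A
    )


# ---------------------------------------------------------------------------
# warp-grid traits and interpolation
# ---------------------------------------------------------------------------


def scaled_outline(outline: Outline, length: float) -> Outline:
    """Uniformly scale an outline so its anteroposterior extent equals
    ``length`` mm (warp shapes are unit-size; the bending test needs mm)."""
    cur = np.ptp(outline.points[:, 0])
    return Outline(outline.points * (length / cur), id=outline.id, canonical=outline.canonical)


def compute_warp_traits(
    warps: list[WarpModel],
    params: SolverParams | None = None,
    model_length: float = 100.0,
) -> pd.DataFrame:
    """Measure MA/AR on every warp model and run the cantilever simulation on
    the valid ones (scaled to a common ``model_length``), mirroring bench
    tests on identically sized physical models.  Returns one row per warp."""
    params = params or SolverParams()
    rows = []
    for w in warps:
        rec: dict[str, float | int | bool] = {
            "i": w.i, "j": w.j, "PC1": w.pc1, "PC2": w.pc2, "valid": w.valid,
        }
        if w.valid:
            out = scaled_outline(w.outline, model_length)
            rec["MA"] = mechanical_advantage(out)
            rec["AR"] = aspect_ratio(out)
            rec["velocity"] = 1.0 / rec["AR"]
            defl, se = cantilever_solve(out, params)
            rec["deflection"] = defl
            rec["SE"] = se
        else:
            rec.update({t: np.nan for t in TRAIT_NAMES})
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class TraitGrid:
    """Biomechanical trait values on the regular (PC1, PC2) warp lattice.

    ``values`` maps trait name to a (ny, nx) array; ``missing`` flags nodes
    that are invalid warps or were excluded by the analyst.
    """

    pc1: np.ndarray  # (nx,) lattice coordinates, ascending
    pc2: np.ndarray  # (ny,)
    values: dict[str, np.ndarray] = field(default_factory=dict)
    missing: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.pc2), len(self.pc1)

    def n_populated(self) -> int:
        return int((~self.missing).sum())


def trait_grid(
    warps: list[WarpModel],
    traits: pd.DataFrame,
    exclude: list[tuple[int, int]] | None = None,
) -> TraitGrid:
    """Arrange per-warp trait measurements on the lattice, masking invalid
    warps and analyst-excluded (i, j) nodes."""
    nx = max(w.i for w in warps) + 1
    ny = max(w.j for w in warps) + 1
    pc1 = np.full(nx, np.nan)
    pc2 = np.full(ny, np.nan)
    missing = np.ones((ny, nx), dtype=bool)
    values = {t: np.full((ny, nx), np.nan) for t in TRAIT_NAMES}
    valid_map = {(w.i, w.j): w.valid for w in warps}
    for w in warps:
        pc1[w.i], pc2[w.j] = w.pc1, w.pc2
    for _, row in traits.iterrows():
        i, j = int(row["i"]), int(row["j"])
        if not valid_map.get((i, j), False):
            if np.isfinite(row.get("MA", np.nan)):
                raise ValueError(f"trait record supplied for invalid warp ({i}, {j})")
            continue
        if not np.all(np.isfinite([row[t] for t in TRAIT_NAMES])):
            continue
        for t in TRAIT_NAMES:
            values[t][j, i] = row[t]
        missing[j, i] = False
    for i, j in exclude or []:
        missing[j, i] = True
        for t in TRAIT_NAMES:
            values[t][j, i] = np.nan
    return TraitGrid(pc1=pc1, pc2=pc2, values=values, missing=missing)


def interpolate_bilinear(
    grid: TraitGrid, points: np.ndarray, traits: tuple[str, ...] = TRAIT_NAMES
) -> pd.DataFrame:
    """Double linear interpolation of grid traits at (PC1, PC2) query points.

    Queries that coincide with a populated node return that node's values
    exactly.  A query inside a cell with any missing corner, or outside the
    lattice, returns NaN for every trait.
    """
    points = np.atleast_2d(np.asarray(points, float))
    nx, ny = len(grid.pc1), len(grid.pc2)
    px, py = points[:, 0], points[:, 1]
    nq = len(points)

    inside = (
        (px >= grid.pc1[0]) & (px <= grid.pc1[-1])
        & (py >= grid.pc2[0]) & (py <= grid.pc2[-1])
    )
    i = np.clip(np.searchsorted(grid.pc1, px, side="right") - 1, 0, nx - 2)
    j = np.clip(np.searchsorted(grid.pc2, py, side="right") - 1, 0, ny - 2)
    corners_ok = ~(
        grid.missing[j, i] | grid.missing[j, i + 1]
        | grid.missing[j + 1, i] | grid.missing[j + 1, i + 1]
    )
    tx = (px - grid.pc1[i]) / (grid.pc1[i + 1] - grid.pc1[i])
    ty = (py - grid.pc2[j]) / (grid.pc2[j + 1] - grid.pc2[j])
    w00 = (1 - tx) * (1 - ty)
    w10 = tx * (1 - ty)
    w01 = (1 - tx) * ty
    w11 = tx * ty

    # queries exactly on a populated lattice node bypass the cell rule
    eps_x = 1e-9 * max(np.ptp(grid.pc1), 1.0)
    eps_y = 1e-9 * max(np.ptp(grid.pc2), 1.0)
    ix = np.clip(np.searchsorted(grid.pc1, px), 0, nx - 1)
    ix = np.where(
        (ix > 0) & (np.abs(px - grid.pc1[np.maximum(ix - 1, 0)]) <= np.abs(px - grid.pc1[ix])),
        ix - 1, ix,
    )
    jy = np.clip(np.searchsorted(grid.pc2, py), 0, ny - 1)
    jy = np.where(
        (jy > 0) & (np.abs(py - grid.pc2[np.maximum(jy - 1, 0)]) <= np.abs(py - grid.pc2[jy])),
        jy - 1, jy,
    )
    on_node = (
        (np.abs(px - grid.pc1[ix]) <= eps_x)
        & (np.abs(py - grid.pc2[jy]) <= eps_y)
        & ~grid.missing[jy, ix]
    )
    ok = inside & corners_ok

    out = {}
    for t in traits:
        v = grid.values[t]
        vals = np.full(nq, np.nan)
        interp = (
            w00 * v[j, i] + w10 * v[j, i + 1] + w01 * v[j + 1, i] + w11 * v[j + 1, i + 1]
        )
        vals[ok] = interp[ok]
        vals[on_node] = v[jy[on_node], ix[on_node]]
        out[t] = vals
    return pd.DataFrame(out)
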