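"""Synthetic data with known ground truth for every pipeline stage.

The outline generator builds jaw-like closed polygons from smooth arcs — a
ventral arc, a dorsal corpus line with a Gaussian coronoid-process bump and
a posterior condyle — deliberately outside the elliptic-Fourier model class
so the EFA stage is exercised on shapes it cannot represent exactly.
Datasets pair two labelled clades on a pure-birth time tree, with jaw
parameters evolved by Brownian motion along the tree (phylogenetic signal)
around clade-specific means.  Trait simulators provide exact BM/OU/EB and
two-rate realizations, and landscape scenarios place taxa by rejection
sampling on a known weighted performance landscape.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .landscape import PerformanceSurface, evaluate_landscape, fit_surface, _lattice
from .outlines import Outline, canonicalize, self_intersects
from .phylo import TimeTree

__all__ = [
    "JawParams",
    "SimConfig",
    "make_outline",
    "pure_birth_tree",
    "two_clade_tree",
    "fossilize",
    "make_dataset",
    "simulate_traits",
    "make_landscape_scenario",
]


@dataclass
class JawParams:
    """Geometric parameters of a synthetic jaw outline (lengths in mm)."""

    length: float = 100.0
    corpus_depth: float = 20.0
    coronoid_height: float = 25.0
    coronoid_position: float = 0.72
    coronoid_width: float = 0.12
    ramus_curvature: float = 0.15
    condyle_depth: float = 8.0

    # the documented parameter box: outlines are closed, canonical and
    # non-self-intersecting anywhere inside it
    def validate(self) -> "JawParams":
        ok = (
            20.0 <= self.length <= 400.0
            and 0.02 * self.length <= self.corpus_depth <= 0.45 * self.length
            and 0.0 <= self.coronoid_height <= 0.6 * self.length
            and 0.5 < self.coronoid_position < 0.95
            and 0.05 <= self.coronoid_width <= 0.3
            and 0.0 <= self.ramus_curvature <= 0.5
            and 0.0 < self.condyle_depth <= self.corpus_depth
        )
        if not ok:
            raise ValueError(f"jaw parameters outside the documented box: {self}")
        return self

    def clipped(self) -> "JawParams":
        """Project onto the documented box (used after BM evolution)."""
        L = float(np.clip(self.length, 20.0, 400.0))
        return JawParams(
            length=L,
            corpus_depth=float(np.clip(self.corpus_depth, 0.02 * L, 0.45 * L)),
            coronoid_height=float(np.clip(self.coronoid_height, 0.0, 0.6 * L)),
            coronoid_position=float(np.clip(self.coronoid_position, 0.501, 0.949)),
            coronoid_width=float(np.clip(self.coronoid_width, 0.05, 0.3)),
            ramus_curvature=float(np.clip(self.ramus_curvature, 0.0, 0.5)),
            condyle_depth=float(np.clip(self.condyle_depth, 1e-3, self.corpus_depth)),
        )


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def make_outline(p: JawParams, id: str = "", n_dorsal: int = 220, n_ventral: int = 120) -> Outline:
    """Deterministic jaw-like closed outline in the canonical frame.

    Anterior tip at the origin, jaw joint at the posterior (max-x) end; the
    dorsal border carries a smooth coronoid bump of height
    ``coronoid_height`` at ``coronoid_position``·length.
    """
    p.validate()
    L = p.length

    xv = np.linspace(0.0, L, n_ventral)
    yv = -p.ramus_curvature * p.corpus_depth * np.sin(np.pi * xv / L)

    xd = np.linspace(L, 0.0, n_dorsal)
    rise = _smoothstep(xd / (0.15 * L))
    taper = 1.0 - (1.0 - p.condyle_depth / p.corpus_depth) * _smoothstep(
        (xd - 0.85 * L) / (0.15 * L)
    )
    bump = p.coronoid_height * np.exp(-(((xd - p.coronoid_position * L) / (p.coronoid_width * L)) ** 2))
    yd = p.corpus_depth * rise * taper + bump * rise

    pts = np.vstack(
        [np.column_stack([xv, yv]), np.column_stack([xd, yd])]
    )
    # drop near-duplicate consecutive points (the two chains meet at the ends)
    keep = np.ones(len(pts), bool)
    d = np.hypot(*np.diff(np.vstack([pts, pts[:1]]), axis=0).T)
    keep[1:] = d[:-1] > 1e-6 * L
    if d[-1] <= 1e-6 * L:
        keep[0] = keep[0] and True
        pts = pts[keep][:-1] if keep[-1] else pts[keep]
    else:
        pts = pts[keep]
    out = Outline(canonicalize(pts), id=id, canonical=True)
    if self_intersects(out):
        raise ValueError("generated outline self-intersects (parameters at the box edge?)")
    return out


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def pure_birth_tree(n_tips: int, height: float, seed: int, prefix: str = "t") -> TimeTree:
    """Pure-birth (Yule) tree scaled to the requested root-to-tip height."""
    dtree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        rng=_random.Random(int(seed)),
    )
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"{prefix}{i+1}"
    t = TimeTree.from_dendropy(dtree)
    scale = height / t.height
    # floor branch lengths: zero-length edges from the sampler would make
    # the BM covariance singular
    blen = np.maximum(t.blen * scale, 1e-4 * height)
    blen[0] = 0.0
    t = TimeTree(t.parent, blen, t.labels)
    return t


def fossilize(tree: TimeTree, fraction: float, seed: int) -> TimeTree:
    """Turn a fraction of tips into fossils by shortening their terminal
    branches (tips then end before the present, making the tree
    non-ultrametric as in datasets mixing extinct and extant taxa)."""
    rng = np.random.default_rng(seed)
    blen = tree.blen.copy()
    pick = rng.choice(tree.n_tips, int(round(fraction * tree.n_tips)), replace=False)
    for k in pick:
        node = int(tree.tip_nodes[k])
        blen[node] *= rng.uniform(0.05, 0.7)
    return TimeTree(tree.parent, blen, tree.labels)


def two_clade_tree(
    n_a: int, n_b: int, height: float, seed: int, stem_fraction: float = 0.3
) -> TimeTree:
    """Root joining two pure-birth clades (labelled A*/B*), total height
    ``height`` Myr with each clade on a stem of ``stem_fraction``·height."""
    stem = stem_fraction * height
    sub_h = height - stem
    ta = pure_birth_tree(n_a, sub_h, seed * 2 + 1, prefix="A")
    tb = pure_birth_tree(n_b, sub_h, seed * 2 + 2, prefix="B")
    na = ta.to_newick()[:-1]  # strip ';'
    nb = tb.to_newick()[:-1]
    return TimeTree.from_newick(f"({na}:{stem:.10g},{nb}:{stem:.10g});")


# ---------------------------------------------------------------------------
# trait simulation
# ---------------------------------------------------------------------------


def simulate_traits(
    tree: TimeTree, model: str, params: dict, seed: int = 0
) -> pd.Series:
    """Exact recursive simulation of a continuous trait along the tree.

    Models: ``BM`` (sigma2, z0), ``OU`` (sigma2, alpha, z0, optional theta),
    ``EB`` (sigma2, r, z0) and ``two_rate`` (sigma2, z0, scalar plus
    ``shift_node`` id or ``shift_tipset``).
    """
    model = model.lower()
    rng = np.random.default_rng(seed)
    z0 = float(params.get("z0", 0.0))
    sigma2 = float(params["sigma2"])
    values = np.empty(tree.n_nodes)
    values[0] = z0

    if model == "two_rate":
        shift = params.get("shift_node")
        if shift is None:
            tipset = frozenset(params["shift_tipset"])
            matches = [
                i for i in range(tree.n_nodes)
                if not tree.is_tip[i] and tree.clade_tipset(i) == tipset
            ]
            if not matches:
                raise ValueError("shift_tipset does not match any clade")
            shift = matches[0]
        in_clade = np.zeros(tree.n_nodes, bool)
        stack = [int(shift)]
        while stack:
            i = stack.pop()
            in_clade[i] = True
            stack.extend(tree.children[i])

    for i in range(1, tree.n_nodes):
        par = tree.parent[i]
        b = tree.blen[i]
        x = values[par]
        if model == "bm":
            values[i] = x + rng.normal(0.0, np.sqrt(sigma2 * b))
        elif model == "ou":
            alpha = float(params["alpha"])
            theta = float(params.get("theta", z0))
            if alpha * b < 1e-12:
                values[i] = x + rng.normal(0.0, np.sqrt(sigma2 * b))
            else:
                mean = theta + (x - theta) * np.exp(-alpha * b)
                var = sigma2 * (1.0 - np.exp(-2 * alpha * b)) / (2 * alpha)
                values[i] = mean + rng.normal(0.0, np.sqrt(var))
        elif model == "eb":
            r = float(params["r"])
            t1, t2 = tree.depth[par], tree.depth[i]
            bl = b if abs(r) < 1e-12 else (np.exp(r * t2) - np.exp(r * t1)) / r
            values[i] = x + rng.normal(0.0, np.sqrt(sigma2 * bl))
        elif model == "two_rate":
            s = float(params["scalar"]) if in_clade[i] else 1.0
            values[i] = x + rng.normal(0.0, np.sqrt(sigma2 * s * b))
        else:
            raise ValueError(f"unknown model {model!r}")
    return pd.Series(
        values[tree.tip_nodes], index=tree.tip_labels, name=f"{model}_trait"
    )


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

_PARAM_FIELDS = (
    "length", "corpus_depth", "coronoid_height", "coronoid_position",
    "coronoid_width", "ramus_curvature", "condyle_depth",
)


@dataclass
class SimConfig:
    """Configuration of a two-clade synthetic dataset.

    Clade A is generated deeper-jawed and higher-crowned than clade B by
    default, echoing a mammal-versus-non-mammal contrast in corpus depth and
    coronoid development.
    """

    seed: int
    n_taxa: tuple[int, int] = (40, 40)
    tree_height: float = 250.0
    n_trees: int = 1
    group_means: dict = field(default_factory=lambda: {
        "A": JawParams(length=100.0, corpus_depth=26.0, coronoid_height=30.0,
                       coronoid_position=0.72, coronoid_width=0.14,
                       ramus_curvature=0.18, condyle_depth=9.0),
        "B": JawParams(length=100.0, corpus_depth=14.0, coronoid_height=14.0,
                       coronoid_position=0.74, coronoid_width=0.12,
                       ramus_curvature=0.12, condyle_depth=7.0),
    })
    group_sds: dict = field(default_factory=lambda: {
        "length": 8.0, "corpus_depth": 3.5, "coronoid_height": 5.0,
        "coronoid_position": 0.04, "coronoid_width": 0.02,
        "ramus_curvature": 0.05, "condyle_depth": 1.2,
    })
    mass_log10_mean: float = 3.0   # ~1 kg
    mass_log10_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if any(v < 0 for v in self.group_sds.values()):
            raise ValueError("parameter sds must be nonnegative")


@dataclass
class SyntheticDataset:
    outlines: list[Outline]
    trees: list[TimeTree]
    groups: pd.Series
    masses: pd.Series
    params: pd.DataFrame


def make_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Generate outlines, a time-tree ensemble, group labels and body masses.

    Jaw parameters evolve by BM along the first tree (rate chosen so the
    marginal tip standard deviation equals the configured sd) around each
    clade's mean, then are clipped to the documented box — so shapes carry
    phylogenetic signal and clade structure, as real clades do.
    """
    rng = np.random.default_rng(cfg.seed)
    n_a, n_b = cfg.n_taxa
    trees = [
        two_clade_tree(n_a, n_b, cfg.tree_height, seed=int(cfg.seed * 1000 + k))
        for k in range(cfg.n_trees)
    ]
    tree = trees[0]
    groups = pd.Series(
        {t: ("A" if t.startswith("A") else "B") for t in tree.tip_labels}, name="group"
    )

    # BM deviations per parameter, variance-normalized to the configured sd
    devs = {}
    for j, fieldname in enumerate(_PARAM_FIELDS):
        sd = cfg.group_sds[fieldname]
        dev = simulate_traits(
            tree, "bm", {"sigma2": 1.0 / cfg.tree_height, "z0": 0.0},
            seed=int(rng.integers(2**31)),
        )
        devs[fieldname] = dev * sd

    records, outlines = {}, []
    for label in tree.tip_labels:
        mean = cfg.group_means[groups[label]]
        raw = JawParams(**{
            f: getattr(mean, f) + float(devs[f][label]) for f in _PARAM_FIELDS
        })
        p = raw.clipped()
        records[label] = {f: getattr(p, f) for f in _PARAM_FIELDS}
        outlines.append(make_outline(p, id=label))
    masses = pd.Series(
        rng.normal(cfg.mass_log10_mean, cfg.mass_log10_sd, len(tree.tip_labels)),
        index=tree.tip_labels, name="log10_mass",
    )
    return SyntheticDataset(
        outlines=outlines,
        trees=trees,
        groups=groups,
        masses=masses,
        params=pd.DataFrame(records).T,
    )


# ---------------------------------------------------------------------------
# landscape scenarios
# ---------------------------------------------------------------------------


def make_landscape_scenario(
    true_weights,
    n_taxa: int = 50,
    seed: int = 0,
    bounds: tuple[float, float, float, float] = (-1.0, 1.0, -1.0, 1.0),
    curvature: float = 6.0,
) -> dict:
    """Four known quadratic performance surfaces plus taxa placed by
    rejection sampling proportional to the combined landscape at
    ``true_weights``.

    The surfaces are equal-curvature bowls peaking at the four corners of
    the morphospace box, so each weight has a distinct, recoverable
    signature in where taxa concentrate.
    """
    w = np.asarray(true_weights, float)
    if len(w) != 4 or np.any(w < 0) or abs(w.sum() - 1) > 1e-9:
        raise ValueError("true_weights must be a length-4 simplex vector")
    # distinct peak locations AND curvature matrices: mixtures of these are
    # affinely inequivalent, so the weights are identifiable (curvature
    # *scale* is irrelevant — surface standardization absorbs it)
    lat = _lattice(bounds, 50)
    x, y = lat[:, 0], lat[:, 1]
    shapes = [
        -((x + 0.7) ** 2 + (y + 0.7) ** 2),
        -(3.0 * (x - 0.7) ** 2 + 0.3 * (y + 0.7) ** 2),
        -(0.3 * (x + 0.7) ** 2 + 3.0 * (y - 0.7) ** 2),
        -((x - 0.7) ** 2 + (y - 0.7) ** 2),
    ]
    surfaces = [
        fit_surface(lat, curvature * v, bounds=bounds, trait=f"F{k+1}")
        for k, v in enumerate(shapes)
    ]
    # flatness guard: the combined raw landscape must vary over the lattice
    comb = evaluate_landscape(surfaces, w, lat)
    if comb.max() - comb.min() < 1e-9:
        raise ValueError("combined landscape is flat; cannot place taxa")
    rng = np.random.default_rng(seed)
    pts = []
    lo = np.array([bounds[0], bounds[2]])
    hi = np.array([bounds[1], bounds[3]])
    while len(pts) < n_taxa:
        cand = rng.uniform(lo, hi, size=(4 * n_taxa, 2))
        acc = rng.uniform(size=len(cand)) < evaluate_landscape(surfaces, w, cand)
        pts.extend(cand[acc])
    return {"surfaces": surfaces, "points": np.array(pts[:n_taxa]), "true_weights": w}
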