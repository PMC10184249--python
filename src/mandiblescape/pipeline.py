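"""End-to-end orchestration: synthetic data (or outline files) through
morphospace, biomechanics, statistics, adaptive landscape and trait
evolution, driven by one config with a single global seed.

The global seed fans out to per-stage seeds at fixed offsets so any stage
can be re-run in isolation and reproduce byte-identical artifacts.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import biomech as bm
from . import landscape as ls
from . import phylo as ph
from . import stats as st
from . import synthetic as syn
from .io import write_csv_with_seed, write_outline_csv, write_warp_svg
from .outlines import build_morphospace, efa, procrustes_align, resample_outline, warp_grid

__all__ = ["RunConfig", "run_pipeline", "load_config"]

STAGE_ORDER = ["simulate", "outlines", "biomech", "stats", "landscape", "phylo"]
SEED_OFFSETS = {s: 1000 * i for i, s in enumerate(STAGE_ORDER)}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    out_dir: str
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    n_taxa: tuple[int, int] = (30, 30)
    tree_height: float = 250.0
    n_trees: int = 1
    outlines_path: str | None = None   # optional: skip 'simulate', read CSV
    k: int = 300
    power: float = 0.99
    grid: tuple[int, int] = (10, 10)
    solver: dict = field(default_factory=dict)
    model_length: float = 100.0
    exclude: list[tuple[int, int]] = field(default_factory=list)
    n_sets: int = 200
    n_draws: int = 500
    n_boot: int = 100
    step: float = 0.05
    models: tuple[str, ...] = ("BM", "OU", "EB")
    min_clade: int = 5
    n_perm: int = 999
    write_svg: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.outlines_path is not None and not os.path.exists(self.outlines_path):
            raise ValueError(f"outlines_path does not exist: {self.outlines_path}")
        self.stages = [s for s in STAGE_ORDER if s in self.stages]


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("n_taxa", "grid"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "exclude" in raw:
        raw["exclude"] = [tuple(e) for e in raw["exclude"]]
    if "models" in raw:
        raw["models"] = tuple(raw["models"])
    return RunConfig(**raw)


def _stage_seed(cfg: RunConfig, stage: str) -> int:
    return int(cfg.seed + SEED_OFFSETS[stage])


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages in dependency order, writing per-stage
    CSV/JSON artifacts plus a consolidated ``report.json`` into
    ``cfg.out_dir``.  Returns the report dict."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    log: list[str] = []
    report: dict = {"seed": cfg.seed, "stages": cfg.stages, "counts": {}, "artifacts": []}
    ctx: dict = {}

    def art(name: str) -> str:
        path = os.path.join(cfg.out_dir, name)
        report["artifacts"].append(name)
        return path

    def need(stage: str, key: str):
        if key not in ctx:
            raise RuntimeError(
                f"stage {stage!r} requires upstream artifact {key!r}; "
                f"run its producing stage first"
            )
        return ctx[key]

    if "simulate" in cfg.stages:
        seed = _stage_seed(cfg, "simulate")
        ds = syn.make_dataset(syn.SimConfig(
            seed=seed, n_taxa=cfg.n_taxa, tree_height=cfg.tree_height,
            n_trees=cfg.n_trees,
        ))
        ctx["outlines"] = ds.outlines
        ctx["trees"] = ds.trees
        ctx["groups"] = ds.groups
        ctx["masses"] = ds.masses
        write_outline_csv(ds.outlines, art("outlines.csv"), seed=cfg.seed)
        with open(art("trees.nwk"), "w") as fh:
            for t in ds.trees:
                fh.write(t.to_newick() + "\n")
        meta = pd.DataFrame({"group": ds.groups, "log10_mass": ds.masses})
        meta.index.name = "taxon"
        write_csv_with_seed(meta.reset_index(), art("taxa.csv"), seed=cfg.seed)
        report["counts"]["simulate"] = {"taxa_in": len(ds.outlines), "taxa_dropped": 0}
        log.append(f"simulate: {len(ds.outlines)} taxa, {len(ds.trees)} trees, seed {seed}")
    elif cfg.outlines_path is not None:
        from .io import read_outline_csv

        ctx["outlines"] = read_outline_csv(cfg.outlines_path)
        log.append(f"loaded {len(ctx['outlines'])} outlines from {cfg.outlines_path}")

    if "outlines" in cfg.stages:
        outlines = need("outlines", "outlines")
        res = [resample_outline(o, cfg.k) for o in outlines]
        aligned = procrustes_align(res)
        coefs, H = efa(aligned, cfg.power)
        space = build_morphospace(coefs, ids=aligned.ids)
        warps = warp_grid(space, *cfg.grid)
        ctx["space"], ctx["warps"] = space, warps
        scores = pd.DataFrame(
            space.scores[:, : min(10, space.n_pc)],
            index=space.ids,
            columns=[f"PC{i+1}" for i in range(min(10, space.n_pc))],
        )
        scores.index.name = "taxon"
        write_csv_with_seed(scores.reset_index(), art("scores.csv"), seed=cfg.seed)
        if cfg.write_svg:
            svg_dir = os.path.join(cfg.out_dir, "warps")
            os.makedirs(svg_dir, exist_ok=True)
            for w in warps:
                write_warp_svg(w, os.path.join(svg_dir, f"{w.outline.id}.svg"))
        n_valid = sum(w.valid for w in warps)
        report["counts"]["outlines"] = {
            "taxa_in": len(outlines), "taxa_dropped": 0,
            "harmonics": H,
            "pc12_variance_pct": float(space.variance_fractions[:2].sum() * 100),
            "warps_valid": n_valid, "warps_invalid": len(warps) - n_valid,
        }
        log.append(f"outlines: H={H}, PC1+PC2 {report['counts']['outlines']['pc12_variance_pct']:.1f}%")

    if "biomech" in cfg.stages:
        space = need("biomech", "space")
        warps = need("biomech", "warps")
        params = bm.SolverParams(**cfg.solver)
        warp_traits = bm.compute_warp_traits(warps, params, cfg.model_length)
        grid = bm.trait_grid(warps, warp_traits, exclude=cfg.exclude)
        taxa_traits = bm.interpolate_bilinear(grid, space.scores[:, :2])
        taxa_traits.index = pd.Index(space.ids, name="taxon")
        ctx["grid"], ctx["taxa_traits"] = grid, taxa_traits
        write_csv_with_seed(warp_traits, art("warp_traits.csv"), seed=cfg.seed)
        write_csv_with_seed(taxa_traits.reset_index(), art("taxon_traits.csv"), seed=cfg.seed)
        n_missing = int(taxa_traits["MA"].isna().sum())
        report["counts"]["biomech"] = {
            "taxa_in": len(taxa_traits),
            "taxa_dropped": n_missing,
            "grid_populated": grid.n_populated(),
        }
        log.append(f"biomech: {grid.n_populated()} grid nodes, {n_missing} taxa uninterpolable")

    if "stats" in cfg.stages:
        space = need("stats", "space")
        grid = need("stats", "grid")
        taxa_traits = need("stats", "taxa_traits")
        groups = need("stats", "groups")
        seed = _stage_seed(cfg, "stats")
        nulltest = st.null_morphospace_test(
            space.scores[:, :2], grid, n_sets=cfg.n_sets, n_draws=cfg.n_draws, seed=seed
        )
        with open(art("nulltest.json"), "w") as fh:
            json.dump(nulltest, fh, indent=2, default=float)
        keep = taxa_traits.dropna()
        summary = st.group_trait_summary(keep, groups, group_order=("A", "B"))
        write_csv_with_seed(summary, art("group_summary.csv"), seed=cfg.seed)
        disp = st.disparity(
            space.scores[:, :2], groups[list(space.ids)].to_numpy(),
            n_boot=cfg.n_boot, seed=seed + 1,
        )
        disp_report = {
            "metric": disp.metric, "observed": disp.observed,
            "rarefy_n": disp.rarefy_n, "p_between": disp.p_between,
        }
        masses = ctx.get("masses")
        allo = None
        if masses is not None:
            allo = st.allometry_scan(keep, masses)
            allo_df = allo["traits"]
            write_csv_with_seed(allo_df, art("allometry.csv"), seed=cfg.seed)
        with open(art("disparity.json"), "w") as fh:
            json.dump(disp_report, fh, indent=2, default=float)
        report["counts"]["stats"] = {
            "taxa_in": len(taxa_traits), "taxa_dropped": len(taxa_traits) - len(keep),
        }
        log.append(f"stats: disparity p={disp.p_between:.3f}")

    if "landscape" in cfg.stages:
        space = need("landscape", "space")
        grid = need("landscape", "grid")
        groups = need("landscape", "groups")
        surfaces = _performance_surfaces(grid)
        sols = {}
        for gname in sorted(groups.unique()):
            members = [t for t in space.ids if groups[t] == gname]
            pts = space.scores[[space.ids.index(t) for t in members], :2]
            sols[gname] = ls.optimize_weights(surfaces, pts, step=cfg.step)
        pairs = {}
        names = sorted(sols)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pairs[f"{names[i]}|{names[j]}"] = ls.compare_groups(sols[names[i]], sols[names[j]])
        lreport = {
            g: {
                "weights": sols[g].weights.tolist(),
                "traits": [s.trait for s in surfaces],
                "lnL": sols[g].lnl,
                "z": sols[g].z,
                "confidence_set_size": len(sols[g].confidence_set),
            }
            for g in names
        }
        lreport["pairwise"] = pairs
        with open(art("landscape.json"), "w") as fh:
            json.dump(lreport, fh, indent=2, default=float)
        ctx["landscape_solutions"] = sols
        report["counts"]["landscape"] = {"groups": len(names)}
        log.append("landscape: " + "; ".join(
            f"{g}: w={np.round(sols[g].weights, 2).tolist()}" for g in names))

    if "phylo" in cfg.stages:
        trees = need("phylo", "trees")
        taxa_traits = need("phylo", "taxa_traits")
        space = need("phylo", "space")
        groups = need("phylo", "groups")
        seed = _stage_seed(cfg, "phylo")
        tree = trees[0]
        fit_rows = []
        shift_results = []
        for trait in ("MA", "AR", "deflection"):
            series = taxa_traits[trait].dropna()
            fits = [ph.fit_trait_model(tree, series, m) for m in cfg.models]
            table = ph.aicc_select(fits)
            table.insert(0, "trait", trait)
            fit_rows.append(table)
            for t in trees:
                shift_results.append(ph.two_rate_search(t, series, min_clade=cfg.min_clade))
        fits_df = pd.concat(fit_rows, ignore_index=True)
        write_csv_with_seed(fits_df, art("phylo_fits.csv"), seed=cfg.seed)
        shifts = ph.summarize_shifts(shift_results, reference=tree)
        write_csv_with_seed(shifts, art("shift_summary.csv"), seed=cfg.seed)
        scores_df = pd.DataFrame(
            space.scores, index=space.ids,
            columns=[f"PC{i+1}" for i in range(space.n_pc)],
        )
        mv = ph.multivariate_rate_test(tree, scores_df, groups, n_perm=cfg.n_perm, seed=seed)
        with open(art("shape_rates.json"), "w") as fh:
            json.dump(mv, fh, indent=2, default=float)
        ctx["phylo_fits"] = fits_df
        ctx["shape_rates"] = mv
        report["counts"]["phylo"] = {
            "trees": len(trees),
            "shifts_found": sum(r is not None for r in shift_results),
        }
        log.append(f"phylo: shape rate ratio {mv['ratio']:.2f} (p={mv['p']:.3f})")

    report["log"] = log
    with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    ctx["report"] = report
    return report


def _performance_surfaces(grid: bm.TraitGrid) -> list[ls.PerformanceSurface]:
    """The four performance surfaces of the adaptive landscape analysis:
    negated strain energy (stiffness, higher = better), MA (force), 1/AR
    (speed) and AR (displacement/compliance)."""
    X, Y = np.meshgrid(grid.pc1, grid.pc2)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    ok = ~grid.missing.ravel()
    bounds = (grid.pc1[0], grid.pc1[-1], grid.pc2[0], grid.pc2[-1])
    spec = [
        ("SE", -grid.values["SE"].ravel(), True),
        ("MA", grid.values["MA"].ravel(), False),
        ("speed", grid.values["velocity"].ravel(), False),
        ("AR", grid.values["AR"].ravel(), False),
    ]
    return [
        ls.fit_surface(pts[ok], vals[ok], bounds=bounds, trait=name, negated=neg)
        for name, vals, neg in spec
    ]
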