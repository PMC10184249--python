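"""Distribution, disparity and allometry statistics.

These are the dataset-level tests around the morphospace: null tests of
whether observed taxa differ from shapes placed at random in the
morphospace, bootstrap/rarefied disparity contrasts between groups, a
mammal-vs-non-mammal style trait summary table, and body-mass allometry
scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .biomech import TRAIT_NAMES, TraitGrid, interpolate_bilinear

__all__ = [
    "wilcoxon_rank_sum",
    "null_morphospace_test",
    "DisparityResult",
    "disparity",
    "group_trait_summary",
    "allometry_scan",
]


def wilcoxon_rank_sum(x, y) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when min(n, m) <= 8 and there are no ties; otherwise
    the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        import warnings

        warnings.warn("all values identical in both samples; p = 1")
        return {"statistic": float(len(x) * len(y) / 2), "p": 1.0}
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}


def null_morphospace_test(
    scores: np.ndarray,
    grid: TraitGrid,
    n_sets: int = 1000,
    n_draws: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Test observed morphospace occupancy against random placement.

    ``n_sets`` simulated datasets of ``n_draws`` (PC1, PC2) points are drawn
    uniformly over the warp-lattice bounding box; biomechanical traits are
    interpolated for each (draws landing in missing cells are dropped and
    the effective n recorded).  Per dataset, a rank-sum test compares the
    simulated distribution against the observed taxa for PC1, PC2 and every
    grid trait; the summary is the fraction of datasets significant at
    ``alpha`` plus one pooled test over all simulated draws.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    if len(scores) == 0:
        raise ValueError("empty observed set")
    if grid.missing.all():
        raise ValueError("trait grid has no populated nodes")
    rng = np.random.default_rng(seed)
    obs_traits = interpolate_bilinear(grid, scores)
    obs = {"PC1": scores[:, 0], "PC2": scores[:, 1]}
    for t in TRAIT_NAMES:
        v = obs_traits[t].to_numpy()
        obs[t] = v[np.isfinite(v)]

    lo = np.array([grid.pc1[0], grid.pc2[0]])
    hi = np.array([grid.pc1[-1], grid.pc2[-1]])
    variables = list(obs.keys())
    sig = {v: 0 for v in variables}
    pooled: dict[str, list[np.ndarray]] = {v: [] for v in variables}
    eff_n = []
    for _ in range(n_sets):
        draws = rng.uniform(lo, hi, size=(n_draws, 2))
        sim_traits = interpolate_bilinear(grid, draws)
        sim = {"PC1": draws[:, 0], "PC2": draws[:, 1]}
        kept = 0
        for t in TRAIT_NAMES:
            v = sim_traits[t].to_numpy()
            v = v[np.isfinite(v)]
            sim[t] = v
            kept = len(v)
        eff_n.append(kept)
        for v in variables:
            if len(sim[v]) == 0 or len(obs[v]) == 0:
                continue
            if wilcoxon_rank_sum(sim[v], obs[v])["p"] < alpha:
                sig[v] += 1
            pooled[v].append(sim[v])
    out = {
        "n_sets": n_sets,
        "n_draws": n_draws,
        "effective_n_mean": float(np.mean(eff_n)),
        "per_variable": {},
    }
    for v in variables:
        allsim = np.concatenate(pooled[v]) if pooled[v] else np.array([])
        pooled_p = (
            wilcoxon_rank_sum(allsim, obs[v])["p"] if len(allsim) and len(obs[v]) else np.nan
        )
        out["per_variable"][v] = {
            "significant_fraction": sig[v] / n_sets,
            "pooled_p": pooled_p,
        }
    return out


# ---------------------------------------------------------------------------
# disparity
# ---------------------------------------------------------------------------


def _sum_of_variances(m: np.ndarray) -> float:
    return float(m.var(axis=0, ddof=1).sum())


def _mean_pairwise_distance(m: np.ndarray) -> float:
    from scipy.spatial.distance import pdist

    return float(pdist(m).mean())


_METRICS = {
    "sum_of_variances": _sum_of_variances,
    "mean_pairwise_distance": _mean_pairwise_distance,
}


@dataclass
class DisparityResult:
    """Group disparity with bootstrap and rarefaction distributions."""

    metric: str
    observed: dict[str, float]
    bootstrap: dict[str, np.ndarray]
    rarefied: dict[str, np.ndarray]
    rarefy_n: int
    p_between: float
    groups: list[str] = field(default_factory=list)


def disparity(
    matrix: np.ndarray,
    groups,
    metric: str = "sum_of_variances",
    n_boot: int = 100,
    rarefy: bool = True,
    seed: int = 0,
) -> DisparityResult:
    """Group disparity in a taxa × dims matrix.

    Bootstrap resamples taxa with replacement within each group; rarefied
    bootstrap subsamples every group to the smallest group's n so uneven
    sampling cannot drive the contrast.  The between-group p is the
    two-sided overlap of the rarefied (or plain bootstrap) distributions:
    2·min(P(A > B), P(B > A)).
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; options: {sorted(_METRICS)}")
    fn = _METRICS[metric]
    matrix = np.atleast_2d(np.asarray(matrix, float))
    groups = np.asarray(groups)
    names = [str(g) for g in pd.unique(groups)]
    idx = {g: np.where(groups == g)[0] for g in names}
    for g, ii in idx.items():
        if len(ii) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 taxa")
    n_min = min(len(ii) for ii in idx.values())
    rng = np.random.default_rng(seed)
    observed, boot, rare = {}, {}, {}
    for g, ii in idx.items():
        observed[g] = fn(matrix[ii])
        boot[g] = np.array(
            [fn(matrix[rng.choice(ii, len(ii), replace=True)]) for _ in range(n_boot)]
        )
        if rarefy:
            rare[g] = np.array(
                [fn(matrix[rng.choice(ii, n_min, replace=True)]) for _ in range(n_boot)]
            )
        else:
            rare[g] = boot[g]
    if len(names) == 2:
        a, b = rare[names[0]], rare[names[1]]
        p = 2.0 * min((a[:, None] > b[None, :]).mean(), (b[:, None] > a[None, :]).mean())
        p = min(max(p, 1.0 / (n_boot * n_boot)), 1.0)
    else:
        p = np.nan
    return DisparityResult(
        metric=metric,
        observed=observed,
        bootstrap=boot,
        rarefied=rare,
        rarefy_n=n_min,
        p_between=float(p),
        groups=names,
    )


# ---------------------------------------------------------------------------
# group contrasts and allometry
# ---------------------------------------------------------------------------


def group_trait_summary(
    traits: pd.DataFrame,
    groups: pd.Series,
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-trait contrast table between two groups (A vs B): medians, means,
    A:B percentage ratios of both, rank-sum p and one-way ANOVA p.

    Taxa missing a trait are dropped for that trait and counted in the
    ``n_dropped`` columns.
    """
    g = groups.dropna().astype(str)
    names = list(group_order) if group_order else sorted(g.unique())
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    a_name, b_name = names
    rows = []
    for trait in traits.columns:
        v = traits[trait]
        common = v.index.intersection(g.index)
        va = v[common][g[common] == a_name].astype(float)
        vb = v[common][g[common] == b_name].astype(float)
        na_drop = int(va.isna().sum() + vb.isna().sum())
        va, vb = va.dropna(), vb.dropna()
        if len(va) == 0 or len(vb) == 0:
            raise ValueError(f"a group has no values for trait {trait!r}")
        rs = wilcoxon_rank_sum(va, vb)
        anova_p = float(sps.f_oneway(va, vb).pvalue)
        rows.append(
            {
                "trait": trait,
                f"{a_name}_median": va.median(),
                f"{b_name}_median": vb.median(),
                "median_ratio_pct": 100.0 * va.median() / vb.median(),
                f"{a_name}_mean": va.mean(),
                f"{b_name}_mean": vb.mean(),
                "mean_ratio_pct": 100.0 * va.mean() / vb.mean(),
                "wilcoxon_p": rs["p"],
                "anova_p": anova_p,
                "n_dropped": na_drop,
            }
        )
    return pd.DataFrame(rows)


def allometry_scan(
    traits: pd.DataFrame,
    log10_mass: pd.Series,
    adductor_mass: pd.Series | None = None,
) -> dict:
    """Ordinary least squares of each trait on log10 body mass (slope, R²),
    plus the allometric exponent of adductor muscle mass on body mass (the
    slope of the log-log 'power trend line')."""
    rows = []
    for trait in traits.columns:
        merged = pd.concat([traits[trait], log10_mass.rename("lm")], axis=1).dropna()
        res = sps.linregress(merged["lm"], merged[trait])
        rows.append(
            {
                "trait": trait,
                "slope": float(res.slope),
                "intercept": float(res.intercept),
                "r_squared": float(res.rvalue**2),
                "p": float(res.pvalue),
                "n": len(merged),
            }
        )
    out = {"traits": pd.DataFrame(rows)}
    if adductor_mass is not None:
        merged = pd.concat(
            [adductor_mass.rename("add"), log10_mass.rename("lm")], axis=1
        ).dropna()
        if (merged["add"] <= 0).any():
            bad = merged.index[merged["add"] <= 0].tolist()
            raise ValueError(f"non-positive adductor mass for rows {bad}")
        res = sps.linregress(merged["lm"], np.log10(merged["add"]))
        out["adductor"] = {
            "exponent": float(res.slope),
            "intercept": float(res.intercept),
            "r_squared": float(res.rvalue**2),
            "n": len(merged),
        }
    return out
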