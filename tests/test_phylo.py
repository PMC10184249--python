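"""Trait-evolution model fits, rate shifts, multivariate rates, ancestral
states."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from mandiblescape.phylo import (
    TimeTree,
    aicc_select,
    ancestral_states_bm,
    fit_trait_model,
    multivariate_rate_test,
    read_trees,
    summarize_shifts,
    two_rate_search,
)
from mandiblescape.phylo import _gls_profile
from mandiblescape.synthetic import (
    fossilize,
    pure_birth_tree,
    simulate_traits,
    two_clade_tree,
)


@pytest.fixture(scope="module")
def tree50():
    return pure_birth_tree(50, 100.0, seed=7)


@pytest.fixture(scope="module")
def traits50(tree50):
    return simulate_traits(tree50, "bm", {"sigma2": 1.5, "z0": 2.0}, seed=3)


class TestTreeContainer:
    def test_newick_round_trip(self, tree50):
        back = read_trees(tree50.to_newick())[0]
        assert back.tip_labels == tree50.tip_labels
        np.testing.assert_allclose(back.mrca_depths(), tree50.mrca_depths(), atol=1e-9)

    def test_non_ultrametric_allowed(self):
        t = read_trees("((A:1,B:0.2):1,C:0.5);")[0]
        depths = dict(zip(t.tip_labels, t.depth[t.tip_nodes]))
        assert depths["A"] == pytest.approx(2.0)
        assert depths["C"] == pytest.approx(0.5)

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            read_trees("((A:1,B:-0.5):1,C:1);")

    def test_clade_tipsets(self):
        t = read_trees("((A:1,B:1):1,(C:1,D:1):1);")[0]
        sets = {t.clade_tipset(i) for i in range(t.n_nodes) if not t.is_tip[i]}
        assert frozenset({"A", "B"}) in sets
        assert frozenset({"C", "D"}) in sets


class TestModelFits:
    def test_ou_limit_is_bm(self, tree50, traits50):
        bm = fit_trait_model(tree50, traits50, "BM")
        ou = fit_trait_model(tree50, traits50, "OU", fixed_param=1e-8)
        assert ou.lnl == pytest.approx(bm.lnl, abs=1e-4)

    def test_eb_limit_is_bm(self, tree50, traits50):
        bm = fit_trait_model(tree50, traits50, "BM")
        eb = fit_trait_model(tree50, traits50, "EB", fixed_param=0.0)
        assert eb.lnl == pytest.approx(bm.lnl, abs=1e-6)

    def test_bm_lnl_matches_mvnormal(self, tree50, traits50):
        """Dual route: profiled GLS likelihood equals a direct multivariate
        normal density at the fitted parameters."""
        fit = fit_trait_model(tree50, traits50, "BM")
        C = tree50.mrca_depths() * fit.sigma2
        x = traits50[tree50.tip_labels].to_numpy()
        direct = stats.multivariate_normal.logpdf(x, mean=np.full(len(x), fit.z0), cov=C)
        assert fit.lnl == pytest.approx(direct, abs=1e-6)

    def test_bm_sigma2_recovery(self):
        tree = pure_birth_tree(100, 100.0, seed=11)
        est = [
            fit_trait_model(
                tree, simulate_traits(tree, "bm", {"sigma2": 2.5, "z0": 0.0}, seed=s), "BM"
            ).sigma2
            for s in range(30)
        ]
        assert np.mean(est) == pytest.approx(2.5, rel=0.1)

    def test_tip_reordering_invariance(self, tree50, traits50):
        shuffled = traits50.sample(frac=1.0, random_state=0)
        a = fit_trait_model(tree50, traits50, "BM")
        b = fit_trait_model(tree50, shuffled, "BM")
        assert a.lnl == pytest.approx(b.lnl, abs=1e-10)

    def test_time_rescaling(self, tree50, traits50):
        """t -> c*t rescales sigma-hat^2 by 1/c; the profiled likelihood is
        unchanged (the rate absorbs the Jacobian)."""
        c = 3.7
        scaled = TimeTree(tree50.parent, tree50.blen * c, tree50.labels)
        a = fit_trait_model(tree50, traits50, "BM")
        b = fit_trait_model(scaled, traits50, "BM")
        assert b.sigma2 == pytest.approx(a.sigma2 / c, rel=1e-9)
        assert b.lnl == pytest.approx(a.lnl, abs=1e-8)

    def test_missing_tips_pruned_with_warning(self, tree50, traits50):
        partial = traits50.drop(traits50.index[:5])
        with pytest.warns(UserWarning, match="pruning"):
            fit = fit_trait_model(tree50, partial, "BM")
        assert fit.n == tree50.n_tips - 5

    def test_ou_alpha_recovery_prefers_ou(self):
        """Strong attraction (alpha*T = 5) makes OU the AICc winner on a
        non-ultrametric (fossil-tip) tree.  On ultrametric trees OU and
        accelerating EB are covariance-equivalent, so fossils are what make
        the models distinguishable."""
        tree = fossilize(pure_birth_tree(150, 100.0, seed=21), 0.5, seed=99)
        wins = 0
        for s in range(10):
            tr = simulate_traits(
                tree, "ou", {"sigma2": 1.0, "alpha": 0.05, "z0": 0.0}, seed=s
            )
            fits = [fit_trait_model(tree, tr, m) for m in ("BM", "OU", "EB")]
            table = aicc_select(fits)
            if table.loc[0, "model"] == "OU" and table.loc[0, "weight"] > 0.9:
                wins += 1
        assert wins >= 8


class TestAICc:
    def test_single_model_weight_one(self, tree50, traits50):
        table = aicc_select([fit_trait_model(tree50, traits50, "BM")])
        assert table["weight"].iloc[0] == pytest.approx(1.0)

    def test_equal_aicc_split_evenly(self, tree50, traits50):
        f = fit_trait_model(tree50, traits50, "BM")
        table = aicc_select([f, f])
        np.testing.assert_allclose(table["weight"], [0.5, 0.5])

    def test_weights_sum_to_one(self, tree50, traits50):
        fits = [fit_trait_model(tree50, traits50, m) for m in ("BM", "OU", "EB")]
        assert aicc_select(fits)["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_aicc_formula(self, tree50, traits50):
        f = fit_trait_model(tree50, traits50, "OU")
        n, k = f.n, f.k
        assert f.aicc == pytest.approx(-2 * f.lnl + 2 * k + 2 * k * (k + 1) / (n - k - 1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aicc_select([])


class TestTwoRateSearch:
    def test_scalar_one_reproduces_single_rate(self, tree50, traits50):
        C = tree50.mrca_depths()
        x = traits50[tree50.tip_labels].to_numpy()
        base_lnl, _, _ = _gls_profile(C, x)
        node = next(
            i for i in range(1, tree50.n_nodes)
            if not tree50.is_tip[i] and len(tree50.clade_tips(i)) >= 5
        )
        clade = tree50.clade_tips(node)
        Cin = np.zeros_like(C)
        Cin[np.ix_(clade, clade)] = C[np.ix_(clade, clade)] - tree50.depth[tree50.parent[node]]
        lnl_s1, _, _ = _gls_profile(C + 0.0 * Cin, x)
        assert lnl_s1 == pytest.approx(base_lnl, abs=1e-12)

    def test_six_tip_grid_oracle(self):
        """ML scalar on a small tree matches a dense grid search."""
        t = read_trees("(((A:1,B:1):1,(C:1,D:1):1):1,(E:2,F:2):1);")[0]
        tr = pd.Series({"A": 1.2, "B": -0.8, "C": 0.9, "D": -0.6, "E": 0.25, "F": 0.1})
        res = two_rate_search(t, tr, min_clade=2, criterion="aic", min_improvement=0.0)
        assert res is not None
        C = t.mrca_depths()
        # oracle: dense grid over log-scalar at the reported node
        node = res.node
        clade = t.clade_tips(node)
        Cin = np.zeros_like(C)
        Cin[np.ix_(clade, clade)] = C[np.ix_(clade, clade)] - t.depth[t.parent[node]]
        grid = np.exp(np.linspace(np.log(1e-4), np.log(1e4), 20001))
        lnls = [
            _gls_profile(C + (s - 1) * Cin, tr[t.tip_labels].to_numpy())[0] for s in grid
        ]
        s_star = grid[int(np.argmax(lnls))]
        assert res.scalar == pytest.approx(s_star, rel=2e-3)

    def test_simulated_shift_recovered(self):
        tree = pure_birth_tree(150, 250.0, seed=5)
        sizes = [
            (i, len(tree.clade_tips(i)))
            for i in range(1, tree.n_nodes) if not tree.is_tip[i]
        ]
        node = min(sizes, key=lambda z: abs(z[1] - 40))[0]
        hits = 0
        for s in range(10):
            tr = simulate_traits(
                tree, "two_rate",
                {"sigma2": 1.0, "z0": 0.0, "scalar": 16.0, "shift_node": node}, seed=s,
            )
            res = two_rate_search(tree, tr)
            if res is not None and 8.0 <= res.scalar <= 32.0:
                true_set = tree.clade_tipset(node)
                if res.tipset == true_set or len(res.tipset ^ true_set) <= 2:
                    hits += 1
        assert hits >= 8

    def test_homogeneous_data_mostly_clean(self, tree50):
        found = sum(
            two_rate_search(
                tree50, simulate_traits(tree50, "bm", {"sigma2": 1.0}, seed=s)
            ) is not None
            for s in range(10)
        )
        assert found <= 3


class TestSummarizeShifts:
    def test_single_result(self, tree50, traits50):
        node = next(i for i in range(1, tree50.n_nodes)
                    if not tree50.is_tip[i]
                    and 10 <= len(tree50.clade_tips(i)) <= 20)
        tr = simulate_traits(tree50, "two_rate",
                             {"sigma2": 1.0, "scalar": 30.0, "shift_node": node},
                             seed=0)
        res = two_rate_search(tree50, tr)
        assert res is not None
        table = summarize_shifts([res], reference=tree50)
        assert table["pct_increase"].iloc[0] == 100.0
        assert table["node"].iloc[0] != -1

    def test_unmapped_tipset_reported(self, tree50, traits50):
        other = pure_birth_tree(20, 50.0, seed=99, prefix="x")
        tr = simulate_traits(other, "two_rate",
                             {"sigma2": 1.0, "scalar": 50.0, "shift_node": 1}, seed=1)
        res = two_rate_search(other, tr, min_clade=3)
        assert res is not None
        table = summarize_shifts([res], reference=tree50)
        assert (table["node"] == -1).all()

    def test_percentages_bounded(self, tree50):
        results = []
        for s in range(5):
            tr = simulate_traits(tree50, "bm", {"sigma2": 1.0}, seed=100 + s)
            results.append(two_rate_search(tree50, tr))
        table = summarize_shifts(results, reference=tree50)
        if len(table):
            assert table["pct_increase"].sum() <= 100.0
            assert table["pct_decrease"].sum() <= 100.0


class TestMultivariateRates:
    @pytest.fixture(scope="class")
    def setup(self):
        tree = two_clade_tree(25, 25, 200.0, seed=13)
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(
            np.column_stack([
                simulate_traits(tree, "bm", {"sigma2": 1.0}, seed=int(rng.integers(2**31)))
                for _ in range(4)
            ]),
            index=tree.tip_labels,
        )
        groups = pd.Series({t: t[0] for t in tree.tip_labels})
        return tree, scores, groups

    def test_seed_reproducible(self, setup):
        tree, scores, groups = setup
        a = multivariate_rate_test(tree, scores, groups, n_perm=99, seed=5)
        b = multivariate_rate_test(tree, scores, groups, n_perm=99, seed=5)
        assert a == b

    def test_equal_rates_ratio_near_one(self, setup):
        tree, scores, groups = setup
        res = multivariate_rate_test(tree, scores, groups, n_perm=199, seed=1)
        assert res["ratio"] < 2.5
        assert res["p"] > 0.01

    def test_elevated_rate_detected(self):
        tree = two_clade_tree(30, 30, 200.0, seed=17)
        cols = []
        for d in range(4):
            tr = simulate_traits(tree, "bm", {"sigma2": 1.0}, seed=40 + d)
            scale = pd.Series(
                np.where([t.startswith("A") for t in tr.index], 1.0, 1.0), index=tr.index
            )
            cols.append(tr)
        # regenerate clade-B columns at 4x rate via a two-rate simulation
        b_node = next(
            i for i in range(1, tree.n_nodes)
            if not tree.is_tip[i] and tree.clade_tipset(i) == frozenset(
                t for t in tree.tip_labels if t.startswith("B"))
        )
        cols = [
            simulate_traits(
                tree, "two_rate",
                {"sigma2": 1.0, "scalar": 4.0, "shift_node": b_node}, seed=60 + d,
            )
            for d in range(4)
        ]
        scores = pd.DataFrame(np.column_stack(cols), index=tree.tip_labels)
        groups = pd.Series({t: t[0] for t in tree.tip_labels})
        res = multivariate_rate_test(tree, scores, groups, n_perm=499, seed=3)
        assert res["ratio"] > 2.0
        assert res["p"] <= 0.05


class TestAncestralStates:
    def test_two_tip_root_is_mean(self):
        t = read_trees("(A:1,B:1);")[0]
        anc = ancestral_states_bm(t, pd.Series({"A": 2.0, "B": 6.0}))
        assert anc[0] == pytest.approx(4.0)

    def test_constant_trait(self, tree50):
        anc = ancestral_states_bm(
            tree50, pd.Series(3.3, index=tree50.tip_labels)
        )
        np.testing.assert_allclose(anc.to_numpy(), 3.3, atol=1e-8)

    def test_matches_direct_gls_oracle(self):
        """Independent oracle: conditional mean of the joint (tips, node)
        Gaussian, with node-tip covariances from explicit ancestor paths."""
        tree = pure_birth_tree(12, 50.0, seed=31)
        x = simulate_traits(tree, "bm", {"sigma2": 1.0, "z0": 1.0}, seed=1)
        anc = ancestral_states_bm(tree, x)
        C = tree.mrca_depths()
        cho = linalg.cho_factor(C)
        ones = np.ones(tree.n_tips)
        Vi1 = linalg.cho_solve(cho, ones)
        z0 = x[tree.tip_labels].to_numpy() @ Vi1 / (ones @ Vi1)

        # ancestor sets by brute-force path walking
        def ancestors(i):
            out = set()
            while i != 0:
                out.add(i)
                i = tree.parent[i]
            out.add(0)
            return out

        anc_sets = {i: ancestors(i) for i in range(tree.n_nodes)}
        for node in range(tree.n_nodes):
            if tree.is_tip[node]:
                continue
            v = np.array([
                sum(tree.blen[a] for a in (anc_sets[node] & anc_sets[int(t)]) if a != 0)
                for t in tree.tip_nodes
            ])
            expect = z0 + v @ linalg.cho_solve(cho, x[tree.tip_labels].to_numpy() - z0)
            assert anc[node] == pytest.approx(expect, abs=1e-8)
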