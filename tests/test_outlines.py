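"""Outline geometry, Procrustes alignment, EFA and morphospace tests."""

import numpy as np
import pytest

from mandiblescape.outlines import (
    Outline,
    build_morphospace,
    canonicalize,
    efa,
    inverse_efa,
    procrustes_align,
    reconstruct_at,
    resample_outline,
    self_intersects,
    warp_grid,
)
from mandiblescape.outlines import _efa_full


def circle(n=200, r=1.0, phase=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


# ---------------------------------------------------------------------------
# brute-force O(n^2) segment-intersection oracle (touching counts)
# ---------------------------------------------------------------------------


def _orient(p, q, r):
    return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])


def _on_segment(p, q, r):
    return (
        min(p[0], q[0]) - 1e-12 <= r[0] <= max(p[0], q[0]) + 1e-12
        and min(p[1], q[1]) - 1e-12 <= r[1] <= max(p[1], q[1]) + 1e-12
    )


def _segments_touch(a, b, c, d):
    o1, o2 = _orient(a, b, c), _orient(a, b, d)
    o3, o4 = _orient(c, d, a), _orient(c, d, b)
    if (o1 > 0) != (o2 > 0) and (o3 > 0) != (o4 > 0) and 0 not in (o1, o2, o3, o4):
        return True
    for (p, q, r) in ((a, b, c), (a, b, d), (c, d, a), (c, d, b)):
        if _orient(p, q, r) == 0 and _on_segment(p, q, r):
            return True
    return False


def brute_force_self_intersects(pts):
    n = len(pts)
    edges = [(pts[i], pts[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent edges share a vertex
            if _segments_touch(*edges[i], *edges[j]):
                return True
    return False


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


class TestResample:
    def test_unit_square_corners(self):
        sq = Outline(np.array([[0.0, 0.0], [1, 0], [1, 1], [0, 1]]), canonical=True)
        out = resample_outline(sq, 4)
        assert out.k == 4
        # starts at the anterior-most (min-x, ventral-most) corner
        np.testing.assert_allclose(out.points[0], [0, 0], atol=1e-12)
        got = {tuple(np.round(p, 9)) for p in out.points}
        assert got == {(0, 0), (1, 0), (1, 1), (0, 1)}

    def test_circle_perimeter_preserved(self):
        out = resample_outline(Outline(circle(500)), 200)
        assert out.perimeter() == pytest.approx(2 * np.pi, rel=0.01)

    def test_identity_on_equally_spaced(self):
        pts = circle(64)
        out = resample_outline(Outline(pts, canonical=True), 64)
        # same point set, rolled to start at the anterior-most point
        start = np.argmin(pts[:, 0] + 1e-9 * pts[:, 1])
        np.testing.assert_allclose(out.points, np.roll(pts, -start, axis=0), atol=1e-9)

    def test_degenerate_outline_rejected(self):
        with pytest.raises(ValueError):
            Outline(np.array([[0.0, 0.0], [0, 0], [0, 0]]))

    @pytest.mark.parametrize("k", [100, 300])
    def test_perimeter_within_one_percent(self, default_jaw, k):
        out = resample_outline(default_jaw, k)
        assert out.perimeter() == pytest.approx(default_jaw.perimeter(), rel=0.01)


# ---------------------------------------------------------------------------
# Procrustes
# ---------------------------------------------------------------------------


class TestProcrustes:
    def test_similarity_invariance(self):
        rng = np.random.default_rng(0)
        base = resample_outline(Outline(circle(100) * [1.0, 0.6]), 100).points
        outlines = []
        for i in range(8):
            th = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            pts = base @ R.T * rng.uniform(0.5, 3.0) + rng.uniform(-5, 5, 2)
            outlines.append(Outline(pts, id=f"s{i}"))
        al = procrustes_align(outlines)
        spread = np.abs(al.coords - al.coords.mean(axis=0)).max()
        assert spread < 1e-6

    def test_distance_symmetric(self):
        a = Outline(circle(80) * [1.0, 0.5], id="a")
        b = Outline(circle(80, phase=0.1) * [0.7, 1.0], id="b")
        d_ab = np.sqrt(((procrustes_align([a, b]).coords[0]
                         - procrustes_align([a, b]).coords[1]) ** 2).sum())
        d_ba = np.sqrt(((procrustes_align([b, a]).coords[0]
                         - procrustes_align([b, a]).coords[1]) ** 2).sum())
        assert d_ab == pytest.approx(d_ba, abs=1e-10)

    def test_consensus_near_base_ellipse(self):
        rng = np.random.default_rng(3)
        base = circle(120) * [1.0, 0.6]
        eps = 0.01
        outlines = [Outline(base + rng.normal(0, eps, base.shape)) for _ in range(20)]
        al = procrustes_align(outlines)
        base_al = procrustes_align([Outline(base), Outline(base)]).coords[0]
        # consensus of perturbed ellipses stays within the perturbation radius
        assert np.abs(al.consensus - base_al).max() < eps

    def test_mismatched_k_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            procrustes_align([Outline(circle(80)), Outline(circle(90))])

    def test_unit_centroid_size_and_origin(self, aligned):
        sizes = np.sqrt((aligned.coords**2).sum(axis=(1, 2)))
        np.testing.assert_allclose(sizes, 1.0, atol=1e-6)
        np.testing.assert_allclose(aligned.coords.mean(axis=1), 0.0, atol=1e-8)


# ---------------------------------------------------------------------------
# EFA
# ---------------------------------------------------------------------------


class TestEFA:
    def _aligned(self, pts_list):
        return procrustes_align([Outline(p, id=str(i)) for i, p in enumerate(pts_list)])

    def test_circle_single_harmonic(self):
        al = self._aligned([circle(128), circle(128)])
        coefs, h = efa(al, 0.99)
        assert h == 1
        assert coefs.cumulative_power()[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_square_needs_more_harmonics(self):
        sq = resample_outline(
            Outline(np.array([[0.0, 0.0], [1, 0], [1, 1], [0, 1]]), canonical=True), 128
        )
        al = self._aligned([sq.points, sq.points])
        _, h = efa(al, 0.99)
        assert h >= 2

    def test_reconstruction_error_monotone(self, aligned):
        full = _efa_full(aligned)
        errs = []
        for h in (1, 3, 8, full.H):
            rec = inverse_efa(full.coeffs[0, :h], aligned.k, full.locus[0])
            errs.append(np.sqrt(((rec - aligned.coords[0]) ** 2).mean()))
        assert all(a >= b for a, b in zip(errs, errs[1:]))

    def test_full_harmonics_reconstruction_exact(self, aligned):
        full = _efa_full(aligned)
        for s in (0, 5):
            rec = inverse_efa(full.coeffs[s], aligned.k, full.locus[s])
            rms = np.sqrt(((rec - aligned.coords[s]) ** 2).mean())
            assert rms < 1e-8

    def test_cumulative_power_nondecreasing(self, aligned):
        coefs = _efa_full(aligned)
        cum = coefs.cumulative_power()
        assert np.all(np.diff(cum, axis=1) >= -1e-15)

    def test_power_target_validated(self, aligned):
        with pytest.raises(ValueError):
            efa(aligned, 0.0)
        with pytest.raises(ValueError):
            efa(aligned, 1.5)


# ---------------------------------------------------------------------------
# morphospace and warps
# ---------------------------------------------------------------------------


class TestMorphospace:
    def test_variance_conservation(self, morphospace, aligned):
        coefs, _ = efa(aligned, 0.99)
        total = coefs.matrix().var(axis=0, ddof=1).sum()
        assert morphospace.eigenvalues.sum() == pytest.approx(total, rel=1e-10)
        assert morphospace.variance_fractions.sum() == pytest.approx(1.0, rel=1e-10)

    def test_scores_zero_mean(self, morphospace):
        np.testing.assert_allclose(morphospace.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_duplicated_dataset_same_axes(self, aligned):
        coefs, _ = efa(aligned, 0.99)
        space1 = build_morphospace(coefs)
        from mandiblescape.outlines import EFACoefficients

        doubled = EFACoefficients(
            np.concatenate([coefs.coeffs, coefs.coeffs]),
            np.concatenate([coefs.locus, coefs.locus]),
            coefs.k,
        )
        space2 = build_morphospace(doubled)
        n = space1.n_pc
        np.testing.assert_allclose(
            space1.variance_fractions[: n - 1],
            space2.variance_fractions[: n - 1],
            atol=1e-8,
        )
        for a in range(min(3, n)):
            dot = abs(space1.eigenvectors[a] @ space2.eigenvectors[a])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_scores_preserve_distances(self, aligned):
        coefs, _ = efa(aligned, 0.99)
        space = build_morphospace(coefs)
        mat = coefs.matrix()
        d_coef = np.linalg.norm(mat[:, None] - mat[None, :], axis=2)
        d_pc = np.linalg.norm(
            space.scores[:, None] - space.scores[None, :], axis=2
        )
        np.testing.assert_allclose(d_pc, d_coef, atol=1e-8)

    def test_too_few_shapes_rejected(self, aligned):
        coefs, _ = efa(aligned, 0.99)
        from mandiblescape.outlines import EFACoefficients

        small = EFACoefficients(coefs.coeffs[:2], coefs.locus[:2], coefs.k)
        with pytest.raises(ValueError):
            build_morphospace(small)

    def test_pipeline_similarity_invariance(self, dataset):
        """A random similarity transform of every input outline leaves PC
        variance fractions unchanged (scale/rotation/translation free)."""
        rng = np.random.default_rng(9)
        outlines = dataset.outlines[:12]

        def space_of(objs):
            al = procrustes_align([resample_outline(o, 200) for o in objs])
            coefs, _ = efa(al, 0.99)
            return build_morphospace(coefs)

        th = rng.uniform(0, 0.4)  # modest rotation keeps start-point matching
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = [
            Outline(o.points @ R.T * 2.5 + [7.0, -3.0], id=o.id) for o in outlines
        ]
        vf1 = space_of(outlines).variance_fractions
        vf2 = space_of(moved).variance_fractions
        np.testing.assert_allclose(vf1, vf2, atol=1e-6)


class TestWarpGrid:
    def test_grid_size(self, warps):
        assert len(warps) == 100

    def test_lattice_spans_scores(self, morphospace, warps):
        xs = sorted({w.pc1 for w in warps})
        ys = sorted({w.pc2 for w in warps})
        s = morphospace.scores
        assert xs[0] <= s[:, 0].min() and xs[-1] >= s[:, 0].max()
        assert ys[0] <= s[:, 1].min() and ys[-1] >= s[:, 1].max()

    def test_warp_at_origin_is_consensus(self, aligned):
        # with every harmonic retained the (0,0) warp is exactly the mean shape
        coefs, _ = efa(aligned, 1.0)
        space = build_morphospace(coefs)
        w0 = reconstruct_at(space, 0.0, 0.0)
        assert np.abs(w0.points - aligned.consensus).max() < 1e-6

    def test_validity_agrees_with_oracle(self, warps):
        for w in warps[::7]:  # subsample: oracle is O(n^2) per outline
            assert w.valid == (not brute_force_self_intersects(w.outline.points))

    def test_small_grid_rejected(self, morphospace):
        with pytest.raises(ValueError):
            warp_grid(morphospace, 1, 10)


class TestSelfIntersects:
    def test_convex(self):
        assert not self_intersects(circle(50))

    def test_bowtie(self):
        bow = np.array([[0.0, 0.0], [1, 1], [1, 0], [0, 1]])
        assert self_intersects(bow)

    def test_agreement_with_brute_force(self):
        rng = np.random.default_rng(1)
        n_agree = 0
        trials = 0
        for _ in range(300):
            n = rng.integers(4, 9)
            pts = rng.uniform(0, 1, (n, 2))
            if rng.uniform() < 0.5:  # star-shaped: usually simple
                ang = np.arctan2(*(pts - pts.mean(0)).T[::-1])
                pts = pts[np.argsort(ang)]
            trials += 1
            if self_intersects(pts) == brute_force_self_intersects(pts):
                n_agree += 1
        assert n_agree == trials


class TestCanonicalize:
    def test_ccw_and_start(self):
        sq = np.array([[1.0, 1.0], [0, 1], [0, 0], [1, 0]])  # clockwise
        out = canonicalize(sq)
        x, y = out[:, 0], out[:, 1]
        area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert area > 0
        np.testing.assert_allclose(out[0], [0, 0])
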