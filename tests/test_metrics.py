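"""Segmentation metrics against brute-force oracles and hand arithmetic."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import wilcoxon as scipy_wilcoxon

from profcorrect.grids import BinaryMask
from profcorrect.metrics import (DegenerateTestError, UndefinedMetricError, dsc,
                                 evaluate_cohort, extract_surface, hd95, msd,
                                 sensitivity_specificity, surface_distances,
                                 wilcoxon_signed_rank)
from tests.conftest import ball_mask, random_mask_pair

# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation path)


def brute_surface(mask):
    """Surface voxels by explicit 6-neighbour scanning."""
    m = mask.data.astype(bool)
    out = []
    for idx in np.argwhere(m):
        z, y, x = idx
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            nz, ny, nx = z + dz, y + dy, x + dx
            if not (0 <= nz < m.shape[0] and 0 <= ny < m.shape[1]
                    and 0 <= nx < m.shape[2]) or not m[nz, ny, nx]:
                out.append((z, y, x))
                break
    return np.asarray(out)


def brute_surface_metrics(a, b):
    """O(n²) pairwise-distance HD95/MSD on pooled bidirectional distances."""
    spacing = np.asarray(a.spacing)
    sa = brute_surface(a) * spacing
    sb = brute_surface(b) * spacing
    d = cdist(sa, sb)
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return np.percentile(pooled, 95), pooled.mean(), pooled


def brute_dsc(a, b):
    inter = np.logical_and(a.data, b.data).sum()
    return 2.0 * inter / (a.data.sum() + b.data.sum())


def brute_wilcoxon(diffs):
    """Exact two-sided p by full 2^n sign enumeration on the observed |d| ranks."""
    import itertools
    d = np.asarray(diffs, float)
    d = d[d != 0]
    absd = np.abs(d)
    order = absd.argsort(kind="stable")
    ranks = np.empty(len(d))
    sorted_abs = absd[order]
    raw = np.arange(1, len(d) + 1, dtype=float)
    i = 0
    while i < len(d):
        j = i
        while j + 1 < len(d) and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        raw[i:j + 1] = raw[i:j + 1].mean()
        i = j + 1
    ranks[order] = raw
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    stat = min(w_plus, w_minus)
    wmax = ranks.sum()
    count = 0
    for signs in itertools.product((0, 1), repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= stat + 1e-12 or w >= wmax - stat - 1e-12:
            count += 1
    return stat, count / 2 ** len(d)


# ---------------------------------------------------------------------------


class TestDsc:
    def test_identical(self):
        m = ball_mask(radius_mm=4)
        assert dsc(m, m) == 1.0

    def test_disjoint(self):
        a = BinaryMask(np.eye(4, dtype=np.uint8)[None].repeat(4, 0) * 0)
        a.data[0, 0, 0] = 1
        b = BinaryMask(np.zeros((4, 4, 4), np.uint8))
        b.data[3, 3, 3] = 1
        assert dsc(a, b) == 0.0

    def test_formula(self):
        a = BinaryMask(np.zeros((1, 1, 4), np.uint8))
        a.data[0, 0, :2] = 1
        b = BinaryMask(np.zeros((1, 1, 4), np.uint8))
        b.data[0, 0, 0] = 1
        assert dsc(a, b) == pytest.approx(2 / 3)

    def test_both_empty_is_one_single_empty_is_zero(self):
        e = BinaryMask(np.zeros((3, 3, 3), np.uint8))
        f = BinaryMask(np.ones((3, 3, 3), np.uint8))
        assert dsc(e, e) == 1.0
        assert dsc(e, f) == 0.0

    def test_erosion_monotonicity(self):
        gt = ball_mask((20, 20, 20), radius_mm=7)
        from scipy import ndimage
        b = BinaryMask(ndimage.binary_erosion(gt.data).astype(np.uint8))
        a = BinaryMask(ndimage.binary_erosion(b.data).astype(np.uint8))
        assert dsc(a, gt) <= dsc(b, gt) <= 1.0


class TestSurface:
    def test_single_voxel(self):
        m = BinaryMask(np.zeros((5, 5, 5), np.uint8))
        m.data[2, 3, 1] = 1
        assert extract_surface(m).tolist() == [[2, 3, 1]]

    def test_solid_cube_surface_count(self):
        m = BinaryMask(np.zeros((5, 5, 5), np.uint8))
        m.data[1:4, 1:4, 1:4] = 1
        assert len(extract_surface(m)) == 26  # all but the centre

    def test_full_grid_border_shell(self):
        m = BinaryMask(np.ones((4, 4, 4), np.uint8))
        surf = extract_surface(m)
        assert len(surf) == 4 ** 3 - 2 ** 3  # interior 2³ removed

    def test_empty_mask_rejected(self):
        with pytest.raises(UndefinedMetricError):
            extract_surface(BinaryMask(np.zeros((3, 3, 3), np.uint8)))


class TestSurfaceDistances:
    def test_identical_all_zero(self):
        m = ball_mask(radius_mm=4)
        sd = surface_distances(m, m)
        assert (sd.pooled == 0).all()

    def test_two_voxels_isotropic(self):
        a = BinaryMask(np.zeros((8, 8, 8), np.uint8)); a.data[1, 4, 4] = 1
        b = BinaryMask(np.zeros((8, 8, 8), np.uint8)); b.data[4, 4, 4] = 1
        sd = surface_distances(a, b)
        assert sd.a_to_b.tolist() == [3.0] and sd.b_to_a.tolist() == [3.0]

    def test_spacing_scales_distance(self):
        a = BinaryMask(np.zeros((8, 8, 8), np.uint8), spacing=(2, 1, 1)); a.data[1, 4, 4] = 1
        b = BinaryMask(np.zeros((8, 8, 8), np.uint8), spacing=(2, 1, 1)); b.data[4, 4, 4] = 1
        assert surface_distances(a, b).a_to_b.tolist() == [6.0]

    def test_hd95_and_msd_hand_values(self):
        from profcorrect.metrics import SurfaceDistanceSet
        sd = SurfaceDistanceSet(np.zeros(19), np.asarray([10.0]))
        # pooled sorted: 19 zeros + one 10; linear-interp 95th percentile
        assert hd95(sd) == pytest.approx(np.percentile(np.r_[np.zeros(19), 10.0], 95))
        assert msd(sd) == pytest.approx(0.5)
        sd2 = SurfaceDistanceSet(np.asarray([2.0]), np.asarray([4.0]))
        assert msd(sd2) == pytest.approx(3.0)

    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = random_mask_pair(rng, (7, 7, 7), spacing=(1.7, 0.9, 1.1), p=0.4)
            if not (a.data.any() and b.data.any()):
                continue
            ab, ba = surface_distances(a, b), surface_distances(b, a)
            assert hd95(ab) == pytest.approx(hd95(ba))
            assert msd(ab) == pytest.approx(msd(ba))

    def test_agrees_with_brute_force(self, rng):
        checked = 0
        while checked < 30:
            shape = tuple(rng.integers(4, 12, 3))
            spacing = tuple(rng.uniform(0.5, 3.0, 3))
            a, b = random_mask_pair(rng, shape, spacing, p=0.3)
            if not (a.data.any() and b.data.any()):
                continue
            sd = surface_distances(a, b)
            bh, bm, _ = brute_surface_metrics(a, b)
            assert hd95(sd) == pytest.approx(bh, rel=1e-9)
            assert msd(sd) == pytest.approx(bm, rel=1e-9)
            assert dsc(a, b) == pytest.approx(brute_dsc(a, b), rel=1e-12)
            checked += 1


class TestSensitivitySpecificity:
    def test_perfect(self):
        g = ball_mask(radius_mm=4)
        assert sensitivity_specificity(g, g) == (1.0, 1.0)

    def test_complement(self):
        g = ball_mask(radius_mm=4)
        inv = BinaryMask(1 - g.data)
        assert sensitivity_specificity(inv, g) == (0.0, 0.0)

    def test_hand_counts(self):
        g = BinaryMask(np.zeros((1, 10, 10), np.uint8))
        g.data[0, 0, :4] = 1
        p = BinaryMask(np.zeros((1, 10, 10), np.uint8))
        p.data[0, 0, :3] = 1   # 3 of 4 tumor voxels
        p.data[0, 5, 5] = 1    # one FP among 96 background voxels
        sens, spec = sensitivity_specificity(p, g)
        assert sens == pytest.approx(0.75)
        assert spec == pytest.approx(95 / 96)

    def test_degenerate_gt_rejected(self):
        g = BinaryMask(np.ones((3, 3, 3), np.uint8))
        with pytest.raises(UndefinedMetricError):
            sensitivity_specificity(g, g)


class TestWilcoxon:
    def test_exact_matches_sign_enumeration(self, rng):
        diffs = [1, 2, 3, -1, 4, 5]
        stat, p = wilcoxon_signed_rank([(d, 0) for d in diffs])
        bstat, bp = brute_wilcoxon(diffs)
        assert stat == pytest.approx(bstat)
        assert p == pytest.approx(bp)

    def test_random_small_samples_exact(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 11))
            diffs = rng.integers(-6, 7, n)
            if not np.any(diffs):
                continue
            stat, p = wilcoxon_signed_rank([(d, 0) for d in diffs])
            bstat, bp = brute_wilcoxon(diffs)
            assert stat == pytest.approx(bstat)
            assert p == pytest.approx(bp), diffs

    def test_symmetric_pair_no_evidence(self):
        _, p = wilcoxon_signed_rank([(0, 1), (2, 1)])  # diffs -1, +1
        assert p == pytest.approx(1.0)

    def test_matches_scipy_without_ties(self, rng):
        x = rng.normal(size=15)
        y = x + rng.normal(0.4, 1.0, size=15)
        stat, p = wilcoxon_signed_rank(list(zip(x, y)))
        ref = scipy_wilcoxon(x, y, zero_method="wilcox", alternative="two-sided",
                             method="exact")
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_normal_approximation_near_exact_at_n12(self, rng):
        for _ in range(10):
            d = rng.normal(0.3, 1.0, 12)
            d = d[d != 0]
            pairs = [(v, 0) for v in d]
            _, p_exact = wilcoxon_signed_rank(pairs)
            # force the large-n path by padding with strictly cancelling pairs? no:
            # evaluate the approximation directly on the same ranks
            from profcorrect.metrics import _signed_ranks
            import math
            ranks = _signed_ranks(d)
            n = d.size
            w_plus = float(ranks[d > 0].sum())
            stat = min(w_plus, ranks.sum() - w_plus)
            mean = n * (n + 1) / 4
            var = n * (n + 1) * (2 * n + 1) / 24
            z = (stat - mean + 0.5) / math.sqrt(var)
            p_approx = min(1.0, math.erfc(-z / math.sqrt(2)))
            assert abs(p_exact - p_approx) < 0.05

    def test_all_zero_differences_rejected(self):
        with pytest.raises(DegenerateTestError):
            wilcoxon_signed_rank([(1.0, 1.0), (2.0, 2.0)])


class TestEvaluateCohort:
    def test_single_perfect_case(self):
        g = ball_mask(radius_mm=4)
        rep = evaluate_cohort([("c0", g, g)])
        assert rep.summary.loc["dsc", "mean"] == 1.0
        assert rep.summary.loc["dsc", "sd"] == 0.0
        assert rep.summary.loc["hd95", "mean"] == 0.0

    def test_identical_prediction_sets_flag_degenerate_test(self):
        g = ball_mask(radius_mm=4)
        rep = evaluate_cohort([("c0", g, g), ("c1", g, g)], baseline=[g, g])
        assert rep.paired_test.p_value is None
        assert any("degenerate" in f for f in rep.flags)

    def test_summary_matches_hand_means(self, rng):
        cases = []
        vals = []
        for i in range(3):
            g = ball_mask((14, 14, 14), radius_mm=4)
            p = ball_mask((14, 14, 14), radius_mm=4 - i * 0.8)
            cases.append((f"c{i}", p, g))
            vals.append(dsc(p, g))
        rep = evaluate_cohort(cases)
        assert rep.summary.loc["dsc", "mean"] == pytest.approx(np.mean(vals))
        assert rep.summary.loc["dsc", "median"] == pytest.approx(np.median(vals))

    def test_empty_mask_case_flagged_not_fatal(self):
        g = ball_mask(radius_mm=4)
        empty = BinaryMask(np.zeros_like(g.data))
        rep = evaluate_cohort([("c0", empty, g), ("c1", g, g)])
        assert np.isnan(rep.per_case.loc[0, "hd95"])
        assert rep.flags
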