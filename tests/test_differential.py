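import math

import numpy as np
import pytest
from scipy import stats

from atackit import differential as dif
from atackit.peaks import Peak


def peaks_of(spans, contig="chr1"):
    return [Peak(contig=contig, start=s, end=e) for s, e in spans]


def cands(n):
    return [dif.CandidateRegion("chr1", i * 10, i * 10 + 5, (True, True))
            for i in range(n)]


class TestCandidateRegions:
    def test_sweep_example(self):
        regions = dif.candidate_regions([peaks_of([(0, 100)]), peaks_of([(50, 150)])])
        assert [(r.start, r.end, r.membership) for r in regions] == [
            (0, 50, (True, False)), (50, 100, (True, True)), (100, 150, (False, True))]

    def test_identical_sets(self):
        a = peaks_of([(0, 100), (200, 300)])
        regions = dif.candidate_regions([a, list(a)])
        assert [(r.start, r.end) for r in regions] == [(0, 100), (200, 300)]
        assert all(r.membership == (True, True) for r in regions)

    def test_disjoint_sets(self):
        regions = dif.candidate_regions([peaks_of([(0, 100)]), peaks_of([(200, 300)])])
        assert [(r.start, r.end, r.membership) for r in regions] == [
            (0, 100, (True, False)), (200, 300, (False, True))]

    def test_union_coverage_vs_mask_oracle(self):
        rng = np.random.default_rng(7)
        sets = []
        for _ in range(3):
            starts = rng.integers(0, 900, 12)
            sets.append(peaks_of([(int(s), int(s) + int(rng.integers(5, 80)))
                                  for s in starts]))
        regions = dif.candidate_regions(sets)
        mask = np.zeros(1000, bool)
        for ps in sets:
            for p in ps:
                mask[p.start:p.end] = True
        got = np.zeros(1000, bool)
        for r in regions:
            assert not got[r.start:r.end].any()  # partition: no double cover
            got[r.start:r.end] = True
        assert np.array_equal(got, mask)

    def test_adjacent_regions_differ(self):
        rng = np.random.default_rng(8)
        sets = [peaks_of([(int(s), int(s) + 50) for s in rng.integers(0, 900, 10)])
                for _ in range(2)]
        regions = dif.candidate_regions(sets)
        for a, b in zip(regions, regions[1:]):
            if a.contig == b.contig and a.end == b.start:
                assert a.membership != b.membership

    def test_needs_two_sets(self):
        with pytest.raises(ValueError):
            dif.candidate_regions([peaks_of([(0, 10)])])


class TestDifferentialPeaks:
    def test_example_call_with_welch_oracle(self):
        g1 = np.array([[10.0, 12.0, 11.0]])
        g2 = np.array([[40.0, 44.0, 38.0]])
        (call,) = dif.differential_peaks(cands(1), g1, g2)
        assert call.significant and call.direction == "up_in_g2"
        assert call.fold_change == pytest.approx((g2.mean() + 1) / (g1.mean() + 1))

        # independent Welch oracle on the log2(x+1) scale
        x, y = np.log2(g1[0] + 1), np.log2(g2[0] + 1)
        vx, vy = x.var(ddof=1) / 3, y.var(ddof=1) / 3
        t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx ** 2 / 2 + vy ** 2 / 2)
        p_expected = 2 * stats.t.sf(abs(t), df)
        assert call.p_value == pytest.approx(p_expected, abs=1e-9)

    def test_identical_groups_not_significant(self):
        g = np.array([[10.0, 12.0, 11.0]])
        (call,) = dif.differential_peaks(cands(1), g, g.copy())
        assert call.fold_change == pytest.approx(1.0)
        assert not call.significant

    def test_fold_gate(self):
        g1 = np.array([[10.0, 11.0]])
        g2 = np.array([[16.0, 17.0]])
        (call,) = dif.differential_peaks(cands(1), g1, g2)
        assert call.fold_change < 2
        assert not call.significant

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="specific_peaks_no_replicate"):
            dif.differential_peaks(cands(1), np.array([[1.0]]), np.array([[1.0, 2.0]]))

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            dif.differential_peaks(cands(1), np.array([[-1.0, 1.0]]),
                                   np.array([[1.0, 2.0]]))

    def test_null_calibration(self):
        fracs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = np.exp(rng.normal(3, 0.5, (1000, 3)))
            b = np.exp(rng.normal(3, 0.5, (1000, 3)))
            calls = dif.differential_peaks(cands(1000), a, b)
            fracs.append(np.mean([c.p_value < 0.05 for c in calls]))
            # the fold gate only removes calls
            assert sum(c.significant for c in calls) <= sum(
                c.p_value < 0.05 for c in calls)
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_power_four_fold(self):
        hit = n = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            a = rng.normal(20, 2.0, (1000, 3)).clip(0.01)
            b = rng.normal(80, 8.0, (1000, 3)).clip(0.01)
            calls = dif.differential_peaks(cands(1000), a, b)
            hit += sum(c.significant for c in calls)
            n += 1000
        assert hit / n >= 0.90

    def test_bh_option_is_stricter(self):
        rng = np.random.default_rng(1)
        a = np.exp(rng.normal(3, 0.5, (200, 3)))
        b = np.exp(rng.normal(3, 0.5, (200, 3)))
        raw = dif.differential_peaks(cands(200), a, b)
        adj = dif.bh_correct(raw)
        assert sum(c.significant for c in adj) <= sum(c.significant for c in raw)


class TestSpecificPeaks:
    def test_disjoint(self):
        a, b = peaks_of([(0, 100)]), peaks_of([(200, 300)])
        sa, sb = dif.specific_peaks_no_replicate(a, b)
        assert [(p.start, p.end) for p in sa] == [(0, 100)]
        assert [(p.start, p.end) for p in sb] == [(200, 300)]

    def test_one_bp_overlap_is_shared(self):
        sa, sb = dif.specific_peaks_no_replicate(peaks_of([(0, 100)]),
                                                 peaks_of([(50, 150)]))
        assert sa == [] and sb == []

    def test_identical_sets(self):
        a = peaks_of([(0, 100)])
        sa, sb = dif.specific_peaks_no_replicate(a, list(a))
        assert sa == [] and sb == []


class TestReproduciblePeaks:
    def test_identical_replicates_all_kept(self):
        a = peaks_of([(0, 100), (200, 300)])
        assert dif.reproducible_peaks([a, list(a)]) == a

    def test_reciprocal_overlap_retained(self):
        kept = dif.reproducible_peaks([peaks_of([(0, 100)]), peaks_of([(40, 140)])])
        assert len(kept) == 1  # overlap 60/100 = 0.6 >= 0.5

    def test_low_overlap_dropped(self):
        kept = dif.reproducible_peaks([peaks_of([(0, 100)]), peaks_of([(90, 190)])])
        assert kept == []  # overlap 10/100 = 0.1

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            dif.reproducible_peaks([peaks_of([(0, 10)])])


def planted_outlier_data(seed=13, n_inliers=500, n_outliers=10):
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, 0.8], [0.8, 1.0]])
    L = np.linalg.cholesky(cov)
    inliers = (rng.normal(size=(n_inliers, 2)) @ L.T) + 5
    ang = rng.uniform(0, 2 * np.pi, n_outliers)
    r = rng.uniform(6, 9, n_outliers)
    outliers = (np.column_stack([np.cos(ang), np.sin(ang)]) * r[:, None] @ L.T) + 5
    X = np.vstack([inliers, outliers])
    pairs = np.clip(2.0 ** X - 1, 0, None)  # so log2(x+1) recovers X
    return pairs, n_inliers


class TestPromoterGMM:
    def test_planted_outliers_flagged(self):
        pairs, n_in = planted_outlier_data()
        calls = dif.differential_promoters_gmm(pairs)
        flags = np.array([c.outlier for c in calls])
        assert flags[n_in:].sum() >= 9
        assert flags[:n_in].mean() <= 0.08

    def test_column_swap_symmetry(self):
        pairs, _ = planted_outlier_data()
        a = dif.differential_promoters_gmm(pairs)
        b = dif.differential_promoters_gmm(pairs[:, ::-1])
        assert [c.outlier for c in a] == [c.outlier for c in b]

    def test_seed_determinism(self):
        pairs, _ = planted_outlier_data()
        a = dif.differential_promoters_gmm(pairs, random_state=5)
        b = dif.differential_promoters_gmm(pairs, random_state=5)
        assert [c.gmm_p for c in a] == [c.gmm_p for c in b]

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            dif.differential_promoters_gmm(np.full((30, 2), 4.0))

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            dif.differential_promoters_gmm(np.random.default_rng(0).random((10, 2)))
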