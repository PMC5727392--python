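"""Statistical operations against hand arithmetic and enumeration oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from branchsense import group_stats as gs
from conftest import oracle_mw_exact_p


class TestMannWhitney:
    def test_extreme_separation_small_sample(self):
        # x entirely below y: U = 0, exact two-sided p = 2/C(6,3) = 0.1
        cmp = gs.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert cmp.u_statistic == 0.0
        assert cmp.p_value == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        cmp = gs.mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert cmp.p_value == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n1, n2 = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            pooled = rng.permutation(np.arange(1, n1 + n2 + 1)).astype(float)
            x, y = pooled[:n1], pooled[n1:]
            cmp = gs.mann_whitney_u(x, y)
            assert cmp.p_value == pytest.approx(oracle_mw_exact_p(list(x), list(y)))

    def test_approximation_close_to_exact_at_boundary(self, rng):
        # The asymptotic branch (continuity-corrected normal) should agree
        # with exact enumeration to within 0.01 at min(n) = 8, no ties.
        # Exact null distribution of the rank sum by subset-counting DP:
        n1, n2 = 8, 8
        N = n1 + n2
        max_sum = sum(range(N - n1 + 1, N + 1))
        f = np.zeros((n1 + 1, max_sum + 1))
        f[0, 0] = 1.0
        for r in range(1, N + 1):
            for k in range(min(r, n1), 0, -1):
                f[k, r:] += f[k - 1, :-r] if r else f[k - 1, :]
        total = f[n1].sum()
        mean_u = n1 * n2 / 2
        from scipy.stats import mannwhitneyu
        worst = 0.0
        for _ in range(200):
            pooled = rng.permutation(np.arange(1, N + 1)).astype(float)
            x, y = pooled[:n1], pooled[n1:]
            u_obs = sum(sorted(pooled).index(v) + 1 for v in x) - n1 * (n1 + 1) / 2
            dev = abs(u_obs - mean_u)
            exact = 0.0
            for s in range(max_sum + 1):
                u = s - n1 * (n1 + 1) / 2
                if abs(u - mean_u) >= dev - 1e-12:
                    exact += f[n1, s]
            exact /= total
            approx = mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic").pvalue
            worst = max(worst, abs(approx - exact))
        # complete enumeration over all attainable U at n1=n2=8 shows the
        # continuity-corrected normal deviates from exact by at most 0.0110
        # (without the correction it is ~0.046), so that is the bound frozen
        assert worst <= 0.0110

    def test_u_statistics_sum_to_n1_n2(self, rng):
        x, y = rng.normal(size=11), rng.normal(size=7)
        u_xy = gs.mann_whitney_u(x, y).u_statistic
        u_yx = gs.mann_whitney_u(y, x).u_statistic
        assert u_xy + u_yx == pytest.approx(len(x) * len(y))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gs.mann_whitney_u([], [1.0])


class TestChi2:
    def test_closed_form_value(self):
        # [[10,90],[30,70]]: 200*(10*70-90*30)^2/(100*100*40*160) = 12.5
        chi2, p = gs.chi2_2x2(10, 100, 30, 100)
        assert chi2 == pytest.approx(12.5)
        assert 0 < p < 1

    def test_equal_proportions_give_zero(self):
        chi2, _ = gs.chi2_2x2(20, 100, 40, 200)
        assert chi2 == pytest.approx(0.0)

    def test_doubling_cells_doubles_chi2(self):
        c1, _ = gs.chi2_2x2(10, 100, 30, 100)
        c2, _ = gs.chi2_2x2(20, 200, 60, 200)
        assert c2 == pytest.approx(2 * c1)

    def test_symmetric_under_group_swap(self):
        c1, p1 = gs.chi2_2x2(10, 100, 30, 100)
        c2, p2 = gs.chi2_2x2(30, 100, 10, 100)
        assert (c1, p1) == (pytest.approx(c2), pytest.approx(p2))

    def test_matches_scipy_contingency(self):
        from scipy.stats import chi2_contingency
        chi2, p = gs.chi2_2x2(17, 120, 55, 300)
        ref = chi2_contingency([[17, 103], [55, 245]], correction=False)
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            gs.chi2_2x2(0, 100, 0, 100)


class TestTTest:
    def test_identical_groups_p_one(self):
        t, p = gs.t_test_psi([10.0, 12.0], [10.0, 12.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_arithmetic_two_points(self):
        # a={10,12}, b={40,42}: means 11, 41; s^2 = 2 each;
        # t = (11-41)/sqrt(2/2 + 2/2) = -30/sqrt(2)
        t, p = gs.t_test_psi([10.0, 12.0], [40.0, 42.0])
        assert t == pytest.approx(-30.0 / math.sqrt(2.0))
        assert p < 0.01

    def test_swap_negates_t(self):
        t1, p1 = gs.t_test_psi([10.0, 12.0], [40.0, 42.0])
        t2, p2 = gs.t_test_psi([40.0, 42.0], [10.0, 12.0])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            gs.t_test_psi([10.0], [1.0, 2.0])


class TestExprSplicingCorrelation:
    def test_perfectly_linear_pair(self):
        fpkm = np.array([1.0, 10.0, 100.0])
        d = np.log10(fpkm + 1)  # linear in the transformed variable
        assert gs.expr_splicing_correlation(d, fpkm) == pytest.approx(1.0)

    def test_anti_linear(self):
        fpkm = np.array([1.0, 10.0, 100.0])
        d = -np.log10(fpkm + 1) + 5
        assert gs.expr_splicing_correlation(d, fpkm) == pytest.approx(-1.0)

    def test_independent_draws_near_zero(self):
        rng = np.random.default_rng(42)
        d = rng.uniform(0, 50, size=2000)
        fpkm = 10 ** rng.normal(1, 0.5, size=2000)
        assert abs(gs.expr_splicing_correlation(d, fpkm)) < 0.05

    def test_zero_variance_is_missing(self):
        assert math.isnan(gs.expr_splicing_correlation([1.0, 1.0, 1.0],
                                                       [1.0, 2.0, 3.0]))


class TestOverlapMatrix:
    def test_pairwise_percentage(self):
        ov = gs.overlap_matrix({"A": {1, 2}, "B": {2, 3}})
        assert ov.pct_shared.loc["A", "B"] == pytest.approx(50.0)
        assert ov.pct_shared.loc["A", "A"] == pytest.approx(100.0)

    def test_disjoint_sets(self):
        ov = gs.overlap_matrix({"A": {1}, "B": {2}})
        assert ov.pct_shared.loc["A", "B"] == 0.0
        assert ov.count("A") == 1 and ov.count("A", "B") == 0

    def test_three_set_regions_match_brute_force(self):
        sets = {"A": {1, 2, 3, 4}, "B": {3, 4, 5}, "C": {4, 5, 6, 7}}
        ov = gs.overlap_matrix(sets)
        regions = {}
        for e in set().union(*sets.values()):
            key = tuple(sorted(n for n, s in sets.items() if e in s))
            regions[key] = regions.get(key, 0) + 1
        for members, count in ov.region_counts.items():
            assert count == regions.get(members, 0)
        assert sum(ov.region_counts.values()) == 7


class TestRnaMap:
    def test_no_matches_gives_zero_profile(self):
        prof = gs.rna_map({"g": ["A" * 50]}, "YNYYRAY", width=40, smooth=1)
        assert np.allclose(prof.coverage["g"], 0.0)

    def test_single_match_covers_exact_positions(self):
        # one 50-nt sequence, TACTAAC planted so the match spans -10..-4
        seq = list("A" * 50)
        seq[-10:-3] = "TACTAAC"
        prof = gs.rna_map({"g": ["".join(seq)]}, "TACTAAC", width=50, smooth=1)
        covered = prof.raw["g"] > 0
        expected = np.zeros(50, dtype=bool)
        # positions -10..-4 -> indices 40..46
        expected[40:47] = True
        assert (covered == expected).all()

    def test_planted_enrichment_separates_groups(self, rng):
        def seqs(planted, n):
            out = []
            for _ in range(n):
                s = list("".join(rng.choice(list("AG"), size=80)))
                if planted:
                    pos = int(rng.integers(-40, -26))
                    s[pos : pos + 7] = "TACTAAC"
                out.append("".join(s))
            return out
        prof = gs.rna_map({"hot": seqs(True, 40), "cold": seqs(False, 40)},
                          "TACTAAC", width=60, smooth=5)
        window = (prof.positions >= -40) & (prof.positions <= -20)
        assert prof.coverage["hot"][window].mean() > prof.coverage["cold"][window].mean()

    def test_profiles_bounded_and_smoothing_preserves_mean(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=100)) for _ in range(30)]
        prof = gs.rna_map({"g": seqs}, "YNYYRAY", width=80, smooth=15)
        assert np.nanmin(prof.coverage["g"]) >= 0.0
        assert np.nanmax(prof.coverage["g"]) <= 1.0
        assert abs(np.nanmean(prof.coverage["g"]) - np.nanmean(prof.raw["g"])) \
            <= 15 / 80

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gs.rna_map({"g": []}, "YNYYRAY")


class TestHeatmapOrder:
    def test_identical_rows_cluster_first(self):
        mat = np.array([[0.0, 0.0], [5.0, 5.0], [0.0, 0.0]])
        order = gs.heatmap_order(mat)
        pos = {r: i for i, r in enumerate(order.row_order)}
        assert abs(pos[0] - pos[2]) == 1  # the identical rows are adjacent

    def test_three_row_merge_order_matches_hand_dendrogram(self):
        # rows r0=(0,0), r1=(0,1), r2=(10,10): r0-r1 merge first (d=1),
        # then {r0,r1} joins r2 at the farthest member: d(r0,r2)=sqrt(200)
        mat = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 10.0]])
        order = gs.heatmap_order(mat)
        link = order.row_linkage
        assert sorted(link[0, :2]) == [0, 1]
        assert link[0, 2] == pytest.approx(1.0)
        assert link[1, 2] == pytest.approx(np.linalg.norm([10.0, 10.0]))

    def test_permutation_invariant_topology(self, rng):
        mat = rng.normal(size=(8, 3))
        base = gs.heatmap_order(mat)
        perm = rng.permutation(8)
        permuted = gs.heatmap_order(mat[perm])
        # same leaf heights in the dendrogram regardless of input order
        assert np.allclose(np.sort(base.row_linkage[:, 2]),
                           np.sort(permuted.row_linkage[:, 2]))

    def test_rows_with_missing_values_dropped_and_reported(self):
        mat = np.array([[0.0, 1.0], [np.nan, 2.0], [3.0, 4.0], [5.0, 6.0]])
        order = gs.heatmap_order(mat)
        assert order.dropped_rows == [1]
        assert sorted(order.row_order) == [0, 2, 3]

    def test_single_row_identity(self):
        order = gs.heatmap_order(np.array([[1.0, 2.0]]))
        assert order.row_order == [0]


class TestBoxplotSummary:
    def test_constant_vector(self):
        s = gs.summarize_boxplot([5.0] * 10)
        assert s.q1 == s.median == s.q3 == s.whisker_lo == s.whisker_hi == 5.0
        assert s.outliers == ()

    def test_1_to_100_quartiles_linear_interpolation(self):
        s = gs.summarize_boxplot(np.arange(1.0, 101.0))
        assert s.q1 == pytest.approx(25.75)
        assert s.median == pytest.approx(50.5)
        assert s.q3 == pytest.approx(75.25)
        assert s.whisker_lo == 1.0 and s.whisker_hi == 100.0

    def test_single_point(self):
        s = gs.summarize_boxplot([3.0])
        assert s.median == 3.0 and s.outliers == ()

    def test_outliers_listed_not_discarded(self):
        vals = list(np.arange(1.0, 21.0)) + [1000.0]
        s = gs.summarize_boxplot(vals)
        assert s.outliers == (1000.0,)
        assert s.whisker_hi == 20.0


class TestCompareFeatures:
    def test_tidy_output_with_stars(self, rng):
        n = 60
        feats = pd.DataFrame({
            "len_intron": np.r_[rng.normal(1000, 50, n), rng.normal(4000, 50, n)],
            "gc": np.r_[rng.normal(0.5, 0.01, n), rng.normal(0.4, 0.01, n)],
        })
        labels = ["ret"] * n + ["ndiff"] * n
        out = gs.compare_features(feats, labels, "ret", "ndiff")
        out = out.set_index("feature")
        assert out.loc["len_intron", "direction"] == -1
        assert out.loc["gc", "direction"] == 1
        assert (out["p_value"] < 1e-4).all()
        assert (out["stars"] == "***").all()
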