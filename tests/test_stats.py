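import itertools
import math

import numpy as np
import pytest

from lumifrontal.stats import (
    chi_square,
    cohens_d,
    perm_anova,
    perm_ttest_ind,
    tmax_correct,
)


def _welch_oracle(a, b):
    """Independent Welch t for the exhaustive-enumeration oracle."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va = a.var(ddof=1) / len(a)
    vb = b.var(ddof=1) / len(b)
    return (a.mean() - b.mean()) / math.sqrt(va + vb)


class TestPermTtestInd:
    def test_identical_multisets_p_one(self):
        a = [1.0, 2.0, 3.0]
        assert perm_ttest_ind(a, list(reversed(a))).p == 1.0

    def test_exhaustive_matches_enumeration_oracle(self):
        """n = 4+4 with complete separation: p equals the fraction of the 70
        label splits with |t*| >= |t|, enumerated independently here."""
        a = np.array([10.0, 11.0, 12.0, 13.0])
        b = np.array([0.0, 1.0, 2.0, 3.0])
        res = perm_ttest_ind(a, b, n_perm=10_000)
        pooled = np.concatenate([a, b])
        t_obs = abs(_welch_oracle(a, b))
        hits = 0
        total = 0
        for idx in itertools.combinations(range(8), 4):
            ga = pooled[list(idx)]
            gb = np.delete(pooled, list(idx))
            if abs(_welch_oracle(ga, gb)) >= t_obs - 1e-12:
                hits += 1
            total += 1
        assert res.exhaustive and total == 70
        assert res.p == pytest.approx(hits / total)
        assert res.p == pytest.approx(2 / 70)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(4)
        rej = 0
        n_runs = 1000
        for i in range(n_runs):
            a = rng.standard_normal(8)
            b = rng.standard_normal(8)
            if perm_ttest_ind(a, b, n_perm=499, seed=i).p <= 0.05:
                rej += 1
        assert 0.03 <= rej / n_runs <= 0.07

    def test_one_sided_tail(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(15) + 2.0
        b = rng.standard_normal(15)
        assert perm_ttest_ind(a, b, sided="greater", seed=0).p < 0.05
        assert perm_ttest_ind(a, b, sided="less", seed=0).p > 0.5

    def test_minimum_attainable_p(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(50) + 100
        b = rng.standard_normal(50)
        res = perm_ttest_ind(a, b, n_perm=999, seed=0)
        assert res.p == pytest.approx(1 / 1000)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            perm_ttest_ind([], [1.0])


class TestPermAnova:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        res = perm_anova([g, g, g], n_perm=200, seed=0)
        assert res.p == 1.0 and res.effect_size == 0.0

    def test_huge_separation_minimum_p(self):
        # group sizes of 4 make label permutations that happen to reproduce
        # the group partition (F is relabelling-invariant) vanishingly rare
        groups = [
            [0.0, 0.1, 0.2, 0.3],
            [10.0, 10.1, 10.2, 10.3],
            [20.0, 20.1, 20.2, 20.3],
        ]
        res = perm_anova(groups, n_perm=499, seed=0)
        assert res.p == pytest.approx(1 / 500)

    def test_eta_squared_hand_computation(self):
        """Six-value toy: eta^2 = SS_between / SS_total computed by hand."""
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        res = perm_anova(groups, n_perm=99, seed=0)
        grand = 3.5
        ss_b = 2 * ((1.5 - grand) ** 2 + (3.5 - grand) ** 2 + (5.5 - grand) ** 2)  # 16
        ss_t = sum((x - grand) ** 2 for g in groups for x in g)  # 17.5
        assert res.effect_size == pytest.approx(ss_b / ss_t)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            perm_anova([[1.0, 2.0]])


class TestTmax:
    def test_single_comparison_close_to_unadjusted(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal(20) + 1.0
        b = rng.standard_normal(20)
        adj = tmax_correct([(a, b)], n_perm=4000, seed=1)[0]
        raw = perm_ttest_ind(a, b, n_perm=4000, seed=2)
        assert adj.p == pytest.approx(raw.p, abs=0.02)

    def test_adjusted_dominates_raw(self):
        rng = np.random.default_rng(7)
        pairs = [(rng.standard_normal(12) + d, rng.standard_normal(12)) for d in (0.0, 0.8, 2.0)]
        adj = tmax_correct(pairs, n_perm=2000, seed=3)
        for (a, b), r in zip(pairs, adj):
            raw = perm_ttest_ind(a, b, n_perm=2000, seed=4)
            assert r.p >= raw.p - 0.02

    def test_family_wise_error_controlled(self):
        """Three independent null comparisons: FWER stays near alpha."""
        rng = np.random.default_rng(8)
        fw = 0
        n_runs = 200
        for i in range(n_runs):
            pairs = [(rng.standard_normal(10), rng.standard_normal(10)) for _ in range(3)]
            adj = tmax_correct(pairs, n_perm=499, seed=i)
            if any(r.p <= 0.05 for r in adj):
                fw += 1
        rate = fw / n_runs
        se = math.sqrt(0.05 * 0.95 / n_runs)
        assert rate <= 0.05 + 4 * se


class TestChiSquare:
    def test_balanced_2x2_hand_pearson(self):
        """[[30,10],[10,30]]: all expected counts are 20, so chi^2 =
        4 * (10^2 / 20) = 20 and phi = sqrt(20/80) = 0.5."""
        res = chi_square([[30, 10], [10, 30]])
        assert res.statistic == pytest.approx(20.0)
        assert res.extra["dof"] == 1
        assert res.effect_size_name == "phi"
        assert res.effect_size == pytest.approx(0.5)

    def test_proportional_rows_zero(self):
        res = chi_square([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0)

    def test_phi_identity(self):
        res = chi_square([[25, 15], [12, 28]])
        assert res.effect_size == pytest.approx(math.sqrt(res.statistic / 80))

    def test_two_proportion_z_identity(self):
        """On a 2x2 table, chi^2 equals the squared two-proportion z."""
        n1, n2, x1, x2 = 40, 60, 12, 33
        res = chi_square([[x1, n1 - x1], [x2, n2 - x2]])
        p_pool = (x1 + x2) / (n1 + n2)
        z = (x1 / n1 - x2 / n2) / math.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
        assert res.statistic == pytest.approx(z**2)

    def test_cramers_v_for_larger_tables(self):
        res = chi_square([[10, 5, 5], [5, 10, 5]])
        assert res.effect_size_name == "cramers_v"

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [5, 5]])


class TestCohensD:
    def test_unit_difference_unit_sd(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(100_000) + 1.0
        b = rng.standard_normal(100_000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.02)

    def test_identical_zero(self):
        a = np.arange(10.0)
        assert cohens_d(a, a, paired=True) == 0.0
        assert cohens_d(a, a.copy()) == 0.0

    def test_paired_vs_unpaired_on_correlated_data(self):
        """Hand formulas: unpaired uses the pooled SD, paired the SD of the
        differences; correlation makes them differ."""
        a = np.array([3.0, 5.0, 7.0, 9.0])
        b = np.array([2.0, 4.0, 6.0, 8.0])
        d = a - b  # constant 1 -> sd 0 -> infinite paired d, flagged as inf
        assert math.isinf(cohens_d(a, b, paired=True))
        sp = math.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        assert cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / sp)
        b2 = np.array([2.0, 5.0, 5.0, 8.0])
        d2 = a - b2
        assert cohens_d(a, b2, paired=True) == pytest.approx(d2.mean() / d2.std(ddof=1))
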