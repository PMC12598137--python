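import math

import numpy as np
import pytest
from scipy import stats

from conftest import random_tied_samples
from npbf.effect import estimate_all
from npbf.hypotheses import (
    brunner_munzel_test,
    c2_degenerate_test,
    c2_test,
    permutation_test,
    satterthwaite_df,
)
from npbf.ranks import TwoSampleData


class TestSatterthwaiteDf:
    def test_symmetric_closed_form(self):
        # equal sizes and variances -> f = 2(n-1)
        assert satterthwaite_df(0.3, 0.3, 12, 12) == pytest.approx(22.0)

    def test_single_term_limit(self):
        assert satterthwaite_df(0.3, 0.0, 9, 5) == pytest.approx(8.0)

    def test_both_zero_raises(self):
        with pytest.raises(ValueError):
            satterthwaite_df(0.0, 0.0, 5, 5)


class TestBrunnerMunzel:
    def test_seventeen_values_pvalue(self, outcomes17):
        res = brunner_munzel_test(outcomes17)
        assert round(res.p_value, 4) == 0.0239
        assert res.reject

    def test_matches_scipy_on_random_data(self):
        """Independent oracle: scipy.stats.brunnermunzel (two-sided,
        t-approximation) on continuous and tied random datasets."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            x1 = rng.normal(size=rng.integers(5, 15))
            x2 = rng.normal(size=rng.integers(5, 15))
            res = brunner_munzel_test(TwoSampleData(x1, x2))
            ref = stats.brunnermunzel(x1, x2)
            assert abs(res.statistic) == pytest.approx(abs(ref.statistic), rel=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-8)

    def test_identical_samples(self):
        res = brunner_munzel_test(TwoSampleData([1, 2, 3], [1, 2, 3]))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_degenerate_branch(self):
        res = brunner_munzel_test(TwoSampleData([1, 2], [3, 4]))
        assert res.degenerate
        assert math.isinf(res.statistic) and res.statistic > 0
        assert res.p_value == 0.0
        tied = brunner_munzel_test(TwoSampleData([2, 2], [2, 2]))
        assert tied.degenerate and tied.p_value == 1.0

    def test_swap_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x1, x2 = random_tied_samples(rng)
            a = brunner_munzel_test(TwoSampleData(x1, x2))
            b = brunner_munzel_test(TwoSampleData(x2, x1))
            assert abs(a.statistic) == pytest.approx(abs(b.statistic), abs=1e-10)
            assert a.p_value == pytest.approx(b.p_value, abs=1e-10)


class TestC2:
    def test_seventeen_values_pvalue(self, outcomes17):
        res = c2_test(outcomes17)
        assert round(res.p_value, 4) == 0.0282
        assert res.reject

    def test_identical_samples(self):
        res = c2_test(TwoSampleData([1, 2, 3], [1, 2, 3]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == 1.0

    def test_complete_separation_statistic_is_m(self):
        res = c2_test(TwoSampleData([1, 2, 3, 4], [5, 6, 7, 8, 9]))
        assert res.degenerate
        assert res.method == "c2-sigma-max"
        assert res.statistic == pytest.approx(4.0)
        assert res.p_value == pytest.approx(stats.chi2.sf(4.0, 1))

    def test_degenerate_rejection_thresholds(self):
        """Smallest m rejecting a separated sample: 4 at alpha=0.05, 7 at 0.01."""
        for alpha, m_min in ((0.05, 4), (0.01, 7)):
            for m in range(2, m_min):
                data = TwoSampleData(np.arange(m), np.arange(m) + m)
                assert not c2_test(data, alpha=alpha).reject
            data = TwoSampleData(np.arange(m_min), np.arange(m_min) + m_min)
            assert c2_test(data, alpha=alpha).reject

    def test_degenerate_tied_constant(self):
        res = c2_degenerate_test(TwoSampleData([5, 5, 5], [5, 5, 5]))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_variance_inflation_formulation_equivalent(self):
        """C2 equals (theta-1/2)^2 / sigma_tilde^2 with sigma_tilde^2 =
        sigma_N^2 / [4 theta(1-theta)] — the two algebraic forms agree."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            x1, x2 = random_tied_samples(rng)
            data = TwoSampleData(x1, x2)
            res = c2_test(data)
            if res.degenerate:
                continue
            _, variances = estimate_all(data)
            theta = res.theta_hat
            sigma_tilde_sq = variances.sigma_n_sq / (4 * theta * (1 - theta))
            assert res.statistic == pytest.approx(
                (theta - 0.5) ** 2 / sigma_tilde_sq, rel=1e-10
            )

    def test_swap_invariance(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            x1, x2 = random_tied_samples(rng)
            a = c2_test(TwoSampleData(x1, x2))
            b = c2_test(TwoSampleData(x2, x1))
            assert a.statistic == pytest.approx(b.statistic, abs=1e-10)

    def test_theta0_generalization(self, pain):
        """C2 at theta0 rejects exactly when theta0 leaves the compatible
        interval, and the statistic vanishes at theta0 = theta_hat grid."""
        from npbf.intervals import c2_interval

        interval = c2_interval(pain, alpha=0.05)
        for theta0 in (0.55, 0.675, 0.838, 0.925, 0.99):
            res = c2_test(pain, alpha=0.05, theta0=theta0)
            assert res.reject == (theta0 not in interval)

    def test_theta0_validation(self, pain):
        with pytest.raises(ValueError):
            c2_test(pain, theta0=1.0)


class TestPermutation:
    def test_exhaustive_matches_bruteforce(self):
        """n1=n2=3: module enumeration over the 20 assignments equals an
        independent brute-force enumeration."""
        from itertools import combinations

        x1, x2 = [1.0, 3.0, 5.0], [2.0, 4.0, 4.5]
        data = TwoSampleData(x1, x2)
        res = permutation_test(data, exact=True)
        assert res.n_permutations == 20

        pooled = np.array(x1 + x2)
        stats_all = []
        for idx in combinations(range(6), 3):
            mask = np.zeros(6, bool)
            mask[list(idx)] = True
            a, b = pooled[mask], pooled[~mask]
            stats_all.append(stats.brunnermunzel(a, b).statistic)
        t_obs = stats.brunnermunzel(x1, x2).statistic
        lower = np.mean([t <= t_obs for t in stats_all])
        upper = np.mean([t >= t_obs for t in stats_all])
        assert res.p_value == pytest.approx(min(1.0, 2 * min(lower, upper)))

    def test_observed_statistic_zero_gives_p_one(self):
        res = permutation_test(TwoSampleData([1, 2, 3], [1, 2, 3]),
                               n_permutations=500, seed=1)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_add_one_minimal_pvalue(self, pain):
        """No permuted statistic reaches the observed one, so the add-one
        rule reports 1/(np+1)."""
        res = permutation_test(pain, n_permutations=10_000, seed=4, p_rule="add-one")
        assert res.p_value == pytest.approx(1 / 10_001)
        plain = permutation_test(pain, n_permutations=10_000, seed=4, p_rule="plain")
        assert plain.p_value == 0.0

    def test_seeded_determinism(self, outcomes17):
        a = permutation_test(outcomes17, n_permutations=2000, seed=123)
        b = permutation_test(outcomes17, n_permutations=2000, seed=123)
        assert a.p_value == b.p_value

    def test_degenerate_permuted_replicates_handled(self):
        # separated observed sample: observed statistic infinite, p small
        res = permutation_test(TwoSampleData([1, 2, 3, 4], [5, 6, 7, 8]),
                               n_permutations=400, seed=2)
        assert res.degenerate
        assert math.isinf(res.statistic)
        assert res.p_value <= 0.05
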