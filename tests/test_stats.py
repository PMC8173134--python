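"""Statistical battery: KS normality, ANOVA, Duncan, rank-sum."""

import numpy as np
import pytest
from scipy import stats as sps

from ukacontact.errors import DegenerateSampleError, InvalidInputError
from ukacontact.stats import (
    duncan_posthoc,
    ks_normality,
    one_way_anova,
    rank_sum_test,
)


class TestKSNormality:
    def test_plotting_positions_bound_with_known_params(self):
        """A sample placed at the N(0,1) plotting-position quantiles has
        D <= 1/(2n) against that same normal."""
        n = 10
        z = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        d, _ = ks_normality(z, mu=0.0, sigma=1.0)
        assert d <= 1.0 / (2 * n) + 1e-12

    def test_affine_invariance(self, rng):
        x = rng.normal(2.0, 3.0, 40)
        d1, p1 = ks_normality(x)
        d2, p2 = ks_normality(x * 5.0 - 7.0)
        assert np.isclose(d1, d2, atol=1e-12)
        assert np.isclose(p1, p2, atol=1e-12)

    def test_matches_brute_force_sup(self, rng):
        x = rng.uniform(0, 1, 100)
        d, _ = ks_normality(x)
        xs = np.sort(x)
        mu, sg = xs.mean(), xs.std(ddof=0)
        cdf = sps.norm.cdf((xs - mu) / sg)
        brute = max(
            max(abs((i + 1) / 100 - cdf[i]) for i in range(100)),
            max(abs(cdf[i] - i / 100) for i in range(100)),
        )
        assert np.isclose(d, brute, atol=1e-14)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            ks_normality([2.0, 2.0, 2.0, 2.0])
        with pytest.raises(InvalidInputError):
            ks_normality([1.0, 2.0, 3.0])


class TestAnova:
    def test_identical_groups_f_zero(self):
        r = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert r.F == 0.0
        assert r.p_value == 1.0

    def test_separation_limit(self):
        eps = 1e-6
        r = one_way_anova([[0.0, eps], [1.0, 1.0 + eps]])
        assert r.F > 1e9
        assert r.p_value < 1e-4

    def test_hand_computed_sums_of_squares(self):
        r = one_way_anova([[4.0, 5.0, 6.0], [6.0, 7.0, 8.0], [8.0, 9.0, 10.0]])
        assert np.isclose(r.F, 12.0)
        assert (r.df_between, r.df_within) == (2, 6)
        assert np.isclose(r.ms_error, 1.0)
        assert np.isclose(r.p_value, sps.f.sf(12.0, 2, 6))

    def test_group_order_invariance(self, rng):
        groups = [rng.normal(m, 1, 10) for m in (0.0, 1.0, 2.0)]
        a = one_way_anova(groups)
        b = one_way_anova(groups[::-1])
        assert np.isclose(a.F, b.F)

    def test_degenerate_within_variance(self):
        with pytest.raises(DegenerateSampleError):
            one_way_anova([[1.0, 1.0], [2.0, 2.0]])

    def test_matches_scipy_f_oneway(self):
        """F and p agree with an independent ANOVA implementation to
        floating-point precision on random unbalanced data."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            groups = [rng.normal(0.0, 1.0, rng.integers(5, 20)) for _ in range(3)]
            r = one_way_anova(groups)
            ref = sps.f_oneway(*groups)
            assert np.isclose(r.F, ref.statistic, atol=1e-10)
            assert np.isclose(r.p_value, ref.pvalue, atol=1e-12)


class TestDuncan:
    def test_identical_groups_single_subset(self):
        r = duncan_posthoc(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.01], [1.0, 2.0, 2.99]], labels=list("XYZ")
        )
        assert len(r.homogeneous_subsets) == 1
        assert not any(r.pairwise_significant.values())

    def test_two_group_decision_equals_pooled_t_test(self):
        """With two groups q(alpha, 2, df) = sqrt(2) t(alpha/2, df), so
        Duncan's decision coincides with the two-sided pooled t-test."""
        for seed in range(12):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.0, 1.0, 10)
            b = rng.normal(0.7, 1.0, 10)
            duncan = list(duncan_posthoc([a, b], labels=["a", "b"]).pairwise_significant.values())[0]
            ttest = sps.ttest_ind(a, b).pvalue < 0.05
            assert duncan == ttest

    def test_three_groups_close_pair_not_separated(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(m, 1.0, 14) for m in (0.0, 0.1, 10.0)]
        r = duncan_posthoc(groups, labels=["A", "B", "C"])
        subsets = [set(s) for s in r.homogeneous_subsets]
        assert {"C"} in subsets
        assert {"A", "B"} in subsets
        sig = {frozenset(k): v for k, v in r.pairwise_significant.items()}
        assert sig[frozenset(("A", "C"))] and sig[frozenset(("B", "C"))]
        assert not sig[frozenset(("A", "B"))]

    def test_studentized_range_quantiles_against_reference(self):
        """Frozen reference quantiles q(0.05; p, df) (classical tables)."""
        refs = {(2, 10): 3.151, (3, 10): 3.877, (2, 20): 2.950, (4, 20): 3.958}
        for (p, df), q_ref in refs.items():
            q = sps.studentized_range.ppf(0.95, p, df)
            assert abs(q - q_ref) < 0.01

    def test_familywise_error_exceeds_alpha(self):
        """Duncan's protection level makes the familywise error under the
        complete null exceed the per-comparison alpha (known liberal
        property, asserted directionally)."""
        rng = np.random.default_rng(77)
        n_sim = 400
        fw = 0
        for _ in range(n_sim):
            groups = rng.normal(0.0, 1.0, size=(3, 14))
            r = duncan_posthoc(list(groups))
            if any(r.pairwise_significant.values()):
                fw += 1
        assert fw / n_sim > 0.05

    def test_input_order_invariance(self, rng):
        groups = [rng.normal(m, 1.0, 12) for m in (0.0, 0.5, 3.0)]
        a = duncan_posthoc(groups, labels=["x", "y", "z"])
        b = duncan_posthoc(groups[::-1], labels=["z", "y", "x"])
        assert set(map(frozenset, a.homogeneous_subsets)) == set(
            map(frozenset, b.homogeneous_subsets)
        )


class TestRankSum:
    def test_exact_enumeration_small_example(self):
        w, p = rank_sum_test([1.0, 2.0], [3.0, 4.0], mode="exact")
        assert np.isclose(p, 1.0 / 3.0)

    def test_identical_samples_p_one(self):
        _, p = rank_sum_test([1.0, 2.0], [1.0, 2.0], mode="exact")
        assert p == 1.0

    def test_exact_probabilities_sum_to_one(self):
        """Across the partition of achievable statistics the exact null
        probabilities sum to 1."""
        from itertools import combinations

        x = [1.0, 2.0, 5.0]
        y = [3.0, 4.0, 6.0]
        pooled = np.array(x + y)
        ranks = sps.rankdata(pooled)
        ws = sorted({round(ranks[list(c)].sum(), 6) for c in combinations(range(6), 3)})
        total = 0.0
        seen = set()
        from math import comb

        for c in combinations(range(6), 3):
            w = round(ranks[list(c)].sum(), 6)
            if w not in seen:
                seen.add(w)
                count = sum(
                    1 for cc in combinations(range(6), 3) if round(ranks[list(cc)].sum(), 6) == w
                )
                total += count / comb(6, 3)
        assert np.isclose(total, 1.0)

    def test_approx_close_to_exact(self, rng):
        x = rng.normal(0.0, 1.0, 6)
        y = rng.normal(1.0, 1.0, 6)
        _, pe = rank_sum_test(x, y, mode="exact")
        _, pa = rank_sum_test(x, y, mode="approx")
        assert abs(pe - pa) < 0.05

    def test_matches_scipy_exact(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.normal(0, 1, 5)
            y = r.normal(0.8, 1, 6)
            _, p = rank_sum_test(x, y, mode="exact")
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert np.isclose(p, ref, atol=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            rank_sum_test([], [1.0])
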