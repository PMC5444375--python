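import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from _oracles import naive_binomial_twosided, naive_exact_pvalue
from varpath.errors import EnumerationCapError, ValidationError
from varpath.stat_tests import (
    ExactMultinomialNull,
    bh_adjust,
    binomial_level_test,
    chisq_test,
    enumerate_compositions,
    exact_multinomial_test,
    merge_zero_levels,
    monte_carlo_multinomial_test,
    n_compositions,
    two_group_test,
)


class TestExactMultinomial:
    def test_two_by_two_hand_enumeration(self):
        # outcomes (0,2),(1,1),(2,0) with probs .25,.5,.25; events no more
        # probable than (2,0) sum to 0.5
        assert exact_multinomial_test([2, 0], [0.5, 0.5]) == pytest.approx(0.5)

    def test_mode_gets_pvalue_one(self):
        assert exact_multinomial_test([5, 5], [0.5, 0.5]) == pytest.approx(1.0)

    def test_enumeration_is_visited_exhaustively(self):
        null = ExactMultinomialNull(30, [1 / 3, 1 / 3, 1 / 3])
        assert null.n_outcomes == n_compositions(30, 3) == 496
        comps = enumerate_compositions(30, 3)
        assert np.all(comps.sum(axis=1) == 30)
        assert len(np.unique(comps, axis=0)) == 496

    def test_pvalue_always_positive(self):
        # even the least likely outcome contributes itself
        p = exact_multinomial_test([50, 0], [0.01, 0.99])
        assert 0 < p < 1e-50

    @pytest.mark.parametrize(
        "counts, probs",
        [
            ((3, 7), (0.5, 0.5)),
            ((0, 12), (0.3, 0.7)),
            ((2, 3, 5), (0.2, 0.3, 0.5)),
            ((10, 0, 0), (1 / 3, 1 / 3, 1 / 3)),
            ((1, 4, 3), (0.1, 0.6, 0.3)),
        ],
    )
    def test_matches_naive_enumeration_oracle(self, counts, probs):
        expected = naive_exact_pvalue(counts, probs)
        got = exact_multinomial_test(counts, probs)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_m2_reduces_to_twosided_binomial_enumeration(self):
        for n in (5, 10, 15):
            for p in (0.5, 0.3, 0.8):
                for k in range(n + 1):
                    assert exact_multinomial_test(
                        [k, n - k], [p, 1 - p]
                    ) == pytest.approx(naive_binomial_twosided(k, n, p), rel=1e-12)

    def test_cap_raises_labeled_error(self):
        with pytest.raises(EnumerationCapError, match="chi-squared"):
            exact_multinomial_test([400, 300, 300], [1 / 3, 1 / 3, 1 / 3], cap=1000)

    def test_validity_under_the_null(self):
        """P(p <= alpha) <= alpha + tie slack, exactly over the null table."""
        for n in (10, 30):
            for probs in ((0.5, 0.5), (1 / 3, 1 / 3, 1 / 3), (0.2, 0.3, 0.5)):
                null = ExactMultinomialNull(n, probs)
                pv = np.asarray(null.pvalue(null.outcomes))
                from varpath.stat_tests import multinomial_logpmf

                w = np.exp(multinomial_logpmf(null.outcomes, np.asarray(probs)))
                for alpha in (0.01, 0.05, 0.1):
                    assert w[pv <= alpha].sum() <= alpha + 1e-9


class TestMonteCarlo:
    def test_tracks_exact_within_three_standard_errors(self):
        counts, probs = (3, 12, 15), (0.2, 0.3, 0.5)
        exact = exact_multinomial_test(counts, probs)
        reps = 10_000
        mc = monte_carlo_multinomial_test(counts, probs, reps=reps, seed=0)
        se = np.sqrt(exact * (1 - exact) / reps)
        assert abs(mc - exact) <= 3 * se + 2 / reps

    def test_mode_outcome_near_one(self):
        mc = monte_carlo_multinomial_test([5, 5], [0.5, 0.5], reps=2000, seed=1)
        assert mc >= 1 - 3 * np.sqrt(0.25 / 2000)

    def test_seeded_determinism(self):
        a = monte_carlo_multinomial_test([2, 8, 10], [0.2, 0.4, 0.4], seed=7)
        b = monte_carlo_multinomial_test([2, 8, 10], [0.2, 0.4, 0.4], seed=7)
        assert a == b

    def test_minimum_reps_enforced(self):
        with pytest.raises(ValidationError, match="reps"):
            monte_carlo_multinomial_test([1, 9], [0.5, 0.5], reps=10, seed=0)


class TestChisq:
    def test_perfect_fit(self):
        x2, p = chisq_test([10, 10, 10], [1 / 3, 1 / 3, 1 / 3])
        assert x2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_tail(self):
        x2, p = chisq_test([20, 0], [0.5, 0.5])
        assert x2 == pytest.approx(20.0)
        assert p == pytest.approx(chi2.sf(20, 1))
        assert p == pytest.approx(7.744e-6, rel=1e-3)

    def test_zero_probability_level_rejected(self):
        with pytest.raises(ValidationError, match="merge"):
            chisq_test([5, 5, 1], [0.5, 0.5, 0.0])

    def test_agrees_with_exact_for_large_n(self):
        rng = np.random.default_rng(5)
        probs = np.array([0.25, 0.35, 0.4])
        for _ in range(20):
            counts = rng.multinomial(250, probs)
            _, p_chi = chisq_test(counts, probs)
            p_ex = exact_multinomial_test(counts, probs)
            assert abs(p_chi - p_ex) <= 0.02


class TestTwoGroup:
    def test_identical_counts_pvalue_one(self):
        assert two_group_test([5, 5, 5], [5, 5, 5]) == pytest.approx(1.0)

    def test_extreme_separation_both_methods(self):
        # level 2 empty in both groups drops out; pooled-table X^2 = 60, df 1
        p_chi = two_group_test([30, 0, 0], [0, 0, 30], method="chisq")
        assert p_chi == pytest.approx(chi2.sf(60.0, 1))
        assert p_chi < 1e-6
        assert two_group_test([30, 0, 0], [0, 0, 30], method="exact") < 1e-6

    def test_symmetry_of_homogeneity_chisq(self):
        g1, g2 = [12, 3, 9], [5, 10, 7]
        assert two_group_test(g1, g2) == pytest.approx(two_group_test(g2, g1))

    def test_empty_level_in_both_groups_dropped(self):
        full = two_group_test([10, 0, 5], [3, 0, 12])
        reduced = two_group_test([10, 5], [3, 12])
        assert full == pytest.approx(reduced)

    def test_one_group_all_empty_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            two_group_test([0, 0, 0], [1, 2, 3])

    def test_null_calibration_at_alpha_05(self):
        rng = np.random.default_rng(123)
        probs = np.array([0.3, 0.3, 0.4])
        rej = 0
        reps = 2000
        for _ in range(reps):
            g1 = rng.multinomial(100, probs)
            g2 = rng.multinomial(100, probs)
            rej += two_group_test(g1, g2) < 0.05
        assert 0.035 <= rej / reps <= 0.065


class TestBinomialLevel:
    def test_observed_equals_expectation(self):
        p, direction = binomial_level_test(5, 10, 0.5)
        assert p == pytest.approx(1.0)
        assert direction == "up"  # convention at equality

    def test_doubling_rule_upper_tail(self):
        p, direction = binomial_level_test(10, 10, 0.5)
        assert p == pytest.approx(2 * 0.5**10)
        assert direction == "up"

    def test_symmetry_at_half(self):
        p, direction = binomial_level_test(0, 10, 0.5)
        assert p == pytest.approx(2 * 0.5**10)
        assert direction == "down"

    def test_degenerate_probability_rejected(self):
        for bad in (0.0, 1.0):
            with pytest.raises(ValidationError, match="probability"):
                binomial_level_test(3, 10, bad)


class TestBH:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_value_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    @given(
        ps=st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_idempotent(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)  # adjusted >= raw
        assert np.all((adj >= 0) & (adj <= 1))
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)  # order-preserving


def test_merge_zero_levels():
    p, (c,), merged = merge_zero_levels([0.5, 0.0, 0.5], [3, 0, 7])
    np.testing.assert_allclose(p, [0.5, 0.5])
    np.testing.assert_array_equal(c, [3, 7])
    assert merged == [2]
    p, (c,), merged = merge_zero_levels([0.4, 0.6], [1, 2])
    assert merged == [] and list(c) == [1, 2]
    # leading zero merges into the following level
    p, (c,), merged = merge_zero_levels([0.0, 0.4, 0.6], [2, 1, 2])
    np.testing.assert_allclose(p, [0.4, 0.6])
    np.testing.assert_array_equal(c, [3, 2])
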