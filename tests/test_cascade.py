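"""The exact cascade distribution, its symbolic form, and the enumeration oracle."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from stingcascade import (
    CategoryAssignment,
    EnumerationCapError,
    ParameterVector,
    TerminalPolynomialSet,
    ValidationError,
    brute_force_distribution,
    least_fixed_point,
    outcome_distribution,
    simulate_cascade,
    terminal_polynomials,
)


class TestParameterVector:
    def test_rejects_non_monotone(self):
        with pytest.raises(ValidationError):
            ParameterVector((0.5, 0.3))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            ParameterVector((0.2, 1.2))
        with pytest.raises(ValidationError):
            ParameterVector((-0.1, 0.5))

    def test_band_probabilities_sum_to_one(self):
        q = ParameterVector((0.2, 0.5, 0.9)).band_probabilities()
        assert q == pytest.approx([0.2, 0.3, 0.4, 0.1])
        assert q.sum() == pytest.approx(1.0)


class TestLeastFixedPoint:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((1, 1, 0, 1), 2),  # one initiator recruits the level-1 bee, never-stinger holds out
            ((3, 0, 0, 0), 3),  # all initiators
            ((0, 2, 1, 0), 0),  # nobody initiates, cascade never starts
            ((1, 0, 2, 0), 1),  # level stalls at 1; category-2 bees needed level 2
        ],
    )
    def test_hand_stepped_cases(self, counts, expected):
        assert least_fixed_point(CategoryAssignment(counts)) == expected

    def test_counts_must_sum_to_group_size(self):
        with pytest.raises(ValidationError):
            CategoryAssignment((1, 1, 1, 1))  # sums to 4, group size is 3

    def test_matches_exhaustive_simulation_semantics(self):
        # iterating the recruitment map one category at a time must agree
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(2, 7))
            counts = rng.multinomial(n, np.ones(n + 1) / (n + 1))
            assignment = CategoryAssignment(tuple(counts))
            k, stung = 0, 0
            while True:
                new = sum(counts[j] for j in range(min(k, n - 1) + 1)) - stung
                if new == 0:
                    break
                stung += new
                k = stung
            assert least_fixed_point(assignment) == stung


class TestOutcomeDistribution:
    def test_two_bee_closed_form(self):
        r0, r1 = 0.37, 0.81
        dist = outcome_distribution(ParameterVector((r0, r1)))
        expected = [(1 - r0) ** 2, 2 * r0 * (1 - r1), r0**2 + 2 * r0 * (r1 - r0)]
        assert dist.p == pytest.approx(expected, abs=1e-15)

    def test_constant_probability_is_binomial(self):
        # equal r at all levels means recruitment adds nothing: K ~ Binomial(n, p)
        for n, p in [(2, 0.5), (5, 0.3), (10, 0.77)]:
            dist = outcome_distribution(ParameterVector((p,) * n))
            assert dist.p == pytest.approx(binom.pmf(np.arange(n + 1), n, p), abs=1e-12)

    def test_nobody_stings(self):
        dist = outcome_distribution(ParameterVector((0.0,) * 5))
        assert dist.p[0] == 1.0

    def test_everyone_stings(self):
        dist = outcome_distribution(ParameterVector((1.0,) * 4))
        assert dist.p[4] == 1.0

    def test_three_bee_frozen_values(self):
        # exact rationals for r = (3/10, 1/2, 9/10): (343/1000, 9/40, 63/1000, 369/1000)
        dist = outcome_distribution(ParameterVector((0.3, 0.5, 0.9)))
        assert dist.p == pytest.approx([0.343, 0.225, 0.063, 0.369], abs=1e-12)

    def test_oracle_equivalence_random_vectors(self, random_monotone):
        rng = np.random.default_rng(42)
        for n in range(2, 7):
            polys = terminal_polynomials(n)
            for _ in range(25):
                params = random_monotone(rng, n)
                dp = outcome_distribution(params).as_array()
                bf = brute_force_distribution(params).as_array()
                sym = polys.evaluate(params).as_array()
                np.testing.assert_allclose(dp, bf, atol=1e-12)
                np.testing.assert_allclose(sym, dp, atol=1e-10)

    def test_ties_stall_the_cascade(self):
        # r_1 = r_0 means zero conditional recruitment after the first step
        dist = outcome_distribution(ParameterVector((0.4, 0.4, 0.9)))
        bf = brute_force_distribution(ParameterVector((0.4, 0.4, 0.9)))
        np.testing.assert_allclose(dist.as_array(), bf.as_array(), atol=1e-13)

    def test_saturated_level_handled(self):
        # r_k = 1 at the top level: every remaining bee is recruited
        dist = outcome_distribution(ParameterVector((0.5, 1.0, 1.0)))
        bf = brute_force_distribution(ParameterVector((0.5, 1.0, 1.0)))
        np.testing.assert_allclose(dist.as_array(), bf.as_array(), atol=1e-13)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.integers(min_value=1, max_value=5),
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=5, max_size=5),
    )
    def test_distribution_is_always_normalised(self, n, raw):
        params = ParameterVector(tuple(sorted(raw[:n])))
        dist = outcome_distribution(params)
        assert abs(sum(dist.p) - 1.0) < 1e-12
        assert all(-1e-15 <= p <= 1.0 + 1e-15 for p in dist.p)

    def test_raising_any_level_never_reduces_expected_stings(self):
        base = np.array([0.2, 0.35, 0.5, 0.7])
        mean0 = outcome_distribution(ParameterVector(tuple(base))).mean()
        for k in range(4):
            bumped = base.copy()
            hi = base[k + 1] if k < 3 else 1.0
            bumped[k] = min(base[k] + 0.1, hi)
            mean1 = outcome_distribution(ParameterVector(tuple(bumped))).mean()
            assert mean1 >= mean0 - 1e-12

    def test_brute_force_refuses_large_groups(self):
        with pytest.raises(EnumerationCapError):
            brute_force_distribution(ParameterVector((0.1,) * 9), cap=8)


class TestTerminalPolynomials:
    def test_two_bee_polynomials_exact(self):
        r0, r1 = sp.symbols("r0 r1", nonnegative=True)
        polys = terminal_polynomials(2).polys
        assert sp.expand(polys[0] - (1 - r0) ** 2) == 0
        assert sp.expand(polys[1] - 2 * r0 * (1 - r1)) == 0
        assert sp.expand(polys[2] - (r0**2 + 2 * r0 * (r1 - r0))) == 0

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 6])
    def test_polynomials_sum_to_one(self, n):
        assert sp.simplify(sum(terminal_polynomials(n).polys) - 1) == 0

    def test_symbolic_matches_numeric_at_larger_sizes(self, random_monotone):
        rng = np.random.default_rng(3)
        polys = terminal_polynomials(8)
        for _ in range(10):
            params = random_monotone(rng, 8)
            np.testing.assert_allclose(
                polys.evaluate(params).as_array(),
                outcome_distribution(params).as_array(),
                atol=1e-10,
            )

    def test_json_round_trip(self):
        original = terminal_polynomials(3)
        restored = TerminalPolynomialSet.from_json(original.to_json())
        assert restored.n == original.n
        for a, b in zip(original.polys, restored.polys):
            assert sp.expand(a - b) == 0

    def test_canonical_strings_are_parseable(self):
        polys = terminal_polynomials(2)
        strings = polys.canonical_strings()
        assert len(strings) == 3
        r0, r1 = polys.variables
        for text, expr in zip(strings, polys.polys):
            parsed = sp.parse_expr(text.replace("^", "**"), local_dict={"r0": r0, "r1": r1})
            assert sp.expand(parsed - expr) == 0

    def test_cap_refusal(self):
        with pytest.raises(EnumerationCapError):
            terminal_polynomials(13, cap=12)


class TestSimulation:
    def test_degenerate_traces(self):
        zero = simulate_cascade(ParameterVector((0.0,) * 4), seed=0)
        assert zero.final_count == 0 and zero.new_stings == ()
        ones = simulate_cascade(ParameterVector((1.0,) * 4), seed=0)
        assert ones.final_count == 4 and ones.new_stings == (4,)

    def test_trace_is_reproducible_and_consistent(self):
        params = ParameterVector(tuple(0.2 + 0.1 * k for k in range(5)))
        a = simulate_cascade(params, seed=123)
        b = simulate_cascade(params, seed=123)
        assert a == b
        assert all(s > 0 for s in a.new_stings)
        assert a.final_count == sum(a.new_stings)
        assert a.observable_trace() == tuple(np.cumsum(a.new_stings))

    def test_empirical_frequencies_match_exact_distribution(self):
        params = ParameterVector(tuple(0.2 + 0.05 * k for k in range(5)))
        exact = outcome_distribution(params).as_array()
        rng = np.random.default_rng(2024)
        trials = 20000
        counts = np.zeros(6)
        for _ in range(trials):
            counts[simulate_cascade(params, rng).final_count] += 1
        freq = counts / trials
        se = np.sqrt(exact * (1 - exact) / trials)
        assert np.all(np.abs(freq - exact) <= 4 * se + 1e-9)
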