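"""Point estimation, exact likelihood, the Metropolis sampler and sensitivity."""

import math

import numpy as np
import pytest

from stingcascade import (
    FeasibilityError,
    FitConfig,
    FitError,
    ObservedCounts,
    ParameterVector,
    ShapeSpec,
    expand,
    l2_fit,
    local_sensitivity,
    log_likelihood,
    metropolis_hastings,
    outcome_distribution,
    terminal_polynomials,
)
from stingcascade.synth import GenerationSpec, GroupCondition, generate


class TestLogLikelihood:
    def test_certain_outcome_gives_zero(self):
        data = ObservedCounts((50, 0, 0))
        assert log_likelihood(ShapeSpec("agnostic", (0.0, 0.0)), data) == 0.0

    def test_two_bee_single_trial(self):
        data = ObservedCounts((1, 0, 0))
        ll = log_likelihood(ShapeSpec("agnostic", (0.5, 0.5)), data)
        assert ll == pytest.approx(-2 * math.log(2))

    def test_impossible_observation_is_minus_inf(self):
        data = ObservedCounts((0, 0, 5))
        assert log_likelihood(ShapeSpec("agnostic", (0.0, 0.0)), data) == -math.inf

    def test_infeasible_theta_is_minus_inf_not_error(self):
        data = ObservedCounts((1, 2, 3))
        assert log_likelihood(ShapeSpec("linear", (0.9, 0.5)), data) == -math.inf

    def test_matches_terminal_polynomial_computation(self, fig2):
        # cross-implementation check: likelihood from the symbolic route
        polys = terminal_polynomials(10)
        for theta in [(0.14, 0.055), (0.3, 0.02)]:
            params = expand(ShapeSpec("linear", theta), 10)
            p = polys.evaluate(params).as_array()
            direct = sum(c * math.log(pk) for c, pk in zip(fig2.counts, p) if c)
            assert log_likelihood(ShapeSpec("linear", theta), fig2) == pytest.approx(direct)


class TestL2Fit:
    def test_recovers_generating_linear_shape(self):
        truth = ShapeSpec("linear", (0.2, 0.05))
        spec = GenerationSpec({5: GroupCondition(truth, 10**6)}, seed=11)
        data = generate(spec)[0][5]
        fit = l2_fit(data, "linear", FitConfig(restarts=6, seed=0))
        assert fit.shape.theta == pytest.approx(truth.theta, abs=2e-3)
        assert fit.l2_distance < 1e-5

    def test_all_zero_sting_data_hits_boundary(self):
        data = ObservedCounts((100, 0, 0, 0))
        fit = l2_fit(data, "agnostic", FitConfig(restarts=6, seed=0))
        assert fit.shape.theta[0] == pytest.approx(0.0, abs=1e-4)
        assert fit.l2_distance < 1e-7

    def test_predicted_is_consistent_with_expanded(self, fig2):
        fit = l2_fit(fig2, "linear", FitConfig(restarts=4, seed=1))
        np.testing.assert_allclose(
            fit.predicted.as_array(),
            outcome_distribution(fit.expanded).as_array(),
            atol=1e-10,
        )

    def test_estimates_tighten_with_sample_size(self):
        truth = ShapeSpec("linear", (0.2, 0.05))
        errors = []
        for trials in (100, 1000, 10000):
            data = generate(GenerationSpec({8: GroupCondition(truth, trials)}, seed=5))[0][8]
            fit = l2_fit(data, "linear", FitConfig(restarts=5, seed=0))
            errors.append(np.abs(np.subtract(fit.shape.theta, truth.theta)).max())
        assert errors[-1] < errors[0]
        assert errors[-1] < 0.02


class TestMetropolisHastings:
    @pytest.fixture()
    def small_data(self):
        return ObservedCounts((40, 35, 17))

    def test_identical_seed_identical_trace(self, small_data):
        kw = dict(iterations=500, theta_init=(0.3, 0.5), proposal_scale=0.1, seed=9)
        a = metropolis_hastings(small_data, "agnostic", **kw)
        b = metropolis_hastings(small_data, "agnostic", **kw)
        np.testing.assert_array_equal(a.chain, b.chain)
        np.testing.assert_array_equal(a.accepted, b.accepted)

    def test_likelihood_increases_only_via_accepted_moves(self, small_data):
        trace = metropolis_hastings(
            small_data, "agnostic", iterations=2000, theta_init=(0.3, 0.5),
            proposal_scale=0.1, seed=2,
        )
        rose = np.flatnonzero(np.diff(trace.log_liks) > 0) + 1
        assert trace.accepted[rose].all()

    def test_every_chain_state_is_feasible(self, small_data):
        trace = metropolis_hastings(
            small_data, "agnostic", iterations=3000, theta_init=(0.3, 0.5),
            proposal_scale=0.15, seed=4,
        )
        assert np.all(trace.chain[:, 0] >= 0)
        assert np.all(trace.chain[:, 1] <= 1)
        assert np.all(np.diff(trace.chain, axis=1) >= 0)

    def test_burn_in_split(self, small_data):
        trace = metropolis_hastings(
            small_data, "agnostic", iterations=1000, theta_init=(0.3, 0.5),
            proposal_scale=0.1, burn_in=0.25, seed=0,
        )
        assert trace.posterior().shape[0] == 750
        idx, pts = trace.accepted_points
        assert pts.shape[0] == idx.size == trace.accepted.sum()

    def test_infeasible_init_rejected(self, small_data):
        with pytest.raises(FeasibilityError):
            metropolis_hastings(small_data, "agnostic", 10, (0.9, 0.1), seed=0)

    def test_zero_likelihood_init_rejected(self):
        data = ObservedCounts((0, 0, 10))
        with pytest.raises(FitError):
            metropolis_hastings(data, "agnostic", 10, (0.0, 0.0), seed=0)

    def test_trace_csv_round_trip(self, small_data, tmp_path):
        trace = metropolis_hastings(
            small_data, "agnostic", iterations=50, theta_init=(0.3, 0.5),
            proposal_scale=0.1, seed=0,
        )
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        import pandas as pd

        frame = pd.read_csv(path)
        assert len(frame) == 50
        np.testing.assert_allclose(frame[["theta_0", "theta_1"]].to_numpy(), trace.chain)


class TestLocalSensitivity:
    def test_zero_scale_gives_zero_scores(self, fig2):
        point = ShapeSpec("linear", (0.14, 0.055))
        res = local_sensitivity(point, fig2, scale=0.0)
        assert np.all(res.scores == 0.0)

    def test_late_parameters_are_least_informative(self, fig2):
        # no trial reached 9+ stings: r_9 only enters through near-zero-probability
        # outcomes, so the objective barely reacts to it
        fit = l2_fit(fig2, "agnostic", FitConfig(restarts=8, seed=0))
        res = local_sensitivity(fit.expanded, fig2, scale=0.05, samples=200, seed=1)
        assert res.scores[9] < 0.05 * res.scores[0]

    def test_matches_finite_difference_gradient(self):
        # smooth interior point: the mean |delta objective|/|delta| converges to the
        # absolute gradient of the L2 objective as the perturbation scale shrinks
        data = ObservedCounts((0, 0, 50))
        point = ParameterVector((0.4, 0.6))
        freq = data.frequencies()

        def objective(r):
            return float(
                np.sum((outcome_distribution(ParameterVector(tuple(r))).as_array() - freq) ** 2)
            )

        h = 1e-6
        grad = np.empty(2)
        for i in range(2):
            up, dn = np.array(point.r), np.array(point.r)
            up[i] += h
            dn[i] -= h
            grad[i] = (objective(up) - objective(dn)) / (2 * h)
        res = local_sensitivity(point, data, scale=1e-4, samples=400, seed=0)
        np.testing.assert_allclose(res.scores, np.abs(grad), rtol=0.05)
        assert np.abs(grad[1]) > 0  # r_1 matters here even though only K=2 was seen

    def test_skipped_counts_reported_for_tied_parameters(self):
        data = ObservedCounts((5, 5, 5))
        res = local_sensitivity(ParameterVector((0.5, 0.5)), data, scale=0.05, samples=50, seed=0)
        # the pair is tied: each parameter has one blocked direction, roughly half skipped
        assert res.skipped.sum() > 0
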