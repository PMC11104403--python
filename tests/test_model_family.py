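import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bartmodel import (
    BeliefState,
    ModelSpec,
    ParticipantParams,
    belief_update,
    enumerate_family,
    initial_state,
    optimal_pumps,
    outcome_distribution,
    pump_probability,
    score_trial,
    trial_loglik,
    update_state,
)
from bartmodel.model_family import PARAM_NAMES, block_loglik_matrix
from bartmodel.task_engine import LC, TaskConfig


class TestBeliefUpdate:
    def test_direct_evaluation(self):
        assert belief_update(0.5, 1.0, 10, 10) == pytest.approx(1 - 10.5 / 11)
        assert belief_update(0.5, 1.0, 0, 10) == pytest.approx(1 - 0.5 / 11)

    def test_zero_learning_rate_never_updates(self):
        base = belief_update(0.7, 0.0, 0, 0)
        for cs, cp in [(0, 5), (5, 5), (40, 100)]:
            assert belief_update(0.7, 0.0, cs, cp) == base == pytest.approx(0.3)

    def test_clamped_to_unit_interval(self):
        # transformed prior may exceed 1; belief must stay inside [eps, 1-eps]
        assert belief_update(1.4, 0.1, 0, 0) == pytest.approx(1e-6)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            belief_update(-0.1, 0.5, 0, 0)
        with pytest.raises(ValueError):
            belief_update(0.5, 0.5, 3, 2)  # successes exceed pumps

    @given(
        pb=st.floats(0.1, 1.5),
        lr=st.floats(0.0, 1.0),
        cp=st.integers(0, 200),
        extra=st.integers(1, 20),
    )
    @settings(max_examples=100, deadline=None)
    def test_more_successes_lower_burst_belief(self, pb, lr, cp, extra):
        cs_lo = max(cp - extra, 0)
        lo = belief_update(pb, lr, cs_lo, cp)
        hi = belief_update(pb, lr, cp, cp)
        assert hi <= lo + 1e-12


class TestOptimalPumps:
    def test_unit_target_by_construction(self):
        assert optimal_pumps(1.0, 1 - math.exp(-1)) == pytest.approx(1.0)

    def test_linear_in_risk_taking(self):
        p = 0.3
        assert optimal_pumps(2.4, p) == pytest.approx(2 * optimal_pumps(1.2, p))

    def test_decreasing_in_belief(self):
        ps = np.linspace(0.05, 0.95, 10)
        vals = [optimal_pumps(1.0, p) for p in ps]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_extreme_belief_limit(self):
        eps = 1e-6
        assert optimal_pumps(1.0, 1 - eps) == pytest.approx(1.0 / abs(math.log(eps)))

    def test_raw_boundary_rejected(self):
        for p in (0.0, 1.0):
            with pytest.raises(ValueError):
                optimal_pumps(1.0, p)


class TestPumpProbability:
    def test_sigmoid_midpoint(self):
        assert pump_probability(3.0, 4.0, 4.0) == pytest.approx(0.5)

    def test_one_above_target(self):
        assert pump_probability(1.0, 6.0, 5.0) == pytest.approx(1 / (1 + math.e))

    def test_deterministic_limit_is_step(self):
        assert pump_probability(1e4, 5.0, 5.5) == pytest.approx(1.0)
        assert pump_probability(1e4, 6.0, 5.5) == pytest.approx(0.0)

    def test_decreasing_in_opportunity(self):
        probs = [pump_probability(1.5, o, 5.0) for o in range(1, 12)]
        assert all(a > b for a, b in zip(probs, probs[1:]))


def _log_sigmoid(z):
    return -math.log1p(math.exp(-z)) if z >= 0 else z - math.log1p(math.exp(z))


def _naive_trial_loglik(n_pumps, burst, number_t, beta):
    """Independent oracle: explicit per-opportunity Bernoulli product."""
    ll = 0.0
    for l in range(1, n_pumps + 1):
        ll += _log_sigmoid(-beta * (l - number_t))  # P(pump at l)
    if not burst:
        ll += _log_sigmoid(beta * ((n_pumps + 1) - number_t))  # P(stop at n+1)
    return ll


class TestTrialLoglik:
    def test_matches_naive_bernoulli_product(self, task_main):
        rng = np.random.default_rng(0)
        for _ in range(50):
            params = ParticipantParams(
                float(rng.uniform(0.5, 1.2)),
                float(rng.uniform(0, 1)),
                float(rng.uniform(0.2, 3)),
                float(rng.uniform(0.3, 5)),
            )
            state = initial_state(params)
            thr = int(rng.integers(2, 15))
            n = int(rng.integers(0, thr + 1))
            rec = score_trial(n, thr, LC, task_main)
            number_t = optimal_pumps(params.risk_taking, state.p_belief)
            expected = _naive_trial_loglik(
                n, rec.burst, number_t, params.inverse_temperature
            )
            assert trial_loglik(rec, state, params) == pytest.approx(
                expected, abs=1e-10
            )

    def test_deterministic_agent_matches_observation(self, task_main):
        # beta -> inf, target 5.5: exactly 5 pumps is the only possible outcome
        params = ParticipantParams(0.85, 0.0, -5.5 * math.log(0.85), 5e3)
        state = initial_state(params)
        assert optimal_pumps(params.risk_taking, state.p_belief) == pytest.approx(5.5)
        rec_ok = score_trial(5, 12, LC, task_main)
        assert trial_loglik(rec_ok, state, params) == pytest.approx(0.0, abs=1e-9)
        rec_bad = score_trial(3, 12, LC, task_main)
        assert trial_loglik(rec_bad, state, params) < -100

    def test_one_pump_burst_is_single_bernoulli_term(self, agent, task_main):
        state = initial_state(agent)
        rec = score_trial(1, 1, LC, task_main)
        number_t = optimal_pumps(agent.risk_taking, state.p_belief)
        expected = math.log(pump_probability(agent.inverse_temperature, 1, number_t))
        assert trial_loglik(rec, state, agent) == pytest.approx(expected)

    @pytest.mark.parametrize("threshold", range(1, 11))
    def test_outcome_probabilities_sum_to_one(self, threshold):
        # brute-force conservation over every possible single-trial outcome
        rng = np.random.default_rng(threshold)
        for _ in range(5):
            params = ParticipantParams(
                float(rng.uniform(0.4, 1.3)),
                float(rng.uniform(0, 1)),
                float(rng.uniform(0.1, 4)),
                float(rng.uniform(0.2, 6)),
            )
            state = initial_state(params)
            total = 0.0
            cfg = TaskConfig.preset("main")
            for n in range(threshold + 1):
                rec = score_trial(n, threshold, LC, cfg)
                total += math.exp(trial_loglik(rec, state, params))
            assert total == pytest.approx(1.0, abs=1e-10)
            assert np.sum(outcome_distribution(threshold, state, params)) == (
                pytest.approx(1.0, abs=1e-10)
            )


class TestUpdateState:
    def test_nonburst_counts_all_pumps_as_successes(self, agent, task_main):
        rec = score_trial(4, 12, LC, task_main)
        st1 = update_state(initial_state(agent), rec, agent)
        assert (st1.cum_pumps, st1.cum_successes) == (4, 4)

    def test_burst_discounts_final_pump(self, agent, task_main):
        rec = score_trial(4, 4, LC, task_main)
        st1 = update_state(initial_state(agent), rec, agent)
        assert (st1.cum_pumps, st1.cum_successes) == (4, 3)

    def test_zero_pump_trial_leaves_belief_unchanged(self, agent, task_main):
        st0 = initial_state(agent)
        rec = score_trial(0, 12, LC, task_main)
        st1 = update_state(st0, rec, agent)
        assert st1 == st0

    def test_belief_recomputed_after_trial(self, task_main):
        params = ParticipantParams(0.5, 1.0, 1.0, 1.0)
        rec = score_trial(10, 12, LC, task_main)
        st1 = update_state(initial_state(params), rec, params)
        assert st1.p_belief == pytest.approx(1 - 10.5 / 11)


class TestModelFamily:
    def test_exactly_fifteen_variants(self):
        family = enumerate_family()
        assert len(family) == 15

    def test_full_model_is_a_member(self):
        names = [s.name for s in enumerate_family()]
        assert "full" in names
        assert len(set(names)) == 15

    def test_all_fixed_assignment_excluded(self):
        for spec in enumerate_family():
            assert len(spec.random) >= 1
        with pytest.raises(ValueError):
            ModelSpec(())

    def test_json_roundtrip(self):
        for spec in enumerate_family():
            assert ModelSpec.from_json(spec.to_json()) == spec

    def test_fixed_is_complement_of_random(self):
        spec = ModelSpec(("prior_belief", "risk_taking"))
        assert spec.fixed == ("learning_rate", "inverse_temperature")
        assert spec.name == "pb+rt"


class TestBlockLoglikMatrix:
    def test_matches_scalar_path(self, task_main):
        # vectorized sampler path vs the per-trial scalar implementation
        rng = np.random.default_rng(1)
        N, T = 5, 12
        thresholds = rng.integers(2, 14, size=(N, T))
        params = [
            ParticipantParams(
                float(rng.uniform(0.5, 1.1)),
                float(rng.uniform(0, 1)),
                float(rng.uniform(0.3, 2.5)),
                float(rng.uniform(0.5, 4)),
            )
            for _ in range(N)
        ]
        n_pumps = np.zeros((N, T), dtype=int)
        burst = np.zeros((N, T), dtype=bool)
        expected = np.zeros(N)
        for i, p in enumerate(params):
            state = initial_state(p)
            for t in range(T):
                thr = int(thresholds[i, t])
                n = int(rng.integers(0, thr + 1))
                rec = score_trial(n, thr, LC, task_main, trial_index=t + 1)
                n_pumps[i, t], burst[i, t] = n, rec.burst
                expected[i] += trial_loglik(rec, state, p)
                state = update_state(state, rec, p)
        nat = np.array([p.as_array() for p in params])
        got = block_loglik_matrix(
            n_pumps, burst, nat[:, 0], nat[:, 1], nat[:, 2], nat[:, 3]
        )
        np.testing.assert_allclose(got, expected, atol=1e-8)
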