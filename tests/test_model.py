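"""Trial-by-trial learning model: decision rule, confidence link, CPE
updates and the generative/conditioned session runner."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from cplearn.energy import EnergyObservation, normalize_energies
from cplearn.model import (
    CCW,
    CW,
    ModelParams,
    ModelState,
    choice_probability,
    confidence_log_density,
    confidence_prediction_error,
    decision_activities,
    decision_value,
    decisional_certainty,
    run_session,
    update_expected_confidence,
    update_weights,
)


def make_state(signal=1.0, noise=0.1, c_bar=0.5) -> ModelState:
    return ModelState(
        w_ccw_ccw=signal, w_cw_cw=signal, w_ccw_cw=noise, w_cw_ccw=noise, c_bar=c_bar
    )


class TestDecisionPath:
    def test_hand_evaluated_activities(self):
        E = EnergyObservation(0.8, 0.2, E_ccw=0.8, E_cw=0.2)
        a_ccw, a_cw = decision_activities(E, make_state(signal=1.0, noise=0.1))
        assert a_ccw == pytest.approx(0.82)
        assert a_cw == pytest.approx(0.28)
        assert decision_value(a_ccw, a_cw) == pytest.approx(-0.54)

    def test_zero_weights_give_zero_activities(self):
        E = EnergyObservation(0.8, 0.2, E_ccw=0.8, E_cw=0.2)
        assert decision_activities(E, make_state(0.0, 0.0)) == (0.0, 0.0)

    def test_energy_swap_with_symmetric_weights_swaps_activities(self):
        state = make_state(signal=0.7, noise=0.2)
        e1 = EnergyObservation(0.9, 0.3, E_ccw=0.9, E_cw=0.3)
        e2 = EnergyObservation(0.3, 0.9, E_ccw=0.3, E_cw=0.9)
        a1 = decision_activities(e1, state)
        a2 = decision_activities(e2, state)
        assert a1 == pytest.approx((a2[1], a2[0]))

    def test_decision_value_antisymmetry(self):
        assert decision_value(0.3, 0.8) == -decision_value(0.8, 0.3)

    @pytest.mark.parametrize(
        "dv,beta,expected",
        [(0.0, 5.0, 0.5), (2.0, 0.0, 0.5), (1.0, 2.0, 0.8807970779778823)],
    )
    def test_softmax_choice_probability(self, dv, beta, expected):
        assert choice_probability(dv, beta) == pytest.approx(expected, abs=1e-9)

    def test_softmax_overflow_guarded(self):
        assert choice_probability(-1e6, 100.0) == 0.0
        assert choice_probability(1e6, 100.0) == 1.0

    @pytest.mark.parametrize("dv,lam,expected", [(0.0, 3.0, 0.0), (-0.2, 3.0, 0.6)])
    def test_certainty_scales_absolute_decision_value(self, dv, lam, expected):
        assert decisional_certainty(dv, lam) == pytest.approx(expected)
        assert decisional_certainty(dv, lam) == decisional_certainty(-dv, lam)


class TestConfidenceLearning:
    def test_prediction_error_is_plain_difference(self):
        assert confidence_prediction_error(0.9, 0.5) == pytest.approx(0.4)
        assert confidence_prediction_error(0.5, 0.5) == 0.0
        with pytest.raises(ValueError):
            confidence_prediction_error(1.2, 0.5)

    def test_expected_confidence_update(self):
        assert update_expected_confidence(0.5, 0.4, 0.5) == pytest.approx(0.7)
        assert update_expected_confidence(0.5, 0.4, 0.0) == 0.5

    def test_constant_feed_converges_geometrically(self):
        """Feeding a constant confidence c shrinks |c_bar - c| by (1-alpha_c)
        each trial (closed-form geometric recursion)."""
        alpha_c, c, c_bar = 0.3, 0.9, 0.2
        for t in range(1, 12):
            delta = confidence_prediction_error(c, c_bar)
            c_bar = update_expected_confidence(c_bar, delta, alpha_c)
            assert abs(c_bar - c) == pytest.approx(0.7 * (1 - alpha_c) ** t, abs=1e-12)

    def test_weight_update_hand_value(self):
        state = make_state(signal=0.5, noise=0.1)
        E = EnergyObservation(0.2, 0.6, E_ccw=0.2, E_cw=0.6)
        new = update_weights(state, delta=0.4, E=E, a_choice=0.5, choice=CW, alpha_w=0.01)
        assert new.w_cw_cw - state.w_cw_cw == pytest.approx(0.01 * 0.4 * 0.6 * 0.5)  # 0.0012
        assert new.w_ccw_cw - state.w_ccw_cw == pytest.approx(0.01 * 0.4 * 0.2 * 0.5)

    def test_only_chosen_unit_connections_change(self):
        state = make_state()
        E = EnergyObservation(0.2, 0.6, E_ccw=0.2, E_cw=0.6)
        new = update_weights(state, 0.4, E, 0.5, CCW, 0.01)
        assert new.w_cw_cw == state.w_cw_cw and new.w_ccw_cw == state.w_ccw_cw
        assert new.w_cw_ccw != state.w_cw_ccw and new.w_ccw_ccw != state.w_ccw_ccw

    def test_zero_prediction_error_freezes_weights(self):
        state = make_state()
        E = EnergyObservation(0.2, 0.6, E_ccw=0.2, E_cw=0.6)
        assert update_weights(state, 0.0, E, 0.5, CW, 0.01) == state

    @given(
        confs=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50),
        alpha_c=st.floats(0.0, 1.0),
        c_bar0=st.floats(0.0, 1.0),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_expected_confidence_stays_in_unit_interval(self, confs, alpha_c, c_bar0):
        """The convex Rescorla-Wagner update keeps c_bar in [0, 1] for any
        sequence of confidences in [0, 1]."""
        c_bar = c_bar0
        for c in confs:
            c_bar = update_expected_confidence(c_bar, c - c_bar, alpha_c)
            assert -1e-12 <= c_bar <= 1 + 1e-12


class TestConfidenceLikelihood:
    def test_density_at_mode(self):
        expected = math.log(1.0 / (0.2 * math.sqrt(2 * math.pi)))  # 0.690483...
        assert confidence_log_density(0.5, 0.5, 0.2) == pytest.approx(expected, abs=1e-12)

    def test_boundary_mass_at_zero(self):
        # half the normal mass lies below the boundary when c' = 0
        assert confidence_log_density(0.0, 0.0, 0.3) == pytest.approx(math.log(0.5))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            confidence_log_density(0.5, 0.5, 0.0)
        with pytest.raises(ValueError):
            confidence_log_density(1.5, 0.5, 0.2)

    @pytest.mark.parametrize("c_prime,sigma", [(0.3, 0.2), (0.0, 0.1), (1.4, 0.5), (0.8, 0.05)])
    def test_censored_distribution_normalizes(self, c_prime, sigma):
        """Boundary masses plus the interior density integrate to one."""
        mass0 = math.exp(confidence_log_density(0.0, c_prime, sigma))
        mass1 = math.exp(confidence_log_density(1.0, c_prime, sigma))
        interior, _ = quad(lambda c: norm.pdf(c, c_prime, sigma), 0.0, 1.0)
        assert mass0 + interior + mass1 == pytest.approx(1.0, abs=1e-9)


def _toy_energies(n, rng, separation=0.6):
    truths = [CW if rng.random() < 0.5 else CCW for _ in range(n)]
    raw = []
    for truth in truths:
        des = rng.uniform(0.5, 0.5 + separation)
        opp = rng.uniform(0.0, 0.3)
        raw.append(
            EnergyObservation(E_ccw_raw=opp, E_cw_raw=des)
            if truth == CW
            else EnergyObservation(E_ccw_raw=des, E_cw_raw=opp)
        )
    return normalize_energies(raw, mode="session_max"), truths


class TestRunSession:
    def make_params(self, **kw):
        defaults = dict(alpha_w=0.01, alpha_c=0.4, beta=5.0, lambda_=2.0,
                        sigma_c=0.2, w0_signal=1.0, w0_noise=0.1)
        defaults.update(kw)
        return ModelParams(**defaults)

    def test_zero_learning_rate_freezes_weights(self):
        rng = np.random.default_rng(0)
        energies, truths = _toy_energies(50, rng)
        res = run_session(self.make_params(alpha_w=0.0), energies, "generative",
                          true_orientations=truths, rng=rng)
        for state in res.state_trajectory:
            assert state.w_ccw_ccw == 1.0 and state.w_cw_ccw == 0.1

    def test_deterministic_limit_is_perfectly_accurate(self):
        """With a steep softmax, clean energies and strong signal weights the
        generative observer approaches perfect accuracy."""
        rng = np.random.default_rng(1)
        energies, truths = _toy_energies(400, rng)
        res = run_session(self.make_params(beta=50.0, alpha_w=0.0), energies,
                          "generative", true_orientations=truths, rng=rng)
        accuracy = np.mean([t.correct for t in res.trials])
        assert accuracy > 0.99

    def test_conditioned_mode_reproduces_observed_stream(self):
        rng = np.random.default_rng(2)
        energies, truths = _toy_energies(80, rng)
        params = self.make_params()
        gen = run_session(params, energies, "generative", true_orientations=truths,
                          rng=np.random.default_rng(3))
        cond = run_session(
            params, energies, "conditioned", true_orientations=truths,
            observed_choices=[t.choice for t in gen.trials],
            observed_confidences=[t.confidence for t in gen.trials],
        )
        # identical inputs drive identical weight trajectories
        for a, b in zip(gen.state_trajectory, cond.state_trajectory):
            assert a == b
        assert np.isfinite(cond.log_likelihood)

    def test_relabeling_invariance(self):
        """Swapping cw<->ccw in both energies and weights mirrors choice
        probabilities and leaves certainty unchanged."""
        state = ModelState(w_ccw_ccw=0.9, w_cw_cw=0.6, w_ccw_cw=0.2, w_cw_ccw=0.05)
        mirror = ModelState(w_ccw_ccw=0.6, w_cw_cw=0.9, w_ccw_cw=0.05, w_cw_ccw=0.2)
        E = EnergyObservation(0.8, 0.3, E_ccw=0.8, E_cw=0.3)
        E_m = EnergyObservation(0.3, 0.8, E_ccw=0.3, E_cw=0.8)
        dv = decision_value(*decision_activities(E, state))
        dv_m = decision_value(*decision_activities(E_m, mirror))
        assert dv_m == pytest.approx(-dv)
        assert choice_probability(dv_m, 4.0) == pytest.approx(1 - choice_probability(dv, 4.0))
        assert decisional_certainty(dv_m, 2.0) == pytest.approx(decisional_certainty(dv, 2.0))

    def test_stream_length_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        energies, truths = _toy_energies(10, rng)
        with pytest.raises(ValueError):
            run_session(self.make_params(), energies, "conditioned",
                        observed_choices=[CW] * 5, observed_confidences=[0.5] * 5)

    def test_invalid_param_bounds_rejected(self):
        for bad in [dict(alpha_w=-0.1), dict(alpha_c=1.5), dict(beta=-1.0),
                    dict(lambda_=-0.5), dict(sigma_c=0.0)]:
            with pytest.raises(ValueError):
                self.make_params(**bad)
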