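import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bimodal_inference import model as md
from bimodal_inference import trialdata as td
from conftest import make_series


def params(**kw):
    base = dict(alpha=0.5, hazard=0.45, amp_llr=0.5, amp_psi=1.44,
                freq=0.11, phase=2.72, zeta=4.63)
    base.update(kw)
    return md.ModelParams(**base)


class TestAnalyticIdentities:
    @given(l_prev=st.floats(-30, 30))
    @settings(max_examples=80, deadline=None)
    def test_prior_vanishes_at_uninformative_hazard(self, l_prev):
        assert md.prior_update(l_prev, 0.5) == pytest.approx(0.0, abs=1e-12)

    @given(hazard=st.floats(0.01, 0.99))
    @settings(max_examples=80, deadline=None)
    def test_prior_vanishes_at_zero_posterior(self, hazard):
        assert md.prior_update(0.0, hazard) == pytest.approx(0.0, abs=1e-12)

    @given(l_prev=st.floats(-50, 50), hazard=st.floats(0.02, 0.48))
    @settings(max_examples=100, deadline=None)
    def test_prior_saturation_bound_and_oddness(self, l_prev, hazard):
        bound = math.log((1 - hazard) / hazard)
        psi = float(md.prior_update(l_prev, hazard))
        assert abs(psi) <= bound + 1e-12
        assert psi == pytest.approx(-float(md.prior_update(-l_prev, hazard)), abs=1e-10)

    def test_prior_saturates_in_the_large_posterior_limit(self):
        bound = math.log(0.9 / 0.1)
        assert md.prior_update(500.0, 0.1) == pytest.approx(bound, abs=1e-9)

    def test_prior_monotone_increasing_below_half_hazard(self):
        grid = np.linspace(-20, 20, 400)
        psi = md.prior_update(grid, 0.3)
        assert np.all(np.diff(psi) > 0)

    def test_prior_hand_value(self):
        # (1-H)/H = 9: 2 + log(9 + e^-2) - log(9 + e^2)
        assert md.prior_update(2.0, 0.1) == pytest.approx(1.41554, abs=1e-4)

    def test_hazard_limits(self):
        assert md.prior_update(1.7, 0.0) == pytest.approx(1.7)
        assert md.prior_update(1.7, 1.0) == pytest.approx(-1.7)

    @given(alpha=st.floats(0, 5), s=st.floats(0, 1))
    @settings(max_examples=60, deadline=None)
    def test_llr_identity_binary(self, alpha, s):
        u = md.sensory_observation(s, alpha, td.BINARY_CATEGORY)
        assert float(md.log_likelihood_ratio(u)) == pytest.approx(
            alpha * (s - 0.5), abs=1e-12
        )

    @given(alpha=st.floats(0, 5), s=st.floats(-1, 1))
    @settings(max_examples=60, deadline=None)
    def test_llr_identity_signed_contrast(self, alpha, s):
        u = md.sensory_observation(s, alpha, td.SIGNED_CONTRAST)
        assert float(md.log_likelihood_ratio(u)) == pytest.approx(alpha * s, abs=1e-12)

    def test_sensory_observation_reference_values(self):
        assert float(md.sensory_observation(1.0, 0.5, td.BINARY_CATEGORY)) == pytest.approx(0.5622, abs=5e-5)
        assert float(md.sensory_observation(0.5, 1.06, td.SIGNED_CONTRAST)) == pytest.approx(0.6295, abs=5e-5)
        assert float(md.sensory_observation(0.7, 0.0, td.BINARY_CATEGORY)) == 0.5

    def test_llr_antisymmetry(self):
        u = np.array([0.2, 0.35, 0.5, 0.9])
        np.testing.assert_allclose(
            md.log_likelihood_ratio(u), -md.log_likelihood_ratio(1 - u), atol=1e-12
        )

    def test_precision_weights(self):
        w_llr, w_psi = md.precision_weights(1, 0.5, 0.5, 0.11, 2.72)
        assert float(w_llr) == pytest.approx(1.1533, abs=5e-5)
        t = np.arange(1, 200)
        w_llr, w_psi = md.precision_weights(t, 0.8, 0.8, 0.13, 1.0)
        np.testing.assert_allclose(w_llr + w_psi, 2.0, atol=1e-12)

    def test_zero_amplitudes_give_unit_weights(self):
        w_llr, w_psi = md.precision_weights(np.arange(1, 10), 0.0, 0.0, 0.11, 2.72)
        np.testing.assert_array_equal(w_llr, 1.0)
        np.testing.assert_array_equal(w_psi, 1.0)

    def test_posterior_step_arithmetic_and_sign_symmetry(self):
        assert md.posterior_step(0.25, 0.2, 1.15, 0.85) == pytest.approx(0.4575)
        assert md.posterior_step(-0.25, -0.2, 1.15, 0.85) == pytest.approx(-0.4575)
        assert md.posterior_step(0.3, 0.0, 1.0, 0.7) == pytest.approx(0.3)

    def test_choice_probability_reference_and_symmetry(self):
        assert float(md.choice_probability(0.0, 3.0)) == 0.5
        assert float(md.choice_probability(0.25, 4.63)) == pytest.approx(0.7609, abs=1e-4)
        grid = np.linspace(-4, 4, 33)
        np.testing.assert_allclose(
            md.choice_probability(grid, 2.5) + md.choice_probability(-grid, 2.5),
            1.0, atol=1e-12,
        )


class TestForwardPass:
    def test_flat_prior_variants_are_memoryless(self):
        rng = np.random.default_rng(50)
        s = make_series(rng.integers(0, 2, 200), rng.integers(0, 2, 200))
        p4 = params(hazard=0.5, amp_llr=0.0, amp_psi=0.0, freq=0.1, phase=0.0)
        fit4 = md.forward_pass(s, p4, "M4")
        np.testing.assert_allclose(fit4.L, fit4.llr, atol=1e-12)
        fit5 = md.forward_pass(s, p4, "M5")
        np.testing.assert_array_equal(fit4.L, fit5.L)
        np.testing.assert_array_equal(fit4.y_p, fit5.y_p)

    def test_three_trial_hand_worked_example(self):
        # independent oracle in probability space: prior probability via the
        # hazard-rate mixture, posterior odds as prior odds times likelihood
        # odds, rather than the log-space update formula
        alpha, hazard, zeta = 0.5, 0.4, 2.0
        stimuli, choices = [1, 1, 0], [1, 1, 1]
        sigmoid = lambda z: 1 / (1 + math.exp(-z))
        p_state = None
        expected_L, expected_loss = [], 0.0
        for s_t, y_t in zip(stimuli, choices):
            u = sigmoid(alpha * (s_t - 0.5))
            if p_state is None:
                prior = 0.5
            else:
                prior = hazard * (1 - p_state) + (1 - hazard) * p_state
            post_odds = (prior / (1 - prior)) * (u / (1 - u))
            L = math.log(post_odds)
            p_state = post_odds / (1 + post_odds)
            y_p = sigmoid(zeta * L)
            expected_L.append(L)
            expected_loss -= y_t * math.log(y_p) + (1 - y_t) * math.log(1 - y_p)
        series = make_series(stimuli, choices)
        fit = md.forward_pass(
            series, params(alpha=alpha, hazard=hazard, zeta=zeta,
                           amp_llr=0.0, amp_psi=0.0),
        )
        np.testing.assert_allclose(fit.L, expected_L, atol=1e-10)
        assert fit.neg_log_loss == pytest.approx(expected_loss, abs=1e-10)

    def test_fast_loss_path_matches_literal_forward_pass(self):
        rng = np.random.default_rng(51)
        s = make_series(rng.integers(0, 2, 500), rng.integers(0, 2, 500))
        p = params()
        fit = md.forward_pass(s, p)
        fast = md._nll_jit(md.stimulus_signal(s), s.choice.astype(float), *p.as_array())
        assert fast == pytest.approx(fit.neg_log_loss, abs=1e-8)

    def test_variant_constraint_violation_raises(self):
        rng = np.random.default_rng(52)
        s = make_series(rng.integers(0, 2, 60), rng.integers(0, 2, 60))
        with pytest.raises(ValueError, match="M2"):
            md.forward_pass(s, params(amp_psi=1.0), "M2")

    def test_parameters_outside_boxes_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            params(alpha=7.0).validate()


class TestFitting:
    def test_same_seed_gives_identical_fit(self):
        rng = np.random.default_rng(53)
        s = make_series(rng.integers(0, 2, 300), rng.integers(0, 2, 300))
        a = md.fit_subject(s, "M5", seed=3)
        b = md.fit_subject(s, "M5", seed=3)
        assert a.params.as_array().tolist() == b.params.as_array().tolist()
        assert a.neg_log_loss == b.neg_log_loss

    def test_short_series_rejected(self):
        rng = np.random.default_rng(54)
        s = make_series(rng.integers(0, 2, 30), rng.integers(0, 2, 30))
        with pytest.raises(ValueError, match=">= 50"):
            md.fit_subject(s, "M4")

    def test_aic_formula(self):
        rng = np.random.default_rng(55)
        s = make_series(rng.integers(0, 2, 200), rng.integers(0, 2, 200))
        fit = md.fit_subject(s, "M5", seed=1)
        assert fit.aic == pytest.approx(2 * 2 + 2 * fit.neg_log_loss)

    def test_true_parameters_beat_perturbed_in_expectation(self):
        from bimodal_inference.simulate import SimulationConfig, simulate_cohort
        sim = simulate_cohort(SimulationConfig(n_agents=50, seed=56, trials_min=300, trials_max=400))
        truth = params()
        worse = params(alpha=min(truth.alpha + 0.4, 5.0), hazard=0.2)
        diffs = []
        for s in sim.cohort:
            diffs.append(
                md.forward_pass(s, truth).neg_log_loss
                - md.forward_pass(s, worse).neg_log_loss
            )
        assert np.mean(diffs) < 0


class TestComparison:
    def test_aic_arithmetic_prefers_smaller_model_at_equal_loss(self):
        fit_a = md.ModelFit("s", "g", "M1", params(), *(np.zeros(1),) * 7, 100.0, aic=2 * 7 + 200)
        fit_b = md.ModelFit("s", "g", "M4", params(), *(np.zeros(1),) * 7, 100.0, aic=2 * 3 + 200)
        table = md.compare_models({"s": {"M1": fit_a, "M4": fit_b}})
        row = table.set_index("variant")
        assert row.loc["M4", "group_aic"] + 8 == row.loc["M1", "group_aic"]
        assert row.loc["M4", "n_best"] == 1

    def test_missing_fits_drop_subject_with_warning(self):
        fit = md.ModelFit("s1", "g", "M1", params(), *(np.zeros(1),) * 7, 10.0, aic=34.0)
        fits = {"s1": {"M1": fit, "M4": fit}, "s2": {"M1": fit}}
        with pytest.warns(UserWarning, match="s2"):
            table = md.compare_models(fits)
        assert (table["n_subjects"] == 1).all()


class TestCertaintyDiagnostics:
    def test_confidence_equal_to_certainty_recovers_unit_slope(self):
        rng = np.random.default_rng(57)
        stim = rng.integers(0, 2, 400)
        s = make_series(stim, rng.integers(0, 2, 400))
        fit = md.forward_pass(s, params())
        s2 = make_series(stim, s.choice, confidence=np.abs(fit.L))
        out = md.certainty_diagnostics(fit, s2)
        assert out["confidence_on_certainty"]["certainty"] == pytest.approx(1.0, abs=1e-6)

    def test_rt_anticorrelated_with_certainty_gives_negative_slope(self):
        rng = np.random.default_rng(58)
        stim = rng.integers(0, 2, 500)
        s = make_series(stim, rng.integers(0, 2, 500))
        fit = md.forward_pass(s, params())
        rt = np.clip(2.0 - np.abs(fit.L) + rng.normal(0, 0.1, 500), 0.01, None)
        s2 = make_series(stim, s.choice, response_time=rt)
        out = md.certainty_diagnostics(fit, s2)
        assert out["rt_on_certainty"]["certainty"] < 0

    def test_observer_cohort_history_predicted_by_previous_certainty(self):
        # a strong-prior observer repeats confident choices: the slope of
        # history-congruence on the previous trial's posterior certainty is
        # reliably positive (at weak priors the sign is noise-dominated)
        from bimodal_inference.simulate import SimulationConfig, simulate_cohort
        cfg = SimulationConfig(n_agents=15, seed=59)
        cfg.params.hazard = 0.2
        sim = simulate_cohort(cfg)
        fits = [md.forward_pass(s, params(hazard=0.2)) for s in sim.cohort]
        out = md.certainty_diagnostics(fits, list(sim.cohort))
        assert out["history_on_prev_certainty"]["prev_certainty"] > 0
        assert out["history_on_prev_certainty"]["prev_certainty_p"] < 0.05
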