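import numpy as np
import pytest

from bimodal_inference import congruence as cg
from bimodal_inference import seriality as sr
from conftest import make_series


def brute_force_autocorrelation(x, max_lag):
    """Direct double-loop evaluation of the defining sum."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xbar = x.mean()
    denom = sum((x[t] - xbar) ** 2 for t in range(n))
    out = []
    for k in range(max_lag + 1):
        num = sum((x[t] - xbar) * (x[t + k] - xbar) for t in range(n - k))
        out.append(num / denom)
    return np.array(out)


class TestAutocorrelation:
    def test_alternating_binary_series_lag_one(self):
        r = sr.autocorrelation(np.array([1, 0, 1, 0, 1, 0], float), 1)
        assert r[0] == pytest.approx(1.0)
        assert r[1] == pytest.approx(-1.25 / 1.5, abs=1e-12)

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            n = int(rng.integers(8, 31))
            x = rng.normal(size=n) if rng.random() < 0.5 else rng.integers(0, 2, n).astype(float)
            if x.std() == 0:
                continue
            k = int(rng.integers(1, n - 1))
            np.testing.assert_allclose(
                sr.autocorrelation(x, k), brute_force_autocorrelation(x, k), atol=1e-12
            )

    def test_constant_series_is_zero_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            r = sr.autocorrelation(np.full(10, 3.0), 4)
        np.testing.assert_array_equal(r, 0.0)

    def test_missing_entries_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            sr.autocorrelation(np.array([1.0, np.nan, 0.0]), 1)


class TestPermutationNull:
    def test_reproducible_under_fixed_seed(self):
        x = np.random.default_rng(11).integers(0, 2, 60).astype(float)
        a = sr.permutation_null(x, 5, n_perm=20, rng=7)
        b = sr.permutation_null(x, 5, n_perm=20, rng=7)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (20, 6)

    def test_mean_matches_small_sample_bias(self):
        # the sample autocorrelation of exchangeable data has mean ~ -1/(n-1)
        rng = np.random.default_rng(12)
        n = 50
        x = rng.normal(size=n)
        perm = sr.permutation_null(x, 3, n_perm=4000, rng=rng)
        np.testing.assert_allclose(perm[:, 1:].mean(axis=0), -1 / (n - 1), atol=0.01)

    def test_constant_series_all_zero(self):
        perm = sr.permutation_null(np.full(20, 1.0), 3, n_perm=5, rng=0)
        np.testing.assert_array_equal(perm, 0.0)


class TestIndividualLag:
    def make(self, r_true, fracs, n_perm=100):
        # build a permutation matrix whose exceedance fractions are as given
        K = len(r_true) - 1
        perm = np.zeros((n_perm, K + 1))
        for k in range(1, K + 1):
            n_above = int(round(fracs[k - 1] * n_perm))
            perm[:n_above, k] = r_true[k] + 1.0
            perm[n_above:, k] = r_true[k] - 1.0
        return perm

    def test_count_forced_by_construction(self):
        r = np.array([1.0, 0.3, 0.2, -0.5])
        perm = np.zeros((100, 4))
        assert sr.individual_lag(r, perm) == 2

    def test_zero_when_below_null_median_at_first_lag(self):
        r = np.array([1.0, -0.2])
        perm = np.zeros((100, 2))
        assert sr.individual_lag(r, perm) == 0

    def test_stops_at_first_violating_lag(self):
        r = np.array([1.0, 0.1, 0.1, 0.1, 0.1, 0.1])
        perm = self.make(r, [0.1, 0.4, 0.6, 0.2, 0.1])
        assert sr.individual_lag(r, perm) == 2

    def test_invariant_under_common_shift(self):
        rng = np.random.default_rng(13)
        r = np.concatenate([[1.0], rng.normal(0, 0.2, 8)])
        perm = rng.normal(0, 0.2, (100, 9))
        base = sr.individual_lag(r, perm)
        assert sr.individual_lag(r + 5.0, perm + 5.0) == base


class TestGroupTests:
    def _profiles(self, values_by_subject, groups):
        profiles = []
        for i, (vals, g) in enumerate(zip(values_by_subject, groups)):
            vals = np.asarray(vals, float)
            K = vals.size
            profiles.append(
                sr.AutocorrelationProfile(
                    subject_id=f"s{i}", group_id=g, lags=np.arange(1, K + 1),
                    r_true=vals, r_perm=np.zeros((10, K)), r_corrected=vals,
                    individual_lag=0,
                )
            )
        return profiles

    def test_null_profiles_nothing_significant(self):
        rng = np.random.default_rng(14)
        profs = self._profiles(rng.normal(0, 0.05, (30, 4)), ["g"] * 30)
        table = sr.group_autocorrelation_test(profs)
        assert not table["significant"].any()

    def test_common_positive_lag_detected(self):
        rng = np.random.default_rng(15)
        vals = rng.normal(0, 0.02, (25, 3))
        vals[:, 0] = 0.2
        table = sr.group_autocorrelation_test(self._profiles(vals, ["g"] * 25))
        assert bool(table.loc[table.lag == 1, "significant"].iloc[0])
        assert not table.loc[table.lag > 1, "significant"].any()

    def test_covariate_identical_to_outcome_removes_significance(self):
        rng = np.random.default_rng(16)
        vals = 0.3 + rng.normal(0, 0.01, (20, 2))
        profs = self._profiles(vals, ["g"] * 20)
        covs = {"difficulty": profs}
        table = sr.covariate_controlled_group_test(profs, covs)
        assert not table["significant"].any()

    def test_orthogonal_covariate_keeps_uncontrolled_decision(self):
        rng = np.random.default_rng(17)
        vals = 0.2 + rng.normal(0, 0.02, (25, 2))
        cov_vals = rng.normal(0, 0.02, (25, 2))
        profs = self._profiles(vals, ["g"] * 25)
        covs = {"stim_seq": self._profiles(cov_vals, ["g"] * 25)}
        controlled = sr.covariate_controlled_group_test(profs, covs)
        uncontrolled = sr.group_autocorrelation_test(profs)
        np.testing.assert_array_equal(
            controlled["significant"].to_numpy(), uncontrolled["significant"].to_numpy()
        )


class TestLaggedLogistic:
    def test_iid_indicator_coefficients_near_zero(self):
        rng = np.random.default_rng(18)
        inds = [rng.integers(0, 2, 2000).astype(float) for _ in range(5)]
        table = sr.lagged_logistic_regression(inds, 3)
        assert np.abs(table["coef"]).max() < 0.15

    def test_deterministic_repeat_triggers_penalized_fallback(self):
        ind = np.array([0.0] * 50 + [1.0] * 50)
        with pytest.warns(UserWarning, match="ridge"):
            table = sr.lagged_logistic_regression([ind], 1)
        assert table["coef"].iloc[0] > 2.0

    def test_markov_indicator_matches_maximum_likelihood_oracle(self):
        rng = np.random.default_rng(19)
        n = 100_000
        x = np.empty(n)
        x[0] = 1
        stay = rng.random(n) < 0.7
        for t in range(1, n):  # two-state symmetric Markov chain, persistence 0.7
            x[t] = x[t - 1] if stay[t] else 1 - x[t - 1]
        table = sr.lagged_logistic_regression([x], 1)
        # with only lag 1 in the design the log-odds MLE equals the
        # difference of empirical transition logits, 2*log(0.7/0.3) in
        # expectation for the symmetric chain
        p11 = np.mean(x[1:][x[:-1] == 1])
        p01 = np.mean(x[1:][x[:-1] == 0])
        oracle = np.log(p11 / (1 - p11)) - np.log(p01 / (1 - p01))
        assert table["coef"].iloc[0] == pytest.approx(oracle, abs=0.02)
        assert table["coef"].iloc[0] == pytest.approx(2 * np.log(0.7 / 0.3), abs=0.1)


class TestChoiceHistoryGLM:
    def test_stimulus_only_agent_no_history_effect(self):
        from bimodal_inference.trialdata import CohortDataset, BINARY_CATEGORY
        rng = np.random.default_rng(20)
        series = []
        for i in range(5):
            stim = rng.integers(0, 2, 800)
            noisy = np.where(rng.random(800) < 0.85, stim, 1 - stim)
            series.append(make_series(stim, noisy, subject=f"s{i}"))
        res = sr.choice_history_glm(CohortDataset(series, BINARY_CATEGORY))
        assert abs(res["prev_choice"]) < 0.15
        assert abs(res["delta_aic"]) < 4

    def test_pure_repeat_agent_handled_despite_collinearity(self):
        # choices never vary within subject: previous choice and the bias
        # regressor are collinear, triggering the penalized fallback; the
        # history weight still comes out positive
        from bimodal_inference.trialdata import CohortDataset, BINARY_CATEGORY
        rng = np.random.default_rng(21)
        series = []
        for i in range(4):
            stim = rng.integers(0, 2, 300)
            series.append(make_series(stim, np.full(300, i % 2), subject=f"s{i}"))
        with pytest.warns(UserWarning, match="ridge"):
            res = sr.choice_history_glm(CohortDataset(series, BINARY_CATEGORY))
        assert res["prev_choice"] > 1.0

    def test_near_deterministic_repeater_strong_history(self):
        from bimodal_inference.trialdata import CohortDataset, BINARY_CATEGORY
        rng = np.random.default_rng(25)
        series = []
        for i in range(4):
            stim = rng.integers(0, 2, 400)
            choice = np.empty(400, dtype=int)
            choice[0] = rng.integers(0, 2)
            for t in range(1, 400):  # repeat previous choice 95% of the time
                choice[t] = choice[t - 1] if rng.random() < 0.95 else 1 - choice[t - 1]
            series.append(make_series(stim, choice, subject=f"s{i}"))
        res = sr.choice_history_glm(CohortDataset(series, BINARY_CATEGORY))
        assert res["prev_choice"] > 2.0
        assert res["delta_aic"] > 100

    def test_observer_model_cohort_shows_history_contribution(self):
        # strong-prior observer cohort: perceptual history must be detected
        from bimodal_inference.simulate import (
            POSTERIOR_MEANS_HUMAN, SimulationConfig, simulate_cohort,
        )
        from dataclasses import replace
        cfg = SimulationConfig(
            n_agents=15, seed=24,
            params=replace(POSTERIOR_MEANS_HUMAN, hazard=0.2),
        )
        res = sr.choice_history_glm(simulate_cohort(cfg).cohort)
        assert res["prev_choice"] > 0
        assert res["prev_choice_p"] < 0.05
        assert res["delta_aic"] > 0


class TestBiasCorrectionProperty:
    def test_global_bias_does_not_induce_corrected_autocorrelation(self):
        # reduced-scale version of the falsification suite: biased coin
        # flippers show raw hist-congruence autocorrelation, which the
        # permutation correction removes
        from bimodal_inference.simulate import null_agents
        sim = null_agents("global_bias", n_agents=150, n_trials=100, seed=22, q=0.75)
        corrected = []
        root = np.random.SeedSequence(23)
        for s, ss in zip(sim.cohort, root.spawn(150)):
            prof = sr.AutocorrelationProfile.from_choice_history(
                s.choice, 10, rng=np.random.default_rng(ss)
            )
            corrected.append(prof.r_corrected)
        corrected = np.array(corrected)
        mean = corrected.mean(axis=0)
        se = corrected.std(axis=0, ddof=1) / np.sqrt(corrected.shape[0])
        assert np.all(np.abs(mean) < 3.5 * se)
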