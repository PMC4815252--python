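"""Cohort generator: transforms, confounding mechanism, determinism."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats
from scipy.special import ndtri

import rareps
from rareps import (
    MarginalCoxModel,
    ScenarioError,
    SimulationScenario,
    apply_censoring,
    assign_exposure,
    draw_covariates,
    generate_cohort,
    generate_event_times,
    reference_scenario,
)
from rareps.generate import Cohort, exposure_probability


def _independent_scenario(**kw):
    return SimulationScenario(sigma_ub=0, sigma_uc=0, sigma_bc=0, **kw)


class TestCovariateTransforms:
    def test_independent_sigma_gives_uncorrelated_b_and_u(self, rng):
        cohort = draw_covariates(_independent_scenario(), 100_000, rng)
        corr = np.corrcoef(cohort.b, ndtri(cohort.u))[0, 1]
        assert abs(corr) < 0.01

    def test_conditional_mean_of_latent_given_b(self, rng):
        # E[X_U | X_B > 0] = sigma_ub * E[X_B | X_B > 0] = 0.5 * sqrt(2/pi)
        sc = SimulationScenario(sigma_ub=0.5, sigma_uc=0, sigma_bc=0)
        cohort = draw_covariates(sc, 100_000, rng)
        expected = 0.5 * math.sqrt(2 / math.pi)
        assert ndtri(cohort.u)[cohort.b == 1].mean() == pytest.approx(expected, abs=0.01)

    def test_u_uniform_for_any_valid_covariance(self, rng):
        for sc in (reference_scenario(), SimulationScenario(sigma_ub=0.5, sigma_uc=0.5)):
            cohort = draw_covariates(sc, 10_000, rng)
            stat = stats.kstest(cohort.u, "uniform").statistic
            # 1% critical value of the one-sample KS statistic
            assert stat < 1.63 / math.sqrt(10_000)

    def test_marginal_moments(self, ref_cohort):
        assert ref_cohort.b.mean() == pytest.approx(0.5, abs=0.02)
        assert ref_cohort.c.var() == pytest.approx(1.0, abs=0.05)

    def test_four_confounders_present(self, rng):
        sc = SimulationScenario(n_confounders=4)
        cohort = draw_covariates(sc, 1000, rng)
        assert cohort.b2 is not None and cohort.c2 is not None
        assert cohort.confounders().shape == (1000, 4)
        assert cohort.confounder_names == ("B", "C", "B2", "C2")


class TestExposure:
    def test_null_model_gives_exactly_half(self, rng):
        sc = _independent_scenario(delta_b=0.0, delta_c=0.0).replace(delta0=0.0)
        cohort = draw_covariates(sc, 1000, rng)
        np.testing.assert_array_equal(exposure_probability(cohort), 0.5)

    def test_reference_prevalence(self, ref_cohort):
        assert ref_cohort.e.mean() == pytest.approx(0.05, abs=0.005)

    def test_generating_odds_ratio_is_exact(self, rng):
        sc = _independent_scenario(delta_b=math.log(2), delta_c=0.3).replace(delta0=-2.0)
        cohort = draw_covariates(sc, 10, rng)
        cohort.b = np.array([1, 0] * 5)
        cohort.c = np.zeros(10)
        p = exposure_probability(cohort)
        odds = p / (1 - p)
        assert odds[0] / odds[1] == pytest.approx(2.0, rel=1e-12)

    def test_requires_calibrated_delta0(self, rng):
        cohort = draw_covariates(reference_scenario(), 100, rng)
        with pytest.raises(ScenarioError, match="delta0"):
            assign_exposure(cohort, rng)


class TestEventTimes:
    def test_closed_form_value(self):
        sc = reference_scenario(gamma=0.0).replace(delta0=0.0)
        cohort = Cohort(
            scenario=sc,
            b=np.zeros(1), c=np.zeros(1), u=np.array([math.exp(-1.0)]),
            e=np.zeros(1, dtype=np.int64),
        )
        generate_event_times(cohort)
        assert cohort.t_event[0] == pytest.approx(10.0, rel=1e-12)

    def test_null_effect_marginal_exponential_mean(self, rng):
        sc = reference_scenario(gamma=0.0).replace(delta0=-3.0)
        cohort = draw_covariates(sc, 100_000, rng)
        assign_exposure(cohort, rng)
        generate_event_times(cohort)
        assert cohort.t_event.mean() == pytest.approx(10.0, abs=0.1)

    def test_exposed_rate_doubles_under_log2_effect(self, rng):
        sc = _independent_scenario(gamma=math.log(2), delta_b=0.0, delta_c=0.0).replace(
            delta0=0.0
        )
        cohort = draw_covariates(sc, 100_000, rng)
        assign_exposure(cohort, rng)
        generate_event_times(cohort)
        assert cohort.t_event[cohort.e == 1].mean() == pytest.approx(5.0, abs=0.1)


class TestCensoring:
    def test_infinite_bound_means_no_censoring(self, rng):
        sc = reference_scenario(censoring_rate_target=0.0).replace(
            delta0=-3.0, censor_bound=math.inf
        )
        cohort = generate_cohort(sc, seed=3)
        assert np.all(cohort.y == 1)
        np.testing.assert_array_equal(cohort.t_obs, cohort.t_event)

    def test_decision_rule(self):
        sc = reference_scenario().replace(delta0=0.0, censor_bound=5.0)
        cohort = Cohort(
            scenario=sc, b=np.zeros(2), c=np.zeros(2), u=np.full(2, 0.5),
            e=np.zeros(2, dtype=np.int64),
            t_event=np.array([3.0, 1.0]),
        )
        cohort.t_censor = np.array([2.0, 1.0])  # second is an exact tie
        cohort.y = (cohort.t_event <= cohort.t_censor).astype(np.int64)
        cohort.t_obs = np.where(cohort.y == 1, cohort.t_event, cohort.t_censor)
        assert cohort.y.tolist() == [0, 1]  # tie counts as an event
        assert cohort.t_obs.tolist() == [2.0, 1.0]

    def test_reference_censoring_fraction(self, ref_cohort):
        assert 1 - ref_cohort.y.mean() == pytest.approx(0.50, abs=0.01)


class TestGeneratorInvariants:
    @pytest.mark.parametrize("gamma", [0.0, math.log(1.5), math.log(2.0)])
    def test_marginal_hr_fidelity_without_confounding(self, gamma):
        """Unconfounded, uncensored: crude Cox recovers the designed gamma."""
        sc = _independent_scenario(
            gamma=gamma, censoring_rate_target=0.0, n_cohort=100_000
        ).replace(censor_bound=math.inf)
        sc = sc.replace(delta0=rareps.calibrate_delta0(sc, calib_n=100_000, calib_reps=2))
        cohort = generate_cohort(sc, seed=17)
        res = MarginalCoxModel(cohort.t_obs, cohort.y, cohort.e).fit()
        assert res.converged
        assert abs(res.gamma_hat - gamma) < 3 * res.se_model

    def test_confounding_biases_crude_estimate_upward(self, ref_scenario):
        """Under the reference configuration with a null effect the crude Cox
        estimate is pulled away from zero: exposure selects good-health
        subjects, whose events arrive sooner under this parameterisation."""
        big = ref_scenario.replace(n_cohort=100_000)
        cohort = generate_cohort(big, seed=23)
        res = MarginalCoxModel(cohort.t_obs, cohort.y, cohort.e).fit()
        assert res.gamma_hat > 3 * res.se_model

    def test_conditional_exchangeability(self, rng):
        """E is independent of U given (B, C): the latent term adds nothing
        to the exposure model."""
        sc = reference_scenario()
        sc = sc.replace(delta0=rareps.calibrate_delta0(sc))
        cohort = draw_covariates(sc, 200_000, rng)
        assign_exposure(cohort, rng)
        x = sm.add_constant(
            np.column_stack([ndtri(cohort.u), cohort.b, cohort.c])
        )
        fit = sm.Logit(cohort.e, x).fit(disp=0)
        assert abs(fit.params[1]) < 3 * fit.bse[1]

    def test_bit_identical_under_fixed_seed(self, ref_scenario):
        a = generate_cohort(ref_scenario, seed=42)
        b = generate_cohort(ref_scenario, seed=42)
        for attr in ("b", "c", "u", "e", "t_event", "t_censor", "t_obs", "y"):
            np.testing.assert_array_equal(getattr(a, attr), getattr(b, attr))
        c = generate_cohort(ref_scenario, seed=43)
        assert not np.array_equal(a.u, c.u)

    def test_dataframe_export_hides_latents_by_default(self, ref_cohort):
        df = ref_cohort.to_dataframe()
        assert list(df.columns) == ["id", "B", "C", "E", "t_obs", "Y"]
        dbg = ref_cohort.to_dataframe(debug=True)
        assert {"U", "T", "T_c"} <= set(dbg.columns)
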