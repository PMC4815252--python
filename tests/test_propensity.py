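"""Propensity fitting, weights and greedy caliper matching."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit, logit

import rareps
from rareps import (
    EstimationError,
    PropensityModel,
    compute_weights,
    greedy_caliper_match,
    reference_scenario,
)
from rareps.propensity import PS_FLOOR, PropensityFit


def _fit_from_ps(ps: np.ndarray) -> PropensityFit:
    """A converged PropensityFit with prescribed scores (for matching tests)."""
    ps = np.clip(np.asarray(ps, dtype=float), PS_FLOOR, 1 - PS_FLOOR)
    return PropensityFit(np.zeros(1), ("const",), ps, True, False, ps.size)


class TestPropensityModel:
    def test_independent_covariates_yield_flat_scores(self, rng):
        n = 50_000
        x = rng.standard_normal((n, 2))
        e = (rng.random(n) < 0.2).astype(int)
        fit = PropensityModel(e, x).fit()
        assert fit.converged
        assert np.abs(fit.params[1:]).max() < 0.05
        assert fit.ps.mean() == pytest.approx(0.2, abs=0.01)

    def test_recovers_generating_coefficients(self, rng):
        sc = reference_scenario()
        sc = sc.replace(delta0=rareps.calibrate_delta0(sc))
        cohort = rareps.draw_covariates(sc, 100_000, rng)
        rareps.assign_exposure(cohort, rng)
        fit = PropensityModel(cohort.e, cohort.confounders()).fit()
        assert fit.converged and not fit.separation_flag
        assert fit.params[0] == pytest.approx(sc.delta0, abs=0.1)
        assert fit.params[1] == pytest.approx(sc.delta_b, abs=0.1)
        assert fit.params[2] == pytest.approx(sc.delta_c, abs=0.1)

    def test_perfect_separation_flagged(self):
        b = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        e = b.astype(int)  # exposure perfectly predicted by B
        fit = PropensityModel(e, b[:, None]).fit()
        assert fit.separation_flag
        assert not fit.converged

    def test_single_group_is_an_error(self):
        with pytest.raises(EstimationError):
            PropensityModel(np.ones(5, dtype=int), np.zeros((5, 1))).fit()


class TestWeights:
    def test_att_weight_formulas(self):
        fit = _fit_from_ps([0.05, 0.30, 0.50])
        e = np.array([0, 1, 0])
        ws = compute_weights(fit, e, "ATT")
        assert ws.weights[1] == 1.0  # exposed: exactly one
        assert ws.weights[0] == pytest.approx(0.05 / 0.95)
        assert ws.weights[2] == pytest.approx(1.0)

    def test_stabilized_ate_weight_formulas(self):
        fit = _fit_from_ps([0.25, 0.25])
        e = np.array([1, 0])
        ws = compute_weights(fit, e, "ATE")
        assert ws.pbar == 0.5
        assert ws.weights[0] == pytest.approx(0.5 / 0.25)
        assert ws.weights[1] == pytest.approx(0.5 / 0.75)

    def test_stabilized_ate_group_means_near_one(self, rng):
        """Correctly specified fit: stabilized weights average ~1 per group."""
        sc = reference_scenario()
        sc = sc.replace(delta0=rareps.calibrate_delta0(sc))
        cohort = rareps.draw_covariates(sc, 50_000, rng)
        rareps.assign_exposure(cohort, rng)
        fit = PropensityModel(cohort.e, cohort.confounders()).fit()
        ws = compute_weights(fit, cohort.e, "ATE")
        assert ws.weights[cohort.e == 1].mean() == pytest.approx(1.0, abs=0.05)
        assert ws.weights[cohort.e == 0].mean() == pytest.approx(1.0, abs=0.01)

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            compute_weights(_fit_from_ps([0.5]), np.array([1]), "ATO")

    @given(
        ps=st.lists(st.floats(0.01, 0.99), min_size=2, max_size=30),
        bits=st.integers(1, 2**29),
    )
    def test_weight_identities(self, ps, bits):
        ps = np.asarray(ps)
        e = np.array([(bits >> i) & 1 for i in range(ps.size)])
        if e.min() == e.max():
            e[0] = 1 - e[0]
        fit = _fit_from_ps(ps)
        att = compute_weights(fit, e, "ATT").weights
        ate = compute_weights(fit, e, "ATE").weights
        pbar = e.mean()
        assert np.all(att[e == 1] == 1.0)
        np.testing.assert_allclose(att[e == 0], (fit.ps / (1 - fit.ps))[e == 0])
        # stabilized ATE = (pbar or 1-pbar) times the unstabilized weight
        unstab = np.where(e == 1, 1 / fit.ps, 1 / (1 - fit.ps))
        np.testing.assert_allclose(ate, np.where(e == 1, pbar, 1 - pbar) * unstab)
        assert np.all(np.isfinite(att)) and np.all(np.isfinite(ate))


class TestMatching:
    def test_nearest_within_caliper(self, rng):
        # logits: exposed {0.0}; unexposed {0.05, 1.0}; caliper 0.1
        lps = np.array([0.0, 0.05, 1.0])
        fit = _fit_from_ps(expit(lps))
        e = np.array([1, 0, 0])
        sd = np.std(lps, ddof=1)
        m = greedy_caliper_match(fit, e, rng, caliper_sd_multiplier=0.1 / sd)
        assert m.pairs.tolist() == [[0, 1]]
        assert m.pct_matched == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_contested_single_control(self, seed):
        # both processing orders leave exactly one matched pair
        lps = np.array([0.0, 0.04, 0.02])
        fit = _fit_from_ps(expit(lps))
        e = np.array([1, 1, 0])
        m = greedy_caliper_match(
            fit, e, np.random.default_rng(seed), caliper_sd_multiplier=2.0
        )
        assert m.pairs.shape[0] == 1
        assert m.pct_matched == 0.5

    def test_equidistant_tie_goes_to_lowest_index(self, rng):
        lps = np.array([0.0, -0.1, 0.1])
        fit = _fit_from_ps(expit(lps))
        e = np.array([1, 0, 0])
        m = greedy_caliper_match(fit, e, rng, caliper_sd_multiplier=2.0)
        assert m.pairs.tolist() == [[0, 1]]

    def test_zero_sd_zero_caliper_still_pairs_at_distance_zero(self, rng):
        fit = _fit_from_ps(np.full(4, 0.3))
        e = np.array([1, 0, 1, 0])
        m = greedy_caliper_match(fit, e, rng)
        assert m.caliper_width == 0.0
        assert m.pairs.shape[0] == 2

    def test_constraints_on_generated_samples(self, ref_scenario):
        """Injectivity and the caliper bound hold pair-by-pair."""
        for rep in range(5):
            cohort = rareps.generate_cohort(ref_scenario, seed=300 + rep)
            sample = rareps.select_by_exposed_events(cohort, 20)
            fit = PropensityModel(sample.exposure, sample.confounders()).fit()
            m = greedy_caliper_match(fit, sample.exposure, np.random.default_rng(rep))
            used_controls = m.pairs[:, 1]
            assert len(set(used_controls)) == len(used_controls)
            lps = logit(fit.ps)
            dist = np.abs(lps[m.pairs[:, 0]] - lps[m.pairs[:, 1]])
            assert np.all(dist <= m.caliper_width)
            assert np.all(sample.exposure[m.pairs[:, 0]] == 1)
            assert np.all(sample.exposure[m.pairs[:, 1]] == 0)

    def test_caliper_uses_pooled_logit_sd(self, rng):
        lps = np.array([0.0, 0.5, -0.5, 1.5])
        fit = _fit_from_ps(expit(lps))
        e = np.array([1, 0, 0, 1])
        m = greedy_caliper_match(fit, e, rng)
        assert m.caliper_width == pytest.approx(0.2 * np.std(lps, ddof=1))

    def test_matching_order_is_seed_reproducible(self, ref_scenario):
        cohort = rareps.generate_cohort(ref_scenario, seed=55)
        sample = rareps.select_by_exposed_events(cohort, 20)
        fit = PropensityModel(sample.exposure, sample.confounders()).fit()
        m1 = greedy_caliper_match(fit, sample.exposure, np.random.default_rng(9))
        m2 = greedy_caliper_match(fit, sample.exposure, np.random.default_rng(9))
        np.testing.assert_array_equal(m1.pairs, m2.pairs)
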