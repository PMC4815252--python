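"""Theoretical ATT hazard ratio by potential-outcomes simulation.

The generator fixes the *marginal ATE* log hazard ratio at gamma, but the
treated sub-population differs from the whole population (its latent health
distribution is tilted through the confounders), and hazard ratios are
non-collapsible — so the average treatment effect in the treated (ATT) is a
different number that must be obtained by simulation:

per replicate, simulate a cohort's covariates, latent U and realized
exposure; give every subject *both* potential uncensored event times
T(0) = -log(U)/lambda and T(1) = -log(U)/(lambda exp(gamma)) from the shared
U; keep only subjects with realized exposure; stack each kept subject twice
(once per potential outcome, labelled by the potential treatment) and fit an
unweighted Cox model of potential time on the label.  The log HR is averaged
over replicates on the log scale.

Under a null effect the two potential times coincide subject-by-subject, so
the ATT is exactly 0 and is short-circuited without simulation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cox import MarginalCoxModel
from .exceptions import EstimationError, ScenarioError
from .generate import assign_exposure, draw_covariates
from .scenarios import SimulationScenario

__all__ = ["TheoreticalEffect", "theoretical_att"]

_ORACLE_TAG = 303


@dataclasses.dataclass
class TheoreticalEffect:
    """Reference effects for a scenario: the designed ATE and the simulated ATT."""

    att_log_hr: float
    ate_log_hr: float
    n_per_rep: int
    reps: int
    monte_carlo_se: float

    @property
    def att_hazard_ratio(self) -> float:
        return float(np.exp(self.att_log_hr))

    @property
    def ate_hazard_ratio(self) -> float:
        return float(np.exp(self.ate_log_hr))


def theoretical_att(
    scenario: SimulationScenario,
    n_per_rep: int = 100_000,
    reps: int = 20,
    seed: int | None = None,
) -> TheoreticalEffect:
    """Potential-outcomes ATT log hazard ratio for a calibrated scenario.

    Censoring never enters: potential event times are uncensored by design,
    so the result is invariant to the scenario's censoring parameters.  The
    two stacked rows of a subject are treated as independent in the fit; only
    the point estimate is used, so the variance model is irrelevant.
    """
    if scenario.gamma == 0.0:
        return TheoreticalEffect(0.0, 0.0, n_per_rep, 0, 0.0)
    if scenario.delta0 is None:
        raise ScenarioError("delta0 must be calibrated before the ATT oracle")
    root = scenario.seed if seed is None else seed
    lam = scenario.baseline_hazard
    draws = np.empty(reps)
    for rep in range(reps):
        ss = np.random.SeedSequence([root, _ORACLE_TAG, rep])
        cov_ss, exp_ss = ss.spawn(2)
        cohort = draw_covariates(scenario, n_per_rep, np.random.default_rng(cov_ss))
        assign_exposure(cohort, np.random.default_rng(exp_ss))
        u = np.clip(cohort.u, 1e-300, np.nextafter(1.0, 0.0))
        treated = cohort.e == 1
        t0 = -np.log(u[treated]) / lam
        t1 = t0 * np.exp(-scenario.gamma)
        k = t0.shape[0]
        time = np.concatenate([t0, t1])
        label = np.concatenate([np.zeros(k, dtype=np.int64), np.ones(k, dtype=np.int64)])
        res = MarginalCoxModel(time, np.ones(2 * k, dtype=np.int64), label).fit()
        if not res.converged:
            raise EstimationError(f"oracle Cox fit failed: {res.fail_reason}")
        draws[rep] = res.gamma_hat
    mc_se = float(np.std(draws, ddof=1) / np.sqrt(reps)) if reps > 1 else float("nan")
    return TheoreticalEffect(
        att_log_hr=float(np.mean(draws)),
        ate_log_hr=scenario.gamma,
        n_per_rep=n_per_rep,
        reps=reps,
        monte_carlo_se=mc_se,
    )
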