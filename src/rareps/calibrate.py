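"""Calibration of the two scenario constants that hit the targets.

``delta0`` (exposure-model intercept) is chosen so the population mean of the
per-subject exposure probability equals the target prevalence p; because that
mean is strictly increasing in delta0, a bracketed scalar root search on a
large fixed covariate draw finds it directly (averaged over a few independent
draws for extra precision).  With no covariate effects the answer is exactly
logit(p) and is returned analytically.

``censor_bound`` (upper bound c of the Uniform(0, c) censoring time) is chosen
so the cohort censoring rate equals the target r_c.  Event times depend on
exposure through the full generative chain, so T is simulated from the chain;
the uniform censoring draw is then integrated out exactly —
P(censored | T) = min(T/c, 1) — leaving a smooth, strictly decreasing function
of c for the root search.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .exceptions import CalibrationError
from .generate import assign_exposure, draw_covariates, generate_event_times
from .scenarios import SimulationScenario

__all__ = ["calibrate_delta0", "calibrate_censor_bound", "calibrate_scenario"]

# stream tags keeping the two calibrations' randomness separate from each
# other and from cohort generation
_DELTA0_TAG = 101
_CENSOR_TAG = 202

_DELTA0_LO, _DELTA0_HI = -30.0, 10.0


def calibrate_delta0(
    scenario: SimulationScenario,
    calib_n: int = 200_000,
    calib_reps: int = 5,
    seed: int | None = None,
) -> float:
    """Intercept delta0 inducing the target exposure prevalence.

    Deterministic given ``seed`` (defaults to ``scenario.seed``).  Raises
    :class:`CalibrationError` if the root is not bracketed in [-30, 10].
    """
    p = scenario.prevalence_target
    if scenario.delta_b == 0.0 and scenario.delta_c == 0.0:
        # covariates drop out of the mean: logit^-1(delta0) = p exactly
        return float(logit(p))
    values = []
    for rep in range(calib_reps):
        rng = np.random.default_rng(
            np.random.SeedSequence([scenario.seed if seed is None else seed, _DELTA0_TAG, rep])
        )
        cohort = draw_covariates(scenario, calib_n, rng)
        lp = scenario.delta_b * cohort.b + scenario.delta_c * cohort.c
        if cohort.b2 is not None:
            lp = lp + scenario.delta_b * cohort.b2 + scenario.delta_c * cohort.c2

        def objective(d0: float) -> float:
            return float(np.mean(expit(d0 + lp))) - p

        if objective(_DELTA0_LO) > 0 or objective(_DELTA0_HI) < 0:
            raise CalibrationError(
                f"prevalence {p} not bracketed by delta0 in [{_DELTA0_LO}, {_DELTA0_HI}]"
            )
        values.append(brentq(objective, _DELTA0_LO, _DELTA0_HI, xtol=1e-12))
    return float(np.mean(values))


def calibrate_censor_bound(
    scenario: SimulationScenario,
    calib_n: int = 200_000,
    seed: int | None = None,
) -> float:
    """Uniform censoring bound c inducing the target censoring rate.

    Requires ``delta0`` to be calibrated already (event times depend on
    exposure).  Returns ``inf`` for a zero censoring target (no censoring).
    Deterministic given ``seed``.
    """
    r_c = scenario.censoring_rate_target
    if r_c == 0.0:
        return math.inf
    if scenario.delta0 is None:
        raise CalibrationError("delta0 must be calibrated before the censoring bound")
    base = np.random.SeedSequence([scenario.seed if seed is None else seed, _CENSOR_TAG])
    cov_ss, exp_ss = base.spawn(2)
    cohort = draw_covariates(scenario, calib_n, np.random.default_rng(cov_ss))
    assign_exposure(cohort, np.random.default_rng(exp_ss))
    generate_event_times(cohort)
    t = cohort.t_event

    def objective(c: float) -> float:
        # P(T > T_c) with T_c ~ U(0, c), integrated exactly given the T draw
        return float(np.mean(np.minimum(t / c, 1.0))) - r_c

    lo, hi = 1e-8, 1.0
    while objective(hi) > 0:
        hi *= 10.0
        if hi > 1e12:
            raise CalibrationError(
                f"censoring bound exceeding 1e12 needed for target rate {r_c}"
            )
    return float(brentq(objective, lo, hi, rtol=1e-12))


def calibrate_scenario(
    scenario: SimulationScenario,
    calib_n: int = 200_000,
    calib_reps: int = 5,
    seed: int | None = None,
) -> SimulationScenario:
    """Return a copy of the scenario with both calibrated constants filled in."""
    d0 = calibrate_delta0(scenario, calib_n=calib_n, calib_reps=calib_reps, seed=seed)
    with_d0 = scenario.replace(delta0=d0)
    c = calibrate_censor_bound(with_d0, calib_n=calib_n, seed=seed)
    return with_d0.replace(censor_bound=c)
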