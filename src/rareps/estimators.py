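"""One-call marginal hazard-ratio estimation on an analysis sample.

Three methods are dispatched over the same propensity fit:

* ``PSW-ATE``  — stabilized ATE weights, weighted Cox, robust SE;
* ``PSW-ATT``  — ATT weights, weighted Cox, robust SE;
* ``PS-matching`` — greedy 1:1 caliper matching on the logit PS, unweighted
  Cox on the matched subjects, pair-clustered robust SE.

Every failure mode (single exposure group, propensity separation or
non-convergence, monotone Cox likelihood, no matches) is folded into an
:class:`EffectEstimate` with ``converged=False`` and a reason, never an
exception, so Monte Carlo replicate loops can count failures honestly.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .cox import MarginalCoxModel
from .exceptions import EstimationError
from .propensity import PropensityModel, compute_weights, greedy_caliper_match
from .selection import AnalysisSample

__all__ = ["METHODS", "EffectEstimate", "estimate_effect", "estimate_from_dataframe"]

METHODS = ("PSW-ATE", "PSW-ATT", "PS-matching")

_NAN = float("nan")


@dataclasses.dataclass
class EffectEstimate:
    """Marginal log-hazard-ratio estimate for one sample and one method."""

    method: str
    gamma_hat: float
    se_robust: float
    ci95: tuple[float, float]
    converged: bool
    n_sample: int
    n_used: int
    pct_matched: float = _NAN
    fail_reason: str = ""

    @property
    def hazard_ratio(self) -> float:
        return math.exp(self.gamma_hat)


def _failed(method: str, n_sample: int, reason: str) -> EffectEstimate:
    return EffectEstimate(
        method, _NAN, _NAN, (_NAN, _NAN), False, n_sample, 0, fail_reason=reason
    )


def estimate_with_fit(
    ps_fit,
    time: np.ndarray,
    event: np.ndarray,
    exposure: np.ndarray,
    method: str,
    rng: np.random.Generator | None = None,
) -> EffectEstimate:
    """Apply one method given an already-fitted propensity model.

    Lets a replicate loop share a single propensity fit across the three
    methods on the same sample.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    n = len(time)
    if not ps_fit.converged:
        reason = "propensity separation" if ps_fit.separation_flag else "propensity nonconvergence"
        return _failed(method, n, reason)

    if method in ("PSW-ATE", "PSW-ATT"):
        ws = compute_weights(ps_fit, exposure, method.removeprefix("PSW-"))
        res = MarginalCoxModel(time, event, exposure, weights=ws.weights).fit()
        pct = _NAN
        n_used = n
    else:
        matched = greedy_caliper_match(
            ps_fit, exposure, rng if rng is not None else np.random.default_rng(0)
        )
        pct = matched.pct_matched
        if matched.pairs.shape[0] == 0:
            return _failed(method, n, "no pairs within caliper")
        keep = matched.pair_id >= 0
        res = MarginalCoxModel(
            time[keep], event[keep], exposure[keep], clusters=matched.pair_id[keep]
        ).fit()
        n_used = int(keep.sum())
    if not res.converged:
        est = _failed(method, n, res.fail_reason or "cox nonconvergence")
        est.pct_matched = pct
        return est
    return EffectEstimate(
        method=method,
        gamma_hat=res.gamma_hat,
        se_robust=res.se_robust,
        ci95=res.ci95,
        converged=True,
        n_sample=n,
        n_used=n_used,
        pct_matched=pct,
    )


def estimate_effect(
    time: np.ndarray,
    event: np.ndarray,
    exposure: np.ndarray,
    confounders: np.ndarray,
    method: str,
    rng: np.random.Generator | None = None,
    confounder_names: tuple[str, ...] | None = None,
) -> EffectEstimate:
    """Fit the propensity model and the chosen estimator on raw arrays.

    ``rng`` drives the random processing order of greedy matching (ignored by
    the weighting methods); omit it only for one-off interactive use.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    try:
        ps_fit = PropensityModel(exposure, confounders, names=confounder_names).fit()
    except EstimationError as exc:
        return _failed(method, len(time), str(exc))
    return estimate_with_fit(ps_fit, time, event, exposure, method, rng=rng)


def estimate_on_sample(
    sample: AnalysisSample, method: str, rng: np.random.Generator | None = None
) -> EffectEstimate:
    """Convenience dispatch for an :class:`AnalysisSample`."""
    return estimate_effect(
        sample.time,
        sample.event,
        sample.exposure,
        sample.confounders(),
        method,
        rng=rng,
        confounder_names=sample.confounder_names,
    )


def estimate_from_dataframe(
    df: pd.DataFrame,
    method: str,
    confounders: tuple[str, ...] = ("B", "C"),
    duration_col: str = "t_obs",
    event_col: str = "Y",
    exposure_col: str = "E",
    rng: np.random.Generator | None = None,
) -> EffectEstimate:
    """Estimate from any cohort-shaped table (usable on real CSV data)."""
    return estimate_effect(
        df[duration_col].to_numpy(dtype=float),
        df[event_col].to_numpy(),
        df[exposure_col].to_numpy(),
        df[list(confounders)].to_numpy(dtype=float),
        method,
        rng=rng,
        confounder_names=tuple(confounders),
    )
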