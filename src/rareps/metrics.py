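"""Monte Carlo performance criteria and covariate-balance diagnostics.

For a cell (scenario, method, y) with replicate estimates gamma_hat_i of a
reference log hazard ratio gamma_ref:

* bias              = mean(gamma_hat) - gamma_ref
* RMSE              = sqrt(mean((gamma_hat - gamma_ref)^2))
* variability ratio = mean(estimated SE) / SD(gamma_hat)  (SD with the
  1/(R-1) divisor); above 1 the SEs overstate the true variability
* 1 - coverage      = fraction of replicates whose 95% Wald CI excludes
  gamma_ref

The reference is the designed marginal ATE (gamma) for PSW-ATE and the
simulated theoretical ATT for PSW-ATT and PS-matching.  Only converged
replicates enter the four criteria; the convergence count is always reported
alongside.  Every metric carries a Monte Carlo standard error so reduced-
replication runs can be compared honestly with large-replication results.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .estimators import EffectEstimate

__all__ = ["PerformanceSummary", "summarize", "absolute_standardized_difference"]

_NAN = float("nan")


@dataclasses.dataclass
class PerformanceSummary:
    """Aggregated criteria for one (scenario, method, y) cell."""

    scenario_name: str
    method: str
    y_target: int | None
    reps_total: int
    reps_converged: int
    reps_excluded: int
    reference_log_hr: float
    bias: float = _NAN
    rmse: float = _NAN
    variability_ratio: float = _NAN
    one_minus_coverage: float = _NAN
    mean_n: float = _NAN
    mean_pct_matched: float = _NAN
    bias_mc_se: float = _NAN
    rmse_mc_se: float = _NAN
    coverage_mc_se: float = _NAN
    available: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize(
    estimates: list[EffectEstimate],
    reference_log_hr: float,
    scenario_name: str = "",
    method: str = "",
    y_target: int | None = None,
    reps_excluded: int = 0,
) -> PerformanceSummary:
    """Aggregate per-replicate estimates into the four performance criteria.

    ``reps_excluded`` counts replicates whose cohort could not supply the
    requested number of exposed events (never analysed).  Fewer than 2
    converged replicates yields a summary marked unavailable.
    """
    reps_total = len(estimates)
    conv = [est for est in estimates if est.converged]
    n_samples = np.array([est.n_sample for est in estimates if est.n_sample > 0], dtype=float)
    mean_n = float(n_samples.mean()) if n_samples.size else _NAN
    base = PerformanceSummary(
        scenario_name=scenario_name,
        method=method,
        y_target=y_target,
        reps_total=reps_total,
        reps_converged=len(conv),
        reps_excluded=reps_excluded,
        reference_log_hr=reference_log_hr,
        mean_n=mean_n,
    )
    if len(conv) < 2:
        base.available = False
        return base
    r = len(conv)
    g = np.array([est.gamma_hat for est in conv])
    se = np.array([est.se_robust for est in conv])
    dev = g - reference_log_hr
    sq = dev**2
    rmse = float(np.sqrt(sq.mean()))
    emp_sd = float(np.std(g, ddof=1))
    lo = g - 1.96 * se
    hi = g + 1.96 * se
    miss = float(np.mean((reference_log_hr < lo) | (reference_log_hr > hi)))
    pct = np.array([est.pct_matched for est in conv])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pct for weighting
        mean_pct = float(np.nanmean(pct))
    base.bias = float(dev.mean())
    base.rmse = rmse
    base.variability_ratio = float(se.mean() / emp_sd) if emp_sd > 0 else _NAN
    base.one_minus_coverage = miss
    base.mean_pct_matched = mean_pct
    base.bias_mc_se = emp_sd / np.sqrt(r)
    base.rmse_mc_se = (
        float(np.std(sq, ddof=1) / (2.0 * rmse * np.sqrt(r))) if rmse > 0 else 0.0
    )
    base.coverage_mc_se = float(np.sqrt(miss * (1.0 - miss) / r))
    return base


def _group_stats(x: np.ndarray, w: np.ndarray):
    sw = w.sum()
    mean = float(np.sum(w * x) / sw)
    var = float(np.sum(w * (x - mean) ** 2) / sw)
    return mean, var


def absolute_standardized_difference(
    covariate: np.ndarray,
    exposure: np.ndarray,
    weights: np.ndarray | None = None,
    binary: bool | None = None,
) -> float:
    """Absolute standardized difference (ASD) of a covariate between groups.

    Continuous: |m1 - m0| / sqrt((s1^2 + s0^2)/2); binary: the analogue with
    Bernoulli variances p(1-p).  ``weights`` gives the weighted (IPTW) ASD;
    restrict the arrays to matched subjects for the matched ASD.  Returns 0
    when both the pooled SD and the mean difference vanish, NaN (undefined)
    when only the SD does.
    """
    x = np.asarray(covariate, dtype=float)
    e = np.asarray(exposure)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if binary is None:
        binary = set(np.unique(x)) <= {0.0, 1.0}
    m1, v1 = _group_stats(x[e == 1], w[e == 1])
    m0, v0 = _group_stats(x[e == 0], w[e == 0])
    if binary:
        v1 = m1 * (1.0 - m1)
        v0 = m0 * (1.0 - m0)
    pooled = np.sqrt((v1 + v0) / 2.0)
    diff = abs(m1 - m0)
    if pooled == 0.0:
        return 0.0 if diff == 0.0 else _NAN
    return float(diff / pooled)
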