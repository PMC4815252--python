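"""Propensity-score estimation, inverse-probability weights and caliper matching.

The propensity model regresses exposure on exactly the confounders that enter
the generating exposure model (so it is correctly specified by construction
in simulations, and accepts arbitrary covariates on real data).  Weights:

* ATT: exposed get weight 1, unexposed PS/(1-PS) — reweights the unexposed to
  the confounder distribution of the treated.
* ATE (stabilized): exposed get pbar/PS, unexposed (1-pbar)/(1-PS), where pbar
  is the exposed fraction of the analysis sample; stabilization keeps the
  group-wise mean weight near 1.

Matching is greedy nearest-neighbour 1:1 without replacement on the logit of
the PS, within a caliper of 0.2 pooled standard deviations of the logit PS.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .exceptions import EstimationError

try:  # statsmodels moved/renamed this across versions
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
except ImportError:  # pragma: no cover
    PerfectSeparationError = RuntimeError  # type: ignore[assignment,misc]

__all__ = [
    "PS_FLOOR",
    "PropensityModel",
    "PropensityFit",
    "compute_weights",
    "WeightedSample",
    "greedy_caliper_match",
    "MatchedSet",
]

#: predicted probabilities are clipped to [PS_FLOOR, 1 - PS_FLOOR] before
#: weights/logits: prevents infinite weights from numerically saturated fits
#: while leaving honest extremes untouched
PS_FLOOR = 1e-9

#: |coefficient| beyond this declares separation (diverging logistic fit)
_SEPARATION_COEF = 15.0


@dataclasses.dataclass
class PropensityFit:
    """Results of the propensity logistic fit."""

    params: np.ndarray | None
    names: tuple[str, ...]
    ps: np.ndarray | None
    converged: bool
    separation_flag: bool
    nobs: int

    def summary(self) -> str:
        lines = [
            "Propensity model (logistic, maximum likelihood)",
            f"  observations: {self.nobs}",
            f"  converged:    {self.converged}",
            f"  separation:   {self.separation_flag}",
        ]
        if self.params is not None:
            for name, value in zip(self.names, self.params):
                lines.append(f"  {name:>10s}  {value: .6f}")
        return "\n".join(lines)


class PropensityModel:
    """Logistic model of exposure on measured confounders.

    Parameters
    ----------
    exposure : (n,) 0/1 array
    confounders : (n, k) array of covariate columns
    names : optional covariate names for reporting
    """

    def __init__(
        self,
        exposure: np.ndarray,
        confounders: np.ndarray,
        names: tuple[str, ...] | None = None,
    ) -> None:
        self.exposure = np.asarray(exposure)
        self.confounders = np.atleast_2d(np.asarray(confounders, dtype=float))
        if self.confounders.shape[0] != self.exposure.shape[0]:
            self.confounders = self.confounders.T
        k = self.confounders.shape[1]
        self.names = ("const",) + tuple(names or (f"x{i}" for i in range(k)))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        confounders: tuple[str, ...] = ("B", "C"),
        exposure_col: str = "E",
    ) -> "PropensityModel":
        return cls(
            df[exposure_col].to_numpy(),
            df[list(confounders)].to_numpy(dtype=float),
            names=tuple(confounders),
        )

    def fit(self, maxiter: int = 100, tol: float = 1e-8) -> PropensityFit:
        """Newton maximum-likelihood fit with separation detection.

        An all-exposed or all-unexposed sample is an estimation error; a
        separated or non-convergent fit is *not* an exception — it is
        reported through the flags so replicate loops can record a failure.
        """
        e = self.exposure
        n = e.shape[0]
        if e.min() == e.max():
            raise EstimationError("sample contains a single exposure group")
        x = np.column_stack([np.ones(n), self.confounders])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(e, x).fit(
                    method="newton", maxiter=maxiter, tol=tol, disp=0,
                    warn_convergence=False,
                )
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return PropensityFit(None, self.names, None, False, True, n)
        params = np.asarray(res.params, dtype=float)
        diverged = bool(np.abs(params).max() > _SEPARATION_COEF) or not np.all(
            np.isfinite(params)
        )
        converged = bool(res.mle_retvals.get("converged", False)) and not diverged
        ps = np.clip(expit(x @ params), PS_FLOOR, 1.0 - PS_FLOOR)
        return PropensityFit(params, self.names, ps, converged, diverged, n)


@dataclasses.dataclass
class WeightedSample:
    """Per-subject inverse-probability weights."""

    weights: np.ndarray
    weight_type: str  # "ATE" (stabilized) | "ATT"
    pbar: float


def compute_weights(
    fit: PropensityFit, exposure: np.ndarray, weight_type: str
) -> WeightedSample:
    """ATT or stabilized-ATE weights from a converged propensity fit."""
    if not fit.converged or fit.ps is None:
        raise EstimationError("propensity fit did not converge; no weights")
    e = np.asarray(exposure)
    ps = fit.ps
    if weight_type == "ATT":
        w = np.where(e == 1, 1.0, ps / (1.0 - ps))
        pbar = float(np.mean(e))
    elif weight_type == "ATE":
        pbar = float(np.mean(e))
        w = np.where(e == 1, pbar / ps, (1.0 - pbar) / (1.0 - ps))
    else:
        raise ValueError(f"unknown weight_type {weight_type!r} (use 'ATE' or 'ATT')")
    if not np.all(np.isfinite(w)):
        raise EstimationError("non-finite weight encountered")
    return WeightedSample(weights=w, weight_type=weight_type, pbar=pbar)


@dataclasses.dataclass
class MatchedSet:
    """Greedy 1:1 caliper matches on the logit propensity scale."""

    pairs: np.ndarray  # (k, 2) [exposed index, unexposed index]
    pair_id: np.ndarray  # (n,) pair label per subject, -1 if unmatched
    caliper_width: float
    pct_matched: float
    n_exposed: int


def greedy_caliper_match(
    fit: PropensityFit,
    exposure: np.ndarray,
    rng: np.random.Generator,
    caliper_sd_multiplier: float = 0.2,
) -> MatchedSet:
    """Greedy nearest-neighbour 1:1 matching without replacement.

    Exposed subjects are processed in random order; each takes the nearest
    still-unmatched unexposed subject on the logit-PS scale provided the
    distance does not exceed the caliper (``caliper_sd_multiplier`` times the
    standard deviation of the logit PS over the whole sample, both groups
    pooled).  Equidistant candidates: lowest subject index wins.  A zero
    pooled SD yields a zero caliper; exact-distance-0 pairs still form.
    """
    if not fit.converged or fit.ps is None:
        raise EstimationError("propensity fit did not converge; no matching")
    e = np.asarray(exposure)
    lps = np.log(fit.ps) - np.log1p(-fit.ps)
    sd = float(np.std(lps, ddof=1)) if lps.size > 1 else 0.0
    caliper = caliper_sd_multiplier * sd
    exp_idx = np.flatnonzero(e == 1)
    une_idx = np.flatnonzero(e == 0)
    if exp_idx.size == 0:
        raise EstimationError("no exposed subjects to match")
    order = rng.permutation(exp_idx.size)
    lpu = lps[une_idx]
    available = np.ones(une_idx.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for oi in order:
        cand = np.flatnonzero(available)
        if cand.size == 0:
            break
        i = exp_idx[oi]
        dist = np.abs(lpu[cand] - lps[i])
        best = int(np.argmin(dist))  # first minimum = lowest subject index
        if dist[best] <= caliper:
            j = cand[best]
            pairs.append((int(i), int(une_idx[j])))
            available[j] = False
    pair_arr = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    pair_id = np.full(e.shape[0], -1, dtype=np.int64)
    for pid, (a, b) in enumerate(pair_arr):
        pair_id[a] = pid
        pair_id[b] = pid
    return MatchedSet(
        pairs=pair_arr,
        pair_id=pair_id,
        caliper_width=caliper,
        pct_matched=pair_arr.shape[0] / exp_idx.size,
        n_exposed=int(exp_idx.size),
    )
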