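"""Weighted Cox partial likelihood for a single binary exposure.

The marginal hazard model is lambda(t) = lambda_0(t) exp(gamma E) with E the
only covariate.  The (optionally weighted) log partial likelihood is maximised
by Newton iteration; because E is binary the risk-set sums reduce to two
suffix sums, making each fit O(n log n).  Standard errors are the Lin–Wei
robust sandwich built from per-subject score residuals; with matched data the
residual contributions are summed within pair before squaring (cluster-robust).

Event times in this package are continuous, so tied times occur with
probability zero; risk sets are formed with the Breslow convention, which
coincides with Efron's correction in the absence of ties.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .exceptions import EstimationError

__all__ = ["MarginalCoxModel", "MarginalCoxResults"]

_MONOTONE_BOUND = 15.0  # |gamma| beyond this flags a monotone likelihood


@dataclasses.dataclass
class MarginalCoxResults:
    """Point estimate, variances and diagnostics for the marginal fit."""

    gamma_hat: float
    se_robust: float
    se_model: float
    ci95: tuple[float, float]
    converged: bool
    monotone: bool
    nobs: int
    n_events: int
    n_clusters: int | None
    fail_reason: str = ""

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.gamma_hat))

    def summary(self) -> str:
        lo, hi = self.ci95
        lines = [
            "Marginal Cox model (exposure only, robust sandwich SE)",
            f"  observations: {self.nobs}   events: {self.n_events}",
            f"  converged:    {self.converged}"
            + (f"   ({self.fail_reason})" if self.fail_reason else ""),
            f"  log HR:       {self.gamma_hat: .6f}  (robust SE {self.se_robust:.6f})",
            f"  HR:           {self.hazard_ratio: .6f}  95% CI "
            f"[{np.exp(lo):.6f}, {np.exp(hi):.6f}]",
        ]
        if self.n_clusters is not None:
            lines.append(f"  clusters:     {self.n_clusters} (pair-robust variance)")
        return "\n".join(lines)


class MarginalCoxModel:
    """Cox model of observed time on a binary exposure.

    Parameters
    ----------
    time, event, exposure : (n,) arrays (event and exposure coded 0/1)
    weights : optional non-negative per-subject weights (IPTW); default 1
    clusters : optional integer cluster labels (e.g. matched-pair ids); when
        given, the robust variance sums score contributions within cluster.
    """

    def __init__(
        self,
        time: np.ndarray,
        event: np.ndarray,
        exposure: np.ndarray,
        weights: np.ndarray | None = None,
        clusters: np.ndarray | None = None,
    ) -> None:
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=np.int64)
        self.exposure = np.asarray(exposure, dtype=np.int64)
        n = self.time.shape[0]
        if self.event.shape[0] != n or self.exposure.shape[0] != n:
            raise ValueError("time, event and exposure must have equal length")
        self.weights = (
            np.ones(n) if weights is None else np.asarray(weights, dtype=float)
        )
        if np.any(self.weights < 0) or not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite and non-negative")
        self.clusters = None if clusters is None else np.asarray(clusters)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        duration_col: str = "t_obs",
        event_col: str = "Y",
        exposure_col: str = "E",
        weights_col: str | None = None,
        cluster_col: str | None = None,
    ) -> "MarginalCoxModel":
        return cls(
            df[duration_col].to_numpy(),
            df[event_col].to_numpy(),
            df[exposure_col].to_numpy(),
            weights=None if weights_col is None else df[weights_col].to_numpy(),
            clusters=None if cluster_col is None else df[cluster_col].to_numpy(),
        )

    # -- internals ---------------------------------------------------------

    def _prepared(self):
        order = np.argsort(self.time, kind="stable")
        t = self.time[order]
        d = self.event[order]
        x = self.exposure[order].astype(float)
        w = self.weights[order]
        # risk set of a subject at time t_i = all rows with t_j >= t_i;
        # `first` maps each row to the first row of its tied-time block
        first = np.searchsorted(t, t, side="left")
        last = np.searchsorted(t, t, side="right") - 1
        a1 = np.cumsum((w * x)[::-1])[::-1]
        a0 = np.cumsum((w * (1.0 - x))[::-1])[::-1]
        return order, t, d, x, w, first, last, a1[first], a0[first]

    @staticmethod
    def _score_info(gamma, d, x, w, A1, A0):
        eg = np.exp(gamma)
        s0 = A0 + eg * A1
        m = eg * A1 / s0  # S1/S0; x is binary so S2 = S1
        ev = d == 1
        ll = float(np.sum(w[ev] * (gamma * x[ev] - np.log(s0[ev]))))
        score = float(np.sum(w[ev] * (x[ev] - m[ev])))
        info = float(np.sum(w[ev] * m[ev] * (1.0 - m[ev])))
        return ll, score, info, m, s0

    def fit(self, max_iter: int = 50, tol: float = 1e-10) -> MarginalCoxResults:
        """Newton maximisation with step halving.

        Degenerate samples (no events in one exposure group — a monotone
        likelihood — or a missing exposure group) are *not* exceptions: the
        result is returned with ``converged=False`` so that replicate loops
        can record the failure.
        """
        n = self.time.shape[0]
        n_events = int(self.event.sum())
        n_clusters = None if self.clusters is None else int(len(np.unique(self.clusters)))

        def failed(reason: str) -> MarginalCoxResults:
            nan = float("nan")
            return MarginalCoxResults(
                nan, nan, nan, (nan, nan), False, "monotone" in reason,
                n, n_events, n_clusters, fail_reason=reason,
            )

        if n == 0:
            return failed("empty sample")
        used = self.weights > 0
        if self.exposure[used].min(initial=1) == 1 or self.exposure[used].max(initial=0) == 0:
            return failed("single exposure group")
        ev_exp = int(np.sum((self.event == 1) & (self.exposure == 1) & used))
        ev_une = int(np.sum((self.event == 1) & (self.exposure == 0) & used))
        if ev_exp == 0 or ev_une == 0:
            return failed("monotone likelihood: no events in one exposure group")

        order, t, d, x, w, first, last, A1, A0 = self._prepared()
        gamma = 0.0
        ll, score, info, m, s0 = self._score_info(gamma, d, x, w, A1, A0)
        converged = False
        for _ in range(max_iter):
            if info <= 0:
                return failed("singular information")
            step = score / info
            new_gamma = gamma + step
            new_ll, new_score, new_info, new_m, new_s0 = self._score_info(
                new_gamma, d, x, w, A1, A0
            )
            halvings = 0
            while new_ll < ll - 1e-12 and halvings < 20:
                step *= 0.5
                new_gamma = gamma + step
                new_ll, new_score, new_info, new_m, new_s0 = self._score_info(
                    new_gamma, d, x, w, A1, A0
                )
                halvings += 1
            gamma, ll, score, info, m, s0 = new_gamma, new_ll, new_score, new_info, new_m, new_s0
            if abs(gamma) > _MONOTONE_BOUND:
                return failed("monotone likelihood: estimate diverged")
            if abs(step) < tol and abs(score) < 1e-6 * max(1.0, info):
                converged = True
                break
        if not converged:
            return failed("Newton iteration did not converge")

        se_model = float(np.sqrt(1.0 / info))
        se_robust = self._robust_se(gamma, info, order, d, x, w, last, m, s0)
        ci = (gamma - 1.96 * se_robust, gamma + 1.96 * se_robust)
        return MarginalCoxResults(
            float(gamma), se_robust, se_model, ci, True, False,
            n, n_events, n_clusters,
        )

    def _robust_se(self, gamma, info, order, d, x, w, last, m, s0) -> float:
        """Lin–Wei sandwich from score residuals (optionally pair-clustered)."""
        ev = d == 1
        hk = np.zeros_like(s0)
        qk = np.zeros_like(s0)
        hk[ev] = w[ev] / s0[ev]
        qk[ev] = w[ev] * m[ev] / s0[ev]
        # cumulative over all events with t_k <= t_j (includes tied times)
        p_j = np.cumsum(hk)[last]
        q_j = np.cumsum(qk)[last]
        resid = d * (x - m) - np.exp(gamma * x) * (x * p_j - q_j)
        dfbeta = w * resid / info
        if self.clusters is None:
            var = float(np.sum(dfbeta**2))
        else:
            cl = self.clusters[order]
            _, codes = np.unique(cl, return_inverse=True)
            var = float(np.sum(np.bincount(codes, weights=dfbeta) ** 2))
        return float(np.sqrt(var))
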