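"""Synthetic cohort generation.

The generator implements a marginal-structural survival design with purely
baseline confounding.  A latent normal vector (X_U, X_B, X_C[, X_B', X_C'])
is drawn with the scenario's covariance; measured confounders are obtained by
thresholding (B = 1{X_B > 0}) and identity (C = X_C), while the latent
"general health" variable U = Phi(X_U) is uniform by the probability integral
transform.  Exposure E is Bernoulli with logistic probability in the measured
confounders only; the event time is T = -log(U) / (lambda * exp(gamma * E)),
i.e. exponential with the *marginal* hazard ratio exp(gamma), driven by the
very same U that correlates with the confounders — that shared U is the
confounding mechanism.  Censoring is uniform on (0, c), independent of
everything else.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .exceptions import ScenarioError
from .scenarios import CovarianceSpec, SimulationScenario, build_covariance

__all__ = [
    "Cohort",
    "draw_covariates",
    "assign_exposure",
    "generate_event_times",
    "apply_censoring",
    "generate_cohort",
]

#: lower clamp on U before -log(U); numerically invisible, prevents infinities
_U_EPS = 1e-300
#: upper clamp: largest double strictly below 1, so -log(U) stays positive
_U_UPPER = np.nextafter(1.0, 0.0)


@dataclasses.dataclass
class Cohort:
    """Per-subject arrays for one simulated cohort.

    ``u``, ``t_event`` and ``t_censor`` are unobservable bookkeeping: the
    estimator layer must only ever see the confounders, ``e``, ``t_obs`` and
    ``y`` (which is what :meth:`to_dataframe` exports by default).
    """

    scenario: SimulationScenario
    b: np.ndarray
    c: np.ndarray
    u: np.ndarray
    b2: np.ndarray | None = None
    c2: np.ndarray | None = None
    e: np.ndarray | None = None
    t_event: np.ndarray | None = None
    t_censor: np.ndarray | None = None
    t_obs: np.ndarray | None = None
    y: np.ndarray | None = None

    def __len__(self) -> int:
        return self.b.shape[0]

    @property
    def confounder_names(self) -> tuple[str, ...]:
        return ("B", "C") if self.b2 is None else ("B", "C", "B2", "C2")

    def confounders(self) -> np.ndarray:
        """(n, k) matrix of measured confounders, columns per confounder_names."""
        cols = [self.b, self.c]
        if self.b2 is not None:
            cols += [self.b2, self.c2]
        return np.column_stack(cols)

    def to_dataframe(self, debug: bool = False) -> pd.DataFrame:
        """Observable columns id, B, C[, B2, C2], E, t_obs, Y.

        With ``debug=True`` the unobservable U, T and T_c are appended.
        """
        data: dict[str, np.ndarray] = {"id": np.arange(len(self)), "B": self.b, "C": self.c}
        if self.b2 is not None:
            data["B2"] = self.b2
            data["C2"] = self.c2
        for name, arr in (("E", self.e), ("t_obs", self.t_obs), ("Y", self.y)):
            if arr is None:
                raise ScenarioError("cohort is not fully generated")
            data[name] = arr
        if debug:
            data["U"] = self.u
            data["T"] = self.t_event
            data["T_c"] = self.t_censor
        return pd.DataFrame(data)


def _sampling_factor(spec: CovarianceSpec) -> np.ndarray:
    """Matrix L with L L^T = Sigma via eigendecomposition (PSD-safe)."""
    w, v = np.linalg.eigh(spec.matrix)
    w = np.clip(w, 0.0, None)  # build_covariance already rejected w < -1e-10
    return v * np.sqrt(w)


def draw_covariates(
    scenario: SimulationScenario, n: int, rng: np.random.Generator
) -> Cohort:
    """Draw the latent normal vector and transform to (B, C[, B', C'], U)."""
    spec = build_covariance(scenario)
    z = rng.standard_normal((n, spec.dimension))
    x = z @ _sampling_factor(spec).T
    u = ndtr(x[:, 0])
    b = (x[:, 1] > 0).astype(np.int64)
    c = x[:, 2].copy()
    b2 = c2 = None
    if spec.dimension == 5:
        b2 = (x[:, 3] > 0).astype(np.int64)
        c2 = x[:, 4].copy()
    return Cohort(scenario=scenario, b=b, c=c, u=u, b2=b2, c2=c2)


def exposure_probability(cohort: Cohort) -> np.ndarray:
    """Per-subject generating probability of exposure (requires delta0)."""
    sc = cohort.scenario
    if sc.delta0 is None:
        raise ScenarioError("delta0 is not calibrated; run calibrate_delta0 first")
    lp = sc.delta0 + sc.delta_b * cohort.b + sc.delta_c * cohort.c
    if cohort.b2 is not None:
        lp = lp + sc.delta_b * cohort.b2 + sc.delta_c * cohort.c2
    return expit(lp)


def assign_exposure(cohort: Cohort, rng: np.random.Generator) -> Cohort:
    """Draw exposure Bernoulli(logit^-1(delta0 + delta_B B + delta_C C [...]))."""
    pz = exposure_probability(cohort)
    cohort.e = (rng.random(len(cohort)) < pz).astype(np.int64)
    return cohort


def generate_event_times(cohort: Cohort) -> Cohort:
    """Event time T = -log(U) / (lambda * exp(gamma * E)) from the shared U.

    Reusing the copula's U here (rather than a fresh uniform) is what makes
    the confounders confound; it must never be replaced.
    """
    if cohort.e is None:
        raise ScenarioError("exposure must be assigned before event times")
    sc = cohort.scenario
    u = np.clip(cohort.u, _U_EPS, _U_UPPER)
    rate = sc.baseline_hazard * np.exp(sc.gamma * cohort.e)
    cohort.t_event = -np.log(u) / rate
    return cohort


def apply_censoring(cohort: Cohort, rng: np.random.Generator) -> Cohort:
    """Uniform(0, c) censoring, independent of everything else.

    An infinite bound means no censoring.  Ties T == T_c count as events.
    """
    sc = cohort.scenario
    if sc.censor_bound is None:
        raise ScenarioError("censor_bound is not calibrated; run calibrate_censor_bound first")
    if cohort.t_event is None:
        raise ScenarioError("event times must be generated before censoring")
    n = len(cohort)
    if np.isinf(sc.censor_bound):
        cohort.t_censor = np.full(n, np.inf)
    else:
        cohort.t_censor = rng.uniform(0.0, sc.censor_bound, size=n)
    cohort.y = (cohort.t_event <= cohort.t_censor).astype(np.int64)
    cohort.t_obs = np.where(cohort.y == 1, cohort.t_event, cohort.t_censor)
    return cohort


def generate_cohort(
    scenario: SimulationScenario,
    seed: int | np.random.SeedSequence | None = None,
) -> Cohort:
    """Generate one full cohort of ``scenario.n_cohort`` subjects.

    A single root seed is split into three named independent streams
    (covariates, exposure, censoring) so that per-stage diagnostics stay
    reproducible when other stages change.  Bit-identical for a fixed seed.
    """
    if seed is None:
        seed = scenario.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence([int(seed)])
    cov_ss, exp_ss, cen_ss = ss.spawn(3)
    cohort = draw_covariates(scenario, scenario.n_cohort, np.random.default_rng(cov_ss))
    assign_exposure(cohort, np.random.default_rng(exp_ss))
    generate_event_times(cohort)
    apply_censoring(cohort, np.random.default_rng(cen_ss))
    return cohort
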