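"""Simulation scenarios and the latent-covariate covariance structure.

A scenario bundles every knob of the synthetic cohort generator: cohort size,
target exposure prevalence, the covariances tying the measured confounders
(one binary B, one continuous C, optionally a second pair B', C') to the
latent uniform health variable U, the exposure-model log-odds coefficients,
the marginal log hazard ratio, the baseline hazard, and the target censoring
rate.  Two constants are not free parameters but are *calibrated* to hit the
prevalence and censoring targets: the exposure-model intercept ``delta0`` and
the upper bound ``censor_bound`` of the uniform censoring distribution (see
:mod:`rareps.calibrate`).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Any

import numpy as np
import yaml

from .exceptions import ScenarioError

__all__ = [
    "SimulationScenario",
    "CovarianceSpec",
    "build_covariance",
    "reference_scenario",
    "load_scenario",
    "save_scenario",
]

#: eigenvalues of the latent covariance below this are a configuration error;
#: eigenvalues in [-_EIG_TOL, 0] are clamped to 0 (degenerate but samplable)
_EIG_TOL = 1e-10


@dataclasses.dataclass
class SimulationScenario:
    """All generator knobs plus the two calibrated constants.

    Defaults correspond to the reference configuration: prevalence 5%,
    moderate confounder-health covariance (0.3), independent confounders,
    moderate exposure association (odds ratio 1.5 per confounder), null
    marginal effect, two confounders, 50% censoring, cohorts of 10,000.
    """

    n_cohort: int = 10_000
    prevalence_target: float = 0.05
    sigma_ub: float = 0.3
    sigma_uc: float = 0.3
    sigma_bc: float = 0.0
    delta_b: float = math.log(1.5)
    delta_c: float = math.log(1.5)
    gamma: float = 0.0
    baseline_hazard: float = 0.1
    censoring_rate_target: float = 0.5
    n_confounders: int = 2
    delta0: float | None = None
    censor_bound: float | None = None
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_cohort <= 0:
            raise ScenarioError("n_cohort must be a positive integer")
        if not 0.0 < self.prevalence_target < 1.0:
            raise ScenarioError("prevalence_target must lie in (0, 1)")
        for attr in ("sigma_ub", "sigma_uc", "sigma_bc"):
            v = getattr(self, attr)
            if not -1.0 <= v <= 1.0:
                raise ScenarioError(f"{attr}={v} outside [-1, 1]")
        if self.baseline_hazard <= 0:
            raise ScenarioError("baseline_hazard must be positive")
        if not 0.0 <= self.censoring_rate_target < 1.0:
            raise ScenarioError("censoring_rate_target must lie in [0, 1)")
        if self.n_confounders not in (2, 4):
            raise ScenarioError("n_confounders must be 2 or 4")

    # -- calibration bookkeeping ------------------------------------------

    @property
    def is_calibrated(self) -> bool:
        """True once both delta0 and censor_bound have been set."""
        return self.delta0 is not None and self.censor_bound is not None

    def replace(self, **changes: Any) -> "SimulationScenario":
        return dataclasses.replace(self, **changes)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if d["censor_bound"] is not None and math.isinf(d["censor_bound"]):
            d["censor_bound"] = ".inf"
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationScenario":
        d = dict(d)
        if d.get("censor_bound") == ".inf":
            d["censor_bound"] = math.inf
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ScenarioError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**d)


def reference_scenario(**overrides: Any) -> SimulationScenario:
    """The named reference configuration, optionally with overrides."""
    base = SimulationScenario(name="reference")
    return base.replace(**overrides) if overrides else base


@dataclasses.dataclass
class CovarianceSpec:
    """Covariance matrix of the latent normal vector (U, X_B, X_C[, X_B', X_C']).

    The diagonal is 1 by construction; ``degenerate`` marks a singular (but
    positive semi-definite, hence still samplable) matrix.
    """

    dimension: int
    matrix: np.ndarray
    degenerate: bool = False

    @property
    def labels(self) -> tuple[str, ...]:
        return ("U", "B", "C") if self.dimension == 3 else ("U", "B", "C", "B2", "C2")


def build_covariance(scenario: SimulationScenario) -> CovarianceSpec:
    """Assemble and validate the latent covariance matrix Sigma.

    Layout (unit diagonal throughout): cov(U,B)=cov(U,B')=sigma_ub,
    cov(U,C)=cov(U,C')=sigma_uc, cov(B,C)=cov(B',C')=sigma_bc, and the two
    pairs are mutually independent (cov(B,B')=cov(C,C')=cov(B,C')=cov(B',C)=0).

    Raises
    ------
    ScenarioError
        If Sigma has an eigenvalue below -1e-10 (not positive semi-definite).
        Eigenvalues in [-1e-10, 0] are clamped to zero and the spec is flagged
        degenerate with a warning.
    """
    dim = 3 if scenario.n_confounders == 2 else 5
    s = np.eye(dim)
    u, b, c = 0, 1, 2
    s[u, b] = s[b, u] = scenario.sigma_ub
    s[u, c] = s[c, u] = scenario.sigma_uc
    s[b, c] = s[c, b] = scenario.sigma_bc
    if dim == 5:
        b2, c2 = 3, 4
        s[u, b2] = s[b2, u] = scenario.sigma_ub
        s[u, c2] = s[c2, u] = scenario.sigma_uc
        s[b2, c2] = s[c2, b2] = scenario.sigma_bc
    eigvals = np.linalg.eigvalsh(s)
    min_eig = float(eigvals.min())
    if min_eig < -_EIG_TOL:
        raise ScenarioError(
            "covariance matrix is not positive semi-definite "
            f"(min eigenvalue {min_eig:.3e}) for sigma_ub={scenario.sigma_ub}, "
            f"sigma_uc={scenario.sigma_uc}, sigma_bc={scenario.sigma_bc}, "
            f"n_confounders={scenario.n_confounders}"
        )
    degenerate = min_eig < _EIG_TOL
    if degenerate:
        warnings.warn(
            "latent covariance matrix is singular (min eigenvalue "
            f"{min_eig:.3e}); sampling proceeds on its PSD clamp",
            RuntimeWarning,
            stacklevel=2,
        )
    return CovarianceSpec(dimension=dim, matrix=s, degenerate=degenerate)


def save_scenario(scenario: SimulationScenario, path: str) -> None:
    """Write a scenario (including any calibrated constants) to a YAML file."""
    with open(path, "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=False)


def load_scenario(path: str) -> SimulationScenario:
    """Read a scenario from a YAML file written by :func:`save_scenario`."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ScenarioError(f"{path} does not contain a scenario mapping")
    return SimulationScenario.from_dict(d)
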