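"""Event-anchored analysis-sample selection.

With a rare exposure, fixing the sample size risks samples with no events
among the exposed (unanalysable) — dropping those would over-represent lucky
samples.  Instead the analysis sample is the first (minimal) prefix of the
cohort, in generation order, containing exactly ``y_target`` events among
exposed subjects.  Generation order is exchangeable, so the prefix is a
representative sample of the cohort.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .exceptions import ScenarioError
from .generate import Cohort

__all__ = ["AnalysisSample", "select_by_exposed_events"]


@dataclasses.dataclass
class AnalysisSample:
    """A prefix of a cohort with exactly ``y_target`` exposed events.

    ``achieved`` is False when the whole cohort holds fewer exposed events
    than requested; the sample is then the full cohort and downstream cells
    must record the replicate as excluded rather than silently regenerate.
    """

    cohort: Cohort
    y_target: int
    n_selected: int
    achieved: bool

    def __len__(self) -> int:
        return self.n_selected

    # -- observable prefix views ------------------------------------------

    @property
    def exposure(self) -> np.ndarray:
        return self.cohort.e[: self.n_selected]

    @property
    def time(self) -> np.ndarray:
        return self.cohort.t_obs[: self.n_selected]

    @property
    def event(self) -> np.ndarray:
        return self.cohort.y[: self.n_selected]

    def confounders(self) -> np.ndarray:
        return self.cohort.confounders()[: self.n_selected]

    @property
    def confounder_names(self) -> tuple[str, ...]:
        return self.cohort.confounder_names

    def to_dataframe(self) -> pd.DataFrame:
        return self.cohort.to_dataframe().iloc[: self.n_selected].reset_index(drop=True)


def select_by_exposed_events(
    cohort: Cohort, y_target: int, enforce_grid: bool = True
) -> AnalysisSample:
    """Minimal cohort prefix containing ``y_target`` events among the exposed.

    ``y_target`` must be an even integer in [2, 200] (the study grid);
    ``enforce_grid=False`` lifts that contract and accepts any positive
    integer.
    """
    if enforce_grid and (y_target < 2 or y_target > 200 or y_target % 2 != 0):
        raise ValueError(
            f"y_target={y_target} outside the grid (even, in [2, 200]); "
            "pass enforce_grid=False to override"
        )
    if y_target < 1:
        raise ValueError("y_target must be positive")
    if cohort.e is None or cohort.y is None:
        raise ScenarioError("cohort is not fully generated")
    exposed_event = (cohort.e == 1) & (cohort.y == 1)
    positions = np.flatnonzero(exposed_event)
    if positions.size < y_target:
        return AnalysisSample(cohort, y_target, n_selected=len(cohort), achieved=False)
    n_selected = int(positions[y_target - 1]) + 1
    return AnalysisSample(cohort, y_target, n_selected=n_selected, achieved=True)
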