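"""The shipped worked example: a 3x2 combination trial at target rate 0.4.

Six candidate orderings (the complete monotone set for a 3x2 grid, with the
by-rows ordering listed twice so it carries double prior weight), an
indifference-interval skeleton with halfwidth 0.08 anchored at position 3,
the alpha**exp(a) power model with a Normal(0, 1.34) prior, and the data
state after eleven single-patient cohorts::

    n = (1, 0, 1, 6, 2, 1)    patients per dose
    y = (0, 0, 0, 3, 1, 1)    DLTs per dose

Cohort 12 is then assigned dose 2 (the model-selection recommendation) and
observes no DLT.  This update is the canonical demonstration of estimation
incoherency: under model selection the estimate at dose 4 — universally more
toxic than the non-toxic dose 2 — *rises* by about 0.07, while the
model-averaged estimates all move coherently.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data import TrialData
from .models import WorkingModelConfig
from .orderings import DoseGrid, PartialOrderSpec, enumerate_matrix_orderings
from .skeleton import Skeleton, indifference_interval_skeleton

__all__ = ["WorkedExample", "worked_example"]

THETA = 0.4
HALFWIDTH = 0.08
PRIOR_MTD = 3
N_COHORT_11 = (1, 0, 1, 6, 2, 1)
Y_COHORT_11 = (0, 0, 0, 3, 1, 1)
N_COHORT_12 = (1, 1, 1, 6, 2, 1)
Y_COHORT_12 = (0, 0, 0, 3, 1, 1)


@dataclass(frozen=True)
class WorkedExample:
    grid: DoseGrid
    spec: PartialOrderSpec
    skeleton: Skeleton
    model: WorkingModelConfig
    theta: float
    data_cohort11: TrialData
    data_cohort12: TrialData


def worked_example() -> WorkedExample:
    """Construct the worked-example configuration and both data states."""
    grid = DoseGrid(3, 2)
    spec = PartialOrderSpec.uniform(enumerate_matrix_orderings(grid), grid=grid)
    skeleton = indifference_interval_skeleton(
        K=grid.K, target=THETA, halfwidth=HALFWIDTH, prior_mtd=PRIOR_MTD
    )
    model = WorkingModelConfig()
    return WorkedExample(
        grid=grid,
        spec=spec,
        skeleton=skeleton,
        model=model,
        theta=THETA,
        data_cohort11=TrialData.from_counts(N_COHORT_11, Y_COHORT_11),
        data_cohort12=TrialData.from_counts(N_COHORT_12, Y_COHORT_12),
    )
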