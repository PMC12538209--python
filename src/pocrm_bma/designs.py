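"""Dose-allocation engines.

Four designs share the same allocation criterion — assign the dose whose
estimated DLT risk is closest to the target toxicity rate — and differ only in
how the per-ordering posteriors are turned into estimates:

``pocrm_select``
    classic partial-ordering CRM: select the maximum-posterior ordering and
    plug its posterior-mean parameter into the working model.
``bma_pocrm``
    model averaging on the posterior *densities* of the toxicity risk; the
    allocation uses the mixture-posterior mean.
``bma_zhang``
    model averaging on the per-ordering *point estimates*.  Provably yields
    the same estimates as ``bma_pocrm`` (the integration orders commute); it
    is kept as an independent code path so the equivalence can be tested.
``bma_wages``
    model averaging on the per-ordering *recommended doses*: each ordering
    votes for its own allocation with weight equal to its posterior
    probability, and the dose with the largest combined vote is assigned.
    This design carries no averaged toxicity estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import TrialData
from .exceptions import InvalidParameterError
from .inference import compute_tables, select_ordering
from .models import WorkingModelConfig
from .orderings import DoseGrid, PartialOrderSpec
from .skeleton import Skeleton

__all__ = ["DesignConfig", "Recommendation", "allocate_next_dose", "recommend", "DESIGNS"]

DESIGNS = ("pocrm_select", "bma_pocrm", "bma_zhang", "bma_wages")


@dataclass(frozen=True)
class DesignConfig:
    """Trial-level design settings.

    ``allow_skipping=True`` runs the pure allocation criterion; when False the
    chosen dose is clamped to at most one untried level above the highest
    level tried so far in each drug's margin (common escalation practice,
    provided as an option).
    """

    design: str
    theta: float
    cohort_size: int = 1
    n_cohorts: int = 60
    start_dose: int = 1
    allow_skipping: bool = True
    tie_break: str = "highest"

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise InvalidParameterError(f"unknown design {self.design!r}")
        if not 0.0 < self.theta < 1.0:
            raise InvalidParameterError("theta must be in (0, 1)")
        if self.cohort_size < 1 or self.n_cohorts < 1:
            raise InvalidParameterError("cohort_size and n_cohorts must be >= 1")
        if self.start_dose < 1:
            raise InvalidParameterError("start_dose must be >= 1")

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "theta": self.theta,
            "cohort_size": self.cohort_size,
            "n_cohorts": self.n_cohorts,
            "start_dose": self.start_dose,
            "allow_skipping": self.allow_skipping,
            "tie_break": self.tie_break,
        }


def allowed_doses(grid: DoseGrid | None, data: TrialData | None) -> np.ndarray | None:
    """Mask of doses reachable without skipping an untried level in either margin.

    A dose is allowed when its drug-A level is at most one above the highest
    drug-A level tried so far, and likewise for drug B.  With no grid the
    constraint cannot be evaluated and ``None`` (no restriction) is returned.
    """
    if grid is None or data is None:
        return None
    max_row = 0
    max_col = 0
    for k, nk in enumerate(data.n, start=1):
        if nk > 0:
            i, j = grid.rowcol(k)
            max_row = max(max_row, i)
            max_col = max(max_col, j)
    mask = np.zeros(grid.K, dtype=bool)
    for k in range(1, grid.K + 1):
        i, j = grid.rowcol(k)
        mask[k - 1] = i <= max_row + 1 and j <= max_col + 1
    return mask


def allocate_next_dose(
    estimates, theta: float, allowed: np.ndarray | None = None
) -> int:
    """Dose minimizing |estimate - theta|; ties go to the lower dose index.

    ``allowed`` optionally restricts the candidates (no-skipping clamp).
    Returns a 1-based dose index.
    """
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise InvalidParameterError("empty estimate vector")
    if np.any(est <= 0.0) or np.any(est >= 1.0):
        raise InvalidParameterError("estimates must lie in (0, 1)")
    dist = np.abs(est - theta)
    if allowed is not None:
        allowed = np.asarray(allowed, dtype=bool)
        if not allowed.any():
            raise InvalidParameterError("no dose is allowed")
        dist = np.where(allowed, dist, np.inf)
    return int(np.argmin(dist)) + 1  # argmin takes the first (lowest) minimum


@dataclass(frozen=True)
class Recommendation:
    """Output of one estimation-allocation step."""

    next_dose: int
    estimates: np.ndarray | None
    ordering_post: np.ndarray
    selected_m: int | None = None
    wages_pi: np.ndarray | None = None


def recommend(
    design: DesignConfig,
    data: TrialData,
    spec: PartialOrderSpec,
    skeleton: Skeleton,
    config: WorkingModelConfig,
) -> Recommendation:
    """Run one design update: estimates (where defined) and the next dose."""
    t = compute_tables(data, spec, skeleton, config)
    allowed = None
    if not design.allow_skipping:
        allowed = allowed_doses(spec.grid, data)
    if design.design == "pocrm_select":
        m = select_ordering(t.ordering_post, design.tie_break)
        est = np.asarray(config.psi(t.alpha[m - 1], np.asarray(t.a_hat[m - 1])), dtype=float)
        nxt = allocate_next_dose(est, design.theta, allowed)
        return Recommendation(nxt, est, t.ordering_post, selected_m=m)
    if design.design == "bma_pocrm":
        est = t.ordering_post @ t.est
        nxt = allocate_next_dose(est, design.theta, allowed)
        return Recommendation(nxt, est, t.ordering_post)
    if design.design == "bma_zhang":
        # average of per-ordering point estimates, accumulated explicitly
        est = np.zeros(spec.K)
        for m in range(t.M):
            est = est + t.ordering_post[m] * t.est[m]
        nxt = allocate_next_dose(est, design.theta, allowed)
        return Recommendation(nxt, est, t.ordering_post)
    # bma_wages: each ordering votes for its own Eq-1 recommendation
    pi = np.zeros(spec.K)
    for m in range(t.M):
        est_m = np.asarray(config.psi(t.alpha[m], np.asarray(t.a_hat[m])), dtype=float)
        rec_m = allocate_next_dose(est_m, design.theta, allowed)
        pi[rec_m - 1] += t.ordering_post[m]
    nxt = int(np.argmax(pi)) + 1  # argmax takes the first (lowest) maximum
    return Recommendation(nxt, None, t.ordering_post, wages_pi=pi)
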