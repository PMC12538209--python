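"""Replay of a completed trial's summary data under model-guided designs.

A completed trial reports per-dose patient counts ``n_j`` and DLT counts
``y_j``.  To replay the trial under a different escalation rule each dose
needs a full-length *response stream*: the first ``n_j`` entries are a seeded
random permutation of the dose's observed outcomes, and the remainder are
imputed by drawing a DLT probability from the posterior
``Beta(1 + y_j, 1 + n_j - y_j)`` (a uniform prior updated by the observed
counts) and then a Bernoulli response — doses never assigned in the original
trial fall back to a weakly-informative ``Beta(3, 3)``.  Because the j-th
patient ever assigned to a dose always receives entry j of that dose's
stream, every design replayed on the same streams sees identical responses
wherever their allocation paths overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import TrialData
from .designs import DesignConfig, allocate_next_dose, recommend
from .exceptions import InvalidParameterError, StreamExhaustedError
from .models import WorkingModelConfig
from .orderings import PartialOrderSpec
from .simulation import TrialRecord
from .skeleton import Skeleton

__all__ = ["ResponseStreams", "build_response_streams", "replay_trial"]


@dataclass(frozen=True)
class ResponseStreams:
    """Fixed per-dose binary outcome sequences of equal length.

    ``observed_mask[k, j]`` is True where entry j of dose k's stream came from
    permuting the original study's outcomes rather than Beta sampling.
    """

    outcomes: np.ndarray       # (K, total_patients) of 0/1
    observed_mask: np.ndarray  # (K, total_patients) bool

    @property
    def K(self) -> int:
        return self.outcomes.shape[0]

    @property
    def total_patients(self) -> int:
        return self.outcomes.shape[1]


def build_response_streams(
    observed_n,
    observed_y,
    total_patients: int,
    seed,
    beta_draw: str = "per_patient",
) -> ResponseStreams:
    """Construct fixed response streams from per-dose summary counts.

    ``beta_draw`` controls how imputed entries use the Beta posterior:
    ``"per_patient"`` draws a fresh probability for every synthetic patient;
    ``"per_dose"`` draws one probability per dose and reuses it.
    """
    n = np.asarray(observed_n, dtype=int)
    y = np.asarray(observed_y, dtype=int)
    if n.shape != y.shape or n.ndim != 1:
        raise InvalidParameterError("observed_n and observed_y must be 1-D of equal length")
    if np.any(n < 0) or np.any(y < 0) or np.any(y > n):
        raise InvalidParameterError("need 0 <= y_j <= n_j")
    if total_patients < int(n.max(initial=0)):
        raise InvalidParameterError("total_patients must cover the largest observed n_j")
    if beta_draw not in ("per_patient", "per_dose"):
        raise InvalidParameterError("beta_draw must be 'per_patient' or 'per_dose'")
    rng = np.random.default_rng(seed)
    K = n.size
    out = np.zeros((K, total_patients), dtype=int)
    mask = np.zeros((K, total_patients), dtype=bool)
    for k in range(K):
        observed = np.concatenate([np.ones(y[k], dtype=int), np.zeros(n[k] - y[k], dtype=int)])
        out[k, : n[k]] = rng.permutation(observed)
        mask[k, : n[k]] = True
        m = total_patients - n[k]
        if m == 0:
            continue
        if n[k] == 0:
            a, b = 3.0, 3.0
        else:
            a, b = 1.0 + y[k], 1.0 + n[k] - y[k]
        if beta_draw == "per_patient":
            p = rng.beta(a, b, size=m)
        else:
            p = np.full(m, rng.beta(a, b))
        out[k, n[k]:] = (rng.random(m) < p).astype(int)
    return ResponseStreams(out, mask)


def replay_trial(
    streams: ResponseStreams,
    design: DesignConfig,
    spec: PartialOrderSpec,
    skeleton: Skeleton,
    model: WorkingModelConfig,
    initial_cohorts: list[tuple[int, int]] | None = None,
) -> TrialRecord:
    """Replay a design against fixed response streams.

    ``initial_cohorts`` lists fixed run-in allocations as ``(dose, size)``
    pairs, entered into the data (in the listed order) before the first model
    update; thereafter allocation is model-guided for ``design.n_cohorts``
    cohorts of ``design.cohort_size``.  Raises
    :class:`~pocrm_bma.exceptions.StreamExhaustedError` if any dose's stream
    runs out.
    """
    K = spec.K
    if streams.K != K:
        raise InvalidParameterError("streams and ordering spec disagree on K")
    consumed = np.zeros(K, dtype=int)

    def draw(dose: int) -> int:
        if consumed[dose - 1] >= streams.total_patients:
            raise StreamExhaustedError(f"response stream for dose {dose} exhausted")
        out = int(streams.outcomes[dose - 1, consumed[dose - 1]])
        consumed[dose - 1] += 1
        return out

    data = TrialData.empty(K)
    record = TrialRecord(design.design, None)
    for dose, size in initial_cohorts or []:
        outs = [draw(dose) for _ in range(size)]
        for out in outs:
            data = data.with_outcome(dose, out)
        record.allocations.append(dose)
        record.outcomes.append(outs)
    # estimates for the state after the run-in (or the prior state)
    rec = recommend(design, data, spec, skeleton, model)
    # states recorded from here on: one per model-guided cohort
    record.estimates = [None if rec.estimates is None else rec.estimates.copy()]
    record.selected = [rec.selected_m]
    # run-in cohorts precede the audited window; drop them from the per-cohort
    # lists so estimates/allocations stay aligned for auditing
    run_in = list(zip(record.allocations, record.outcomes))
    record.allocations, record.outcomes = [], []
    dose = rec.next_dose
    for _ in range(design.n_cohorts):
        outs = [draw(dose) for _ in range(design.cohort_size)]
        for out in outs:
            data = data.with_outcome(dose, out)
        record.allocations.append(dose)
        record.outcomes.append(outs)
        rec = recommend(design, data, spec, skeleton, model)
        record.estimates.append(None if rec.estimates is None else rec.estimates.copy())
        record.selected.append(rec.selected_m)
        dose = rec.next_dose
    if rec.estimates is not None:
        record.final_recommendation = allocate_next_dose(rec.estimates, design.theta)
    else:
        record.final_recommendation = rec.next_dose
    record.final_data = data
    record.run_in = run_in  # type: ignore[attr-defined]
    return record
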