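"""Sequential-trial simulation and operating characteristics.

Trials are simulated one cohort at a time: the design's estimation rule is
refitted after every cohort and the allocation criterion picks the next dose.
Outcomes are pre-drawn as independent per-dose Bernoulli *streams* so that the
j-th patient ever assigned to a dose receives the same outcome under every
design sharing the stream (common random numbers), which removes outcome
noise from design comparisons.

Operating characteristics follow the usual Phase I vocabulary: PCS (correct
selections: recommended dose's true toxicity equals the target), PAS
(acceptable: true toxicity within [theta-0.1, theta] — the interval is
deliberately asymmetric), POTS (overly toxic selections: true toxicity above
110% of the target), NPTOT (patients treated at overly toxic doses), plus
estimation-incoherency statistics and the RMSE of the final estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coherency import DEFAULT_THRESHOLD, audit_trial, CoherencyReport
from .data import TrialData
from .designs import DesignConfig, Recommendation, allocate_next_dose, recommend
from .exceptions import InvalidParameterError
from .models import WorkingModelConfig
from .orderings import DoseGrid, PartialOrderSpec, comparability_sets
from .skeleton import Skeleton

__all__ = [
    "Scenario",
    "TrialRecord",
    "OperatingCharacteristics",
    "draw_outcome_streams",
    "run_trial",
    "operating_characteristics",
    "generate_scenarios",
    "compare_designs",
]

SCENARIO_FAMILIES = ("zero_correct", "one_correct", "two_correct", "all_toxic", "all_safe")


@dataclass(frozen=True)
class Scenario:
    """A simulation truth: per-dose DLT probabilities and the target rate."""

    true_R: tuple[float, ...]
    theta: float
    grid: DoseGrid
    label: str = ""

    def __post_init__(self) -> None:
        R = np.asarray(self.true_R, dtype=float)
        if R.size != self.grid.K:
            raise InvalidParameterError("true_R length must match the grid")
        if np.any(R <= 0.0) or np.any(R >= 1.0):
            raise InvalidParameterError("true toxicity probabilities must be in (0, 1)")

    @property
    def R(self) -> np.ndarray:
        return np.asarray(self.true_R, dtype=float)

    def to_dict(self) -> dict:
        return {
            "true_R": list(self.true_R),
            "theta": self.theta,
            "grid": [self.grid.n_rows, self.grid.n_cols],
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(
            tuple(float(v) for v in d["true_R"]),
            float(d["theta"]),
            DoseGrid(*d["grid"]),
            d.get("label", ""),
        )


@dataclass
class TrialRecord:
    """Full trajectory of one simulated or replayed trial.

    ``estimates`` and ``selected`` have one entry per *state*: index 0 is the
    prior state (before any data), index c the state after cohort c.  For
    designs without averaged estimates (dose-voting) the estimate entries are
    None.
    """

    design: str
    seed: int | None
    allocations: list[int] = field(default_factory=list)
    outcomes: list[list[int]] = field(default_factory=list)
    estimates: list[np.ndarray | None] = field(default_factory=list)
    selected: list[int | None] = field(default_factory=list)
    final_recommendation: int = -1
    final_data: TrialData | None = None

    @property
    def n_cohorts(self) -> int:
        return len(self.allocations)

    def patients_at(self, K: int) -> np.ndarray:
        n = np.zeros(K, dtype=int)
        for d, outs in zip(self.allocations, self.outcomes):
            n[d - 1] += len(outs)
        return n


def draw_outcome_streams(true_R, n_patients: int, seed) -> np.ndarray:
    """(K, n_patients) array of pre-drawn Bernoulli outcomes per dose."""
    R = np.asarray(true_R, dtype=float)
    rng = np.random.default_rng(seed)
    return (rng.random((R.size, n_patients)) < R[:, None]).astype(int)


def run_trial(
    scenario: Scenario,
    design: DesignConfig,
    spec: PartialOrderSpec,
    skeleton: Skeleton,
    model: WorkingModelConfig,
    seed=None,
    streams: np.ndarray | None = None,
) -> TrialRecord:
    """Simulate one trial; fully reproducible from (seed, configs).

    ``streams`` may be supplied to share outcomes across designs (common
    random numbers); otherwise they are drawn from ``seed``.
    """
    K = spec.K
    total = design.n_cohorts * design.cohort_size
    if streams is None:
        streams = draw_outcome_streams(scenario.R, total, seed)
    if streams.shape[0] != K or streams.shape[1] < total:
        raise InvalidParameterError("streams shape inconsistent with design")
    consumed = np.zeros(K, dtype=int)
    data = TrialData.empty(K)
    record = TrialRecord(design.design, seed if isinstance(seed, int) else None)
    rec = recommend(design, data, spec, skeleton, model)
    record.estimates.append(None if rec.estimates is None else rec.estimates.copy())
    record.selected.append(rec.selected_m)
    dose = design.start_dose
    for _ in range(design.n_cohorts):
        outs = []
        for _ in range(design.cohort_size):
            out = int(streams[dose - 1, consumed[dose - 1]])
            consumed[dose - 1] += 1
            data = data.with_outcome(dose, out)
            outs.append(out)
        record.allocations.append(dose)
        record.outcomes.append(outs)
        rec = recommend(design, data, spec, skeleton, model)
        record.estimates.append(None if rec.estimates is None else rec.estimates.copy())
        record.selected.append(rec.selected_m)
        dose = rec.next_dose
    # final MTD recommendation: the allocation rule applied once more, with
    # no skipping clamp (all doses have been estimable throughout)
    if rec.estimates is not None:
        record.final_recommendation = allocate_next_dose(rec.estimates, design.theta)
    else:
        record.final_recommendation = rec.next_dose
    record.final_data = data
    return record


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Aggregate metrics over repeated simulated trials."""

    pcs: float
    pas: float
    pots: float
    nptot: float
    incoherency_trial_fraction: float
    mean_incoherent_cohorts: float
    max_incoherent_magnitude: float
    rmse: tuple[float, ...]
    mean_rmse: float
    n_trials: int

    def to_dict(self) -> dict:
        return {
            "pcs": self.pcs, "pas": self.pas, "pots": self.pots,
            "nptot": self.nptot,
            "incoherency_trial_fraction": self.incoherency_trial_fraction,
            "mean_incoherent_cohorts": self.mean_incoherent_cohorts,
            "max_incoherent_magnitude": self.max_incoherent_magnitude,
            "rmse": list(self.rmse), "mean_rmse": self.mean_rmse,
            "n_trials": self.n_trials,
        }


def operating_characteristics(
    records: list[TrialRecord],
    scenario: Scenario,
    spec: PartialOrderSpec | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    sided: str = "two",
    overdose_factor: float = 1.1,
    pas_interval: tuple[float, float] | None = None,
) -> OperatingCharacteristics:
    """Selection, safety, incoherency and estimation metrics for one scenario.

    A *correct* selection is a recommended dose whose true toxicity equals the
    target exactly (to 1e-9); an *overly toxic* dose has true toxicity above
    ``overdose_factor * theta``.  ``pas_interval`` defaults to
    ``[theta - 0.1, theta]``.
    """
    if not records:
        raise InvalidParameterError("no trial records supplied")
    R = scenario.R
    theta = scenario.theta
    lo, hi = pas_interval if pas_interval is not None else (theta - 0.1, theta)
    toxic = R > overdose_factor * theta
    n_trials = len(records)
    pcs = np.mean([abs(R[r.final_recommendation - 1] - theta) <= 1e-9 for r in records])
    pas = np.mean([lo - 1e-12 <= R[r.final_recommendation - 1] <= hi + 1e-12 for r in records])
    pots = np.mean([toxic[r.final_recommendation - 1] for r in records])
    nptot = np.mean([int(r.patients_at(R.size)[toxic].sum()) for r in records])
    inc_frac = inc_cohorts = inc_max = float("nan")
    if spec is not None and all(r.estimates[0] is not None for r in records):
        sets = comparability_sets(spec)
        reports = [audit_trial(r, sets, threshold=threshold, sided=sided) for r in records]
        inc_frac = np.mean([rep.any_incoherent for rep in reports])
        inc_cohorts = np.mean([rep.n_cohorts_with_event for rep in reports])
        inc_max = max((rep.max_magnitude for rep in reports), default=0.0)
    if all(r.estimates[-1] is not None for r in records):
        final = np.stack([r.estimates[-1] for r in records])
        rmse = np.sqrt(np.mean((final - R[None, :]) ** 2, axis=0))
    else:
        rmse = np.full(R.size, np.nan)
    return OperatingCharacteristics(
        float(pcs), float(pas), float(pots), float(nptot),
        float(inc_frac), float(inc_cohorts), float(inc_max),
        tuple(float(v) for v in rmse), float(np.mean(rmse)), n_trials,
    )


# -- synthetic scenario generation ------------------------------------------

def _values_along_ordering(
    rng: np.random.Generator, K: int, theta: float, mtd_rank: int
) -> np.ndarray:
    """Strictly increasing toxicity values with the dose at ``mtd_rank`` == theta."""
    gaps = rng.uniform(0.04, 0.11, size=K - 1)
    vals = np.empty(K)
    vals[mtd_rank - 1] = theta
    for k in range(mtd_rank - 1, 0, -1):
        vals[k - 1] = vals[k] - gaps[k - 1]
    for k in range(mtd_rank, K):
        vals[k] = vals[k - 1] + gaps[k - 1]
    return np.clip(vals, 0.01, 0.95)


def _sorting_orderings(spec: PartialOrderSpec, R: np.ndarray) -> list[int]:
    """1-based indices of candidate orderings that strictly sort ``R``."""
    out = []
    for m, o in enumerate(spec.orderings, start=1):
        seq = np.asarray(o.sequence) - 1
        if np.all(np.diff(R[seq]) > 0):
            out.append(m)
    return out


def generate_scenarios(
    grid: DoseGrid,
    theta: float,
    family: str,
    seed,
    spec: PartialOrderSpec | None = None,
    n_scenarios: int = 1,
) -> list[Scenario]:
    """Synthetic scenario families with controlled ordering agreement.

    ``zero/one/two_correct`` control how many candidate orderings (counting
    duplicates) strictly rank-sort the true toxicities; ``all_toxic`` makes
    every dose overly toxic (true toxicity > 1.1*theta) and ``all_safe``
    keeps every dose below the target.  All families are monotone within each
    drug margin.  ``spec`` defaults to the grid's six-ordering scheme.
    """
    from .orderings import enumerate_matrix_orderings

    if family not in SCENARIO_FAMILIES:
        raise InvalidParameterError(f"unknown scenario family {family!r}")
    if spec is None:
        spec = PartialOrderSpec.uniform(enumerate_matrix_orderings(grid), grid=grid)
    K = grid.K
    rng = np.random.default_rng(seed)
    # ordering indices by multiplicity of their permutation in the candidate set
    counts: dict[tuple[int, ...], int] = {}
    for o in spec.orderings:
        counts[o.sequence] = counts.get(o.sequence, 0) + 1
    once = [m for m, o in enumerate(spec.orderings, 1) if counts[o.sequence] == 1]
    twice = [m for m, o in enumerate(spec.orderings, 1) if counts[o.sequence] == 2]
    if family == "one_correct" and not once:
        raise InvalidParameterError("no ordering appears exactly once in the candidate set")
    if family == "two_correct" and not twice:
        raise InvalidParameterError("no ordering appears exactly twice in the candidate set")

    scenarios: list[Scenario] = []
    attempts = 0
    while len(scenarios) < n_scenarios:
        attempts += 1
        if attempts > 200 * n_scenarios:
            raise InvalidParameterError(f"family {family!r} infeasible for this grid")
        if family in ("one_correct", "two_correct", "zero_correct"):
            pool = once if family == "one_correct" else (twice or once)
            m = int(rng.choice(pool))
            seq = np.asarray(spec.orderings[m - 1].sequence) - 1
            mtd_rank = int(rng.integers(2, K))  # keep the MTD off the extremes
            vals = _values_along_ordering(rng, K, theta, mtd_rank)
            R = np.empty(K)
            R[seq] = vals
            if family == "zero_correct":
                # tie an incomparable adjacent pair so no total order sorts R
                pair = None
                for p in range(K - 1):
                    ka, kb = int(seq[p]) + 1, int(seq[p + 1]) + 1
                    if p + 1 != mtd_rank and p + 2 != mtd_rank and not _comparable(spec, ka, kb):
                        pair = (ka, kb)
                        break
                if pair is None:
                    continue
                R[pair[1] - 1] = R[pair[0] - 1]
            n_sort = len(_sorting_orderings(spec, R))
            want = {"zero_correct": 0, "one_correct": 1, "two_correct": 2}[family]
            if n_sort != want:
                continue
        elif family == "all_toxic":
            base = 1.1 * theta + 0.05
            if base >= 0.9:
                raise InvalidParameterError("all_toxic infeasible: theta too large")
            m = int(rng.integers(1, spec.M + 1))
            seq = np.asarray(spec.orderings[m - 1].sequence) - 1
            vals = base + np.concatenate([[0.0], np.cumsum(rng.uniform(0.01, (0.93 - base) / K, K - 1))])
            R = np.empty(K)
            R[seq] = np.clip(vals, base, 0.95)
        else:  # all_safe
            hi = theta - 0.02
            m = int(rng.integers(1, spec.M + 1))
            seq = np.asarray(spec.orderings[m - 1].sequence) - 1
            vals = np.sort(rng.uniform(0.01, hi, K))
            if np.any(np.diff(vals) <= 0):
                continue
            R = np.empty(K)
            R[seq] = vals
        scenarios.append(Scenario(
            tuple(float(v) for v in R), theta, grid,
            label=f"{family}_{len(scenarios) + 1}",
        ))
    return scenarios


def _comparable(spec: PartialOrderSpec, ka: int, kb: int) -> bool:
    ranks = spec.rank_matrix()
    d = ranks[:, ka - 1] - ranks[:, kb - 1]
    return bool(np.all(d < 0) or np.all(d > 0))


def compare_designs(
    scenarios: list[Scenario],
    designs: list[DesignConfig],
    spec: PartialOrderSpec,
    skeleton: Skeleton,
    model: WorkingModelConfig,
    n_reps: int,
    seed: int,
    threshold: float = DEFAULT_THRESHOLD,
    sided: str = "two",
) -> pd.DataFrame:
    """Tidy table of operating characteristics, paired across designs.

    Every design sees the same pre-drawn outcome streams within a replicate
    (common random numbers).  Returns one row per (scenario, design, metric),
    plus cross-scenario arithmetic means labelled scenario ``"mean"``.
    """
    rows = []
    per_design_metrics: dict[str, dict[str, list[float]]] = {}
    for sc_idx, scenario in enumerate(scenarios):
        records: dict[str, list[TrialRecord]] = {d.design: [] for d in designs}
        for rep in range(n_reps):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(sc_idx, rep))
            total = max(d.n_cohorts * d.cohort_size for d in designs)
            streams = draw_outcome_streams(scenario.R, total, ss)
            for d in designs:
                records[d.design].append(
                    run_trial(scenario, d, spec, skeleton, model, seed=None, streams=streams)
                )
        for d in designs:
            ocs = operating_characteristics(
                records[d.design], scenario, spec=spec, threshold=threshold, sided=sided
            )
            metrics = {
                "pcs": ocs.pcs, "pas": ocs.pas, "pots": ocs.pots, "nptot": ocs.nptot,
                "incoherency_trial_fraction": ocs.incoherency_trial_fraction,
                "mean_incoherent_cohorts": ocs.mean_incoherent_cohorts,
                "max_incoherent_magnitude": ocs.max_incoherent_magnitude,
                "mean_rmse": ocs.mean_rmse,
            }
            store = per_design_metrics.setdefault(d.design, {})
            for name, value in metrics.items():
                rows.append({
                    "scenario": scenario.label or f"scenario_{sc_idx + 1}",
                    "design": d.design, "metric": name, "value": value,
                })
                store.setdefault(name, []).append(value)
    for design_name, store in per_design_metrics.items():
        for name, values in store.items():
            rows.append({
                "scenario": "mean", "design": design_name,
                "metric": name, "value": float(np.mean(values)),
            })
    return pd.DataFrame(rows)
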