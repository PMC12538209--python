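"""Estimation-coherency auditing and 2x2 coherency conditions.

*Estimation coherency* demands that after a non-DLT at dose ``d_i`` the
toxicity estimates of every dose that is comparable to ``d_i`` under all
candidate orderings do not rise, and after a DLT do not fall.  The two-sided
form audits the union ``nu_i | xi_i`` of universally-less-toxic and
universally-more-toxic doses in both directions; the one-sided form only
checks ``nu_i`` after a non-DLT and ``xi_i`` after a DLT.

For 2x2 grids with the two monotone orderings and the plain power model
``psi = alpha**a`` there are closed-form sufficient conditions for the
coherency of model selection and of model averaging, built from the plug-in
exponent sets ``A_m = {log R_k / log alpha_{m,k}}``; these are implemented as
runnable checkers returning the verdict plus all intermediate quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError
from .orderings import ComparabilitySets

__all__ = [
    "CoherencyEvent",
    "CoherencyReport",
    "detect_incoherencies",
    "audit_trial",
    "pocrm_2x2_condition",
    "bma_2x2_condition",
    "magnitude_bound_check",
]

DEFAULT_THRESHOLD = 0.001  # numerical-noise guard on estimate changes


@dataclass(frozen=True)
class CoherencyEvent:
    """One incoherent estimate update.

    ``direction`` is ``"rise-after-nonDLT"`` or ``"fall-after-DLT"``;
    ``magnitude`` is the absolute wrong-direction change.
    ``ordering_changed`` records whether the selected ordering changed at this
    update (meaningful for model selection; None when unknown).
    """

    cohort: int
    administered_dose: int
    outcome: int
    violating_dose: int
    direction: str
    magnitude: float
    ordering_changed: bool | None = None


@dataclass(frozen=True)
class CoherencyReport:
    """Aggregate of the incoherencies found in one trial."""

    events: tuple[CoherencyEvent, ...]
    n_cohorts: int
    n_cohorts_with_event: int
    max_magnitude: float
    fraction_coinciding_with_ordering_change: float | None

    @property
    def any_incoherent(self) -> bool:
        return len(self.events) > 0


def detect_incoherencies(
    prev_estimates,
    new_estimates,
    administered_dose: int,
    outcome: int,
    sets: ComparabilitySets,
    threshold: float = DEFAULT_THRESHOLD,
    sided: str = "two",
    cohort: int = -1,
    ordering_changed: bool | None = None,
) -> list[CoherencyEvent]:
    """Flag wrong-direction estimate changes at universally comparable doses.

    After a non-DLT (outcome 0) at ``administered_dose``, a rise beyond
    ``threshold`` at any dose in the audited set is incoherent; after a DLT
    (outcome 1), a fall is.  ``sided="two"`` audits ``nu | xi``; ``"one"``
    audits ``nu`` after a non-DLT and ``xi`` after a DLT.
    """
    prev = np.asarray(prev_estimates, dtype=float)
    new = np.asarray(new_estimates, dtype=float)
    if prev.shape != new.shape:
        raise InvalidParameterError("estimate vectors must have equal length")
    K = prev.size
    if not 1 <= administered_dose <= K:
        raise InvalidParameterError(f"administered dose {administered_dose} outside 1..{K}")
    if threshold < 0:
        raise InvalidParameterError("threshold must be >= 0")
    if sided not in ("one", "two"):
        raise InvalidParameterError("sided must be 'one' or 'two'")
    i = administered_dose
    if sided == "two":
        audited = sets.combined(i)
    else:
        audited = sets.nu[i - 1] if outcome == 0 else sets.xi[i - 1]
    delta = new - prev
    events: list[CoherencyEvent] = []
    for j in sorted(audited):
        change = float(delta[j - 1])
        if outcome == 0 and change > threshold:
            events.append(CoherencyEvent(
                cohort, i, outcome, j, "rise-after-nonDLT", change, ordering_changed
            ))
        elif outcome == 1 and -change > threshold:
            events.append(CoherencyEvent(
                cohort, i, outcome, j, "fall-after-DLT", -change, ordering_changed
            ))
    return events


def audit_trial(
    record,
    sets: ComparabilitySets,
    threshold: float = DEFAULT_THRESHOLD,
    sided: str = "two",
) -> CoherencyReport:
    """Audit a whole trial trajectory for estimation incoherencies.

    ``record`` must expose per-cohort ``allocations`` and ``outcomes``,
    ``estimates`` (one vector per state, index 0 = prior state, so one more
    entry than cohorts) and optionally ``selected`` orderings per state
    (same layout as estimates; None entries for averaged designs).

    Updates whose cohort mixes DLT and non-DLT outcomes have no single audit
    direction and are skipped; with cohorts of size one (the usual setting)
    every update is audited.
    """
    allocations = list(record.allocations)
    outcomes = [list(np.atleast_1d(o)) for o in record.outcomes]
    estimates = list(record.estimates)
    selected = list(getattr(record, "selected", None) or [None] * len(estimates))
    n_cohorts = len(allocations)
    if len(estimates) != n_cohorts + 1:
        raise InvalidParameterError(
            "need one estimate vector per state (prior + one per cohort)"
        )
    events: list[CoherencyEvent] = []
    cohorts_with_event: set[int] = set()
    for c in range(n_cohorts):
        outs = set(outcomes[c])
        if len(outs) != 1:
            continue  # mixed-outcome cohort: no single audit direction
        outcome = outs.pop()
        ordering_changed = None
        if selected[c] is not None and selected[c + 1] is not None:
            ordering_changed = selected[c + 1] != selected[c]
        found = detect_incoherencies(
            estimates[c], estimates[c + 1], allocations[c], outcome, sets,
            threshold=threshold, sided=sided, cohort=c + 1,
            ordering_changed=ordering_changed,
        )
        if found:
            cohorts_with_event.add(c + 1)
            events.extend(found)
    known = [e.ordering_changed for e in events if e.ordering_changed is not None]
    frac_change = (sum(known) / len(known)) if known else None
    return CoherencyReport(
        tuple(events),
        n_cohorts,
        len(cohorts_with_event),
        max((e.magnitude for e in events), default=0.0),
        frac_change,
    )


# -- 2x2 closed-form conditions ---------------------------------------------

def _check_2x2_inputs(alpha, true_R) -> tuple[np.ndarray, np.ndarray]:
    alpha = np.asarray(alpha, dtype=float)
    R = np.asarray(true_R, dtype=float)
    if alpha.shape != (4,) or R.shape != (4,):
        raise InvalidParameterError("2x2 conditions need 4-vectors")
    if np.any(alpha <= 0) or np.any(alpha >= 1) or np.any(R <= 0) or np.any(R >= 1):
        raise InvalidParameterError("skeleton and true probabilities must be in (0, 1)")
    if np.any(np.diff(alpha) <= 0):
        raise InvalidParameterError("skeleton must be strictly increasing")
    return alpha, R


def _exponent_sets(alpha: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Plug-in exponent sets under the two 2x2 orderings.

    Ordering 1 keeps the skeleton order; ordering 2 swaps the middle values
    (doses 2 and 3 are the incomparable diagonal pair).
    """
    logR = np.log(R)
    A1 = logR / np.log(alpha)
    a2 = alpha[[0, 2, 1, 3]]
    A2 = logR / np.log(a2)
    return A1, A2


def pocrm_2x2_condition(alpha, true_R) -> tuple[bool, dict]:
    """Sufficient condition for estimation coherency of model selection (2x2).

    Under the plain power model with both 2x2 orderings at equal prior weight,
    coherency holds when::

        alpha_3 ** a2_min <= alpha_2 ** a1_max
        alpha_3 ** a1_min <= alpha_2 ** a2_max

    where ``a_m_min/max`` are the extremes of the plug-in exponent set
    ``A_m = {log R_k / log alpha_{m,k}}``.  Returns the verdict and all
    intermediate quantities.
    """
    alpha, R = _check_2x2_inputs(alpha, true_R)
    A1, A2 = _exponent_sets(alpha, R)
    a1_min, a1_max = float(A1.min()), float(A1.max())
    a2_min, a2_max = float(A2.min()), float(A2.max())
    lhs1, rhs1 = alpha[2] ** a2_min, alpha[1] ** a1_max
    lhs2, rhs2 = alpha[2] ** a1_min, alpha[1] ** a2_max
    holds = bool(lhs1 <= rhs1 and lhs2 <= rhs2)
    return holds, {
        "A1": A1, "A2": A2,
        "a1_min": a1_min, "a1_max": a1_max,
        "a2_min": a2_min, "a2_max": a2_max,
        "inequalities": ((lhs1, rhs1), (lhs2, rhs2)),
    }


def bma_2x2_condition(alpha, true_R, u4_exponent: str = "a1_max") -> tuple[bool, dict]:
    """Sufficient condition for estimation coherency of model averaging (2x2).

    Evaluates, with ``A_m`` and extremes as in :func:`pocrm_2x2_condition`::

        1/(1 - log alpha_1) <= min( a3^{a2_min} (a3^{U1} - 1) / (1 - a2^{a1_min}/a3^{a2_max}),
                                    a3^{a1_min} (a3^{U2} - 1) / (1 - a2^{a2_min}/a3^{a1_max}) )
        1/(1 - log alpha_4) <= min( a3^{a2_min} (a3^{U3} - 1) / (1 - a2^{a1_min}/a3^{a2_max}),
                                    a3^{a1_min} (a3^{U4} - 1) / (1 - a2^{a2_min}/a3^{a1_max}) )

    with ``U1 = c1*a2_max - s1``, ``U2 = c1*a1_max - s1``,
    ``U3 = c4*a2_max - s4`` and ``U4 = c4*x - s4`` where
    ``c_q = (1 - 2 log alpha_q)/(1 - log alpha_q)``,
    ``s_q = 1/(1 - log alpha_q)**2``.  The exponent ``x`` entering ``U4`` is
    ambiguous in the source derivation; ``u4_exponent`` selects ``"a1_max"``
    (default, the choice symmetric with ``U2``) or ``"a2_max"``.
    """
    alpha, R = _check_2x2_inputs(alpha, true_R)
    if u4_exponent not in ("a1_max", "a2_max"):
        raise InvalidParameterError("u4_exponent must be 'a1_max' or 'a2_max'")
    A1, A2 = _exponent_sets(alpha, R)
    a1_min, a1_max = float(A1.min()), float(A1.max())
    a2_min, a2_max = float(A2.min()), float(A2.max())
    a2v, a3v = alpha[1], alpha[2]

    def coeff(aq: float) -> tuple[float, float]:
        la = np.log(aq)
        return (1.0 - 2.0 * la) / (1.0 - la), 1.0 / (1.0 - la) ** 2

    c1, s1 = coeff(alpha[0])
    c4, s4 = coeff(alpha[3])
    U1 = c1 * a2_max - s1
    U2 = c1 * a1_max - s1
    U3 = c4 * a2_max - s4
    U4 = c4 * (a1_max if u4_exponent == "a1_max" else a2_max) - s4
    den1 = 1.0 - a2v ** a1_min / a3v ** a2_max
    den2 = 1.0 - a2v ** a2_min / a3v ** a1_max
    with np.errstate(divide="ignore", invalid="ignore"):
        rhs_top = min(
            a3v ** a2_min * (a3v ** U1 - 1.0) / den1,
            a3v ** a1_min * (a3v ** U2 - 1.0) / den2,
        )
        rhs_bot = min(
            a3v ** a2_min * (a3v ** U3 - 1.0) / den1,
            a3v ** a1_min * (a3v ** U4 - 1.0) / den2,
        )
    lhs_top = 1.0 / (1.0 - np.log(alpha[0]))
    lhs_bot = 1.0 / (1.0 - np.log(alpha[3]))
    holds = bool(np.isfinite(rhs_top) and np.isfinite(rhs_bot)
                 and lhs_top <= rhs_top and lhs_bot <= rhs_bot)
    return holds, {
        "A1": A1, "A2": A2,
        "a1_min": a1_min, "a1_max": a1_max,
        "a2_min": a2_min, "a2_max": a2_max,
        "U": (U1, U2, U3, U4),
        "inequalities": ((lhs_top, float(rhs_top)), (lhs_bot, float(rhs_bot))),
    }


def magnitude_bound_check(
    alpha, events_pocrm, events_bma
) -> tuple[bool, dict]:
    """Check that averaged-design incoherencies shrink by 1/(1 - log alpha_K).

    When both the model-selection and the model-averaged design are
    incoherent at the same update, the averaged magnitude ``M_A`` must obey
    ``M_A <= M_S / (1 - log alpha_K)``.  Events are paired by cohort index
    (per-cohort magnitudes are the maxima across violating doses); cohorts
    with an event under only one design are skipped and reported.
    """
    alpha = np.asarray(alpha, dtype=float)
    factor = 1.0 / (1.0 - np.log(alpha[-1]))

    def per_cohort(events) -> dict[int, float]:
        out: dict[int, float] = {}
        for e in events:
            out[e.cohort] = max(out.get(e.cohort, 0.0), e.magnitude)
        return out

    ms = per_cohort(events_pocrm)
    ma = per_cohort(events_bma)
    shared = sorted(set(ms) & set(ma))
    skipped = sorted(set(ms) ^ set(ma))
    violations = [
        (c, ma[c], ms[c]) for c in shared if ma[c] > factor * ms[c] + 1e-12
    ]
    return len(violations) == 0, {
        "factor": float(factor),
        "paired_cohorts": shared,
        "skipped_cohorts": skipped,
        "violations": violations,
    }
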