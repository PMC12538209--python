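"""Toxicity skeletons for the one-parameter power working model.

A *skeleton* is a strictly increasing vector alpha_1 < ... < alpha_K in (0,1)
of prior guesses for the DLT probability at each toxicity position.  The
standard construction is the indifference-interval calibration of Lee & Cheung
(the ``getprior`` recipe): anchor the prior MTD position at the target rate
theta, then choose each neighbouring value so that at the model parameter
where one dose's estimated risk sits at theta - delta, the next dose's sits at
theta + delta.  Under the power model this makes the design indifferent
between adjacent doses exactly when their estimates straddle the target
symmetrically with halfwidth delta.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .exceptions import InvalidParameterError

__all__ = ["Skeleton", "indifference_interval_skeleton"]

_EPS = 1e-12


@dataclass(frozen=True)
class Skeleton:
    """Strictly increasing prior toxicity guesses in (0, 1)."""

    alpha: tuple[float, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        if a.ndim != 1 or a.size < 1:
            raise InvalidParameterError("skeleton must be a 1-D vector")
        if np.any(a <= 0.0) or np.any(a >= 1.0):
            raise InvalidParameterError("skeleton values must lie strictly in (0, 1)")
        if a.size > 1 and np.any(np.diff(a) <= 0.0):
            raise InvalidParameterError("skeleton must be strictly increasing")

    @property
    def K(self) -> int:
        return len(self.alpha)

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.alpha, dtype=float)

    def to_dict(self) -> dict:
        return {"alpha": [float(v) for v in self.alpha]}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "Skeleton":
        if "alpha" in d:
            return cls(tuple(float(v) for v in d["alpha"]))
        return indifference_interval_skeleton(
            K=int(d["K"]),
            target=float(d["target"]),
            halfwidth=float(d["halfwidth"]),
            prior_mtd=int(d["prior_mtd"]),
        )

    @classmethod
    def from_json(cls, path) -> "Skeleton":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "Skeleton":
        return cls(tuple(float(v) for v in values))


def _solve_power(exponent: float, prob: float, lo: float, hi: float) -> float:
    """Solve x**exponent = prob for x in (lo, hi) by bracketing."""
    f = lambda x: x ** exponent - prob
    lo = max(lo, _EPS)
    hi = min(hi, 1.0 - _EPS)
    if f(lo) * f(hi) > 0:
        raise InvalidParameterError(
            "indifference-interval recursion left (0, 1); "
            "halfwidth too large for this target"
        )
    return brentq(f, lo, hi, xtol=1e-12, rtol=8.881784197001252e-16)


def indifference_interval_skeleton(
    K: int, target: float, halfwidth: float, prior_mtd: int
) -> Skeleton:
    """Indifference-interval skeleton for the power model (the getprior recipe).

    Parameters
    ----------
    K : number of toxicity positions.
    target : target toxicity rate theta in (0, 1).
    halfwidth : indifference halfwidth delta, 0 < delta < min(theta, 1-theta).
    prior_mtd : 1-based position nu anchored at the target (alpha_nu = theta).

    Moving up from the anchor, ``alpha[k+1]`` solves
    ``alpha[k+1]**e = theta + delta`` at the power-model exponent ``e`` for
    which ``alpha[k]**e = theta - delta``; the mirrored recursion moves down.
    Each step is solved by 1-D root bracketing.
    """
    if K < 1:
        raise InvalidParameterError("K must be >= 1")
    if not 0.0 < target < 1.0:
        raise InvalidParameterError("target must be in (0, 1)")
    if not 0.0 < halfwidth < min(target, 1.0 - target):
        raise InvalidParameterError("need 0 < halfwidth < min(target, 1-target)")
    if not 1 <= prior_mtd <= K:
        raise InvalidParameterError(f"prior_mtd must be in 1..{K}")

    alpha = np.empty(K)
    alpha[prior_mtd - 1] = target
    for k in range(prior_mtd - 1, K - 1):
        e = np.log(target - halfwidth) / np.log(alpha[k])
        alpha[k + 1] = _solve_power(e, target + halfwidth, alpha[k], 1.0)
    for k in range(prior_mtd - 1, 0, -1):
        e = np.log(target + halfwidth) / np.log(alpha[k])
        alpha[k - 1] = _solve_power(e, target - halfwidth, 0.0, alpha[k])
    if np.any(alpha <= 0.0) or np.any(alpha >= 1.0) or (
        K > 1 and np.any(np.diff(alpha) <= 0.0)
    ):
        raise InvalidParameterError("skeleton recursion produced a non-monotone vector")
    return Skeleton(tuple(alpha))
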