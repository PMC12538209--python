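"""Sequential trial data: per-dose sufficient statistics plus patient order.

The binomial likelihood depends on the data only through the per-dose counts
``(n_k, y_k)``, but coherency auditing needs the patient-level sequence, so
both are carried.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

__all__ = ["TrialData"]


@dataclass(frozen=True)
class TrialData:
    """Per-dose patient and DLT counts, with an optional allocation history.

    ``history`` is an ordered tuple of ``(dose, outcome)`` pairs (1-based dose
    index, outcome 1 for a DLT).  When present it must reproduce ``(n, y)``.
    """

    n: tuple[int, ...]
    y: tuple[int, ...]
    history: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        n = np.asarray(self.n, dtype=int)
        y = np.asarray(self.y, dtype=int)
        if n.shape != y.shape or n.ndim != 1:
            raise InvalidParameterError("n and y must be 1-D vectors of equal length")
        if np.any(n < 0) or np.any(y < 0) or np.any(y > n):
            raise InvalidParameterError("need 0 <= y_k <= n_k for all doses")
        if self.history is not None:
            K = n.size
            nh = np.zeros(K, dtype=int)
            yh = np.zeros(K, dtype=int)
            for dose, out in self.history:
                if not 1 <= dose <= K:
                    raise InvalidParameterError(f"history dose {dose} outside 1..{K}")
                if out not in (0, 1):
                    raise InvalidParameterError("history outcomes must be 0/1")
                nh[dose - 1] += 1
                yh[dose - 1] += out
            if not (np.array_equal(nh, n) and np.array_equal(yh, y)):
                raise InvalidParameterError("history does not reproduce (n, y)")

    @property
    def K(self) -> int:
        return len(self.n)

    @property
    def n_patients(self) -> int:
        return int(sum(self.n))

    @property
    def n_arr(self) -> np.ndarray:
        return np.asarray(self.n, dtype=float)

    @property
    def y_arr(self) -> np.ndarray:
        return np.asarray(self.y, dtype=float)

    @classmethod
    def empty(cls, K: int) -> "TrialData":
        return cls(tuple([0] * K), tuple([0] * K), ())

    @classmethod
    def from_counts(cls, n, y) -> "TrialData":
        return cls(tuple(int(v) for v in n), tuple(int(v) for v in y))

    @classmethod
    def from_history(cls, K: int, pairs) -> "TrialData":
        n = [0] * K
        y = [0] * K
        hist = []
        for dose, out in pairs:
            n[dose - 1] += 1
            y[dose - 1] += int(out)
            hist.append((int(dose), int(out)))
        return cls(tuple(n), tuple(y), tuple(hist))

    def with_outcome(self, dose: int, outcome: int) -> "TrialData":
        """New TrialData with one more patient appended at ``dose``."""
        if not 1 <= dose <= self.K:
            raise InvalidParameterError(f"dose {dose} outside 1..{self.K}")
        n = list(self.n)
        y = list(self.y)
        n[dose - 1] += 1
        y[dose - 1] += int(outcome)
        hist = None if self.history is None else self.history + ((dose, int(outcome)),)
        return TrialData(tuple(n), tuple(y), hist)

    def to_dict(self) -> dict:
        d = {"n": list(self.n), "y": list(self.y)}
        if self.history is not None:
            d["history"] = [list(p) for p in self.history]
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "TrialData":
        hist = d.get("history")
        return cls(
            tuple(int(v) for v in d["n"]),
            tuple(int(v) for v in d["y"]),
            None if hist is None else tuple((int(a), int(b)) for a, b in hist),
        )

    @classmethod
    def from_json(cls, path) -> "TrialData":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
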