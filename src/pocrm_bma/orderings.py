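"""Dose grids, simple dose-toxicity orderings, and partial-ordering specifications.

In a two-drug combination trial the dose combinations live on an
``n_rows x n_cols`` grid (drug-A level by drug-B level).  Toxicity is assumed
monotone within each drug's margin, but diagonal moves (one drug up, the other
down) have no a-priori ordering, so several total orders of the grid — *simple
orderings* — are compatible with the data-generating truth.  A *partial-ordering
specification* is a list of candidate simple orderings with prior weights.

Dose indexing convention (used everywhere in this package): doses are numbered
1..K column-within-row starting from the bottom-left corner of the grid, i.e.
dose ``k = n_cols*(i-1) + j`` sits at drug-A level ``i`` and drug-B level ``j``.
For a 3x2 grid::

    drug A level 3 |  d5  d6
    drug A level 2 |  d3  d4
    drug A level 1 |  d1  d2
                      ------
          drug B:      1   2
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "DoseGrid",
    "SimpleOrdering",
    "PartialOrderSpec",
    "ComparabilitySets",
    "enumerate_matrix_orderings",
    "comparability_sets",
    "skeleton_under_ordering",
]


@dataclass(frozen=True)
class DoseGrid:
    """A rectangular drug-combination dose grid."""

    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidParameterError("grid dimensions must be >= 1")
        if self.n_rows * self.n_cols < 2:
            raise InvalidParameterError("grid must contain at least 2 doses")

    @property
    def K(self) -> int:
        return self.n_rows * self.n_cols

    def index(self, row: int, col: int) -> int:
        """1-based linear dose index of the combination (row, col)."""
        if not (1 <= row <= self.n_rows and 1 <= col <= self.n_cols):
            raise InvalidParameterError(f"({row}, {col}) outside {self.n_rows}x{self.n_cols} grid")
        return self.n_cols * (row - 1) + col

    def rowcol(self, k: int) -> tuple[int, int]:
        """Inverse of :meth:`index`."""
        if not 1 <= k <= self.K:
            raise InvalidParameterError(f"dose index {k} outside 1..{self.K}")
        return (k - 1) // self.n_cols + 1, (k - 1) % self.n_cols + 1


@dataclass(frozen=True)
class SimpleOrdering:
    """A total order of doses from least to most toxic.

    ``sequence[p]`` is the 1-based dose index occupying toxicity position
    ``p+1``; ``rank_of(k)`` is the position (1 = least toxic) of dose ``k``.
    """

    sequence: tuple[int, ...]

    def __post_init__(self) -> None:
        K = len(self.sequence)
        if sorted(self.sequence) != list(range(1, K + 1)):
            raise InvalidParameterError(f"sequence {self.sequence} is not a permutation of 1..{K}")

    @property
    def K(self) -> int:
        return len(self.sequence)

    @property
    def ranks(self) -> np.ndarray:
        """ranks[k-1] = toxicity position of dose k (1-based positions)."""
        r = np.empty(self.K, dtype=int)
        for pos, dose in enumerate(self.sequence, start=1):
            r[dose - 1] = pos
        return r

    def rank_of(self, dose: int) -> int:
        return int(self.ranks[dose - 1])

    def is_margin_monotone(self, grid: DoseGrid) -> bool:
        """True if ranks strictly increase along each single-drug margin."""
        ranks = self.ranks
        for i in range(1, grid.n_rows + 1):
            row = [ranks[grid.index(i, j) - 1] for j in range(1, grid.n_cols + 1)]
            if any(b <= a for a, b in zip(row, row[1:])):
                return False
        for j in range(1, grid.n_cols + 1):
            col = [ranks[grid.index(i, j) - 1] for i in range(1, grid.n_rows + 1)]
            if any(b <= a for a, b in zip(col, col[1:])):
                return False
        return True


@dataclass
class PartialOrderSpec:
    """Candidate simple orderings with prior weights.

    Duplicate orderings are retained verbatim: listing an ordering twice
    intentionally doubles its prior weight under a uniform prior.  Use
    :meth:`deduplicate` to merge duplicates (weights are summed).
    """

    orderings: list[SimpleOrdering]
    prior_weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    grid: DoseGrid | None = None

    def __post_init__(self) -> None:
        if len(self.orderings) < 1:
            raise InvalidParameterError("at least one ordering is required")
        K = self.orderings[0].K
        if any(o.K != K for o in self.orderings):
            raise InvalidParameterError("orderings have inconsistent K")
        if self.prior_weights is None:
            self.prior_weights = np.full(len(self.orderings), 1.0 / len(self.orderings))
        self.prior_weights = np.asarray(self.prior_weights, dtype=float)
        if self.prior_weights.shape != (len(self.orderings),):
            raise InvalidParameterError("prior_weights length must match orderings")
        if np.any(self.prior_weights < 0):
            raise InvalidParameterError("prior weights must be nonnegative")
        if abs(self.prior_weights.sum() - 1.0) > 1e-12:
            raise InvalidParameterError("prior weights must sum to 1 (within 1e-12)")

    @property
    def M(self) -> int:
        return len(self.orderings)

    @property
    def K(self) -> int:
        return self.orderings[0].K

    def rank_matrix(self) -> np.ndarray:
        """(M, K) array of toxicity positions; row m gives ranks of doses 1..K."""
        return np.stack([o.ranks for o in self.orderings])

    def deduplicate(self) -> "PartialOrderSpec":
        seen: dict[tuple[int, ...], int] = {}
        orderings: list[SimpleOrdering] = []
        weights: list[float] = []
        for o, w in zip(self.orderings, self.prior_weights):
            if o.sequence in seen:
                weights[seen[o.sequence]] += w
            else:
                seen[o.sequence] = len(orderings)
                orderings.append(o)
                weights.append(float(w))
        return PartialOrderSpec(orderings, np.asarray(weights), grid=self.grid)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "K": self.K,
            "orderings": [list(o.sequence) for o in self.orderings],
            "prior_weights": [float(w) for w in self.prior_weights],
        }
        if self.grid is not None:
            d["grid"] = [self.grid.n_rows, self.grid.n_cols]
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PartialOrderSpec":
        orderings = [SimpleOrdering(tuple(seq)) for seq in d["orderings"]]
        weights = d.get("prior_weights")
        grid = DoseGrid(*d["grid"]) if "grid" in d else None
        return cls(orderings, None if weights is None else np.asarray(weights), grid=grid)

    @classmethod
    def from_json(cls, path) -> "PartialOrderSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def uniform(cls, orderings: Iterable[SimpleOrdering], grid: DoseGrid | None = None) -> "PartialOrderSpec":
        return cls(list(orderings), None, grid=grid)


@dataclass(frozen=True)
class ComparabilitySets:
    """Per-dose sets of universally comparable doses.

    ``nu[k-1]`` holds the doses less toxic than dose k under *every* candidate
    ordering; ``xi[k-1]`` the doses more toxic under every candidate ordering.
    Doses outside both sets are incomparable with k under the partial order.
    """

    nu: tuple[frozenset[int], ...]
    xi: tuple[frozenset[int], ...]

    def combined(self, k: int) -> frozenset[int]:
        return self.nu[k - 1] | self.xi[k - 1]


def comparability_sets(spec: PartialOrderSpec) -> ComparabilitySets:
    """Compute the universally-less/more-toxic sets from the candidate orderings."""
    ranks = spec.rank_matrix()  # (M, K)
    K = spec.K
    nu, xi = [], []
    for i in range(K):
        less = frozenset(
            j + 1 for j in range(K) if j != i and np.all(ranks[:, j] < ranks[:, i])
        )
        more = frozenset(
            j + 1 for j in range(K) if j != i and np.all(ranks[:, j] > ranks[:, i])
        )
        nu.append(less)
        xi.append(more)
    return ComparabilitySets(tuple(nu), tuple(xi))


def skeleton_under_ordering(alpha: Sequence[float], ordering: SimpleOrdering) -> np.ndarray:
    """Permute skeleton values onto doses: dose k receives ``alpha[rank_of(k)-1]``."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (ordering.K,):
        raise InvalidParameterError(
            f"skeleton length {alpha.shape} does not match K={ordering.K}"
        )
    return alpha[ordering.ranks - 1]


# -- ordering enumeration ---------------------------------------------------

def _diagonals(grid: DoseGrid) -> list[list[int]]:
    """Anti-diagonals (constant row+col), each listed from low drug-A row upward."""
    diags: list[list[int]] = []
    for s in range(2, grid.n_rows + grid.n_cols + 1):
        d = [
            grid.index(i, s - i)
            for i in range(1, grid.n_rows + 1)
            if 1 <= s - i <= grid.n_cols
        ]
        diags.append(d)
    return diags


def enumerate_matrix_orderings(grid: DoseGrid) -> list[SimpleOrdering]:
    """The six-ordering scheme for a rectangular dose grid.

    The candidates are: by rows, by columns, up-down the anti-diagonals,
    down-up the anti-diagonals, and the two alternating-diagonal variants.
    For a 2x2 grid the scheme collapses to the two distinct monotone orderings
    (each appearing three times), which are returned deduplicated with equal
    weight; duplicates are retained for every other grid shape (on 3x2 the
    by-rows and down-up-diagonal orderings coincide, so that ordering carries
    double prior weight under a uniform prior — this is deliberate).
    Degenerate single-row/column grids have a unique monotone ordering.
    """
    if grid.K < 2:
        raise InvalidParameterError("grid too small: need at least 2 doses")
    by_rows = [grid.index(i, j) for i in range(1, grid.n_rows + 1) for j in range(1, grid.n_cols + 1)]
    if grid.n_rows == 1 or grid.n_cols == 1:
        return [SimpleOrdering(tuple(by_rows))]
    by_cols = [grid.index(i, j) for j in range(1, grid.n_cols + 1) for i in range(1, grid.n_rows + 1)]
    diags = _diagonals(grid)
    # "up" traverses a diagonal from high drug-A level to low (reversed list),
    # "down" from low to high.
    up_down = [k for d in diags for k in d[::-1]]
    down_up = [k for d in diags for k in d]
    alt_down_up = [k for t, d in enumerate(diags) for k in (d if t % 2 == 1 else d[::-1])]
    alt_up_down = [k for t, d in enumerate(diags) for k in (d[::-1] if t % 2 == 1 else d)]
    # Ordering of the candidates matters for reproducibility: rows, columns,
    # up-down, down-up, then the two alternating variants.
    seqs = [by_rows, by_cols, up_down, down_up, alt_down_up, alt_up_down]
    orderings = [SimpleOrdering(tuple(s)) for s in seqs]
    bad = [o for o in orderings if not o.is_margin_monotone(grid)]
    if bad:  # pragma: no cover - construction guarantees monotonicity
        raise InvalidParameterError(f"non-monotone ordering constructed: {bad}")
    if (grid.n_rows, grid.n_cols) == (2, 2):
        unique: list[SimpleOrdering] = []
        for o in orderings:
            if all(o.sequence != u.sequence for u in unique):
                unique.append(o)
        return unique
    return orderings
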