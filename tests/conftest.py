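import numpy as np
import pytest

from pocrm_bma import (
    DoseGrid,
    PartialOrderSpec,
    Skeleton,
    TrialData,
    WorkingModelConfig,
    comparability_sets,
    enumerate_matrix_orderings,
    worked_example,
)


@pytest.fixture(scope="session")
def ex():
    """The shipped worked example (3x2 grid, TTR 0.4)."""
    return worked_example()


@pytest.fixture(scope="session")
def ex_sets(ex):
    return comparability_sets(ex.spec)


@pytest.fixture(scope="session")
def two_by_two():
    """2x2 grid with its two monotone orderings and the plain power model."""
    grid = DoseGrid(2, 2)
    spec = PartialOrderSpec.uniform(enumerate_matrix_orderings(grid), grid=grid)
    skeleton = Skeleton.from_values((0.1, 0.2, 0.3, 0.4))
    model = WorkingModelConfig(parametrization="power_plain")
    return grid, spec, skeleton, model


def random_counts(rng: np.random.Generator, K: int, max_n: int = 4) -> TrialData:
    """A random small per-dose count dataset."""
    n = rng.integers(0, max_n, K)
    y = np.array([rng.integers(0, nk + 1) for nk in n])
    return TrialData.from_counts(n, y)


@pytest.fixture(scope="session")
def rspace_rule():
    """Graded Gauss-Legendre panels covering (0, 1) down to the float floor.

    Used to integrate the mixture density in the risk variable itself — the
    independent route for checking the a-space expectations.
    """
    lo = np.logspace(-280, np.log10(0.5), 400)
    hi = 1.0 - np.logspace(-15, np.log10(0.5), 80)[::-1]
    edges = np.unique(np.concatenate([lo, hi]))
    x, w = np.polynomial.legendre.leggauss(12)
    los, his = edges[:-1], edges[1:]
    mid = 0.5 * (los + his)
    half = 0.5 * (his - los)
    r = (mid[:, None] + half[:, None] * x[None, :]).ravel()
    wt = (half[:, None] * w[None, :]).ravel()
    return r, wt
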