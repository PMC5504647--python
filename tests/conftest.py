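import numpy as np
import pytest
from hypothesis import settings

from moremc import FullAtomModel, ToyComplexSpec, make_toy_complex

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy():
    """Small planted-pocket complex shared across tests (seed fixed)."""
    return make_toy_complex(ToyComplexSpec(seed=0))


@pytest.fixture(scope="session")
def model():
    return FullAtomModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_front(points: np.ndarray, maxX: bool, maxY: bool) -> set[tuple[float, float]]:
    """O(n^2) non-dominated scan, independent of the package's sweep.

    Exact duplicates are collapsed first (mirroring the push-order collapse
    rule); orientation handled by sign flips.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    sx = -1.0 if maxX else 1.0
    sy = -1.0 if maxY else 1.0
    q = np.column_stack([sx * pts[:, 0], sy * pts[:, 1]])
    keep = []
    for i in range(len(q)):
        le = (q[:, 0] <= q[i, 0]) & (q[:, 1] <= q[i, 1])
        lt = (q[:, 0] < q[i, 0]) | (q[:, 1] < q[i, 1])
        if not np.any(le & lt):
            keep.append(i)
    return {(pts[i, 0], pts[i, 1]) for i in keep}
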