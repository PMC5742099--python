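import numpy as np
import pytest

from sbnfuse import (
    CohortParams,
    WeightedNetwork,
    generate_cohort,
    generate_roi_geometry,
)


def random_network(n: int, seed: int, density: float = 1.0) -> WeightedNetwork:
    """Random symmetric nonnegative test graph."""
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.1, 1.0, (n, n))
    if density < 1.0:
        mask = rng.random((n, n)) < density
        w = np.where(mask, w, 0.0)
    w = np.triu(w, 1)
    return WeightedNetwork(w + w.T)


@pytest.fixture
def small_geometry():
    return generate_roi_geometry(12, seed=11)


@pytest.fixture
def small_cohort(small_geometry):
    """2 subjects x 2 scans on 12 ROIs — the smallest complete design."""
    params = CohortParams(scan_noise=0.1)
    return generate_cohort(2, 2, small_geometry, params, seed=7)


@pytest.fixture
def k2_pair():
    """Two-node graphs with weights 1 and 2 — closed-form gDDM case."""
    w1 = WeightedNetwork(np.array([[0.0, 1.0], [1.0, 0.0]]))
    w2 = WeightedNetwork(np.array([[0.0, 2.0], [2.0, 0.0]]))
    return w1, w2
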