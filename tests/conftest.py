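import numpy as np
import pytest

from chandelier.skeleton import SkeletonGraph
from chandelier.synthetic import load_preset, generate_structural_population


@pytest.fixture
def chain_skeleton():
    """Straight 50-node chain along +y at 1 um spacing (nm units)."""
    n = 50
    pos = np.zeros((n, 3))
    pos[:, 1] = np.arange(n) * 1000.0
    edges = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    return SkeletonGraph(
        positions=pos, radii=np.full(n, 500.0), edges=edges
    )


@pytest.fixture(scope="session")
def paper_population():
    """One calibrated-preset population shared across read-only tests."""
    params = load_preset("paper")
    params.seed = 42
    return generate_structural_population(params)
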