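import numpy as np
import pytest

from virogenescape import SimulationConfig, StrataMap, Tree, simulate_dataset
from virogenescape.synthetic_data import DEFAULT_FOCAL, DEFAULT_TREE_NEWICK


def random_tree_newick(rng: np.random.Generator, n_leaves: int, scale: float = 1.0) -> str:
    """Random binary topology by iterative joining, with positive lengths."""
    parts = [f"L{i}:{rng.integers(1, 20) * 0.1 * scale:.4f}" for i in range(n_leaves)]
    while len(parts) > 2:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b}):{rng.integers(1, 20) * 0.1 * scale:.4f}")
    return f"({parts[0]},{parts[1]});"


@pytest.fixture(scope="session")
def default_tree() -> Tree:
    return Tree.from_newick(DEFAULT_TREE_NEWICK)


@pytest.fixture(scope="session")
def default_strata(default_tree):
    return StrataMap.identity(default_tree, DEFAULT_FOCAL)


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated genomic-accordion dataset under the study conditions."""
    return simulate_dataset(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def lossless_dataset():
    """Simulation without gene loss: presence sets match birth clades exactly."""
    return simulate_dataset(SimulationConfig(seed=42, loss_rate=0.0))
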