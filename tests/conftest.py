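import numpy as np
import pytest

from clonedelim import SimulationConfig, generate_synthetic_germline_set, simulate_repertoire
from clonedelim.trees import PhyloTree


def random_binary_tree(n_leaves: int, rng: np.random.Generator, mean_edge: float = 0.5) -> PhyloTree:
    """Random-join rooted binary tree with exponential edge lengths."""
    nodes = [PhyloTree(name=f"L{i}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        a.length = float(rng.exponential(mean_edge))
        b.length = float(rng.exponential(mean_edge))
        nodes.append(PhyloTree(children=[a, b]))
    nodes[0].length = None
    return nodes[0]


def two_regime_tree(
    n_families: int,
    leaves_per_family: int,
    speciation_rate: float,
    coalescent_rate: float,
    rng: np.random.Generator,
) -> PhyloTree:
    """Backbone edges ~ Exp(speciation_rate), within-clade edges ~ Exp(coalescent_rate)."""

    def join_all(nodes, rate):
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            b = nodes.pop(int(j))
            a = nodes.pop(int(i))
            a.length = float(rng.exponential(1.0 / rate))
            b.length = float(rng.exponential(1.0 / rate))
            nodes.append(PhyloTree(children=[a, b]))
        return nodes[0]

    clades = [
        join_all([PhyloTree(name=f"f{f}_l{i}") for i in range(leaves_per_family)], coalescent_rate)
        for f in range(n_families)
    ]
    root = join_all(clades, speciation_rate)
    root.length = None
    return root


@pytest.fixture(scope="session")
def germline_small():
    return generate_synthetic_germline_set(5, 3, 2, seed=1)


@pytest.fixture(scope="session")
def repertoire_low_shm(germline_small):
    """16 families, geometric mean 10 leaves, SHM 0.001, whole-sequence scope."""
    config = SimulationConfig(n_families=16, mean_leaves=10, shm_rate=0.001, seed=3)
    return simulate_repertoire(config, germline_small)


@pytest.fixture(scope="session")
def repertoire_high_shm(germline_small):
    config = SimulationConfig(n_families=16, mean_leaves=10, shm_rate=0.2, seed=4)
    return simulate_repertoire(config, germline_small)
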