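import numpy as np
import pytest

from taxogen import (
    SimulationConfig,
    extract_core,
    mcl_cluster,
    presence_matrix,
    score_protein_pairs,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 12 genomes, 3 clades, 1 synonym pair."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def pangenome_products(default_dataset):
    genomes, truth = default_dataset
    graph = score_protein_pairs(genomes)
    families = mcl_cluster(graph)
    matrix = presence_matrix(families, sorted(genomes))
    core = extract_core(matrix)
    return graph, families, matrix, core


@pytest.fixture(scope="session")
def truth_partition(default_dataset):
    """Planted family -> set of gene IDs."""
    _genomes, truth = default_dataset
    part: dict[str, set[str]] = {}
    for gid, fam in truth.gene_map.items():
        part.setdefault(fam, set()).add(gid)
    return part


def random_binary_tree(n_leaves: int, rng: np.random.Generator):
    """Random rooted binary tree newick with unit-scale branch lengths."""
    units = [f"t{i}" for i in range(n_leaves)]
    while len(units) > 1:
        j, k = sorted(rng.choice(len(units), size=2, replace=False))
        a, b = units[j], units[k]
        la, lb = rng.uniform(0.1, 1.0, size=2)
        merged = f"({a}:{la:.4f},{b}:{lb:.4f})"
        units = [u for i, u in enumerate(units) if i not in (j, k)]
        units.append(merged)
    return units[0] + ";"
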