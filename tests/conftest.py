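import numpy as np
import pandas as pd
import pytest

from microslope.containers import AbundanceTable, SignedNetwork
from microslope.synthetic import (
    generate_kingdom_trees,
    generate_truth_network,
    simulate_abundances,
    simulate_functions,
)


def make_metadata(n_samples: int) -> pd.DataFrame:
    per = n_samples // 3
    rows = []
    for p_idx, pos in enumerate(("top", "middle", "bottom")):
        for r in range(per + (1 if p_idx < n_samples - 3 * per else 0)):
            if len(rows) >= n_samples:
                break
            i = len(rows) + 1
            rows.append({"sample": f"S{i:02d}", "position": pos, "plot": f"P{i:02d}"})
    while len(rows) < n_samples:
        i = len(rows) + 1
        rows.append({"sample": f"S{i:02d}", "position": "bottom", "plot": f"P{i:02d}"})
    return pd.DataFrame(rows).set_index("sample")


def make_table(matrix, kingdoms=None, sample_ids=None, taxon_ids=None):
    """Small AbundanceTable from a plain matrix."""
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    sample_ids = sample_ids or [f"S{i + 1:02d}" for i in range(n)]
    taxon_ids = taxon_ids or [f"T{j + 1:03d}" for j in range(p)]
    if kingdoms is None:
        kingdoms = ["bacteria"] * p
    data = pd.DataFrame(matrix, index=sample_ids, columns=taxon_ids)
    meta = make_metadata(n)
    meta.index = sample_ids
    return AbundanceTable(data, pd.Series(kingdoms, index=taxon_ids), meta)


@pytest.fixture(scope="session")
def small_world():
    """A small three-kingdom synthetic dataset shared across tests."""
    truth = generate_truth_network(
        {"bacteria": 25, "rhizobia": 10, "am_fungi": 8}, seed=42
    )
    trees = generate_kingdom_trees(truth, seed=42)
    tables = simulate_abundances(truth, trees, scenario="selection", seed=43)
    functions = simulate_functions(tables, truth, noise_sd=0.5, seed=44)
    return {"truth": truth, "trees": trees, "tables": tables, "functions": functions}


@pytest.fixture
def toy_network():
    """5-node, 4-edge signed network with mixed kingdoms."""
    nodes = {
        "A": "bacteria",
        "B": "bacteria",
        "C": "am_fungi",
        "D": "am_fungi",
        "E": "rhizobia",
    }
    edges = [
        ("A", "B", 1, 0.5),
        ("B", "C", -1, 0.3),
        ("C", "D", 1, 0.2),
        ("A", "E", -1, 0.1),
    ]
    return SignedNetwork(nodes, edges)
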