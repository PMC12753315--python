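import numpy as np
import pytest

from synbench.data_model import (CellLineSynergyNetwork, SynergyTriplet,
                                 TripletTable)


@pytest.fixture
def toy_table() -> TripletTable:
    """3 drugs x 2 cell lines, all pairs present in c1, one pair in c2."""
    rows = [("A", "B", "c1", 1.0), ("A", "C", "c1", -2.0),
            ("B", "C", "c1", 3.0), ("A", "B", "c2", 4.0)]
    return TripletTable([SynergyTriplet.make(*r) for r in rows])


@pytest.fixture
def random_table() -> TripletTable:
    """Denser random table: 10 drugs x 3 cell lines, ~60% of pairs."""
    rng = np.random.default_rng(42)
    drugs = [f"d{i}" for i in range(10)]
    cells = ["c1", "c2", "c3"]
    triplets = []
    for c in cells:
        for i in range(len(drugs)):
            for j in range(i + 1, len(drugs)):
                if rng.random() < 0.6:
                    triplets.append(SynergyTriplet.make(
                        drugs[i], drugs[j], c, float(rng.normal(0, 10))))
    return TripletTable(triplets)


def random_signed_network(seed: int, n_nodes: int = 20,
                          density: float = 0.4) -> CellLineSynergyNetwork:
    rng = np.random.default_rng(seed)
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < density:
                edges.append((nodes[i], nodes[j], float(rng.normal(0, 5))))
    return CellLineSynergyNetwork(cell_line=f"cell{seed}", nodes=set(nodes),
                                  edges=edges)
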