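import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mirpath.io import GeneSet, PairedExpressionMatrix, WeightedGeneNetwork


def make_network(edges) -> WeightedGeneNetwork:
    """Build a weighted network from (u, v, weight) triples."""
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return WeightedGeneNetwork(g)


def make_matrix(case, control, feature_ids=None, log2_scale=True) -> PairedExpressionMatrix:
    """Paired matrix from features-by-subjects case and control arrays."""
    case = np.atleast_2d(np.asarray(case, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    n_f, n_p = case.shape
    feature_ids = feature_ids or [f"F{i+1:03d}" for i in range(n_f)]
    subjects = [f"P{j+1:02d}" for j in range(n_p)]
    cols, ids, meta = [], [], []
    for j, s in enumerate(subjects):
        ids += [f"{s}_case", f"{s}_ctrl"]
        cols += [case[:, j], control[:, j]]
        meta += [(f"{s}_case", s, "case"), (f"{s}_ctrl", s, "control")]
    values = pd.DataFrame(np.column_stack(cols), index=feature_ids, columns=ids)
    pairing = pd.DataFrame(meta, columns=["sample_id", "subject_id", "condition"]).set_index(
        "sample_id")
    return PairedExpressionMatrix(values=values, pairing=pairing, log2_scale=log2_scale)


@pytest.fixture
def two_node_network():
    return make_network([("A", "B", 1.0)])


@pytest.fixture
def star_network():
    return make_network([("HUB", f"L{i}", 1.0) for i in range(1, 5)])


@pytest.fixture
def seed_a():
    return GeneSet.from_iterable("seed", ["A"])
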