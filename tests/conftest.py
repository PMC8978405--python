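import numpy as np
import pytest

from dtlink import FixtureSpec, SimilarityGraph, gen_compounds, gen_interactions, gen_proteins


@pytest.fixture(scope="session")
def small_fixture():
    """A small planted-structure dataset shared across tests."""
    spec = FixtureSpec(
        n_drugs=24, n_proteins=18, n_drug_clusters=3, n_protein_families=2,
        sequence_length=60, seed=11,
    )
    compounds, drug_truth = gen_compounds(spec)
    proteins, prot_truth = gen_proteins(spec)
    table = gen_interactions(spec, compounds, proteins, drug_truth, prot_truth)
    return spec, compounds, proteins, table, drug_truth, prot_truth


@pytest.fixture
def two_clique_graph():
    """Two 10-cliques joined by a single bridge edge."""
    n = 20
    w = np.zeros((n, n))
    w[:10, :10] = 1.0
    w[10:, 10:] = 1.0
    w[9, 10] = w[10, 9] = 1.0
    np.fill_diagonal(w, 1.0)
    ids = [f"n{i:02d}" for i in range(n)]
    return SimilarityGraph(node_ids=ids, weights=w, kind="drug")


@pytest.fixture
def triangle_pendant_graph():
    """Triangle a-b-c with a pendant node d attached to b (unit weights)."""
    ids = ["a", "b", "c", "d"]
    w = np.eye(4)
    for i, j in [(0, 1), (1, 2), (0, 2), (1, 3)]:
        w[i, j] = w[j, i] = 1.0
    return SimilarityGraph(node_ids=ids, weights=w, kind="drug")
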