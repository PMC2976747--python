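import networkx as nx
import numpy as np
import pytest

from coexdiff import ExpressionMatrix, GeneNetwork


def make_expr(values, gene_ids=None, n_affected=None, prefix="S"):
    """Expression matrix from a raw array; first half of samples affected."""
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    gene_ids = gene_ids or [f"G{i:03d}" for i in range(1, m + 1)]
    if n_affected is None:
        n_affected = n // 2
    samples = [f"{prefix}{i:03d}" for i in range(1, n + 1)]
    groups = {
        s: ("affected" if i < n_affected else "control")
        for i, s in enumerate(samples)
    }
    return ExpressionMatrix(gene_ids, samples, values, groups)


def random_network(m, p, rng, gene_ids=None):
    """Erdos-Renyi network via networkx (independent of package builders)."""
    g = nx.gnp_random_graph(m, p, seed=int(rng.integers(2**31)))
    gene_ids = gene_ids or [f"G{i:03d}" for i in range(1, m + 1)]
    edges = [(gene_ids[a], gene_ids[b]) for a, b in g.edges()]
    return GeneNetwork.from_edges(gene_ids, edges)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
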