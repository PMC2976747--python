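"""Correlation, neighbour ranking and the two rank-and-threshold edge rules."""

import numpy as np
import pytest

from coexdiff import (
    EdgeRuleConfig,
    build_network,
    correlation_matrix,
    network_from_correlation,
    rank_neighbours,
)

from conftest import make_expr


def oracle_edges(r, gene_ids, cfg):
    """Exhaustive pairwise evaluation of both conditions in both directions."""
    m = len(gene_ids)
    sim = np.abs(r) if cfg.use_absolute_correlation else r

    def topk(i, k):
        others = sorted(
            (j for j in range(m) if j != i),
            key=lambda j: (-sim[i][j], gene_ids[j]),
        )
        return set(others[:k])

    edges = set()
    for i in range(m):
        for j in range(i + 1, m):
            c1 = sim[i][j] >= cfg.base_threshold and (
                j in topk(i, cfg.top_k_strict) or i in topk(j, cfg.top_k_strict)
            )
            c2 = sim[i][j] >= cfg.high_threshold and (
                j in topk(i, cfg.top_k_relaxed) or i in topk(j, cfg.top_k_relaxed)
            )
            if c1 or c2:
                edges.add((i, j))
    return edges


def adjacency_edges(net):
    return set(zip(*np.nonzero(np.triu(net.adjacency, k=1))))


def corr_with_row(values_a, row_genes):
    """4-gene correlation matrix with given first-row correlations."""
    m = len(values_a) + 1
    r = np.full((m, m), 0.1)
    np.fill_diagonal(r, 1.0)
    for j, v in enumerate(values_a, start=1):
        r[0, j] = r[j, 0] = v
    return r, ["A"] + row_genes


class TestCorrelationMatrix:
    def test_duplicated_gene_has_unit_correlation(self, rng):
        x = rng.standard_normal(6)
        expr = make_expr(np.vstack([x, x, rng.standard_normal(6)]))
        r = correlation_matrix(expr)
        assert r[0, 1] == pytest.approx(1.0)

    def test_negated_gene_has_minus_one(self, rng):
        x = rng.standard_normal(6)
        expr = make_expr(np.vstack([x, -x]))
        r = correlation_matrix(expr)
        assert r[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        values = rng.standard_normal((5, 6))
        r = correlation_matrix(make_expr(values))
        for i in range(5):
            for j in range(5):
                xi = values[i] - values[i].mean()
                xj = values[j] - values[j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert r[i, j] == pytest.approx(expected)

    def test_zero_variance_gene_named(self, rng):
        values = rng.standard_normal((3, 5))
        values[1] = 7.0
        with pytest.raises(ValueError, match="G002"):
            correlation_matrix(make_expr(values))

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError, match=">= 3 samples"):
            correlation_matrix(make_expr(rng.standard_normal((4, 2))))


class TestRankNeighbours:
    def test_descending_correlation_order(self):
        r, ids = corr_with_row([0.4, 0.32, 0.3], ["B", "C", "D"])
        assert rank_neighbours(r, ids, "A") == ["B", "C", "D"]

    def test_all_equal_falls_back_to_id_order(self):
        r, ids = corr_with_row([0.5, 0.5, 0.5], ["D", "C", "B"])
        assert rank_neighbours(r, ids, "A") == ["B", "C", "D"]

    def test_agrees_with_sorting_oracle(self, rng):
        m = 12
        r = np.round(rng.uniform(-1, 1, size=(m, m)), 2)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        ids = [f"G{i:02d}" for i in range(m)]
        for gene in ids[:4]:
            i = ids.index(gene)
            expected = sorted((j for j in range(m) if j != i),
                              key=lambda j: (-r[i][j], ids[j]))
            assert rank_neighbours(r, ids, gene) == [ids[j] for j in expected]


class TestEdgeConditions:
    def test_three_candidates_above_base_all_link(self):
        r, ids = corr_with_row([0.3, 0.32, 0.4], ["B", "C", "D"])
        net = network_from_correlation(r, ids)
        assert net.degrees()[0] == 3

    def test_only_threshold_clearing_candidate_links(self):
        r, ids = corr_with_row([0.3, 0.28, 0.29], ["B", "C", "D"])
        net = network_from_correlation(r, ids)
        assert net.degrees()[0] == 1
        assert net.neighbours("A") == ["B"]

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError, match="empty gene set"):
            network_from_correlation(np.zeros((0, 0)), [])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        expr = make_expr(rng.standard_normal((8, 6)))
        cfg = EdgeRuleConfig(high_threshold=0.7, top_k_relaxed=5)
        net = build_network(expr, cfg)
        r = correlation_matrix(expr)
        assert adjacency_edges(net) == oracle_edges(r, expr.gene_ids, cfg)

    def test_absolute_mode_matches_oracle(self, rng):
        expr = make_expr(rng.standard_normal((8, 6)))
        cfg = EdgeRuleConfig(use_absolute_correlation=True)
        net = build_network(expr, cfg)
        r = correlation_matrix(expr)
        assert adjacency_edges(net) == oracle_edges(r, expr.gene_ids, cfg)


class TestNetworkProperties:
    def test_simple_undirected_binary(self, rng):
        net = build_network(make_expr(rng.standard_normal((15, 8))))
        assert np.array_equal(net.adjacency, net.adjacency.T)
        assert net.adjacency.trace() == 0
        assert set(np.unique(net.adjacency)) <= {0, 1}

    def test_both_conditions_superset_of_condition_one(self, rng):
        expr = make_expr(rng.standard_normal((20, 8)))
        both = build_network(expr, EdgeRuleConfig(high_threshold=0.6))
        # pushing the relaxed rule out of reach leaves condition 1 alone
        only1 = build_network(
            expr, EdgeRuleConfig(high_threshold=0.999, top_k_relaxed=1)
        )
        assert adjacency_edges(both) >= adjacency_edges(only1)

    def test_raising_t_never_adds_edges(self, rng):
        expr = make_expr(rng.standard_normal((20, 8)))
        low = build_network(expr, EdgeRuleConfig(high_threshold=0.5))
        high = build_network(expr, EdgeRuleConfig(high_threshold=0.8))
        assert adjacency_edges(high) <= adjacency_edges(low)

    def test_minimum_degree_when_top3_clear_base(self):
        # Block design where every gene's top-3 correlations exceed 0.3 and
        # nothing reaches the condition-2 threshold.
        rng = np.random.default_rng(11)
        factors = rng.standard_normal((5, 60))
        block = np.repeat(np.arange(5), 6)
        values = np.sqrt(0.45) * factors[block] + np.sqrt(0.55) * (
            rng.standard_normal((30, 60))
        )
        expr = make_expr(values)
        r = correlation_matrix(expr)
        top3 = np.sort(np.where(np.eye(30, dtype=bool), -np.inf, r), axis=1)[:, -3]
        assert top3.min() >= 0.3 and r[~np.eye(30, dtype=bool)].max() < 0.7
        net = build_network(expr)
        assert net.degrees().min() >= 3
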