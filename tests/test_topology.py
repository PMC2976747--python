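"""Cross-network topological overlap, zero-overlap genes, degree contrasts."""

import numpy as np
import pytest

from coexdiff import (
    GeneNetwork,
    degree_report,
    to_profile,
    topological_overlap,
    topological_overlap_min,
    zero_to_genes,
)

from conftest import random_network


def star_pair():
    """Hub gene with 200 neighbours in net1, the first 10 of them in net2."""
    nodes = ["HUB"] + [f"N{i:03d}" for i in range(1, 201)] + ["PAD"]
    net1 = GeneNetwork.from_edges(nodes, [("HUB", n) for n in nodes[1:201]])
    net2 = GeneNetwork.from_edges(nodes, [("HUB", n) for n in nodes[1:11]])
    return net1, net2


def oracle_profile(net1, net2):
    """Per-gene set-operations oracle via explicit neighbour sets."""
    g1, g2 = net1.to_networkx(), net2.to_networkx()
    out = {}
    for gene in net1.gene_ids:
        x, y = set(g1.neighbors(gene)), set(g2.neighbors(gene))
        inter = len(x & y)
        dmax, dmin = max(len(x), len(y)), min(len(x), len(y))
        out[gene] = (
            len(x), len(y), inter,
            round(inter / dmax, 4) if dmax else 0.0,
            round(inter / dmin, 4) if dmin else 0.0,
        )
    return out


class TestWorkedExample:
    def test_wide_hub_with_conserved_core_scores_five_percent(self):
        net1, net2 = star_pair()
        entry = topological_overlap(net1, net2, "HUB")
        assert (entry.d1, entry.d2, entry.overlap) == (200, 10, 10)
        assert entry.to == 0.05

    def test_min_denominator_variant_saturates(self):
        net1, net2 = star_pair()
        assert topological_overlap_min(net1, net2, "HUB") == 1.0


class TestProfile:
    def test_identical_networks_score_one(self, rng):
        net = random_network(25, 0.3, rng)
        profile = to_profile(net, net)
        active = profile[~profile["isolated"]]
        assert (active["to"] == 1.0).all()
        assert (active["to_min"] == 1.0).all()

    def test_disjoint_neighbourhoods_score_zero(self):
        nodes = ["A", "B", "C", "D", "E"]
        net1 = GeneNetwork.from_edges(nodes, [("A", "B"), ("A", "C")])
        net2 = GeneNetwork.from_edges(nodes, [("A", "D"), ("A", "E")])
        assert topological_overlap(net1, net2, "A").to == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_set_operations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net1 = random_network(30, 0.2, rng)
        net2 = random_network(30, 0.2, rng, gene_ids=net1.gene_ids)
        profile = to_profile(net1, net2).set_index("gene")
        oracle = oracle_profile(net1, net2)
        for gene, (d1, d2, inter, to, to_min) in oracle.items():
            row = profile.loc[gene]
            assert (row["d1"], row["d2"], row["overlap"]) == (d1, d2, inter)
            assert row["to"] == to
            assert row["to_min"] == to_min

    def test_symmetric_in_network_order(self, rng):
        net1 = random_network(20, 0.25, rng)
        net2 = random_network(20, 0.25, rng, gene_ids=net1.gene_ids)
        fwd = to_profile(net1, net2)
        rev = to_profile(net2, net1)
        np.testing.assert_array_equal(fwd["to"], rev["to"])
        np.testing.assert_array_equal(fwd["d1"], rev["d2"])

    def test_max_denominator_never_exceeds_min_variant(self, rng):
        for _ in range(5):
            net1 = random_network(20, 0.3, rng)
            net2 = random_network(20, 0.3, rng, gene_ids=net1.gene_ids)
            profile = to_profile(net1, net2)
            assert (profile["to"] <= profile["to_min"] + 1e-12).all()
            assert profile["to"].between(0, 1).all()

    def test_shared_edge_addition_never_decreases_to(self, rng):
        net1 = random_network(15, 0.4, rng)
        net2 = random_network(15, 0.2, rng, gene_ids=net1.gene_ids)
        a1, a2 = net1.adjacency, net2.adjacency
        candidates = np.argwhere((a1 == 1) & (a2 == 0))
        assert len(candidates)
        i, j = candidates[0]
        before = to_profile(net1, net2).set_index("gene")
        grown = a2.copy()
        grown[i, j] = grown[j, i] = 1
        after = to_profile(net1, GeneNetwork(net2.gene_ids, grown)).set_index("gene")
        gene = net1.gene_ids[i]
        assert after.loc[gene, "to"] >= before.loc[gene, "to"]

    def test_mismatched_node_sets_rejected(self, rng):
        net1 = random_network(10, 0.3, rng)
        net2 = random_network(10, 0.3, rng, gene_ids=[f"X{i}" for i in range(10)])
        with pytest.raises(ValueError, match="identical ordered gene set"):
            to_profile(net1, net2)


class TestZeroTO:
    def test_identical_networks_yield_none(self, rng):
        net = random_network(20, 0.3, rng)
        assert zero_to_genes(to_profile(net, net)) == []

    def test_matches_brute_force_filter(self, rng):
        net1 = random_network(30, 0.1, rng)
        net2 = random_network(30, 0.1, rng, gene_ids=net1.gene_ids)
        profile = to_profile(net1, net2)
        oracle = oracle_profile(net1, net2)
        expected = [g for g in net1.gene_ids
                    if oracle[g][2] == 0 and (oracle[g][0] or oracle[g][1])]
        assert zero_to_genes(profile) == expected

    def test_isolated_in_both_excluded(self):
        nodes = ["A", "B", "C", "LONER"]
        net1 = GeneNetwork.from_edges(nodes, [("A", "B")])
        net2 = GeneNetwork.from_edges(nodes, [("A", "C")])
        zero = zero_to_genes(to_profile(net1, net2))
        assert "LONER" not in zero
        assert "A" in zero  # active in both with disjoint neighbourhoods

    def test_positive_threshold_selects_low_to(self):
        net1, net2 = star_pair()
        profile = to_profile(net1, net2)
        assert "HUB" not in zero_to_genes(profile, to_threshold=0.0)
        assert "HUB" in zero_to_genes(profile, to_threshold=0.05)


class TestDegreeReport:
    def test_identical_networks_all_zero(self, rng):
        net = random_network(15, 0.3, rng)
        report = degree_report(net, net)
        assert (report["abs_diff"] == 0).all()

    def test_constructed_contrast_sorts_first(self):
        nodes = [f"G{i:02d}" for i in range(30)]
        net1 = GeneNetwork.from_edges(nodes, [("G00", n) for n in nodes[1:4]])
        net2 = GeneNetwork.from_edges(nodes, [("G00", n) for n in nodes[1:25]])
        report = degree_report(net1, net2)
        top = report.iloc[0]
        assert (top["gene"], top["d1"], top["d2"], top["abs_diff"]) == \
            ("G00", 3, 24, 21)

    def test_sorted_against_naive_recomputation(self, rng):
        net1 = random_network(25, 0.2, rng)
        net2 = random_network(25, 0.3, rng, gene_ids=net1.gene_ids)
        report = degree_report(net1, net2)
        naive = sorted(
            zip(net1.gene_ids, net1.degrees(), net2.degrees()),
            key=lambda row: (-abs(row[1] - row[2]), row[0]),
        )
        assert report["gene"].tolist() == [g for g, *_ in naive]

    def test_subset_restriction(self, rng):
        net1 = random_network(10, 0.4, rng)
        net2 = random_network(10, 0.4, rng, gene_ids=net1.gene_ids)
        subset = net1.gene_ids[:3]
        report = degree_report(net1, net2, subset)
        assert set(report["gene"]) == set(subset)
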