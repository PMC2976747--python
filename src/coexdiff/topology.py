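"""Cross-network topological overlap and zero-overlap gene selection.

For a gene *g* present in two networks over the same node set, let X and Y
be its neighbour sets and d1, d2 its degrees.  The topological overlap is

    TO(g) = |X ∩ Y| / max(d1, d2)

The *larger* degree in the denominator is deliberate: it measures what
fraction of the gene's widest neighbourhood is conserved, so a gene with 200
neighbours in one network and 10 in the other — of which all 10 are shared —
scores 0.05 (5% of the wide neighbourhood conserved), not 1.  The
min-denominator variant is provided for comparison.  TO values are rounded
to 4 decimal places for reporting; zero-overlap selection tests the integer
intersection size exactly, so rounding is purely cosmetic.

Genes isolated in both networks have no neighbourhoods to compare; their TO
is defined as 0 but they are flagged and excluded from zero-overlap output.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .types import GeneNetwork


class TOEntry(NamedTuple):
    gene: str
    d1: int
    d2: int
    overlap: int
    to: float
    to_min: float
    isolated: bool


def _check_same_nodes(net1: GeneNetwork, net2: GeneNetwork) -> None:
    if net1.gene_ids != net2.gene_ids:
        raise ValueError("networks must share an identical ordered gene set")


def to_profile(net1: GeneNetwork, net2: GeneNetwork) -> pd.DataFrame:
    """Per-gene topological overlap between two networks on the same nodes.

    Returns a DataFrame in node order with columns ``gene``, ``d1``, ``d2``,
    ``overlap`` (|X ∩ Y|), ``to`` (max-denominator, rounded to 4 decimals),
    ``to_min`` (min-denominator variant) and ``isolated``.  Symmetric in the
    network order up to swapping the two degree columns.
    """
    _check_same_nodes(net1, net2)
    a1 = net1.adjacency.astype(bool)
    a2 = net2.adjacency.astype(bool)
    d1 = a1.sum(axis=1).astype(int)
    d2 = a2.sum(axis=1).astype(int)
    overlap = (a1 & a2).sum(axis=1).astype(int)
    dmax = np.maximum(d1, d2)
    dmin = np.minimum(d1, d2)
    with np.errstate(invalid="ignore", divide="ignore"):
        to = np.where(dmax > 0, overlap / np.where(dmax > 0, dmax, 1), 0.0)
        to_min = np.where(dmin > 0, overlap / np.where(dmin > 0, dmin, 1), 0.0)
    return pd.DataFrame(
        {
            "gene": net1.gene_ids,
            "d1": d1,
            "d2": d2,
            "overlap": overlap,
            "to": np.round(to, 4),
            "to_min": np.round(to_min, 4),
            "isolated": (d1 == 0) & (d2 == 0),
        }
    )


def _single(net1: GeneNetwork, net2: GeneNetwork, gene: str) -> TOEntry:
    _check_same_nodes(net1, net2)
    if gene not in net1.gene_ids:
        raise ValueError(f"gene {gene!r} not in the networks' node set")
    profile = to_profile(net1, net2)
    row = profile.loc[profile["gene"] == gene].iloc[0]
    return TOEntry(
        gene, int(row.d1), int(row.d2), int(row.overlap),
        float(row.to), float(row.to_min), bool(row.isolated),
    )


def topological_overlap(net1: GeneNetwork, net2: GeneNetwork, gene: str) -> TOEntry:
    """Topological overlap record for one gene (max-denominator in ``to``)."""
    return _single(net1, net2, gene)


def topological_overlap_min(net1: GeneNetwork, net2: GeneNetwork, gene: str) -> float:
    """Min-denominator overlap ratio for one gene (comparison variant only)."""
    return _single(net1, net2, gene).to_min


def zero_to_genes(profile: pd.DataFrame, to_threshold: float = 0.0) -> list[str]:
    """Genes whose neighbourhoods share no members between the two networks.

    At the default threshold 0 the test is ``overlap == 0`` exactly (integer,
    unaffected by rounding); a positive threshold instead selects
    ``to <= to_threshold``.  Genes isolated in both networks are excluded —
    they have no neighbourhoods to diverge.
    """
    active = ~profile["isolated"]
    if to_threshold == 0.0:
        mask = (profile["overlap"] == 0) & active
    else:
        mask = (profile["to"] <= to_threshold) & active
    return profile.loc[mask, "gene"].tolist()


def isolated_genes(profile: pd.DataFrame) -> list[str]:
    """Genes with no neighbours in either network (reported separately)."""
    return profile.loc[profile["isolated"], "gene"].tolist()


def degree_report(
    net1: GeneNetwork,
    net2: GeneNetwork,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Connectivity contrast table: (gene, d1, d2, |d1 - d2|).

    Sorted by descending absolute degree difference (ties by gene ID); large
    differences flag genes whose co-expression activity shifts between the
    two conditions.
    """
    _check_same_nodes(net1, net2)
    d1 = net1.degrees()
    d2 = net2.degrees()
    table = pd.DataFrame(
        {"gene": net1.gene_ids, "d1": d1, "d2": d2, "abs_diff": np.abs(d1 - d2)}
    )
    if genes is not None:
        wanted = set(genes)
        unknown = wanted - set(net1.gene_ids)
        if unknown:
            raise ValueError(f"genes not in node set: {sorted(unknown)[:5]}")
        table = table[table["gene"].isin(wanted)]
    return (
        table.sort_values(["abs_diff", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )
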