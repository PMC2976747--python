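"""Degree-preserving randomization null for the zero-overlap gene count.

The question: is the observed number of zero-topological-overlap genes lower
than expected if the two networks shared only their degree sequences?  Each
null replicate rewires the networks by repeated double-edge swaps — pick two
disjoint edges (a,b), (c,d) and replace them with (a,d), (c,b) whenever that
creates no self-loop or duplicate edge — which randomizes topology while
keeping every gene's degree exactly equal to the original.  The observed
count is compared to the null replicate counts with a two-sample t-statistic

    t = |mu1 - mu2| / (SD * sqrt(1/n1 + 1/n2))

where mu1 is the observed count (one real network pair, n2 = 1), mu2 and SD
are the mean and standard deviation of the n1 null counts (n1 = 1000 by
default), and the two-sided p-value comes from the t distribution with
n1 + n2 - 2 degrees of freedom (999 at the default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import GeneNetwork
from .topology import to_profile, zero_to_genes


@dataclass
class NullSummary:
    """Observed zero-overlap count against its rewiring null distribution."""

    observed_zero_to: int
    null_counts: np.ndarray
    mu2: float
    sd: float
    t_stat: float
    df: int
    p_value: float
    seed: int | None = None
    n_random: int = field(init=False)

    def __post_init__(self) -> None:
        self.null_counts = np.asarray(self.null_counts)
        self.n_random = len(self.null_counts)

    def to_dict(self) -> dict:
        return {
            "observed_zero_to": int(self.observed_zero_to),
            "n_random": int(self.n_random),
            "null_mean": float(self.mu2),
            "null_sd": float(self.sd),
            "t_statistic": float(self.t_stat),
            "df": int(self.df),
            "p_value": float(self.p_value),
            "seed": self.seed,
        }


def rewire(
    net: GeneNetwork,
    seed: int | None = None,
    swap_factor: int = 10,
    rng: np.random.Generator | None = None,
) -> GeneNetwork:
    """Randomize a network while preserving every gene's degree exactly.

    Attempts ``swap_factor * n_edges`` double-edge swaps; invalid proposals
    (shared endpoints, would duplicate an edge) are skipped.  A graph that
    admits no valid swap (e.g. a triangle, the unique simple graph with its
    degree sequence) is returned unchanged with a warning.  Seeded and
    deterministic.
    """
    if net.n_edges < 2:
        warnings.warn("fewer than 2 edges: nothing to rewire, returning a copy")
        return GeneNetwork(net.gene_ids, net.adjacency.copy(), dict(net.fingerprint))
    if rng is None:
        rng = np.random.default_rng(seed)
    index_edges = [
        (int(i), int(j)) for i, j in zip(*np.nonzero(np.triu(net.adjacency, k=1)))
    ]
    edge_set = set(index_edges)
    edges = list(index_edges)
    n_edges = len(edges)
    n_attempts = swap_factor * n_edges
    successes = 0
    for _ in range(n_attempts):
        e1, e2 = rng.integers(0, n_edges, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:  # randomize pairing orientation for uniformity
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        new1 = (a, d) if a < d else (d, a)
        new2 = (c, b) if c < b else (b, c)
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(edges[e1])
        edge_set.discard(edges[e2])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1] = new1
        edges[e2] = new2
        successes += 1
    if successes == 0:
        warnings.warn("no valid double-edge swap found; returning network unchanged")
        return GeneNetwork(net.gene_ids, net.adjacency.copy(), dict(net.fingerprint))
    adj = np.zeros_like(net.adjacency)
    rows = np.fromiter((e[0] for e in edges), dtype=int, count=n_edges)
    cols = np.fromiter((e[1] for e in edges), dtype=int, count=n_edges)
    adj[rows, cols] = 1
    adj[cols, rows] = 1
    return GeneNetwork(net.gene_ids, adj, dict(net.fingerprint))


def _zero_to_count(net1: GeneNetwork, net2: GeneNetwork) -> int:
    return len(zero_to_genes(to_profile(net1, net2)))


def null_distribution(
    net1: GeneNetwork,
    net2: GeneNetwork,
    n_random: int = 1000,
    seed: int | None = None,
    rewire_mode: str = "both",
    swap_factor: int = 10,
) -> np.ndarray:
    """Zero-overlap counts between independently rewired network pairs.

    ``rewire_mode`` is ``"both"`` (default: each replicate rewires both
    networks with independent sub-seeded streams) or ``"second"`` (the first
    network is held fixed).  Returns ``n_random`` integer counts.
    """
    if net1.gene_ids != net2.gene_ids:
        raise ValueError("networks must share an identical ordered gene set")
    if rewire_mode not in ("both", "second"):
        raise ValueError(f"rewire_mode must be 'both' or 'second', got {rewire_mode!r}")
    streams = np.random.SeedSequence(seed).spawn(n_random)
    counts = np.empty(n_random, dtype=int)
    for rep, stream in enumerate(streams):
        sub1, sub2 = stream.spawn(2)
        r1 = (
            rewire(net1, rng=np.random.default_rng(sub1), swap_factor=swap_factor)
            if rewire_mode == "both"
            else net1
        )
        r2 = rewire(net2, rng=np.random.default_rng(sub2), swap_factor=swap_factor)
        counts[rep] = _zero_to_count(r1, r2)
    return counts


def t_statistic(
    observed: int, null_counts: np.ndarray, seed: int | None = None
) -> NullSummary:
    """Compare the observed zero-overlap count with the null counts.

    mu1 = observed (single real network pair), mu2 and SD = mean and sample
    standard deviation of the null counts; two-sided p from the t
    distribution with ``len(null_counts) + 1 - 2`` degrees of freedom.
    """
    null_counts = np.asarray(null_counts, dtype=float)
    n1 = len(null_counts)
    if n1 < 2:
        raise ValueError("need >= 2 null counts")
    mu2 = float(null_counts.mean())
    sd = float(null_counts.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate null: all null counts identical (sd = 0)")
    n2 = 1
    t = abs(observed - mu2) / (sd * np.sqrt(1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    p = float(2.0 * stats.t.sf(t, df))
    return NullSummary(int(observed), null_counts, mu2, sd, float(t), df, p, seed)


def assess_zero_to(
    net1: GeneNetwork,
    net2: GeneNetwork,
    n_random: int = 1000,
    seed: int | None = None,
    rewire_mode: str = "both",
    swap_factor: int = 10,
) -> NullSummary:
    """Observed zero-overlap count, its rewiring null, and the t-test summary."""
    observed = _zero_to_count(net1, net2)
    counts = null_distribution(
        net1, net2, n_random=n_random, seed=seed,
        rewire_mode=rewire_mode, swap_factor=swap_factor,
    )
    return t_statistic(observed, counts, seed=seed)
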