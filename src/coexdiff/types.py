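"""Core domain types shared by every analysis stage.

The pipeline compares gene co-expression networks built for two conditions
(e.g. two brain regions) over a shared node set.  The types here are thin,
validated containers: an expression matrix with sample group labels, a binary
undirected gene network stored as a symmetric adjacency matrix, the edge-rule
configuration that produced a network, and a named gene-set collection for
over-representation testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

AFFECTED = "affected"
CONTROL = "control"
GROUP_LABELS = (AFFECTED, CONTROL)


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {kind} ID: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Genes × samples table of summarized expression values with group labels.

    Parameters
    ----------
    gene_ids : ordered unique gene identifiers (rows).
    sample_ids : ordered unique sample identifiers (columns).
    values : float array of shape ``(len(gene_ids), len(sample_ids))``;
        all entries must be finite.
    groups : mapping sample ID -> ``"affected"`` or ``"control"``; every
        sample in the matrix must be labelled.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        for s in self.sample_ids:
            if s not in self.groups:
                raise ValidationError(f"sample {s!r} missing from group labels")
            if self.groups[s] not in GROUP_LABELS:
                raise ValidationError(
                    f"sample {s!r} has unknown group {self.groups[s]!r}; "
                    f"expected one of {GROUP_LABELS}"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def group_mask(self, label: str) -> np.ndarray:
        """Boolean mask over sample columns belonging to ``label``."""
        if label not in GROUP_LABELS:
            raise ValueError(f"unknown group label {label!r}")
        return np.array([self.groups[s] == label for s in self.sample_ids])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``gene_ids`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            list(gene_ids), list(self.sample_ids), self.values[rows], dict(self.groups)
        )

    def subset_samples(self, selector: str) -> "ExpressionMatrix":
        """Restrict columns to ``"affected"``, ``"control"`` or ``"all"``."""
        if selector == "all":
            return self
        mask = self.group_mask(selector)
        kept = [s for s, m in zip(self.sample_ids, mask) if m]
        return ExpressionMatrix(
            list(self.gene_ids), kept, self.values[:, mask], dict(self.groups)
        )


@dataclass(frozen=True)
class EdgeRuleConfig:
    """Parameters of the two rank-and-threshold co-expression edge conditions.

    An undirected edge joins genes *i*, *j* when at least one condition holds
    in at least one direction:

    1. ``r[i, j] >= base_threshold`` and one gene ranks within the other's
       ``top_k_strict`` most-correlated genes (defaults 0.3 and 3);
    2. ``r[i, j] >= high_threshold`` and one gene ranks within the other's
       ``top_k_relaxed`` most-correlated genes (defaults 0.7 and 50).

    Thresholds are inclusive (``>=``).  ``use_absolute_correlation`` switches
    the similarity from signed Pearson r to ``|r|``; off by default.
    """

    base_threshold: float = 0.3
    top_k_strict: int = 3
    high_threshold: float = 0.7
    top_k_relaxed: int = 50
    use_absolute_correlation: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.base_threshold <= self.high_threshold < 1):
            raise ValidationError(
                "thresholds must satisfy 0 < base_threshold <= high_threshold < 1, "
                f"got {self.base_threshold} and {self.high_threshold}"
            )
        if self.top_k_strict < 1 or self.top_k_relaxed < 1:
            raise ValidationError("rank cutoffs must be >= 1")

    def fingerprint(self) -> dict:
        return {
            "base_threshold": self.base_threshold,
            "top_k_strict": self.top_k_strict,
            "high_threshold": self.high_threshold,
            "top_k_relaxed": self.top_k_relaxed,
            "use_absolute_correlation": self.use_absolute_correlation,
            "threshold_semantics": ">= (inclusive)",
        }


@dataclass
class GeneNetwork:
    """Undirected simple graph over an ordered gene list.

    Stored as a symmetric binary adjacency matrix with zero diagonal.
    ``fingerprint`` records the configuration that produced the network
    (edge rule, sample selector, ...) for provenance.
    """

    gene_ids: list[str]
    adjacency: np.ndarray
    fingerprint: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        _check_unique(self.gene_ids, "gene")
        adj = np.asarray(self.adjacency)
        m = len(self.gene_ids)
        if adj.shape != (m, m):
            raise ValidationError(f"adjacency shape {adj.shape} != ({m}, {m})")
        if not np.isin(adj, (0, 1)).all():
            raise ValidationError("adjacency entries must be 0 or 1")
        adj = adj.astype(np.uint8)
        if not np.array_equal(adj, adj.T):
            raise ValidationError("adjacency must be symmetric")
        if adj.trace() != 0:
            raise ValidationError("adjacency must have zero diagonal (no self-loops)")
        self.adjacency = adj

    @classmethod
    def from_edges(
        cls,
        gene_ids: Sequence[str],
        edges: Iterable[tuple[str, str]],
        fingerprint: dict | None = None,
    ) -> "GeneNetwork":
        index = {g: i for i, g in enumerate(gene_ids)}
        m = len(index)
        adj = np.zeros((m, m), dtype=np.uint8)
        for a, b in edges:
            if a not in index or b not in index:
                unknown = a if a not in index else b
                raise ValidationError(f"edge names unknown gene {unknown!r}")
            if a == b:
                raise ValidationError(f"self-loop on gene {a!r}")
            adj[index[a], index[b]] = 1
            adj[index[b], index[a]] = 1
        return cls(list(gene_ids), adj, fingerprint or {})

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        """Per-gene degree (row sums), in gene order."""
        return self.adjacency.sum(axis=1).astype(int)

    def neighbours(self, gene_id: str) -> list[str]:
        i = self.gene_ids.index(gene_id)
        return [self.gene_ids[j] for j in np.flatnonzero(self.adjacency[i])]

    def edges(self) -> list[tuple[str, str]]:
        """Canonical edge list: smaller ID first within a pair, rows sorted."""
        out = []
        for i, j in zip(*np.nonzero(np.triu(self.adjacency, k=1))):
            a, b = self.gene_ids[i], self.gene_ids[j]
            out.append((a, b) if a <= b else (b, a))
        return sorted(out)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.gene_ids)
        g.add_edges_from(self.edges())
        return g


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT) evaluated against a stated gene universe.

    Members outside the universe are retained in storage but do not count
    toward a set's effective size.
    """

    sets: dict[str, tuple[str, list[str]]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, list[str]]] = {}
        for name, (desc, members) in self.sets.items():
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                warnings.warn(f"gene set {name!r}: duplicate members removed")
            clean[name] = (desc, deduped)
        self.sets = clean
        if self.universe is not None:
            self.universe = list(self.universe)
            _check_unique(self.universe, "universe gene")

    def effective_members(self, name: str) -> list[str]:
        """Members intersected with the universe (all members if no universe)."""
        _, members = self.sets[name]
        if self.universe is None:
            return list(members)
        uni = set(self.universe)
        return [g for g in members if g in uni]

    def names(self) -> list[str]:
        return list(self.sets)
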