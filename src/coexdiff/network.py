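"""Co-expression network construction by rank-and-threshold edge rules.

Similarity is the Pearson correlation of two genes' expression profiles
across the samples supplied.  Two genes are linked when at least one of two
conditions holds in at least one direction: a modest correlation combined
with a strict mutual-rank requirement (top-3 by default), or a high
correlation combined with a relaxed rank requirement (top-50 by default).
The strict rule gives every gene whose top correlations clear the base
threshold a minimum degree equal to the strict rank cutoff; the relaxed rule
lets strongly correlated hub neighbourhoods grow beyond it.

Rank ties are broken by ascending gene ID so networks are bit-reproducible.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .types import EdgeRuleConfig, ExpressionMatrix, GeneNetwork


def correlation_matrix(expr: ExpressionMatrix) -> np.ndarray:
    """Pearson correlations between all gene pairs across all supplied samples.

    Requires >= 3 samples and nonzero variance for every gene (a constant
    gene has no defined correlation and is rejected by name).
    """
    if expr.n_samples < 3:
        raise ValueError(f"need >= 3 samples to correlate, got {expr.n_samples}")
    sd = expr.values.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if len(flat):
        raise ValueError(f"gene {expr.gene_ids[flat[0]]!r} has zero variance")
    r = np.atleast_2d(np.corrcoef(expr.values))
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def _id_order(gene_ids: Sequence[str]) -> np.ndarray:
    """Lexicographic position of each gene ID, used as the rank tie-breaker."""
    return np.argsort(np.argsort(np.asarray(gene_ids, dtype=object)))


def _rank_matrix(r: np.ndarray, gene_ids: Sequence[str]) -> np.ndarray:
    """ranks[i, j] = 1-based rank of j among i's neighbours by decreasing
    correlation (self excluded; ties by ascending gene ID)."""
    m = r.shape[0]
    tie = _id_order(gene_ids)
    ranks = np.empty((m, m), dtype=np.int64)
    work = r.copy()
    np.fill_diagonal(work, -np.inf)  # self always ranks last
    for i in range(m):
        order = np.lexsort((tie, -work[i]))
        ranks[i, order] = np.arange(1, m + 1)
    return ranks


def rank_neighbours(
    r: np.ndarray, gene_ids: Sequence[str], gene: str
) -> list[str]:
    """Genes ordered by decreasing correlation with ``gene`` (ties by ID)."""
    gene_ids = list(gene_ids)
    i = gene_ids.index(gene)
    ranks = _rank_matrix(r, gene_ids)[i]
    order = np.argsort(ranks)
    return [gene_ids[j] for j in order if j != i]


def network_from_correlation(
    r: np.ndarray,
    gene_ids: Sequence[str],
    cfg: EdgeRuleConfig | None = None,
    fingerprint_extra: dict | None = None,
) -> GeneNetwork:
    """Apply both edge conditions to a precomputed correlation matrix."""
    cfg = cfg or EdgeRuleConfig()
    gene_ids = list(gene_ids)
    if len(gene_ids) == 0:
        raise ValueError("empty gene set: cannot build a network")
    r = np.asarray(r, dtype=float)
    sim = np.abs(r) if cfg.use_absolute_correlation else r
    ranks = _rank_matrix(sim, gene_ids)

    strict = ranks <= cfg.top_k_strict
    relaxed = ranks <= cfg.top_k_relaxed
    cond1 = (sim >= cfg.base_threshold) & (strict | strict.T)
    cond2 = (sim >= cfg.high_threshold) & (relaxed | relaxed.T)
    adj = (cond1 | cond2).astype(np.uint8)
    np.fill_diagonal(adj, 0)

    fingerprint = dict(cfg.fingerprint())
    if fingerprint_extra:
        fingerprint.update(fingerprint_extra)
    return GeneNetwork(gene_ids, adj, fingerprint)


def build_network(
    expr: ExpressionMatrix, cfg: EdgeRuleConfig | None = None
) -> GeneNetwork:
    """Correlate ``expr`` (already restricted to the intersection genes and to
    the chosen sample subset) and apply the edge rules."""
    r = correlation_matrix(expr)
    return network_from_correlation(
        r, expr.gene_ids, cfg, fingerprint_extra={"n_samples": expr.n_samples}
    )
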