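"""Differential expression between affected and control samples.

The score is a moderated mean-difference statistic in the SAM family:

    d_i = (mean_affected_i - mean_control_i) / (s_i + s0)

where ``s_i`` is the two-group pooled standard error of the mean difference
and ``s0`` — the exchangeability constant that damps scores of low-variance
genes — is the median of all ``s_i``.  Significance comes from permuting the
sample group labels: the per-gene q-value is the expected number of permuted
scores at least as extreme as the observed one (pooled across genes),
divided by the observed count at that threshold, clipped to [0, 1] and made
monotone non-increasing in |d|.  With few samples all distinct labelings are
enumerated exactly, so the permutation null is then exhaustive.

Differentially expressed genes called in both members of a region pair — the
intersection genes — form the shared node set for the pair's two networks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .types import AFFECTED, CONTROL, ExpressionMatrix

DEFAULT_FDR = 0.005  # relaxed 0.5% threshold used to keep intersections large


@dataclass
class DEResult:
    """Per-gene differential-expression scores and permutation q-values.

    ``table`` has one row per gene (input order) with columns ``gene``,
    ``d_statistic``, ``q_value`` and ``called`` (q <= ``fdr_threshold``).
    """

    table: pd.DataFrame
    fdr_threshold: float
    n_permutations: int

    @property
    def called_genes(self) -> list[str]:
        return self.table.loc[self.table["called"], "gene"].tolist()

    def recall(self, fdr_threshold: float) -> list[str]:
        """Genes called at a different FDR threshold (monotone in threshold)."""
        return self.table.loc[self.table["q_value"] <= fdr_threshold, "gene"].tolist()


def _group_arrays(expr: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    aff = expr.group_mask(AFFECTED)
    ctl = expr.group_mask(CONTROL)
    if aff.sum() < 2 or ctl.sum() < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {int(aff.sum())} affected "
            f"and {int(ctl.sum())} control"
        )
    return expr.values[:, aff], expr.values[:, ctl]


def _d_from_groups(a: np.ndarray, c: np.ndarray) -> np.ndarray:
    n1, n2 = a.shape[1], c.shape[1]
    diff = a.mean(axis=1) - c.mean(axis=1)
    ssd = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (c - c.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    pooled_var = ssd / (n1 + n2 - 2)
    s = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    s0 = np.median(s)
    return diff / (s + s0)


def de_statistic(expr: ExpressionMatrix) -> np.ndarray:
    """Moderated d-statistic per gene (affected minus control), in gene order."""
    a, c = _group_arrays(expr)
    return _d_from_groups(a, c)


def _label_masks(
    n: int, n_affected: int, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (n_perm × n) matrix of affected-sample masks.

    Enumerates all C(n, n_affected) labelings when there are no more of them
    than requested, warning that the exhaustive null is used instead.
    """
    total = math.comb(n, n_affected)
    if total <= n_permutations:
        warnings.warn(
            f"only {total} distinct labelings exist; enumerating all of them "
            f"instead of sampling {n_permutations}"
        )
        masks = np.zeros((total, n), dtype=bool)
        for row, idx in enumerate(combinations(range(n), n_affected)):
            masks[row, list(idx)] = True
        return masks
    masks = np.zeros((n_permutations, n), dtype=bool)
    for row in range(n_permutations):
        masks[row, rng.permutation(n)[:n_affected]] = True
    return masks


def permutation_fdr(
    expr: ExpressionMatrix,
    n_permutations: int = 1000,
    seed: int | None = None,
    fdr_threshold: float = DEFAULT_FDR,
) -> DEResult:
    """Call DE genes with a label-permutation pooled false-discovery estimate.

    Parameters
    ----------
    n_permutations : number of label permutations (>= 100); if fewer distinct
        labelings exist they are enumerated exactly.
    seed : seed for the permutation sampler; fixed seed => identical q-values.
    fdr_threshold : q-value cutoff for the ``called`` flag.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    rng = np.random.default_rng(seed)
    aff_mask = expr.group_mask(AFFECTED)
    d_obs = de_statistic(expr)
    abs_obs = np.abs(d_obs)

    masks = _label_masks(expr.n_samples, int(aff_mask.sum()), n_permutations, rng)
    perm_abs = np.empty((masks.shape[0], expr.n_genes))
    for row, mask in enumerate(masks):
        perm_abs[row] = np.abs(
            _d_from_groups(expr.values[:, mask], expr.values[:, ~mask])
        )

    # Pooled tail counts: for gene i, how many permuted |d| (across all genes
    # and permutations) reach |d_i|, averaged per permutation, versus how many
    # observed |d| reach it.
    pooled = np.sort(perm_abs.ravel())
    exceed_perm = len(pooled) - np.searchsorted(pooled, abs_obs, side="left")
    numerator = exceed_perm / masks.shape[0]
    sorted_obs = np.sort(abs_obs)
    denominator = len(abs_obs) - np.searchsorted(sorted_obs, abs_obs, side="left")
    q = np.clip(numerator / denominator, 0.0, 1.0)

    # Step-up monotonicity: a gene's q never exceeds that of any less extreme
    # gene, enforced by a cumulative minimum from least to most extreme.
    order = np.argsort(-abs_obs, kind="stable")
    q_sorted = q[order]
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_mono = np.empty_like(q)
    q_mono[order] = q_sorted

    table = pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "d_statistic": d_obs,
            "q_value": q_mono,
            "called": q_mono <= fdr_threshold,
        }
    )
    return DEResult(table, fdr_threshold, masks.shape[0])


def intersect_de(list_a: Sequence[str], list_b: Sequence[str]) -> list[str]:
    """Intersection genes of two DE lists, ordered by the first list."""
    in_b = set(list_b)
    return [g for g in list_a if g in in_b]
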