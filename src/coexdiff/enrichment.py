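"""Hypergeometric over-representation testing of gene lists against GMT sets.

One-sided test per set: drawing |query| genes from the universe, how likely
is an overlap at least as large as observed, given the set's effective size
within the universe?  Benjamini-Hochberg FDR across sets.  The recommended
universe is the pool the query was drawn from (here: the intersection genes
of a region pair), which conditions the test on the sampled gene space.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import GeneSetCollection


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone in raw p)."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


def enrich(
    genes: Sequence[str],
    sets: GeneSetCollection,
    universe: Sequence[str] | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of ``genes`` in each set of ``sets``.

    Parameters
    ----------
    genes : query gene IDs; members outside the universe are dropped with a
        warning.
    universe : background gene pool; defaults to the collection's stated
        universe.
    fdr : Benjamini-Hochberg threshold for the ``significant`` flag.

    Returns a DataFrame sorted by ascending p-value with columns
    ``set_name``, ``set_size`` (effective, within universe),
    ``overlap_count``, ``p_value``, ``bh_fdr``, ``significant``.
    """
    if universe is None:
        universe = sets.universe
    if universe is None or len(universe) == 0:
        raise ValueError("empty universe: an explicit background gene pool is required")
    uni = list(dict.fromkeys(universe))
    uni_set = set(uni)
    query = list(dict.fromkeys(genes))
    dropped = [g for g in query if g not in uni_set]
    if dropped:
        warnings.warn(
            f"{len(dropped)} query gene(s) outside the universe dropped "
            f"(first: {dropped[0]!r})"
        )
    query_set = {g for g in query if g in uni_set}

    big_n = len(uni)
    n_draw = len(query_set)
    rows = []
    for name in sets.names():
        members = set(sets.sets[name][1]) & uni_set
        big_k = len(members)
        k = len(members & query_set)
        # P(X >= k), X ~ Hypergeometric(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n_draw)) if big_k else 1.0
        rows.append((name, big_k, k, min(p, 1.0)))

    table = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap_count", "p_value"])
    table["bh_fdr"] = _bh_fdr(table["p_value"].to_numpy()) if len(table) else []
    table["significant"] = table["bh_fdr"] <= fdr
    return (
        table.sort_values(["p_value", "set_name"]).reset_index(drop=True)
    )
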