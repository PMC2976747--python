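"""Readers and writers for every on-disk format the pipeline touches.

All formats are plain text: tab-separated expression matrices (header row of
sample IDs, first column of gene IDs), two-column sample-group files,
one-ID-per-line gene lists, two-column edge lists, standard GMT gene-set
files, and a YAML configuration file.  Every reader/writer pair is a faithful
round trip.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .types import EdgeRuleConfig, ExpressionMatrix, GeneNetwork, GeneSetCollection


class LoadError(ValueError):
    """Raised when an input file fails validation; names the offending spot."""


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping sample ID -> group label."""
    groups: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise LoadError(f"{path}: line {ln}: expected 2 tab-separated fields")
        sample, label = parts
        if sample in groups:
            raise LoadError(f"{path}: line {ln}: duplicate sample ID {sample!r}")
        groups[sample] = label
    return groups


def write_groups(groups: dict[str, str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{s}\t{g}\n" for s, g in groups.items()))


def read_expression(path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Load and validate an expression matrix plus its sample-group file.

    Rejects duplicate IDs, blank/non-numeric cells and samples absent from
    the groups file, naming the offending row/column.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise LoadError(f"{path}: header must contain at least one sample column")
    sample_ids = header[1:]
    dupes = {s for s in sample_ids if sample_ids.count(s) > 1}
    if dupes:
        raise LoadError(f"{path}: duplicate sample ID {sorted(dupes)[0]!r} in header")

    frame = pd.read_csv(
        path, sep="\t", skiprows=1, header=None, names=["__gene__"] + sample_ids,
        index_col=0, dtype={"__gene__": str}, float_precision="round_trip",
    )
    gene_ids = [str(g) for g in frame.index]
    gdupes = frame.index[frame.index.duplicated()]
    if len(gdupes):
        raise LoadError(f"{path}: duplicate gene ID {gdupes[0]!r}")
    for col in sample_ids:
        column = pd.to_numeric(frame[col], errors="coerce")
        bad = column.index[column.isna()]
        if len(bad):
            raise LoadError(
                f"{path}: missing or non-numeric value at gene {bad[0]!r}, "
                f"sample {col!r}"
            )
        frame[col] = column
    values = frame.to_numpy(dtype=float)

    groups = read_groups(groups_path)
    missing = [s for s in sample_ids if s not in groups]
    if missing:
        raise LoadError(
            f"{groups_path}: sample {missing[0]!r} present in matrix but not in "
            "groups file"
        )
    groups = {s: groups[s] for s in sample_ids}
    return ExpressionMatrix(gene_ids, sample_ids, values, groups)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write a genes × samples TSV (full float precision)."""
    frame = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    frame.to_csv(path, sep="\t", index_label="gene")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene ID per line; blank lines skipped; duplicates rejected."""
    ids: list[str] = []
    seen: set[str] = set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        gid = line.strip()
        if not gid:
            continue
        if gid in seen:
            raise LoadError(f"{path}: line {ln}: duplicate gene ID {gid!r}")
        seen.add(gid)
        ids.append(gid)
    return ids


def write_gene_list(ids: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in ids))


def write_edge_list(net: GeneNetwork, path: str | Path) -> None:
    """Canonical edge-list TSV: each undirected edge once, smaller ID first,
    rows lexicographically sorted (so network files diff cleanly)."""
    Path(path).write_text("".join(f"{a}\t{b}\n" for a, b in net.edges()))


def read_edge_list(path: str | Path, gene_ids: Sequence[str]) -> GeneNetwork:
    """Reconstruct a network over ``gene_ids`` from an edge-list TSV."""
    edges: list[tuple[str, str]] = []
    known = set(gene_ids)
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise LoadError(f"{path}: line {ln}: expected 2 tab-separated fields")
        a, b = parts
        for g in (a, b):
            if g not in known:
                raise LoadError(f"{path}: line {ln}: unknown gene {g!r}")
        edges.append((a, b))
    return GeneNetwork.from_edges(gene_ids, edges)


def read_gmt(path: str | Path, universe: Sequence[str] | None = None) -> GeneSetCollection:
    """Read a standard GMT file (set name, description, member genes)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise LoadError(
                f"{path}: line {ln}: GMT lines need >= 3 tab-separated fields "
                "(name, description, members...)"
            )
        name, desc, *members = parts
        if name in sets:
            raise LoadError(f"{path}: line {ln}: duplicate set name {name!r}")
        sets[name] = (desc, [m for m in members if m])
    return GeneSetCollection(sets, list(universe) if universe is not None else None)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, (desc, members) in collection.sets.items():
        lines.append("\t".join([name, desc, *members]) + "\n")
    Path(path).write_text("".join(lines))


def read_config(path: str | Path) -> dict:
    """Read a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise LoadError(f"{path}: top-level YAML structure must be a mapping")
    return cfg


def edge_rule_from_config(cfg: dict) -> EdgeRuleConfig:
    """Build an :class:`EdgeRuleConfig` from a (possibly partial) mapping."""
    fields = {
        "base_threshold", "top_k_strict", "high_threshold",
        "top_k_relaxed", "use_absolute_correlation",
    }
    kwargs = {k: v for k, v in cfg.items() if k in fields}
    return EdgeRuleConfig(**kwargs)
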