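"""End-to-end orchestration for one region pair (and thin multi-pair loop).

Stages: per-region differential expression (or externally supplied DE
lists) → intersection genes → two co-expression networks → cross-network
topological-overlap profile → zero-overlap genes → degree-preserving
randomization null → connectivity contrast report → optional gene-set
enrichment.  Every stage's inputs, outputs and counts land in a JSON
manifest; all intermediate files are written in the package's own formats,
so each is re-readable by the corresponding reader.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import io
from .de import DEFAULT_FDR, DEResult, intersect_de, permutation_fdr
from .enrichment import enrich
from .network import build_network
from .nullmodel import NullSummary, assess_zero_to
from .topology import degree_report, isolated_genes, to_profile, zero_to_genes
from .types import EdgeRuleConfig, ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage cannot proceed (e.g. empty intersection)."""


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the full pair analysis; all defaults are the standard run."""

    edge_rule: EdgeRuleConfig = field(default_factory=EdgeRuleConfig)
    fdr_threshold: float = DEFAULT_FDR
    n_permutations: int = 200
    samples: str = "affected"  # sample subset fed to the correlations
    n_random: int = 1000
    rewire_mode: str = "both"
    swap_factor: int = 10
    to_threshold: float = 0.0
    seed: int = 0

    def fingerprint(self) -> dict:
        fp = asdict(self)
        fp["edge_rule"] = self.edge_rule.fingerprint()
        return fp


@dataclass
class PairResult:
    """All stage outputs of one region-pair run, plus the manifest."""

    de_a: DEResult | None
    de_b: DEResult | None
    de_list_a: list[str]
    de_list_b: list[str]
    intersection: list[str]
    net_a: "object"
    net_b: "object"
    profile: pd.DataFrame
    zero_to: list[str]
    isolated: list[str]
    null_summary: NullSummary | None
    degree_table: pd.DataFrame
    enrichment: pd.DataFrame | None
    manifest: dict


def run_pair(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    config: PipelineConfig | None = None,
    de_lists: tuple[Sequence[str], Sequence[str]] | None = None,
    gene_sets: GeneSetCollection | None = None,
    outdir: str | Path | None = None,
) -> PairResult:
    """Run the full differential-topology analysis for one region pair.

    Parameters
    ----------
    de_lists : optional precomputed DE gene lists (one per region), e.g. from
        an external SAM run; when given, the DE stage is skipped.
    gene_sets : optional GMT collection; enrichment of the zero-overlap genes
        is tested against the intersection-gene universe.
    outdir : when given, every stage output plus ``manifest.json`` is written
        there.
    """
    config = config or PipelineConfig()
    manifest: dict = {"config": config.fingerprint(), "stages": {}}

    def log_stage(name: str, **info) -> None:
        manifest["stages"][name] = info
        logger.info("stage %s: %s", name, info)

    de_a = de_b = None
    if de_lists is not None:
        list_a, list_b = [list(x) for x in de_lists]
        log_stage("de", source="external DE lists", n_de_a=len(list_a),
                  n_de_b=len(list_b))
    else:
        de_a = permutation_fdr(
            expr_a, n_permutations=config.n_permutations,
            seed=config.seed, fdr_threshold=config.fdr_threshold,
        )
        de_b = permutation_fdr(
            expr_b, n_permutations=config.n_permutations,
            seed=config.seed + 1, fdr_threshold=config.fdr_threshold,
        )
        list_a, list_b = de_a.called_genes, de_b.called_genes
        log_stage("de", source="permutation FDR", fdr=config.fdr_threshold,
                  n_permutations=config.n_permutations,
                  n_de_a=len(list_a), n_de_b=len(list_b))

    intersection = intersect_de(list_a, list_b)
    if not intersection:
        raise PipelineError(
            f"empty intersection: {len(list_a)} DE genes in region A and "
            f"{len(list_b)} in region B share no members"
        )
    log_stage("intersection", n_genes=len(intersection))

    sub_a = expr_a.subset_genes(intersection).subset_samples(config.samples)
    sub_b = expr_b.subset_genes(intersection).subset_samples(config.samples)
    net_a = build_network(sub_a, config.edge_rule)
    net_b = build_network(sub_b, config.edge_rule)
    log_stage("networks", samples=config.samples,
              n_edges_a=net_a.n_edges, n_edges_b=net_b.n_edges)

    profile = to_profile(net_a, net_b)
    zero = zero_to_genes(profile, config.to_threshold)
    isolated = isolated_genes(profile)
    log_stage("topological_overlap", n_genes=len(profile),
              n_zero_to=len(zero), n_isolated_both=len(isolated),
              to_threshold=config.to_threshold)

    null_summary = None
    if config.n_random >= 2:
        try:
            null_summary = assess_zero_to(
                net_a, net_b, n_random=config.n_random, seed=config.seed,
                rewire_mode=config.rewire_mode, swap_factor=config.swap_factor,
            )
            log_stage("randomization_null", **null_summary.to_dict())
        except ValueError as exc:  # degenerate null (e.g. near-empty networks)
            log_stage("randomization_null", skipped=str(exc))

    degrees = degree_report(net_a, net_b, zero if zero else None)
    log_stage("degree_report", n_rows=len(degrees))

    enrichment_table = None
    if gene_sets is not None:
        enrichment_table = enrich(zero, gene_sets, universe=intersection)
        log_stage("enrichment", n_sets=len(enrichment_table),
                  n_significant=int(enrichment_table["significant"].sum()))

    result = PairResult(
        de_a, de_b, list_a, list_b, intersection, net_a, net_b, profile,
        zero, isolated, null_summary, degrees, enrichment_table, manifest,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PairResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for tag, de in (("a", result.de_a), ("b", result.de_b)):
        if de is not None:
            de.table.to_csv(outdir / f"de_scores_{tag}.tsv", sep="\t", index=False)
    io.write_gene_list(result.de_list_a, outdir / "de_genes_a.txt")
    io.write_gene_list(result.de_list_b, outdir / "de_genes_b.txt")
    io.write_gene_list(result.intersection, outdir / "intersection_genes.txt")
    io.write_edge_list(result.net_a, outdir / "network_a.edges.tsv")
    io.write_edge_list(result.net_b, outdir / "network_b.edges.tsv")
    result.profile.to_csv(outdir / "to_profile.tsv", sep="\t", index=False)
    io.write_gene_list(result.zero_to, outdir / "zero_to_genes.txt")
    result.degree_table.to_csv(outdir / "degree_report.tsv", sep="\t", index=False)
    if result.null_summary is not None:
        (outdir / "null_summary.json").write_text(
            json.dumps(result.null_summary.to_dict(), indent=2) + "\n"
        )
        pd.Series(result.null_summary.null_counts, name="zero_to_count").to_csv(
            outdir / "null_counts.tsv", sep="\t", index=False
        )
    if result.enrichment is not None:
        result.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2) + "\n")


def run_all(
    regions: Sequence[tuple[str, ExpressionMatrix]],
    config: PipelineConfig | None = None,
    gene_sets: GeneSetCollection | None = None,
    outdir: str | Path | None = None,
) -> pd.DataFrame:
    """All pairwise comparisons over named regions; one summary row per pair.

    A thin loop over :func:`run_pair` — no cross-pair statistics beyond the
    summary table are defined.
    """
    rows = []
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            name_a, expr_a = regions[i]
            name_b, expr_b = regions[j]
            pair_dir = (
                Path(outdir) / f"{name_a}_vs_{name_b}" if outdir is not None else None
            )
            res = run_pair(expr_a, expr_b, config, gene_sets=gene_sets,
                           outdir=pair_dir)
            rows.append(
                {
                    "region_a": name_a,
                    "region_b": name_b,
                    "n_de_a": len(res.de_list_a),
                    "n_de_b": len(res.de_list_b),
                    "n_intersection": len(res.intersection),
                    "n_zero_to": len(res.zero_to),
                    "null_p_value": (
                        res.null_summary.p_value if res.null_summary else None
                    ),
                }
            )
    summary = pd.DataFrame(rows)
    if outdir is not None:
        summary.to_csv(Path(outdir) / "pairwise_summary.tsv", sep="\t", index=False)
    return summary
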