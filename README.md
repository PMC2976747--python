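# coexdiff

Differential gene co-expression **network topology** analysis: compare how a
gene's co-expression neighbourhood changes between two conditions — for
example, two brain regions affected by a progressive disease — rather than
how its expression level changes.

## The problem and who this is for

When the same disease hits different tissues or regions at different times,
differential-expression lists from each region look broadly similar, and
level-based comparisons struggle to say which region is further along.
A gene's *network context* is more telling: if its co-expression partners in
region A share nothing with its partners in region B, the gene's activity is
likely region- or stage-specific. `coexdiff` is for transcriptomics and
systems-biology researchers who have per-condition expression matrices
(microarray or otherwise summarized values) and want a tested, reproducible
implementation of this differential-topology workflow.

## The method

For each region, affected-vs-control differentially expressed (DE) genes are
called with a moderated statistic d·ᵢ = (x̄ᵢ,aff − x̄ᵢ,ctl)/(sᵢ + s₀) and a
label-permutation FDR (precomputed DE lists, e.g. from SAM, are accepted
directly). The genes DE in **both** regions — the *intersection genes* —
form a shared node set, over which one co-expression network per region is
built from Pearson correlations r with two edge rules (edge if either holds
in either direction):

1. r ≥ 0.3 and one gene ranks in the other's top-3 most-correlated genes;
2. r ≥ t (t = 0.7 or 0.8) and one gene ranks in the other's top-50.

For every gene *i* with neighbour sets X, Y and degrees d1ᵢ, d2ᵢ in the two
networks, the **cross-network topological overlap** is

    TO(geneᵢ) = |X ∩ Y| / max(d1ᵢ, d2ᵢ)

The max-denominator keeps wide neighbourhoods honest: a gene with 200
neighbours in one network, 10 in the other and all 10 shared scores 0.05
(5% of its widest neighbourhood conserved), not 1. Genes with TO = 0 —
disjoint neighbourhoods — are the *zero-TO genes*, the method's unit of
differential topology. Their count is tested against a degree-preserving
double-edge-swap rewiring null with the statistic

    t = |μ1 − μ2| / (SD · √(1/n1 + 1/n2)),   df = n1 + n2 − 2

(μ1 observed count, n2 = 1 real pair; μ2, SD from n1 = 1000 rewired pairs),
and per-gene degree contrasts (d1, d2, |d1 − d2|) flag activity shifts.
Zero-TO lists can be tested for pathway over-representation against any GMT
collection (hypergeometric + Benjamini–Hochberg, universe = the intersection
genes).

A fully seeded synthetic generator (latent-factor co-expression blocks, DE
mean shifts, planted genes whose blocks differ between regions) provides
ground truth for every stage; see `docs/methods.md`.

## Worked example

Generate a synthetic two-region dataset and run the full pipeline:

```bash
coexdiff simulate --spec spec.yaml --seed 17 --outdir demo/data
# spec.yaml: "de_effect: 2.0"  (stronger DE shift than the default 1 SD)
coexdiff run \
  --expr-a demo/data/region1.expr.tsv --groups-a demo/data/region1.groups.tsv \
  --expr-b demo/data/region2.expr.tsv --groups-b demo/data/region2.groups.tsv \
  --config cfg.yaml --seed 17 --outdir demo/out
# cfg.yaml: n_permutations: 200, n_random: 200, fdr_threshold: 0.01
```

Printed result:

```
synthetic pair (300 genes) -> demo/data
169 intersection genes, 54 zero-TO genes -> demo/out
```

`demo/out/manifest.json` records every stage: 178 and 171 DE genes per
region, 169 intersection genes, networks of 623 and 626 edges, 54 zero-TO
genes against a rewiring-null mean of 120.6 (SD 7.4), t = 9.0 with 199 df,
p ≈ 1.8 × 10⁻¹⁶. The real pair has **fewer** zero-TO genes than its
degree-matched randomizations — shared biology aligns the two networks —
and 9 of the 10 genes planted with region-switching neighbourhoods are
recovered in the zero-TO list. The top of `degree_report.tsv`
(`G218: d1=3, d2=14`) shows the connectivity contrasts used to reason about
a gene's activity change between conditions.

Every step is also available as a separate subcommand (`de`, `intersect`,
`network`, `to`, `zeroto`, `degrees`, `null`, `enrich`, `run-all`) and as a
plain Python API (`coexdiff.run_pair`, `coexdiff.to_profile`, ...).

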