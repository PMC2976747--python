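# Methods

## Model and procedure

`coexdiff` treats a condition (e.g. a brain region sampled in affected and
control subjects) as a gene co-expression network and quantifies, gene by
gene, how much of the gene's neighbourhood survives between two conditions.
The pipeline is: per-region DE calling → intersection genes → one network
per region over that shared node set → per-gene cross-network topological
overlap → zero-overlap gene selection → degree-preserving randomization
null → degree contrast report → optional gene-set over-representation.

### Differential expression

The score d·ᵢ = (x̄ᵢ,aff − x̄ᵢ,ctl)/(sᵢ + s₀) uses the two-group pooled
standard error sᵢ and the exchangeability constant s₀ = median(sᵢ), which
keeps low-variance genes from dominating the ranking. Significance is by
permutation of the sample group labels: the q-value of gene *i* is the mean
number of permuted |d| values (pooled across genes) at least as large as
|dᵢ|, divided by the number of observed |d| at least that large, clipped to
[0, 1] and made monotone non-increasing in |d| by a step-up pass. When the
sample count admits fewer distinct labelings than requested permutations,
all labelings are enumerated and the null is exact. The default calling
threshold is a deliberately relaxed q ≤ 0.005, so that region pairs retain
a large common gene set; the `called` flag is recomputable at any other
threshold from the stored q-values.

This scorer is a documented stand-in for SAM: it reproduces the moderated
mean-difference idea but not SAM's exact tuning of s₀ or its delta-based
cutoffs. Analyses that start from an external SAM run should pass the
resulting gene lists via `de_lists`/`--de-lists`; the DE stage is then
skipped and the manifest records the external source.

### Edge rules

Pearson correlation is computed across whichever sample subset is selected
(`affected` by default — the networks are interpreted as disease-state
co-expression; `control` and `all` are available and recorded in the
network fingerprint). Both edge conditions are evaluated in both
directions; thresholds are inclusive (≥), which is what the linking
examples imply (a candidate at exactly r = 0.3 links). Rank ties are broken
by ascending gene ID so that rebuilt networks are identical across
platforms. When every gene's top-3 correlations clear the base threshold
and nothing reaches the condition-2 threshold, each gene contributes
exactly its top-3 edges and the genes picked by no one else have degree
exactly 3 — the minimum-connectivity property checked in the acceptance
suite.

Signed correlation is the default similarity; `use_absolute_correlation`
switches to |r| for analyses where anti-correlation should also link genes.

### Topological overlap

TO(geneᵢ) = |X ∩ Y| / max(d1ᵢ, d2ᵢ). The max denominator is a
false-negative guard: with min(d1, d2) a gene whose small neighbourhood is
fully contained in its large one would score 1 and escape a
low-overlap screen, although only a small fraction of its widest
neighbourhood is conserved. The min-denominator variant is computed
alongside for comparison, and TO_max ≤ TO_min always. Reported TO values
are rounded to 4 decimal places; zero-overlap selection tests the integer
intersection size, so rounding can never turn a positive overlap into an
apparent zero. Genes isolated in both networks are flagged and excluded
from the zero-TO list (they have no neighbourhoods to diverge); genes
isolated in exactly one network have overlap 0 by construction and are
retained. A nonzero `to_threshold` selects low-but-positive overlap genes
instead, for analyses that justify a laxer cut.

### Randomization null

"Degree-preserving randomization" is implemented as repeated double-edge
swaps — the standard construction: two disjoint edges (a,b), (c,d) are
replaced by (a,d), (c,b) unless that would create a self-loop or duplicate
edge. Attempted swaps per rewiring = 10 × |E| (the `swap_factor`), enough
to decorrelate edge placement at these densities. Each null replicate
rewires **both** networks with independent sub-seeded streams
(`rewire_mode="both"`; `"second"` holds the first network fixed) and counts
zero-TO genes between the rewired pair. The observed count is compared to
the replicate counts with the two-sample t-statistic above (n2 = 1 real
pair); with the default 1000 replicates the reference distribution has
999 df. Graphs admitting no valid swap (e.g. a triangle) are returned
unchanged with a warning. A null in which every replicate yields the same
count (SD = 0, typical of near-empty networks) is reported as a skipped
stage rather than a fabricated p-value.

### Enrichment

A per-set one-sided hypergeometric tail with Benjamini–Hochberg correction
replaces any proprietary pathway database: users supply GMT files. The
universe defaults to the intersection genes of the comparison — the pool
the zero-TO genes were drawn from — which conditions the test on the
sampled gene space instead of the whole genome.

## Synthetic data: what it emulates, what it does not

`SyntheticSpec` defaults describe a small two-region case–control study:
300 genes, 10 affected and 13 control samples per region, fourteen
20-gene latent-factor blocks (loading 0.8, residual SD 0.6, hence
within-block correlation 0.8²/(0.8² + 0.6²) = 0.64), 60% of genes DE with
a 1-SD shift applied to affected samples of both regions (so the DE truth
is also the intersection truth), baseline log-scale expression 8, and 10
planted genes whose block membership differs between the regions. The
20 genes outside any block are unstructured noise. Planted genes are
always DE (they model disease-relevant genes), and their
(source block → target block) mappings are forced distinct: two planted
genes sharing a mapping would remain mutually co-expressed in both regions
and their true overlap would not be zero. With distinct mappings the true
neighbourhoods are disjoint by construction and, at vanishing noise,
planted TO is exactly 0.

The generator controls Pearson correlation analytically (a factor model),
which is exactly the quantity the edge rules consume — that is why it was
chosen over copula or graph-conditioned samplers. It does **not** emulate
probe-level noise, normalization artifacts, heavy-tailed expression,
correlated noise between blocks, or sample covariates. Passing recovery
tests therefore show that the method finds genuinely rewired genes under
clean factor structure at realistic sample sizes; they do not certify
performance under array-specific artifacts.

One empirical caveat the tests encode: planted-gene *sensitivity* is not a
monotone casualty of noise. At high noise all structure collapses, nearly
every gene's neighbourhoods become disjoint chance sets, and the zero-TO
list balloons — sensitivity stays high while precision collapses (mean
false-discovery proportion among zero-TO genes rises from ≈0.5 at noise SD
0.2 to ≈0.94 at 1.2 under defaults). The monotone degradation is in
precision, and that is the property the suite asserts. At default settings
mean planted-gene sensitivity over 10 seeds is ≈0.94.

## Numerical and design choices

- Correlations are clipped to [−1, 1] and the diagonal forced to 1 before
  ranking; a zero-variance gene is an error naming the gene, not a NaN.
- Exact float round-trips through TSV require pandas'
  `float_precision="round_trip"` parser; the default parser is off by an
  ulp and would break adjacency/rank reproducibility guarantees.
- Gene identifiers are opaque strings; probe-to-gene mapping is upstream.
  Edge lists are serialized canonically (smaller ID first, sorted rows) so
  network files diff cleanly.
- All randomness (permutations, rewiring, generation) flows from explicit
  seeds through `numpy` generators; replicate streams are spawned with
  `SeedSequence` so replicate r is independent of n_random.
- Missing expression values are rejected at load, not imputed.
- The multi-region driver is a plain loop over pairs with a summary table;
  no cross-pair statistic is defined.

## Problem sizes in the validation suite

The test and acceptance runs use desk-scale versions of the workflow's
study conditions: 8-gene fixtures against an exhaustive edge-rule oracle
(100 draws), 30-node graph pairs against a set-operations overlap oracle
(100 draws), 200 genes × 120 samples for the minimum-connectivity
property (within-block correlation 0.45, verified to satisfy the
premise that all correlations stay below the condition-2 threshold),
default 300-gene synthetic pairs with 25-replicate nulls for the
direction-of-effect check (20 seeds), and 10-seed recovery runs. These
sizes make every stage's behaviour observable in seconds while leaving the
algorithms identical to full-scale runs.

## Known limitations

- The DE stage is SAM-like, not SAM; exact DE counts from SAM runs will
  differ. Use external lists for faithful reproduction of a SAM analysis.
- The pooled permutation FDR is conservative for strongly correlated genes
  (co-expression blocks violate gene independence in the pooled null).
- Double-edge-swap rewiring samples degree-preserving graphs approximately
  uniformly; extremely sparse or near-complete graphs mix slowly.
- The hypergeometric enrichment ignores gene-gene correlation within sets,
  as all standard over-representation tests do.
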