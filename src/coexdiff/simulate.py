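"""Synthetic two-region expression data with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* latent-factor co-expression blocks — every gene in block *b* is
  ``loading * factor_b + noise_sd * eps``, so within-block Pearson
  correlation is analytically ``loading^2 / (loading^2 + noise_sd^2)`` and
  between-block correlation is 0 in expectation;
* differentially expressed genes — a mean shift (in units of the gene's
  total SD) added to affected samples of both regions, so the same genes are
  DE in each region and form the truth intersection;
* planted differential-topology genes — genes that load on one block in
  region 1 and on a *different* block in region 2.  Their true neighbour
  sets are disjoint across regions, so at low noise their cross-network
  topological overlap is exactly 0; these are the recoverable signal.

Everything is driven by one seed; the truth record is exact.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .network import build_network
from .topology import to_profile, zero_to_genes
from .types import EdgeRuleConfig, ExpressionMatrix


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the two-region generator.

    Defaults model a laser-capture microarray study of two brain regions:
    300 genes, 10 affected and 13 control subjects per region, co-expression
    blocks of 20 genes with factor loading 0.8 and residual noise SD 0.6
    (within-block correlation 0.64), 60% of genes DE with a 1-SD shift, and
    10 planted genes whose block membership switches between regions.
    """

    m_genes: int = 300
    n_affected: int = 10
    n_control: int = 13
    de_fraction: float = 0.6
    de_effect: float = 1.0
    n_blocks: int = 14
    block_size: int = 20
    loading: float = 0.8
    noise_sd: float = 0.6
    n_planted_diff: int = 10
    baseline: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.m_genes, self.n_affected, self.n_control, self.block_size) < 1:
            raise ValueError("all counts must be positive")
        if self.n_blocks * self.block_size > self.m_genes:
            raise ValueError(
                f"{self.n_blocks} blocks x {self.block_size} genes exceed "
                f"m_genes={self.m_genes}"
            )
        if self.n_planted_diff > 0 and self.n_blocks < 2:
            raise ValueError("planted differential-topology genes need >= 2 blocks")
        if self.n_planted_diff > self.n_blocks * self.block_size:
            raise ValueError("more planted genes than block genes")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.noise_sd < 0 or self.loading < 0:
            raise ValueError("loading and noise_sd must be non-negative")


@dataclass
class Truth:
    """Exact ground truth for one generated region pair."""

    de_genes: list[str]
    planted_genes: list[str]
    blocks_region1: dict[str, int]  # -1 = unstructured background gene
    blocks_region2: dict[str, int]
    spec: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def block_values(
    block_of: np.ndarray,
    n_samples: int,
    loading: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent-factor expression draw: genes × samples.

    ``block_of[g]`` is the block index of gene g, or -1 for an unstructured
    gene (unit-variance noise).  Block genes are
    ``loading * factor_block + noise_sd * eps``.
    """
    n_blocks = int(block_of.max()) + 1 if (block_of >= 0).any() else 0
    m = len(block_of)
    values = np.empty((m, n_samples))
    factors = rng.standard_normal((max(n_blocks, 1), n_samples))
    eps = rng.standard_normal((m, n_samples))
    structured = block_of >= 0
    values[structured] = (
        loading * factors[block_of[structured]] + noise_sd * eps[structured]
    )
    values[~structured] = eps[~structured]
    return values


def _gene_ids(m: int) -> list[str]:
    width = len(str(m))
    return [f"G{i:0{width}d}" for i in range(1, m + 1)]


def generate_pair(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, Truth]:
    """Generate expression matrices for two regions plus the truth record."""
    root = np.random.SeedSequence(spec.seed)
    ss_struct, ss_r1, ss_r2 = root.spawn(3)
    rng = np.random.default_rng(ss_struct)

    m = spec.m_genes
    genes = _gene_ids(m)
    n_block_genes = spec.n_blocks * spec.block_size
    block1 = np.full(m, -1, dtype=int)
    block1[:n_block_genes] = np.arange(n_block_genes) // spec.block_size

    # Planted genes: same gene, different (hence disjoint) block per region.
    # No two planted genes may share the same (source, target) block pair —
    # such a pair would stay mutually co-expressed in both regions and their
    # true cross-network overlap would not be zero.
    planted_idx = rng.choice(n_block_genes, size=spec.n_planted_diff, replace=False)
    planted_idx = np.sort(planted_idx)
    block2 = block1.copy()
    used_mappings: set[tuple[int, int]] = set()
    for g in planted_idx:
        b1 = int(block1[g])
        targets = [b for b in range(spec.n_blocks)
                   if b != b1 and (b1, b) not in used_mappings]
        if not targets:  # all targets taken for this source block
            targets = [b for b in range(spec.n_blocks) if b != b1]
        b2 = int(rng.choice(targets))
        used_mappings.add((b1, b2))
        block2[g] = b2

    # DE truth: planted genes are disease-relevant by construction and always
    # included; the remainder sampled uniformly.
    n_de = int(round(spec.de_fraction * m))
    n_de = max(n_de, spec.n_planted_diff)
    others = np.setdiff1d(np.arange(m), planted_idx)
    extra = rng.choice(others, size=n_de - spec.n_planted_diff, replace=False)
    de_idx = np.sort(np.concatenate([planted_idx, extra]))
    de_mask = np.zeros(m, dtype=bool)
    de_mask[de_idx] = True

    total_sd = np.where(
        block1 >= 0, np.hypot(spec.loading, spec.noise_sd), 1.0
    )

    def one_region(block_of: np.ndarray, ss, tag: str) -> ExpressionMatrix:
        region_rng = np.random.default_rng(ss)
        n = spec.n_affected + spec.n_control
        values = spec.baseline + block_values(
            block_of, n, spec.loading, spec.noise_sd, region_rng
        )
        values[de_mask, : spec.n_affected] += (
            spec.de_effect * total_sd[de_mask, None]
        )
        samples = [f"{tag}A{i:02d}" for i in range(1, spec.n_affected + 1)] + [
            f"{tag}C{i:02d}" for i in range(1, spec.n_control + 1)
        ]
        groups = {
            s: ("affected" if s[len(tag)] == "A" else "control") for s in samples
        }
        return ExpressionMatrix(genes, samples, values, groups)

    expr1 = one_region(block1, ss_r1, "R1")
    expr2 = one_region(block2, ss_r2, "R2")
    truth = Truth(
        de_genes=[genes[i] for i in np.flatnonzero(de_mask)],
        planted_genes=[genes[i] for i in planted_idx],
        blocks_region1={g: int(b) for g, b in zip(genes, block1)},
        blocks_region2={g: int(b) for g, b in zip(genes, block2)},
        spec=asdict(spec),
    )
    return expr1, expr2, truth


@dataclass
class RecoveryResult:
    """Planted-gene recovery metrics for one generated pair."""

    sensitivity: float  # NaN when no genes were planted
    false_discovery_proportion: float
    zero_to: list[str]
    planted: list[str]


def recovery_test(
    spec: SyntheticSpec,
    cfg: EdgeRuleConfig | None = None,
    samples: str = "affected",
    to_threshold: float = 0.0,
) -> RecoveryResult:
    """End-to-end check: are planted genes recovered as zero-overlap genes?

    Builds both regional networks over the truth DE genes (the intersection,
    since the generator shifts the same genes in both regions), computes the
    topological-overlap profile, and scores the zero-overlap list against
    the planted genes.
    """
    expr1, expr2, truth = generate_pair(spec)
    nodes = truth.de_genes
    net1 = build_network(expr1.subset_genes(nodes).subset_samples(samples), cfg)
    net2 = build_network(expr2.subset_genes(nodes).subset_samples(samples), cfg)
    zero = zero_to_genes(to_profile(net1, net2), to_threshold)
    planted = truth.planted_genes
    zero_set = set(zero)
    if planted:
        sensitivity = len(zero_set & set(planted)) / len(planted)
    else:
        sensitivity = float("nan")
    fdp = len(zero_set - set(planted)) / len(zero) if zero else 0.0
    return RecoveryResult(sensitivity, fdp, zero, list(planted))
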