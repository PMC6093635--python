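"""Per-trait gene-based tests with an LD-aware Monte-Carlo null.

The gene statistic is the sum of squared per-SNP z-scores (beta/SE). Its
null distribution is simulated by drawing zero-mean multivariate-normal
vectors with covariance equal to the gene's (PD-shrunk) LD matrix; the
p-value uses the +1/+1 correction so it is never zero. Simulation counts
escalate through stages while the estimate is still in the extreme tail,
giving a floor of 1/(max stage + 1). Genes significant for more than one
trait at the Bonferroni threshold are called pleiotropic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._rng import stable_rng
from .annotate import GeneSnpMap, HarmonizedStats, LdMatrix, compute_ld
from .cca import shrink_to_pd
from .io_formats import ReferencePanel

logger = logging.getLogger(__name__)

DEFAULT_STAGES = (1_000, 10_000, 1_000_000)
_CHUNK = 65_536  # draws per block, bounds peak memory at ~m * _CHUNK floats


@dataclass
class GeneTraitMatrix:
    """Per-gene, per-trait Monte-Carlo p-values plus the shared threshold."""

    genes: list[str]
    traits: list[str]
    p: np.ndarray  # (n_genes, K), entries in (0, 1]
    sims_used: np.ndarray  # (n_genes, K) int
    threshold: float

    def significant_mask(self) -> np.ndarray:
        return self.p < self.threshold


@dataclass
class PleiotropyCall:
    gene: str
    significant_traits: list[str]
    p_values: dict[str, float]


def snp_z_scores(
    harmonized: HarmonizedStats, trait: str, snp_ids: Sequence[str]
) -> np.ndarray:
    """z_j = beta_j / se_j for the trait, in the given SNP order."""
    rows = harmonized.rows(snp_ids)
    k = harmonized.trait_index(trait)
    return harmonized.beta[rows, k] / harmonized.se[rows, k]


def gene_statistic(z: Sequence[float]) -> float:
    """Sum of squared z-scores; the order of SNPs is irrelevant."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("gene_statistic requires at least one z-score")
    return float(np.sum(z**2))


def vegas_pvalue(
    z: Sequence[float],
    ld: LdMatrix,
    stages: Sequence[int] = DEFAULT_STAGES,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, int]:
    """Monte-Carlo p-value for the sum-of-squared-z statistic under LD.

    Draws come from N(0, ld.r) after PD shrinkage; at each stage s the
    estimate is p = (#{draws >= observed} + 1) / (s + 1), and the next
    stage is entered while p < 10/s. Returns (p, sims_used).
    """
    z = np.asarray(z, dtype=float)
    m = len(ld.snp_ids)
    if z.shape != (m,):
        raise ValueError(f"z length {z.shape} does not match LD dimension {m}")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = gene_statistic(z)
    cov, _ = shrink_to_pd(ld.r)
    chol = np.linalg.cholesky(cov)

    p = 1.0
    sims_used = 0
    for stage_i, sims in enumerate(stages):
        exceed = 0
        remaining = int(sims)
        while remaining > 0:
            c = min(remaining, _CHUNK)
            draws = rng.standard_normal((c, m)) @ chol.T
            exceed += int(np.count_nonzero(np.einsum("ij,ij->i", draws, draws) >= observed))
            remaining -= c
        p = (exceed + 1) / (sims + 1)
        sims_used = int(sims)
        last = stage_i == len(stages) - 1
        if not last and p >= 10.0 / sims:
            break
        if last:
            break
    return p, sims_used


def run_gene_tests(
    harmonized: HarmonizedStats,
    gene_map: GeneSnpMap,
    panel: ReferencePanel,
    genes: Sequence[str],
    seed: int,
    stages: Sequence[int] = DEFAULT_STAGES,
    alpha: float = 0.05,
) -> GeneTraitMatrix:
    """Per-trait Monte-Carlo gene p-values for the selected genes.

    The Bonferroni threshold is ``alpha / len(genes)``. Each (gene, trait)
    cell uses its own RNG stream derived from the master seed by stable
    hashing, so results do not depend on execution order. Per-gene
    failures are logged and reported as p = NaN, never fatal.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("run_gene_tests requires at least one gene")
    unknown = [g for g in genes if g not in gene_map.genes]
    if unknown:
        raise KeyError(f"genes absent from the gene-SNP map: {unknown[:5]}")
    traits = list(harmonized.trait_names)
    p = np.full((len(genes), len(traits)), np.nan)
    sims = np.zeros((len(genes), len(traits)), dtype=np.int64)
    for i, gene in enumerate(genes):
        snp_ids = gene_map.genes[gene]
        try:
            ld = compute_ld(panel, snp_ids)
        except (KeyError, ValueError) as exc:
            logger.warning("gene %s skipped in gene-based stage: %s", gene, exc)
            continue
        for k, trait in enumerate(traits):
            z = snp_z_scores(harmonized, trait, snp_ids)
            rng = stable_rng(seed, "vegas", gene, trait)
            p[i, k], sims[i, k] = vegas_pvalue(z, ld, stages=stages, rng=rng)
    return GeneTraitMatrix(
        genes=genes,
        traits=traits,
        p=p,
        sims_used=sims,
        threshold=alpha / len(genes),
    )


def call_pleiotropy(matrix: GeneTraitMatrix) -> list[PleiotropyCall]:
    """Keep genes significant for more than one trait.

    A gene is called pleiotropic iff at least two traits have
    p < matrix.threshold. Calls are sorted by significant-trait count
    (descending) then by the gene's smallest p-value.
    """
    calls: list[PleiotropyCall] = []
    mask = matrix.significant_mask()
    for i, gene in enumerate(matrix.genes):
        hits = [t for k, t in enumerate(matrix.traits) if mask[i, k]]
        if len(hits) >= 2:
            calls.append(
                PleiotropyCall(
                    gene=gene,
                    significant_traits=hits,
                    p_values={t: float(matrix.p[i, k]) for k, t in enumerate(matrix.traits)},
                )
            )
    calls.sort(
        key=lambda c: (-len(c.significant_traits), min(c.p_values.values()), c.gene)
    )
    return calls
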