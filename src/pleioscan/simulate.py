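"""Synthetic multi-trait GWAS scenarios with planted pleiotropic genes.

Genotypes are built per gene from latent AR(1) Gaussians thresholded at
MAF-derived quantiles (two haplotypes summed into {0,1,2} dosages); genes
are mutually LD-independent. Phenotypes combine planted standardized-SNP
effects with correlated Gaussian residuals so the total trait correlation
approximates the configured matrix when effects are small. Summary
statistics come from per-SNP univariate regressions on per-trait
subsamples, emulating distinct (partially overlapping) consortium cohorts
of unequal size. Ground truth (which gene affects which trait, and through
which SNP) is retained for recovery testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sp_stats

from ._rng import stable_rng
from .cca import shrink_to_pd
from .io_formats import (
    GeneRange,
    GeneSetLibrary,
    ReferencePanel,
    SummaryStatsTable,
    TraitCorrelationMatrix,
    write_gene_ranges,
    write_gmt,
    write_panel_matrix,
    write_summary_stats,
    write_trait_correlations,
)

logger = logging.getLogger(__name__)

#: six-trait default: glycemic (FG, FI), adiposity (BMI, WHR) and lipid
#: (HDL, TG) phenotypes with a realistic correlation structure
DEFAULT_TRAIT_NAMES = ("FG", "FI", "BMI", "WHR", "HDL", "TG")

DEFAULT_TRAIT_CORR = np.array(
    [
        [1.00, 0.35, 0.24, 0.17, -0.15, 0.19],
        [0.35, 1.00, 0.52, 0.39, -0.37, 0.40],
        [0.24, 0.52, 1.00, 0.51, -0.32, 0.30],
        [0.17, 0.39, 0.51, 1.00, -0.30, 0.33],
        [-0.15, -0.37, -0.32, -0.30, 1.00, -0.52],
        [0.19, 0.40, 0.30, 0.33, -0.52, 1.00],
    ]
)

#: per-trait GWAS sample sizes, one tenth of the consortium-scale template
#: (46,694 / 24,245 / 87,048 / 54,572 / 62,166 / 62,166)
DEFAULT_PER_TRAIT_N = (4669, 2424, 8704, 5457, 6216, 6216)


@dataclass
class SimulationConfig:
    """Knobs for one synthetic scenario; every field has a runnable default."""

    n_genes: int = 60
    snps_min: int = 1
    snps_max: int = 40
    snps_mean: float = 13.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.5
    trait_names: tuple[str, ...] = DEFAULT_TRAIT_NAMES
    trait_corr: np.ndarray = field(default_factory=lambda: DEFAULT_TRAIT_CORR.copy())
    per_trait_n: tuple[int, ...] = DEFAULT_PER_TRAIT_N
    n_cohort: int = 10_000
    n_panel: int = 500
    n_pleio: int = 5
    n_single: int = 5
    traits_per_pleio: int = 2
    h2_per_gene: float = 0.01
    n_noise_sets: int = 10
    noise_set_size: int = 8
    planted_set_extra: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.trait_corr = np.asarray(self.trait_corr, dtype=float)
        k = len(self.trait_names)
        if self.trait_corr.shape != (k, k):
            raise ValueError("trait_corr shape does not match trait_names")
        if len(self.per_trait_n) != k:
            raise ValueError("per_trait_n length does not match trait_names")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 <= abs(self.ld_rho) < 1.0:
            raise ValueError("ld_rho must satisfy |rho| < 1")
        if not 0.0 < self.h2_per_gene < 1.0:
            raise ValueError("h2_per_gene must lie in (0, 1)")
        if self.n_pleio + self.n_single > self.n_genes:
            raise ValueError("n_pleio + n_single exceeds n_genes")
        if max(self.per_trait_n) > self.n_cohort:
            raise ValueError("per_trait_n entries must not exceed n_cohort")
        if not 2 <= self.traits_per_pleio <= k:
            raise ValueError("traits_per_pleio must lie in [2, K]")

    @property
    def k(self) -> int:
        return len(self.trait_names)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("trait_names", "per_trait_n", "maf_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "trait_corr" in raw:
            raw["trait_corr"] = np.asarray(raw["trait_corr"], dtype=float)
        return cls(**raw)


@dataclass
class GenomeLayout:
    """Deterministic gene/SNP scaffold derived from the config seed."""

    gene_names: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    maf: np.ndarray
    gene_of_snp: np.ndarray  # gene index per SNP
    snp_slices: list[slice]  # per-gene contiguous SNP ranges

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class SyntheticTruth:
    """Planted gene-trait effects and their causal SNPs."""

    gene_names: list[str]
    trait_names: list[str]
    effect_matrix: np.ndarray  # (n_genes, K) standardized effect sizes
    causal_snps: dict[str, list[int]]  # gene -> SNP indices within the gene

    @property
    def pleiotropic_genes(self) -> list[str]:
        counts = np.count_nonzero(self.effect_matrix, axis=1)
        return [g for g, c in zip(self.gene_names, counts) if c >= 2]

    @property
    def single_trait_genes(self) -> list[str]:
        counts = np.count_nonzero(self.effect_matrix, axis=1)
        return [g for g, c in zip(self.gene_names, counts) if c == 1]

    @property
    def null_genes(self) -> list[str]:
        counts = np.count_nonzero(self.effect_matrix, axis=1)
        return [g for g, c in zip(self.gene_names, counts) if c == 0]


@dataclass
class Scenario:
    """A complete self-consistent input bundle plus its ground truth."""

    config: SimulationConfig
    layout: GenomeLayout
    panel: ReferencePanel
    tables: list[SummaryStatsTable]
    ranges: list[GeneRange]
    trait_corr: TraitCorrelationMatrix
    library: GeneSetLibrary
    truth: SyntheticTruth
    genotypes: np.ndarray | None = None  # GWAS cohort dosages (individuals x SNPs)
    phenotypes: np.ndarray | None = None  # cohort phenotype matrix (individuals x K)
    planted_set_name: str = "PLANTED_SET"


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

_GENE_SPACING = 1_000_000
_SNP_SPACING = 1_000


def make_layout(config: SimulationConfig) -> GenomeLayout:
    """Draw gene sizes and MAFs; gene g's SNPs sit at regular positions so
    gene ranges tile them exactly."""
    rng = stable_rng(config.seed, "layout")
    sizes = 1 + rng.poisson(config.snps_mean - 1, size=config.n_genes)
    sizes = np.clip(sizes, config.snps_min, config.snps_max)
    gene_names, snp_ids, chrom, pos, maf, gene_of, slices = [], [], [], [], [], [], []
    cursor = 0
    for g, m in enumerate(sizes):
        name = f"GENE{g + 1:04d}"
        gene_names.append(name)
        start = 1 + g * _GENE_SPACING
        for j in range(m):
            snp_ids.append(f"rs{g + 1:04d}_{j + 1:03d}")
            chrom.append("1")
            pos.append(start + j * _SNP_SPACING)
        maf.extend(rng.uniform(*config.maf_range, size=m))
        gene_of.extend([g] * m)
        slices.append(slice(cursor, cursor + int(m)))
        cursor += int(m)
    return GenomeLayout(
        gene_names=gene_names,
        snp_ids=snp_ids,
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        maf=np.asarray(maf, dtype=float),
        gene_of_snp=np.asarray(gene_of, dtype=int),
        snp_slices=slices,
    )


def layout_ranges(layout: GenomeLayout) -> list[GeneRange]:
    ranges = []
    for g, name in enumerate(layout.gene_names):
        s = layout.snp_slices[g]
        ranges.append(
            GeneRange(
                name=name,
                chrom=str(layout.chrom[s.start]),
                start=int(layout.pos[s.start]),
                end=int(layout.pos[s.stop - 1]),
            )
        )
    return ranges


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _gene_dosages(
    n_individuals: int, maf: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Dosages for one gene: two latent AR(1) haplotypes thresholded at the
    MAF quantile and summed."""
    m = maf.size
    thresholds = sp_stats.norm.ppf(1.0 - maf)
    z = rng.standard_normal((2 * n_individuals, m))
    latent = np.empty_like(z)
    latent[:, 0] = z[:, 0]
    scale = np.sqrt(1.0 - rho**2)
    for j in range(1, m):
        latent[:, j] = rho * latent[:, j - 1] + scale * z[:, j]
    haplo = (latent > thresholds).astype(np.int8)
    return (haplo[:n_individuals] + haplo[n_individuals:]).astype(np.int8)


def simulate_genotypes(
    config: SimulationConfig,
    layout: GenomeLayout,
    n_individuals: int,
    stream: str,
) -> np.ndarray:
    """Full dosage matrix (individuals x SNPs); genes are LD-independent."""
    out = np.empty((n_individuals, layout.n_snps), dtype=np.int8)
    for g in range(len(layout.gene_names)):
        s = layout.snp_slices[g]
        rng = stable_rng(config.seed, "genotypes", stream, g)
        out[:, s] = _gene_dosages(n_individuals, layout.maf[s], config.ld_rho, rng)
    return out


def simulate_panel(
    config: SimulationConfig,
    layout: GenomeLayout | None = None,
    n_individuals: int | None = None,
) -> ReferencePanel:
    """Reference panel drawn independently of the GWAS cohort."""
    layout = layout or make_layout(config)
    n = n_individuals or config.n_panel
    dosages = simulate_genotypes(config, layout, n, stream="panel").astype(float)
    var = dosages.var(axis=0)
    keep = var > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("simulated panel: %d monomorphic SNPs dropped", dropped)
    return ReferencePanel(
        snp_ids=[s for s, k in zip(layout.snp_ids, keep) if k],
        chrom=layout.chrom[keep],
        pos=layout.pos[keep],
        dosages=dosages[:, keep],
    )


# ---------------------------------------------------------------------------
# truth and phenotypes
# ---------------------------------------------------------------------------


def make_truth(config: SimulationConfig, layout: GenomeLayout) -> SyntheticTruth:
    """Plant effects: ``n_pleio`` genes touch ``traits_per_pleio`` traits,
    ``n_single`` genes touch one trait; each planted (gene, trait) effect
    explains ``h2_per_gene`` of trait variance through the gene's FIRST
    SNP (which the keep-first pruner always retains)."""
    rng = stable_rng(config.seed, "truth")
    k = config.k
    effects = np.zeros((config.n_genes, k))
    chosen = rng.choice(config.n_genes, size=config.n_pleio + config.n_single, replace=False)
    pleio, single = chosen[: config.n_pleio], chosen[config.n_pleio :]
    beta = np.sqrt(config.h2_per_gene)
    causal: dict[str, list[int]] = {}
    for g in pleio:
        traits = rng.choice(k, size=config.traits_per_pleio, replace=False)
        effects[g, traits] = beta * rng.choice((-1.0, 1.0), size=traits.size)
        causal[layout.gene_names[g]] = [0]
    for g in single:
        trait = rng.integers(k)
        effects[g, trait] = beta * rng.choice((-1.0, 1.0))
        causal[layout.gene_names[g]] = [0]
    return SyntheticTruth(
        gene_names=list(layout.gene_names),
        trait_names=list(config.trait_names),
        effect_matrix=effects,
        causal_snps=causal,
    )


def simulate_phenotypes(
    genotypes: np.ndarray,
    layout: GenomeLayout,
    truth: SyntheticTruth,
    trait_corr: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Phenotype matrix (individuals x K).

    Trait k = sum over planted genes of effect * standardized causal
    genotype + correlated residual; the residual correlation equals the
    target matrix, so total phenotypic correlations approximate it when
    planted effects are small.
    """
    n, _ = genotypes.shape
    k = len(truth.trait_names)
    genetic = np.zeros((n, k))
    residual_var = np.ones(k)
    gene_index = {g: i for i, g in enumerate(layout.gene_names)}
    for gene, snps in truth.causal_snps.items():
        g = gene_index[gene]
        row = truth.effect_matrix[g]
        s = layout.snp_slices[g]
        for j in snps:
            x = genotypes[:, s.start + j].astype(float)
            sd = x.std()
            if sd == 0:
                logger.warning("causal SNP of %s is monomorphic in the cohort", gene)
                continue
            x_std = (x - x.mean()) / sd
            share = row / max(1, len(snps))
            genetic += np.outer(x_std, share)
            residual_var -= share**2
    residual_var = np.clip(residual_var, 1e-6, None)
    corr_pd, _ = shrink_to_pd(np.asarray(trait_corr, dtype=float))
    chol = np.linalg.cholesky(corr_pd)
    residual = rng.standard_normal((n, k)) @ chol.T
    return genetic + residual * np.sqrt(residual_var)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def compute_summary_stats(
    genotypes: np.ndarray,
    phenotypes: np.ndarray,
    layout: GenomeLayout,
    trait_names: Sequence[str],
    per_trait_n: Sequence[int],
    rng: np.random.Generator,
) -> list[SummaryStatsTable]:
    """Per-trait univariate GWAS on an independent subsample per trait.

    For each trait a random subset of ``per_trait_n`` individuals is drawn
    (subsets may overlap across traits, mimicking partially overlapping
    consortium cohorts); the trait is standardized within its subsample
    and regressed on each dosage column, yielding beta, SE and n.
    """
    n_cohort, n_snps = genotypes.shape
    if max(per_trait_n) > n_cohort:
        raise ValueError("per-trait subsample exceeds cohort size")
    tables = []
    for trait, n_sub in zip(trait_names, per_trait_n):
        idx = rng.choice(n_cohort, size=int(n_sub), replace=False)
        x = genotypes[idx].astype(float)
        y = phenotypes[idx, list(trait_names).index(trait)]
        y = (y - y.mean()) / y.std()
        xc = x - x.mean(axis=0)
        sxx = np.einsum("ij,ij->j", xc, xc)
        sxy = xc.T @ y
        syy = float(y @ y)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = sxy / sxx
            rss = np.clip(syy - beta * sxy, 0.0, None)
            sigma2 = rss / (n_sub - 2)
            se = np.sqrt(sigma2 / sxx)
        ok = np.isfinite(beta) & np.isfinite(se) & (se > 0)
        if not ok.all():
            logger.warning(
                "trait %s: %d SNPs monomorphic in subsample dropped", trait, int((~ok).sum())
            )
        df = pd.DataFrame(
            {
                "SNP": np.asarray(layout.snp_ids, dtype=object)[ok],
                "CHR": layout.chrom[ok],
                "POS": layout.pos[ok],
                "EA": "A",
                "OA": "G",
                "BETA": beta[ok],
                "SE": se[ok],
                "N": int(n_sub),
            }
        )
        tables.append(SummaryStatsTable(trait, df))
    return tables


# ---------------------------------------------------------------------------
# null summary-level blocks (for calibration studies)
# ---------------------------------------------------------------------------


def simulate_null_sigma_xy(
    sigma_xx: np.ndarray,
    sigma_yy: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a normalized-beta block under the global null.

    vec(sigma_xy) ~ N(0, kron(sigma_xx, sigma_yy) / n), realized as
    L_xx @ Z @ L_yy' / sqrt(n) with iid standard-normal Z — the sampling
    distribution of SNP-trait sample correlations at large n.
    """
    m, k = sigma_xx.shape[0], sigma_yy.shape[0]
    lxx = np.linalg.cholesky(sigma_xx)
    lyy = np.linalg.cholesky(sigma_yy)
    z = rng.standard_normal((m, k))
    return (lxx @ z @ lyy.T) / np.sqrt(n)


# ---------------------------------------------------------------------------
# scenario assembly and writing
# ---------------------------------------------------------------------------


def make_scenario(config: SimulationConfig) -> Scenario:
    """Generate a complete input bundle (panel, summary stats, gene ranges,
    trait correlations, GMT library with one planted set) plus truth."""
    layout = make_layout(config)
    truth = make_truth(config, layout)
    genotypes = simulate_genotypes(config, layout, config.n_cohort, stream="cohort")
    phenotypes = simulate_phenotypes(
        genotypes, layout, truth, config.trait_corr, stable_rng(config.seed, "phenotypes")
    )
    tables = compute_summary_stats(
        genotypes,
        phenotypes,
        layout,
        config.trait_names,
        config.per_trait_n,
        stable_rng(config.seed, "gwas-subsamples"),
    )
    panel = simulate_panel(config, layout)
    trait_corr = TraitCorrelationMatrix(list(config.trait_names), config.trait_corr)
    library = _make_library(config, layout, truth)
    return Scenario(
        config=config,
        layout=layout,
        panel=panel,
        tables=tables,
        ranges=layout_ranges(layout),
        trait_corr=trait_corr,
        library=library,
        truth=truth,
        genotypes=genotypes,
        phenotypes=phenotypes,
    )


def _make_library(
    config: SimulationConfig, layout: GenomeLayout, truth: SyntheticTruth
) -> GeneSetLibrary:
    rng = stable_rng(config.seed, "library")
    all_genes = np.asarray(layout.gene_names, dtype=object)
    sets: dict[str, list[str]] = {}
    planted = list(truth.pleiotropic_genes)
    if planted:
        others = [g for g in all_genes if g not in set(planted)]
        extra = min(config.planted_set_extra, len(others))
        noise = list(rng.choice(others, size=extra, replace=False)) if extra else []
        sets["PLANTED_SET"] = planted + noise
    for i in range(config.n_noise_sets):
        size = min(config.noise_set_size, len(all_genes))
        sets[f"NOISE_SET_{i + 1:02d}"] = list(rng.choice(all_genes, size=size, replace=False))
    return GeneSetLibrary(sets=sets, source_label="synthetic")


def write_scenario(scenario: Scenario, out_dir: str | Path) -> dict[str, str]:
    """Write every bundle component as plain text; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for table in scenario.tables:
        p = out / f"sumstats_{table.trait_name}.tsv"
        write_summary_stats(table, p)
        paths[f"sumstats:{table.trait_name}"] = str(p)
    p = out / "trait_corr.tsv"
    write_trait_correlations(scenario.trait_corr, p)
    paths["trait_corr"] = str(p)
    p = out / "genes.glist"
    write_gene_ranges(scenario.ranges, p)
    paths["gene_ranges"] = str(p)
    p = out / "panel.dosage.tsv"
    write_panel_matrix(scenario.panel, p)
    paths["panel"] = str(p)
    p = out / "library.gmt"
    write_gmt(scenario.library, p)
    paths["gene_sets"] = str(p)
    p = out / "truth_effects.tsv"
    pd.DataFrame(
        scenario.truth.effect_matrix,
        index=scenario.truth.gene_names,
        columns=scenario.truth.trait_names,
    ).to_csv(p, sep="\t")
    paths["truth"] = str(p)
    return paths
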