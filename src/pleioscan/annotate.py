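"""SNP harmonization across traits, gene assignment, and LD pruning.

The harmonization step intersects SNPs across all traits and the reference
panel, aligns effect alleles to the first trait (flipping beta signs where
the allele pair is reversed), and drops strand-ambiguous (A/T, C/G) and
allele-mismatched SNPs. Gene assignment uses 1-based inclusive intervals.
Pruning is the greedy keep-first scan in ascending position order at
r^2 <= r2_max, applied per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneRange, ReferencePanel, SummaryStatsTable

logger = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {frozenset("AT"), frozenset("CG")}


@dataclass
class HarmonizationReport:
    kept: int = 0
    flipped: int = 0  # (SNP, trait) beta sign flips
    dropped_ambiguous: int = 0
    dropped_mismatch: int = 0
    dropped_not_shared: int = 0


@dataclass
class HarmonizedStats:
    """Allele-aligned summary statistics on the shared SNP set.

    Arrays are SNP-major: ``beta``, ``se`` and ``n`` have one row per SNP
    (position order) and one column per trait. ``ea``/``oa`` are the
    common effect/other alleles after alignment to the first trait.
    """

    trait_names: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ea: np.ndarray
    oa: np.ndarray
    beta: np.ndarray  # (n_snps, K)
    se: np.ndarray  # (n_snps, K)
    n: np.ndarray  # (n_snps, K) int
    report: HarmonizationReport = field(default_factory=HarmonizationReport)

    def __post_init__(self) -> None:
        self._index = {s: j for j, s in enumerate(self.snp_ids)}

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def rows(self, snp_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in snp_ids if s not in self._index]
        if missing:
            raise KeyError(f"SNPs absent from harmonized stats: {missing[:5]}")
        return np.asarray([self._index[s] for s in snp_ids], dtype=int)

    def trait_index(self, trait: str) -> int:
        try:
            return self.trait_names.index(trait)
        except ValueError:
            raise KeyError(f"unknown trait {trait!r}") from None

    def to_tables(self) -> list[SummaryStatsTable]:
        """Re-materialize one SummaryStatsTable per trait (already aligned)."""
        tables = []
        for k, trait in enumerate(self.trait_names):
            df = pd.DataFrame(
                {
                    "SNP": self.snp_ids,
                    "CHR": self.chrom,
                    "POS": self.pos,
                    "EA": self.ea,
                    "OA": self.oa,
                    "BETA": self.beta[:, k],
                    "SE": self.se[:, k],
                    "N": self.n[:, k],
                }
            )
            tables.append(SummaryStatsTable(trait, df))
        return tables


def harmonize_traits(
    tables: Sequence[SummaryStatsTable], panel: ReferencePanel
) -> HarmonizedStats:
    """Intersect and allele-align summary statistics across traits.

    The first table is the alignment reference. A trait whose (EA, OA)
    pair is the reverse of the reference has its beta negated; SNPs with
    any other allele combination are dropped as mismatches, and
    strand-ambiguous SNPs (A/T or C/G) are dropped outright.

    Raises ``ValueError`` when fewer than two traits are given or the
    intersection is empty.
    """
    if len(tables) < 2:
        raise ValueError("harmonization requires at least two traits")
    report = HarmonizationReport()

    shared: set[str] = set(tables[0].df["SNP"])
    union: set[str] = set(shared)
    for t in tables[1:]:
        ids = set(t.df["SNP"])
        shared &= ids
        union |= ids
    shared &= set(panel.snp_ids)
    union |= set(panel.snp_ids)
    if not shared:
        raise ValueError(
            "no SNPs shared by all traits and the reference panel; "
            "check SNP id conventions across inputs"
        )
    report.dropped_not_shared = len(union) - len(shared)

    ref = tables[0].df.set_index("SNP")
    order = ref.loc[sorted(shared)].sort_values(["CHR", "POS"]).index
    ref = ref.loc[order]

    ea = ref["EA"].to_numpy(dtype=object)
    oa = ref["OA"].to_numpy(dtype=object)
    ambiguous = np.array(
        [frozenset((a, b)) in AMBIGUOUS_PAIRS for a, b in zip(ea, oa)], dtype=bool
    )
    keep = ~ambiguous
    report.dropped_ambiguous = int(ambiguous.sum())

    K = len(tables)
    m = len(order)
    beta = np.empty((m, K))
    se = np.empty((m, K))
    n = np.empty((m, K), dtype=np.int64)
    beta[:, 0] = ref["BETA"].to_numpy(float)
    se[:, 0] = ref["SE"].to_numpy(float)
    n[:, 0] = ref["N"].to_numpy(np.int64)

    for k, table in enumerate(tables[1:], start=1):
        df = table.df.set_index("SNP").loc[order]
        same = (df["EA"].to_numpy(object) == ea) & (df["OA"].to_numpy(object) == oa)
        swapped = (df["EA"].to_numpy(object) == oa) & (df["OA"].to_numpy(object) == ea)
        mismatch = ~(same | swapped)
        report.dropped_mismatch += int((mismatch & keep).sum())
        report.flipped += int((swapped & keep & ~mismatch).sum())
        keep &= ~mismatch
        sign = np.where(swapped, -1.0, 1.0)
        beta[:, k] = df["BETA"].to_numpy(float) * sign
        se[:, k] = df["SE"].to_numpy(float)
        n[:, k] = df["N"].to_numpy(np.int64)

    report.kept = int(keep.sum())
    if report.kept == 0:
        raise ValueError("all shared SNPs were dropped during harmonization")
    logger.info(
        "harmonized %d SNPs across %d traits (%d flips, %d ambiguous, %d mismatched dropped)",
        report.kept, K, report.flipped, report.dropped_ambiguous, report.dropped_mismatch,
    )
    return HarmonizedStats(
        trait_names=[t.trait_name for t in tables],
        snp_ids=list(order[keep]),
        chrom=ref["CHR"].to_numpy(object)[keep],
        pos=ref["POS"].to_numpy(np.int64)[keep],
        ea=ea[keep],
        oa=oa[keep],
        beta=beta[keep],
        se=se[keep],
        n=n[keep],
        report=report,
    )


# ---------------------------------------------------------------------------
# gene assignment
# ---------------------------------------------------------------------------


@dataclass
class GeneSnpMap:
    """Mapping gene -> SNP ids in ascending position order.

    Genes whose interval contains no SNP are omitted from ``genes`` but
    counted in ``n_genes_empty``. A SNP may belong to several overlapping
    genes.
    """

    genes: dict[str, list[str]]
    flank: int = 0
    n_genes_empty: int = 0

    def __len__(self) -> int:
        return len(self.genes)


def assign_snps_to_genes(
    snp_ids: Sequence[str],
    chrom: Sequence[str],
    pos: Sequence[int],
    ranges: Sequence[GeneRange],
    flank: int = 0,
) -> GeneSnpMap:
    """Assign SNPs to genes by 1-based inclusive interval containment.

    A SNP belongs to a gene when ``start - flank <= pos <= end + flank``
    on the matching chromosome (both boundaries inclusive).
    """
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    snp_ids = np.asarray(snp_ids, dtype=object)
    order = np.lexsort((pos, chrom))

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in np.unique(chrom):
        sel = order[chrom[order] == c]
        by_chrom[str(c)] = (pos[sel], snp_ids[sel])

    genes: dict[str, list[str]] = {}
    n_empty = 0
    for g in ranges:
        hit = by_chrom.get(g.chrom)
        if hit is None:
            n_empty += 1
            continue
        p, ids = hit
        lo = np.searchsorted(p, g.start - flank, side="left")
        hi = np.searchsorted(p, g.end + flank, side="right")
        if hi > lo:
            genes[g.name] = list(ids[lo:hi])
        else:
            n_empty += 1
    return GeneSnpMap(genes=genes, flank=flank, n_genes_empty=n_empty)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


@dataclass
class LdMatrix:
    """Pairwise Pearson correlations between dosage vectors."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.snp_ids)
        if self.r.shape != (m, m):
            raise ValueError("LD matrix shape inconsistent with SNP ids")


def compute_ld(panel: ReferencePanel, snp_ids: Sequence[str]) -> LdMatrix:
    """Pearson correlation of mean-imputed dosage columns.

    Missing dosages are imputed to the SNP mean for this computation only.
    Requires at least two panel individuals; absent SNPs raise ``KeyError``
    naming them.
    """
    if panel.n_individuals < 2:
        raise ValueError("LD estimation requires at least two individuals")
    x = panel.columns(snp_ids).copy()
    col_mean = np.nanmean(x, axis=0)
    nan_r, nan_c = np.where(np.isnan(x))
    x[nan_r, nan_c] = col_mean[nan_c]
    if x.shape[1] == 1:
        r = np.ones((1, 1))
    else:
        r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return LdMatrix(snp_ids=list(snp_ids), r=r)


def prune_ld(ld: LdMatrix, r2_max: float = 0.01) -> list[str]:
    """Greedy keep-first LD pruning in the matrix's SNP order.

    A SNP is kept iff its squared correlation with every already-kept SNP
    is <= ``r2_max``; callers pass SNPs in ascending position order.
    """
    kept_idx: list[int] = []
    r2 = ld.r**2
    for j in range(len(ld.snp_ids)):
        if all(r2[j, i] <= r2_max for i in kept_idx):
            kept_idx.append(j)
    return [ld.snp_ids[i] for i in kept_idx]
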