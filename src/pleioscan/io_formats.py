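"""Readers and writers for the external formats the pipeline consumes.

Every reader validates its input strictly, rejects malformed rows with a
counted reason, and returns a typed in-memory structure so downstream
modules never touch raw files. Coordinates are 1-based and ranges are
inclusive on both ends (glist-hg19 convention).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: logical column names of a summary-statistics table, in canonical order
SUMMARY_COLUMNS = ("SNP", "CHR", "POS", "EA", "OA", "BETA", "SE", "N")

VALID_ALLELES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ReadReport:
    """Row-level accounting for one reader invocation.

    ``n_input == n_kept + n_rejected`` always holds; ``reasons`` breaks
    the rejections down by cause.
    """

    n_input: int = 0
    n_kept: int = 0
    n_rejected: int = 0
    reasons: Counter = field(default_factory=Counter)

    def reject(self, reason: str, count: int = 1) -> None:
        self.n_rejected += count
        self.reasons[reason] += count


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


@dataclass
class SummaryStatsTable:
    """One trait's per-SNP (beta, SE, n) records.

    ``df`` carries the canonical columns :data:`SUMMARY_COLUMNS`; SNP ids
    are unique, SE strictly positive and N > 1 for every record.
    """

    trait_name: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SUMMARY_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"summary table missing columns: {missing}")
        self.df = self.df.loc[:, list(SUMMARY_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["SNP"].tolist()


def read_summary_stats(
    path: str | Path,
    trait_name: str,
    column_map: Mapping[str, str] | None = None,
) -> tuple[SummaryStatsTable, ReadReport]:
    """Read a tab/whitespace-delimited per-trait GWAS summary table.

    Parameters
    ----------
    path:
        Header TSV with at least the columns named in ``column_map``.
    trait_name:
        Label attached to the returned table.
    column_map:
        Mapping from logical names (:data:`SUMMARY_COLUMNS`) to the file's
        header names; identity by default.

    Returns
    -------
    (table, report):
        Rows with missing/invalid beta or SE, non-positive SE, invalid
        alleles, N <= 1 or duplicate SNP ids are dropped and counted in
        the report.
    """
    column_map = dict(column_map or {})
    raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    report = ReadReport(n_input=len(raw))

    rename = {}
    for logical in SUMMARY_COLUMNS:
        source = column_map.get(logical, logical)
        if source not in raw.columns:
            raise FormatError(
                f"summary file {path!s} lacks column {source!r} (mapped to {logical})"
            )
        rename[source] = logical
    df = raw.rename(columns=rename)

    for col in ("POS", "N"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("BETA", "SE"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("EA", "OA"):
        df[col] = df[col].astype(str).str.upper()

    bad_missing = df["BETA"].isna() | df["SE"].isna()
    report.reject("missing_beta_or_se", int(bad_missing.sum()))
    df = df[~bad_missing]

    bad_se = df["SE"] <= 0
    report.reject("nonpositive_se", int(bad_se.sum()))
    df = df[~bad_se]

    bad_allele = ~(df["EA"].isin(VALID_ALLELES) & df["OA"].isin(VALID_ALLELES))
    report.reject("invalid_allele", int(bad_allele.sum()))
    df = df[~bad_allele]

    bad_n = df["N"].isna() | (df["N"] <= 1) | df["POS"].isna()
    report.reject("invalid_n_or_pos", int(bad_n.sum()))
    df = df[~bad_n]

    dup = df["SNP"].duplicated(keep="first")
    report.reject("duplicate_snp", int(dup.sum()))
    df = df[~dup]

    df = df.assign(
        POS=df["POS"].astype(np.int64),
        N=df["N"].astype(np.int64),
        CHR=df["CHR"].astype(str),
        SNP=df["SNP"].astype(str),
    )
    report.n_kept = len(df)
    if report.n_rejected:
        logger.warning(
            "read_summary_stats(%s): rejected %d/%d rows (%s)",
            path, report.n_rejected, report.n_input, dict(report.reasons),
        )
    return SummaryStatsTable(trait_name, df), report


def write_summary_stats(table: SummaryStatsTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trait correlation matrix
# ---------------------------------------------------------------------------


@dataclass
class TraitCorrelationMatrix:
    """K x K phenotypic correlation matrix with ordered trait labels."""

    trait_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.trait_names)
        if self.values.shape != (k, k):
            raise FormatError(
                f"trait correlation matrix shape {self.values.shape} != ({k}, {k})"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise FormatError("trait correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12, rtol=0.0):
            raise FormatError("trait correlation matrix diagonal must be 1")
        off = self.values[~np.eye(k, dtype=bool)]
        if off.size and np.max(np.abs(off)) >= 1.0:
            raise FormatError("off-diagonal trait correlations must satisfy |r| < 1")

    @property
    def k(self) -> int:
        return len(self.trait_names)

    def reordered(self, trait_names: Sequence[str]) -> "TraitCorrelationMatrix":
        idx = [self.trait_names.index(t) for t in trait_names]
        return TraitCorrelationMatrix(list(trait_names), self.values[np.ix_(idx, idx)])


def read_trait_correlations(
    path: str | Path, expected_traits: Sequence[str] | None = None
) -> TraitCorrelationMatrix:
    """Read a labeled square correlation table (TSV, row index = trait).

    The matrix is reordered to ``expected_traits`` when given; missing
    traits, asymmetry beyond 1e-12 or a non-unit diagonal raise
    :class:`FormatError`.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path!s}: row and column labels differ")
    matrix = TraitCorrelationMatrix([str(t) for t in df.columns], df.to_numpy(float))
    if expected_traits is not None:
        missing = set(expected_traits) - set(matrix.trait_names)
        if missing:
            raise FormatError(f"{path!s}: traits absent from matrix: {sorted(missing)}")
        matrix = matrix.reordered(list(expected_traits))
    return matrix


def write_trait_correlations(matrix: TraitCorrelationMatrix, path: str | Path) -> None:
    pd.DataFrame(
        matrix.values, index=matrix.trait_names, columns=matrix.trait_names
    ).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# gene ranges (glist-hg19 style)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRange:
    """1-based, both-ends-inclusive genomic interval of one gene."""

    name: str
    chrom: str
    start: int
    end: int


def read_gene_ranges(path: str | Path) -> tuple[list[GeneRange], ReadReport]:
    """Read a 4-column whitespace file: chrom start end name.

    Rows with start > end are rejected with a logged warning; duplicate
    gene names raise :class:`FormatError`. The result is sorted by
    (chrom, start).
    """
    report = ReadReport()
    ranges: list[GeneRange] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            report.n_input += 1
            if len(fields) != 4:
                report.reject("wrong_field_count")
                continue
            chrom, start_s, end_s, name = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                report.reject("non_integer_coordinate")
                continue
            if start > end:
                report.reject("start_after_end")
                logger.warning("gene %s has start > end (%d > %d); dropped", name, start, end)
                continue
            name = name.upper()
            if name in seen:
                raise FormatError(f"duplicate gene name in {path!s}: {name}")
            seen.add(name)
            ranges.append(GeneRange(name=name, chrom=chrom, start=start, end=end))
    report.n_kept = len(ranges)
    if not ranges:
        logger.warning("gene range file %s yielded no usable ranges", path)
    ranges.sort(key=lambda g: (g.chrom, g.start, g.end, g.name))
    return ranges, report


def write_gene_ranges(ranges: Sequence[GeneRange], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in ranges:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\n")


# ---------------------------------------------------------------------------
# gene-set libraries (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetLibrary:
    """Named gene sets; gene symbols are uppercased at ingest."""

    sets: dict[str, list[str]]
    source_label: str = ""

    def __post_init__(self) -> None:
        normalized: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            genes = list(dict.fromkeys(g.upper() for g in genes))
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            normalized[name] = genes
        self.sets = normalized


def read_gmt(path: str | Path, source_label: str = "") -> tuple[GeneSetLibrary, ReadReport]:
    """Read a GMT file: name, description, then member genes (tab-separated).

    Genes are deduplicated within a set (order preserved) and uppercased;
    lines with fewer than three fields, empty sets after dedup, and
    duplicate set names are rejected with a warning.
    """
    report = ReadReport()
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            report.n_input += 1
            fields = line.split("\t")
            if len(fields) < 3:
                report.reject("too_few_fields")
                logger.warning("GMT line with <3 fields dropped: %.60r", line)
                continue
            name = fields[0]
            genes = list(dict.fromkeys(g.strip().upper() for g in fields[2:] if g.strip()))
            if not genes:
                report.reject("empty_set")
                continue
            if name in sets:
                report.reject("duplicate_set_name")
                logger.warning("duplicate GMT set name %r dropped", name)
                continue
            sets[name] = genes
    report.n_kept = len(sets)
    return GeneSetLibrary(sets=sets, source_label=source_label or str(path)), report


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in library.sets.items():
            fh.write("\t".join([name, library.source_label or "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# reference genotype panel
# ---------------------------------------------------------------------------


@dataclass
class ReferencePanel:
    """Dosage matrix (individuals x SNPs) used only for LD estimation.

    Dosages are in {0, 1, 2}; missing entries are NaN and are mean-imputed
    inside LD computation only, never persisted. Monomorphic SNPs are
    dropped at load time.
    """

    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    dosages: np.ndarray  # float, NaN = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.snp_ids):
            raise FormatError("panel dosage matrix shape inconsistent with SNP ids")
        self._index = {s: j for j, s in enumerate(self.snp_ids)}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def columns(self, snp_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in snp_ids if s not in self._index]
        if missing:
            raise KeyError(f"SNPs absent from reference panel: {missing[:5]}")
        idx = [self._index[s] for s in snp_ids]
        return self.dosages[:, idx]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index


def _drop_monomorphic(
    snp_ids: list[str], chrom: list[str], pos: list[int], dosages: np.ndarray,
    report: ReadReport,
) -> ReferencePanel:
    with np.errstate(invalid="ignore"):
        var = np.nanvar(dosages, axis=0)
    keep = np.isfinite(var) & (var > 0)
    n_mono = int((~keep).sum())
    if n_mono:
        report.reject("monomorphic", n_mono)
        logger.info("dropped %d monomorphic SNPs from reference panel", n_mono)
    return ReferencePanel(
        snp_ids=[s for s, k in zip(snp_ids, keep) if k],
        chrom=np.asarray([c for c, k in zip(chrom, keep) if k], dtype=object),
        pos=np.asarray([p for p, k in zip(pos, keep) if k], dtype=np.int64),
        dosages=dosages[:, keep],
    )


def _read_panel_vcf(path: str | Path, report: ReadReport) -> ReferencePanel:
    from cyvcf2 import VCF

    snp_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    cols: list[np.ndarray] = []
    vcf = VCF(str(path))
    for variant in vcf:
        report.n_input += 1
        if len(variant.ALT) != 1:
            report.reject("multiallelic")
            logger.warning("multi-allelic record at %s:%d skipped", variant.CHROM, variant.POS)
            continue
        col = np.empty(len(vcf.samples), dtype=float)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]  # last element is the phased flag
            if len(alleles) != 2:
                raise FormatError(
                    f"non-diploid genotype at {variant.CHROM}:{variant.POS} sample {i}"
                )
            if any(a < 0 for a in alleles):
                col[i] = np.nan
            else:
                col[i] = sum(1 for a in alleles if a >= 1)
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chrom.append(str(variant.CHROM))
        pos.append(int(variant.POS))
        cols.append(col)
    dosages = np.column_stack(cols) if cols else np.empty((0, 0))
    return _drop_monomorphic(snp_ids, chrom, pos, dosages, report)


def _read_panel_matrix(path: str | Path, report: ReadReport) -> ReferencePanel:
    # header cells are either "chrom:pos:id" or a bare SNP id (pos = ordinal)
    df = pd.read_csv(path, sep="\t")
    report.n_input = df.shape[1]
    snp_ids, chrom, pos = [], [], []
    for ordinal, cell in enumerate(df.columns, start=1):
        parts = str(cell).split(":")
        if len(parts) == 3:
            chrom.append(parts[0]); pos.append(int(parts[1])); snp_ids.append(parts[2])
        else:
            chrom.append("NA"); pos.append(ordinal); snp_ids.append(str(cell))
    dosages = df.to_numpy(float)
    bad = np.isfinite(dosages) & ~np.isin(dosages, (0.0, 1.0, 2.0))
    if bad.any():
        raise FormatError(f"{path!s}: dosage values outside {{0,1,2}}")
    return _drop_monomorphic(snp_ids, chrom, pos, dosages, report)


def read_reference_panel(
    path: str | Path, format: str = "auto"
) -> tuple[ReferencePanel, ReadReport]:
    """Load a reference genotype panel from a VCF or a plain dosage matrix.

    ``format`` is one of ``vcf``, ``dosage-matrix`` or ``auto`` (by file
    extension). Multi-allelic VCF records are skipped with a warning;
    non-diploid genotypes are an error; monomorphic SNPs are dropped and
    counted in the report.
    """
    report = ReadReport()
    if format == "auto":
        format = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "dosage-matrix"
    if format == "vcf":
        panel = _read_panel_vcf(path, report)
    elif format == "dosage-matrix":
        panel = _read_panel_matrix(path, report)
    else:
        raise ValueError(f"unknown panel format {format!r}")
    report.n_kept = panel.n_snps
    return panel, report


def write_panel_matrix(panel: ReferencePanel, path: str | Path) -> None:
    """Write a panel as a dosage-matrix TSV with chrom:pos:id headers."""
    header = [f"{c}:{p}:{s}" for c, p, s in zip(panel.chrom, panel.pos, panel.snp_ids)]
    df = pd.DataFrame(panel.dosages, columns=header)
    # integer-format dosages where defined so files round-trip bit-identically
    df.to_csv(path, sep="\t", index=False, float_format="%.0f")
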