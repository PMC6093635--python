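"""End-to-end orchestration: harmonize -> annotate/prune -> summary CCA ->
gene-based tests on the CCA-significant genes -> pleiotropy calls ->
enrichment, with a machine-readable manifest of every stage count."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotate, cca, enrichment, gene_tests
from .io_formats import (
    GeneRange,
    GeneSetLibrary,
    ReferencePanel,
    SummaryStatsTable,
    TraitCorrelationMatrix,
    read_gene_ranges,
    read_gmt,
    read_reference_panel,
    read_summary_stats,
    read_trait_correlations,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    ``summary_stats`` maps trait name -> file path in trait order (the
    first trait is the allele-alignment reference).
    """

    summary_stats: dict[str, str]
    trait_corr: str
    gene_ranges: str
    panel: str
    out_dir: str
    gene_sets: str | None = None
    panel_format: str = "auto"
    column_map: dict[str, str] = field(default_factory=dict)
    r2_max: float = 0.01
    alpha: float = 0.05
    flank: int = 0
    vegas_stages: tuple[int, ...] = gene_tests.DEFAULT_STAGES
    seed: int = 0
    universe: str = "tested"  # or "annotation"
    test_all_genes: bool = False
    prune_within_gene: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.r2_max < 1:
            raise ValueError("r2_max must lie in (0, 1)")
        if self.universe not in ("tested", "annotation"):
            raise ValueError("universe must be 'tested' or 'annotation'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "vegas_stages" in raw:
            raw["vegas_stages"] = tuple(int(s) for s in raw["vegas_stages"])
        return cls(**raw)

    def input_paths(self) -> dict[str, str]:
        paths = {f"sumstats:{t}": p for t, p in self.summary_stats.items()}
        paths["trait_corr"] = self.trait_corr
        paths["gene_ranges"] = self.gene_ranges
        paths["panel"] = self.panel
        if self.gene_sets:
            paths["gene_sets"] = self.gene_sets
        return paths


@dataclass
class RunResult:
    """In-memory products of every pipeline stage."""

    harmonized: annotate.HarmonizedStats
    gene_map: annotate.GeneSnpMap
    pruned_map: annotate.GeneSnpMap
    cca_results: list[cca.CCAResult]
    cca_significant: list[str]
    gene_trait: gene_tests.GeneTraitMatrix | None
    calls: list[gene_tests.PleiotropyCall]
    enrichment: list[enrichment.EnrichmentResult]
    counts: dict[str, object]


def run_stages(
    tables: Sequence[SummaryStatsTable],
    trait_corr: TraitCorrelationMatrix,
    ranges: Sequence[GeneRange],
    panel: ReferencePanel,
    library: GeneSetLibrary | None = None,
    *,
    r2_max: float = 0.01,
    alpha: float = 0.05,
    flank: int = 0,
    vegas_stages: Sequence[int] = gene_tests.DEFAULT_STAGES,
    seed: int = 0,
    universe: str = "tested",
    test_all_genes: bool = False,
) -> RunResult:
    """Run every analysis stage on in-memory inputs; see ``run_pipeline``
    for the file-based wrapper."""
    trait_names = [t.trait_name for t in tables]
    trait_corr = trait_corr.reordered(trait_names)

    harmonized = annotate.harmonize_traits(list(tables), panel)
    gene_map = annotate.assign_snps_to_genes(
        harmonized.snp_ids, harmonized.chrom, harmonized.pos, ranges, flank=flank
    )

    pruned: dict[str, list[str]] = {}
    for gene, snps in gene_map.genes.items():
        ld = annotate.compute_ld(panel, snps)
        pruned[gene] = annotate.prune_ld(ld, r2_max=r2_max)
    pruned_map = annotate.GeneSnpMap(genes=pruned, flank=flank)

    blocks = [
        cca.build_gene_block(gene, snps, harmonized, panel)
        for gene, snps in pruned.items()
    ]
    results = cca.run_metacca(blocks, trait_corr, alpha=alpha)
    significant = [r.gene for r in results if r.significant]

    selected = list(pruned) if test_all_genes else significant
    gene_trait = None
    calls: list[gene_tests.PleiotropyCall] = []
    if selected:
        gene_trait = gene_tests.run_gene_tests(
            harmonized, pruned_map, panel, selected, seed=seed,
            stages=vegas_stages, alpha=alpha,
        )
        calls = gene_tests.call_pleiotropy(gene_trait)

    enrich_results: list[enrichment.EnrichmentResult] = []
    if library is not None and calls:
        universe_genes = (
            [r.gene for r in results] if universe == "tested" else [g.name for g in ranges]
        )
        enrich_results = enrichment.enrich(
            [c.gene for c in calls], library, universe_genes
        )

    per_trait_sig: dict[str, int] = {t: 0 for t in trait_names}
    if gene_trait is not None:
        mask = gene_trait.significant_mask()
        for k, t in enumerate(gene_trait.traits):
            per_trait_sig[t] = int(mask[:, k].sum())

    counts: dict[str, object] = {
        "n_traits": len(tables),
        "n_snps_overlapped": harmonized.n_snps,
        "n_genes_annotated": len(gene_map),
        "n_genes_tested": len(blocks),
        "n_genes_cca_significant": len(significant),
        "genes_selected_for_gene_tests": len(selected),
        "per_trait_significant": per_trait_sig,
        "n_pleiotropy_calls": len(calls),
        "n_enrichment_sets_significant": sum(
            1 for r in enrich_results if r.p_bh < alpha
        ),
    }
    return RunResult(
        harmonized=harmonized,
        gene_map=gene_map,
        pruned_map=pruned_map,
        cca_results=results,
        cca_significant=significant,
        gene_trait=gene_trait,
        calls=calls,
        enrichment=enrich_results,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# file-based entry point
# ---------------------------------------------------------------------------


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_map(gene_map: annotate.GeneSnpMap, pos_of: dict[str, int], path: Path) -> None:
    rows = [
        {"gene": gene, "snp": snp, "pos": pos_of[snp]}
        for gene in sorted(gene_map.genes)
        for snp in gene_map.genes[gene]
    ]
    pd.DataFrame(rows, columns=["gene", "snp", "pos"]).to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow from files and write every stage's TSV.

    Returns the manifest (also written to ``out_dir/manifest.json``): input
    hashes, seed, per-stage status and the funnel counts. A stage failure
    is recorded in the manifest instead of propagating.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "r2_max": config.r2_max,
            "alpha": config.alpha,
            "flank": config.flank,
            "vegas_stages": list(config.vegas_stages),
            "universe": config.universe,
            "test_all_genes": config.test_all_genes,
        },
        "inputs": {},
        "stages": {},
        "counts": {},
        "outputs": {},
        "completed": False,
    }
    for name, path in config.input_paths().items():
        if not Path(path).exists():
            manifest["stages"]["load"] = f"failed: missing input {path}"
            _write_manifest(manifest, out)
            return manifest
        manifest["inputs"][name] = _sha256(path)

    t0 = time.monotonic()
    try:
        tables = []
        for trait, path in config.summary_stats.items():
            table, _ = read_summary_stats(path, trait, config.column_map or None)
            tables.append(table)
        trait_corr = read_trait_correlations(
            config.trait_corr, expected_traits=list(config.summary_stats)
        )
        ranges, _ = read_gene_ranges(config.gene_ranges)
        panel, _ = read_reference_panel(config.panel, format=config.panel_format)
        library = None
        if config.gene_sets:
            library, _ = read_gmt(config.gene_sets)
        manifest["stages"]["load"] = "ok"
    except Exception as exc:  # recorded, not propagated
        logger.exception("input loading failed")
        manifest["stages"]["load"] = f"failed: {exc}"
        _write_manifest(manifest, out)
        return manifest

    try:
        result = run_stages(
            tables, trait_corr, ranges, panel, library,
            r2_max=config.r2_max, alpha=config.alpha, flank=config.flank,
            vegas_stages=config.vegas_stages, seed=config.seed,
            universe=config.universe, test_all_genes=config.test_all_genes,
        )
        manifest["stages"]["analysis"] = "ok"
    except Exception as exc:
        logger.exception("analysis failed")
        manifest["stages"]["analysis"] = f"failed: {exc}"
        _write_manifest(manifest, out)
        return manifest

    manifest["counts"] = result.counts
    pos_of = dict(zip(result.harmonized.snp_ids, (int(p) for p in result.harmonized.pos)))

    rep = result.harmonized.report
    pd.DataFrame(
        {
            "metric": ["kept", "flipped", "dropped_ambiguous", "dropped_mismatch", "dropped_not_shared"],
            "value": [rep.kept, rep.flipped, rep.dropped_ambiguous, rep.dropped_mismatch, rep.dropped_not_shared],
        }
    ).to_csv(out / "harmonization_report.tsv", sep="\t", index=False)
    _write_map(result.gene_map, pos_of, out / "gene_snp_map.tsv")
    _write_map(result.pruned_map, pos_of, out / "pruned_map.tsv")

    n_tested = max(len(result.cca_results), 1)
    pd.DataFrame(
        [
            {
                "gene": r.gene,
                "m_snps": r.m,
                "r1": r.canonical_corrs[0],
                "statistic": r.statistic,
                "p": r.p_value,
                "p_bonferroni_threshold": config.alpha / n_tested,
                "significant": r.significant,
            }
            for r in result.cca_results
        ],
        columns=["gene", "m_snps", "r1", "statistic", "p", "p_bonferroni_threshold", "significant"],
    ).to_csv(out / "metacca_results.tsv", sep="\t", index=False)

    gt_rows = []
    if result.gene_trait is not None:
        gt = result.gene_trait
        for i, gene in enumerate(gt.genes):
            for k, trait in enumerate(gt.traits):
                gt_rows.append(
                    {
                        "gene": gene,
                        "trait": trait,
                        "p": gt.p[i, k],
                        "sims_used": int(gt.sims_used[i, k]),
                        "significant": bool(gt.p[i, k] < gt.threshold),
                    }
                )
    pd.DataFrame(gt_rows, columns=["gene", "trait", "p", "sims_used", "significant"]).to_csv(
        out / "gene_trait_pvalues.tsv", sep="\t", index=False
    )

    pd.DataFrame(
        [
            {
                "gene": c.gene,
                "n_significant_traits": len(c.significant_traits),
                "traits": ";".join(c.significant_traits),
                "p_values": ";".join(f"{t}={c.p_values[t]:.6g}" for t in c.p_values),
            }
            for c in result.calls
        ],
        columns=["gene", "n_significant_traits", "traits", "p_values"],
    ).to_csv(out / "pleiotropy_calls.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "set": r.set_name,
                "k": r.k,
                "set_size": r.set_size,
                "query_size": r.query_size,
                "universe_size": r.universe_size,
                "p": r.p,
                "p_bh": r.p_bh,
                "overlap_genes": ";".join(r.overlap_genes),
            }
            for r in result.enrichment
        ],
        columns=["set", "k", "set_size", "query_size", "universe_size", "p", "p_bh", "overlap_genes"],
    ).to_csv(out / "enrichment.tsv", sep="\t", index=False)

    manifest["outputs"] = {
        name: str(out / name)
        for name in (
            "harmonization_report.tsv", "gene_snp_map.tsv", "pruned_map.tsv",
            "metacca_results.tsv", "gene_trait_pvalues.tsv",
            "pleiotropy_calls.tsv", "enrichment.tsv",
        )
    }
    manifest["completed"] = True
    logger.info("pipeline finished in %.1fs", time.monotonic() - t0)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def stage_report(manifest: dict) -> str:
    """Human-readable funnel summary of a run manifest."""
    lines = ["pipeline funnel"]
    counts = manifest.get("counts", {})
    funnel = (
        ("SNPs overlapped across traits and panel", "n_snps_overlapped"),
        ("genes with >= 1 SNP", "n_genes_annotated"),
        ("genes tested (CCA)", "n_genes_tested"),
        ("genes CCA-significant", "n_genes_cca_significant"),
        ("genes entering gene-based tests", "genes_selected_for_gene_tests"),
        ("pleiotropy calls", "n_pleiotropy_calls"),
        ("enriched sets (BH < alpha)", "n_enrichment_sets_significant"),
    )
    for label, key in funnel:
        if key in counts:
            lines.append(f"  {label}: {counts[key]}")
    per_trait = counts.get("per_trait_significant")
    if per_trait:
        lines.append(
            "  per-trait significant genes: "
            + ", ".join(f"{t}={n}" for t, n in per_trait.items())
        )
    for stage, status in manifest.get("stages", {}).items():
        if status != "ok":
            lines.append(f"  WARNING stage {stage!r}: {status}")
    if not manifest.get("completed"):
        lines.append("  run INCOMPLETE")
    return "\n".join(lines)
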