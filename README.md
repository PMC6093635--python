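# pleioscan

Cross-trait pleiotropic gene scanning from GWAS summary statistics.

Given per-trait GWAS summary statistics (beta, SE, n), a phenotypic trait
correlation matrix, a gene-range annotation list, a reference genotype
panel for LD, and (optionally) GMT gene-set libraries, `pleioscan` runs a
four-stage workflow:

1. **Harmonize & annotate** — intersect SNPs across traits and the panel,
   align effect alleles (flipping betas at swapped allele pairs, dropping
   strand-ambiguous and mismatched SNPs), assign SNPs to genes (1-based
   inclusive intervals, configurable flank), and greedily LD-prune each
   gene's SNPs to near-independence (r² ≤ 0.01, keep-first in position
   order).
2. **Per-gene canonical correlation analysis** — build each gene's
   correlation blocks (SNP–SNP LD from the panel; SNP–trait block from
   normalized betas, `beta / (sqrt(n) * SE)`; the trait correlation matrix),
   shrink to positive definiteness, compute canonical correlations, and
   test their joint significance with Bartlett's chi-square approximation
   to Wilks' lambda, Bonferroni-corrected across genes.
3. **Gene-based tests & pleiotropy filter** — for each CCA-significant
   gene and each trait, a sum-of-squared-z statistic with an LD-aware
   Monte-Carlo null (adaptive simulation stages, p-value floor
   1/(max stage + 1)); genes significant for **more than one trait** at the
   Bonferroni threshold are called pleiotropic.
4. **Enrichment** — hypergeometric over-representation of the pleiotropy
   calls against GMT libraries with Benjamini–Hochberg correction.

A synthetic-data module generates complete, self-consistent input bundles
(LD-structured genotypes, six correlated traits with unequal sample sizes,
planted pleiotropic genes, a planted gene set) together with ground-truth
labels for recovery testing.

## Test

```
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests, and
`tests/test_acceptance.py` with one test per acceptance criterion
(summary-level vs individual-level CCA oracle, null calibration,
Monte-Carlo vs chi-square closed forms, hypergeometric/BH correctness,
end-to-end recovery of planted pleiotropic genes, structural invariants
and byte-identical reruns).

## CLI

Generate a synthetic bundle and run the full pipeline:

```
pleioscan simulate --seed 1 --out bundle/
pleioscan run --config run.yaml
pleioscan report out/manifest.json
```

`run.yaml` names the inputs and parameters:

```yaml
summary_stats:        # trait -> file, order matters (first = allele reference)
  FG: bundle/sumstats_FG.tsv
  FI: bundle/sumstats_FI.tsv
  # ...
trait_corr: bundle/trait_corr.tsv
gene_ranges: bundle/genes.glist
panel: bundle/panel.dosage.tsv     # or a VCF
gene_sets: bundle/library.gmt
out_dir: out
r2_max: 0.01
alpha: 0.05
flank: 0
vegas_stages: [1000, 10000, 1000000]
seed: 1
```

Stage-level subcommands (`harmonize`, `prune`, `metacca`, `genetest`,
`pleiotropy`, `enrich`) run prefixes of the same workflow; every flag
overrides its config key. All outputs are header TSVs plus a
`manifest.json` with input hashes, the seed, and the stage-count funnel.

### File formats

- summary statistics: header TSV with logical columns
  `SNP CHR POS EA OA BETA SE N` (names remappable via `column_map`)
- trait correlations: labeled square TSV
- gene ranges: 4-column `chrom start end name` text (1-based, inclusive)
- panel: VCF (GT fields, biallelic) or a dosage-matrix TSV whose header
  cells are `chrom:pos:id`
- gene sets: standard GMT

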