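import numpy as np
import pytest

from pleioscan.annotate import compute_ld
from pleioscan.io_formats import (
    read_gene_ranges,
    read_gmt,
    read_reference_panel,
    read_summary_stats,
    read_trait_correlations,
)
from pleioscan.simulate import (
    DEFAULT_TRAIT_CORR,
    SimulationConfig,
    make_layout,
    make_scenario,
    make_truth,
    simulate_genotypes,
    simulate_panel,
    simulate_phenotypes,
    write_scenario,
)
from pleioscan._rng import stable_rng


def tiny_config(**overrides):
    kwargs = dict(
        n_genes=10, snps_mean=5, snps_max=10, n_pleio=2, n_single=1,
        n_cohort=500, per_trait_n=(400, 300, 350, 300, 250, 200), n_panel=100,
        seed=3,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


# ---------------------------------------------------------------------------
# config validation
# ---------------------------------------------------------------------------


def test_config_defaults_valid():
    cfg = SimulationConfig()
    assert cfg.k == 6
    assert cfg.per_trait_n == (4669, 2424, 8704, 5457, 6216, 6216)


@pytest.mark.parametrize(
    "bad",
    [
        {"maf_range": (0.0, 0.5)},
        {"h2_per_gene": 0.0},
        {"n_pleio": 20, "n_single": 50, "n_genes": 60},
        {"per_trait_n": (99_999,) * 6},
        {"ld_rho": 1.0},
    ],
)
def test_config_invalid(bad):
    with pytest.raises(ValueError):
        SimulationConfig(**bad)


# ---------------------------------------------------------------------------
# panel generation
# ---------------------------------------------------------------------------


def test_panel_zero_rho_near_independence():
    cfg = tiny_config(ld_rho=0.0, n_genes=5, snps_mean=6, maf_range=(0.2, 0.5))
    layout = make_layout(cfg)
    panel = simulate_panel(cfg, layout, n_individuals=10_000)
    checked = 0
    for g in range(5):
        ids = [s for s in layout.snp_ids if s.startswith(f"rs{g + 1:04d}")]
        ids = [s for s in ids if s in panel.snp_ids]
        if len(ids) < 2:
            continue
        ld = compute_ld(panel, ids)
        off = ld.r[~np.eye(len(ids), dtype=bool)]
        checked += off.size
        assert np.max(off**2) < 0.01
    assert checked >= 10


def test_panel_maf_half_mean_dosage():
    cfg = tiny_config(maf_range=(0.5, 0.5), n_genes=2, snps_mean=4, n_pleio=0, n_single=0)
    panel = simulate_panel(cfg, n_individuals=5000)
    means = panel.dosages.mean(axis=0)
    se = 3 * np.sqrt(0.5 / 5000)  # binomial(2, .5) has variance .5
    assert np.all(np.abs(means - 1.0) < se)


def test_panel_deterministic():
    cfg = tiny_config()
    p1 = simulate_panel(cfg)
    p2 = simulate_panel(cfg)
    np.testing.assert_array_equal(p1.dosages, p2.dosages)
    assert p1.snp_ids == p2.snp_ids


def test_panel_independent_of_cohort_draw():
    cfg = tiny_config()
    layout = make_layout(cfg)
    panel = simulate_panel(cfg, layout)
    cohort = simulate_genotypes(cfg, layout, cfg.n_cohort, stream="cohort")
    assert panel.dosages.shape[0] == cfg.n_panel
    assert cohort.shape[0] == cfg.n_cohort


def test_ar_ld_decays():
    cfg = tiny_config(ld_rho=0.7, n_genes=1, snps_mean=8, snps_max=8, snps_min=8,
                      maf_range=(0.3, 0.5), n_pleio=0, n_single=0)
    layout = make_layout(cfg)
    panel = simulate_panel(cfg, layout, n_individuals=20_000)
    ld = compute_ld(panel, panel.snp_ids)
    m = len(panel.snp_ids)
    adjacent = np.array([ld.r[i, i + 1] for i in range(m - 1)])
    distant = np.array([ld.r[i, j] for i in range(m) for j in range(i + 4, m)])
    assert adjacent.mean() > 0.3
    assert adjacent.mean() > np.abs(distant).mean() + 0.1


# ---------------------------------------------------------------------------
# truth and phenotypes
# ---------------------------------------------------------------------------


def test_truth_pleiotropy_consistency():
    cfg = tiny_config()
    layout = make_layout(cfg)
    truth = make_truth(cfg, layout)
    rows_with_2 = {
        g for g, row in zip(truth.gene_names, truth.effect_matrix)
        if np.count_nonzero(row) >= 2
    }
    assert rows_with_2 == set(truth.pleiotropic_genes)
    assert len(truth.pleiotropic_genes) == cfg.n_pleio
    assert len(truth.single_trait_genes) == cfg.n_single


def test_truth_no_planted():
    cfg = tiny_config(n_pleio=0, n_single=0)
    truth = make_truth(cfg, make_layout(cfg))
    assert truth.pleiotropic_genes == []
    assert not truth.effect_matrix.any()


def test_phenotype_correlation_matches_target():
    # with zero effects, the empirical trait correlations track the target
    cfg = tiny_config(n_pleio=0, n_single=0, n_genes=3)
    layout = make_layout(cfg)
    truth = make_truth(cfg, layout)
    genotypes = simulate_genotypes(cfg, layout, 20_000, stream="x")
    pheno = simulate_phenotypes(
        genotypes, layout, truth, DEFAULT_TRAIT_CORR, stable_rng(0, "p")
    )
    emp = np.corrcoef(pheno, rowvar=False)
    assert np.max(np.abs(emp - DEFAULT_TRAIT_CORR)) < 0.05


def test_planted_h2_realized():
    cfg = tiny_config(n_pleio=1, n_single=0, h2_per_gene=0.01, n_genes=4)
    layout = make_layout(cfg)
    truth = make_truth(cfg, layout)
    genotypes = simulate_genotypes(cfg, layout, 20_000, stream="x")
    pheno = simulate_phenotypes(
        genotypes, layout, truth, DEFAULT_TRAIT_CORR, stable_rng(1, "p")
    )
    gene = truth.pleiotropic_genes[0]
    g = truth.gene_names.index(gene)
    k = int(np.flatnonzero(truth.effect_matrix[g])[0])
    snp_col = layout.snp_slices[g].start  # causal SNP is the gene's first
    r = np.corrcoef(genotypes[:, snp_col], pheno[:, k])[0, 1]
    se = 3 / np.sqrt(20_000)
    assert r**2 == pytest.approx(0.01, abs=2 * se + 0.003)


def test_phenotypes_deterministic():
    cfg = tiny_config()
    layout = make_layout(cfg)
    truth = make_truth(cfg, layout)
    genotypes = simulate_genotypes(cfg, layout, 200, stream="x")
    a = simulate_phenotypes(genotypes, layout, truth, cfg.trait_corr, stable_rng(2, "p"))
    b = simulate_phenotypes(genotypes, layout, truth, cfg.trait_corr, stable_rng(2, "p"))
    np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def test_sumstats_null_z_tail():
    cfg = tiny_config(n_pleio=0, n_single=0, n_genes=40, snps_mean=13,
                      n_cohort=5000, per_trait_n=(5000,) * 6)
    sc = make_scenario(cfg)
    z = np.concatenate([(t.df["BETA"] / t.df["SE"]).to_numpy() for t in sc.tables])
    frac_extreme = float((np.abs(z) > 3.29).mean())
    assert frac_extreme < 0.005  # ~0.1% expected under the null


def test_sumstats_n_echoes_config():
    cfg = tiny_config()
    sc = make_scenario(cfg)
    for table, n in zip(sc.tables, cfg.per_trait_n):
        assert (table.df["N"] == n).all()


def test_causal_beta_sign_agreement():
    # planted effect sign is recovered by the causal SNP's beta
    hits = 0
    total = 0
    for seed in range(30):
        cfg = tiny_config(seed=seed, n_pleio=1, n_single=0, h2_per_gene=0.01,
                          n_genes=4, n_cohort=5000, per_trait_n=(5000,) * 6)
        sc = make_scenario(cfg)
        truth = sc.truth
        gene = truth.pleiotropic_genes[0]
        g = truth.gene_names.index(gene)
        snp_id = sc.layout.snp_ids[sc.layout.snp_slices[g].start]
        for k in np.flatnonzero(truth.effect_matrix[g]):
            table = sc.tables[k]
            beta = table.df.set_index("SNP").loc[snp_id, "BETA"]
            total += 1
            if np.sign(beta) == np.sign(truth.effect_matrix[g, k]):
                hits += 1
    assert hits / total >= 0.95


# ---------------------------------------------------------------------------
# scenario bundle
# ---------------------------------------------------------------------------


def test_scenario_roundtrip_through_readers(tmp_path):
    cfg = tiny_config()
    sc = make_scenario(cfg)
    paths = write_scenario(sc, tmp_path)
    for trait in cfg.trait_names:
        table, report = read_summary_stats(paths[f"sumstats:{trait}"], trait)
        assert report.n_rejected == 0
        assert len(table) == len(sc.tables[0])
    corr = read_trait_correlations(paths["trait_corr"], expected_traits=cfg.trait_names)
    np.testing.assert_allclose(corr.values, cfg.trait_corr)
    ranges, rreport = read_gene_ranges(paths["gene_ranges"])
    assert len(ranges) == cfg.n_genes and rreport.n_rejected == 0
    panel, _ = read_reference_panel(paths["panel"], format="dosage-matrix")
    assert panel.snp_ids == sc.panel.snp_ids
    np.testing.assert_array_equal(panel.dosages, sc.panel.dosages)
    lib, lreport = read_gmt(paths["gene_sets"])
    assert lib.sets == sc.library.sets
    assert lreport.n_rejected == 0


def test_scenario_no_pleio_empty_truth():
    cfg = tiny_config(n_pleio=0, n_single=0)
    sc = make_scenario(cfg)
    assert sc.truth.pleiotropic_genes == []
    assert "PLANTED_SET" not in sc.library.sets


def test_scenario_deterministic():
    cfg = tiny_config()
    a = make_scenario(cfg)
    b = make_scenario(cfg)
    np.testing.assert_array_equal(a.panel.dosages, b.panel.dosages)
    for ta, tb in zip(a.tables, b.tables):
        np.testing.assert_array_equal(ta.df["BETA"].to_numpy(), tb.df["BETA"].to_numpy())
    np.testing.assert_array_equal(a.truth.effect_matrix, b.truth.effect_matrix)


def test_scenario_gene_ranges_tile_snps():
    cfg = tiny_config()
    sc = make_scenario(cfg)
    by_name = {g.name: g for g in sc.ranges}
    for g_idx, gene in enumerate(sc.layout.gene_names):
        s = sc.layout.snp_slices[g_idx]
        rng_ = by_name[gene]
        pos = sc.layout.pos[s]
        assert rng_.start == pos.min() and rng_.end == pos.max()
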