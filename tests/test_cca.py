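import numpy as np
import pytest
from scipy import stats

from pleioscan.annotate import harmonize_traits
from pleioscan.cca import (
    GeneBlock,
    build_gene_block,
    canonical_correlations,
    cca_pvalue,
    normalize_beta,
    run_metacca,
    shrink_to_pd,
)
from pleioscan.io_formats import ReferencePanel, TraitCorrelationMatrix
from pleioscan.simulate import SimulationConfig, make_scenario

from conftest import make_table


# ---------------------------------------------------------------------------
# normalize_beta
# ---------------------------------------------------------------------------


def test_normalize_beta_zero():
    assert normalize_beta(0.0, 0.3, 1000) == 0.0


def test_normalize_beta_arithmetic():
    assert normalize_beta(0.05, 0.01, 100) == pytest.approx(0.5)


def test_normalize_beta_clamped():
    assert normalize_beta(10.0, 1e-6, 100) == pytest.approx(0.999)
    assert normalize_beta(-10.0, 1e-6, 100) == pytest.approx(-0.999)


@pytest.mark.parametrize("se,n", [(0.0, 100), (-1.0, 100), (0.1, 2)])
def test_normalize_beta_domain_errors(se, n):
    with pytest.raises(ValueError):
        normalize_beta(0.1, se, n)


def test_normalize_beta_matches_sample_correlation():
    # oracle: the normalized beta approximates the genotype-phenotype
    # Pearson correlation from the same regression
    rng = np.random.default_rng(42)
    n = 5000
    x = rng.binomial(2, 0.3, size=n).astype(float)
    y = 0.1 * (x - x.mean()) / x.std() + rng.standard_normal(n)
    y = (y - y.mean()) / y.std()
    slope, _, rvalue, _, stderr = stats.linregress(x, y)
    assert normalize_beta(slope, stderr, n) == pytest.approx(rvalue, abs=0.02)


# ---------------------------------------------------------------------------
# shrink_to_pd
# ---------------------------------------------------------------------------


def test_shrink_identity_unchanged():
    out, iters = shrink_to_pd(np.eye(4))
    np.testing.assert_array_equal(out, np.eye(4))
    assert iters == 0


def test_shrink_singular_2x2_closed_form():
    # min eigenvalue of [[1, a], [a, 1]] is 1 - |a|; one factor application
    # already gives 1 - 0.999 = 1e-3 >= 1e-8
    s = np.array([[1.0, 1.0], [1.0, 1.0]])
    out, iters = shrink_to_pd(s, factor=0.999, min_eig=1e-8)
    assert iters == 1
    assert out[0, 1] == pytest.approx(0.999**iters)
    assert np.linalg.eigvalsh(out)[0] >= 1e-8


def test_shrink_pd_input_unchanged():
    s = np.array([[1.0, 0.2], [0.2, 1.0]])
    out, iters = shrink_to_pd(s)
    np.testing.assert_array_equal(out, s)
    assert iters == 0


def test_shrink_only_offdiagonal_changes():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((5, 4))
    s = np.corrcoef(np.column_stack([x, x[:, 0]]), rowvar=False)  # singular
    out, _ = shrink_to_pd(s)
    np.testing.assert_array_equal(np.diag(out), np.diag(s))
    assert np.linalg.eigvalsh(out)[0] >= 1e-8


def test_shrink_rejects_asymmetric():
    with pytest.raises(ValueError):
        shrink_to_pd(np.array([[1.0, 0.5], [0.2, 1.0]]))


# ---------------------------------------------------------------------------
# canonical correlations
# ---------------------------------------------------------------------------


def test_cca_1d_is_abs_correlation():
    cc = canonical_correlations(np.eye(1), np.array([[-0.4]]), np.eye(1))
    assert cc == pytest.approx([0.4])


def test_cca_zero_block():
    cc = canonical_correlations(np.eye(3), np.zeros((3, 2)), np.eye(2))
    np.testing.assert_array_equal(cc, np.zeros(2))


def test_cca_count_and_order():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((500, 4))
    y = rng.standard_normal((500, 2)) + 0.3 * x[:, :2]
    sxx = np.corrcoef(x, rowvar=False)
    syy = np.corrcoef(y, rowvar=False)
    sxy = np.corrcoef(np.hstack([x, y]), rowvar=False)[:4, 4:]
    cc = canonical_correlations(sxx, sxy, syy)
    assert cc.shape == (2,)
    assert np.all(np.diff(cc) <= 0)
    assert np.all((cc >= 0) & (cc <= 1))


def test_cca_snp_permutation_invariant():
    rng = np.random.default_rng(2)
    x = rng.standard_normal((300, 5))
    y = rng.standard_normal((300, 3)) + 0.2 * x[:, [0, 1, 2]]
    sxx = np.corrcoef(x, rowvar=False)
    syy = np.corrcoef(y, rowvar=False)
    sxy = np.corrcoef(np.hstack([x, y]), rowvar=False)[:5, 5:]
    cc = canonical_correlations(sxx, sxy, syy)
    perm = np.random.default_rng(3).permutation(5)
    cc_perm = canonical_correlations(sxx[np.ix_(perm, perm)], sxy[perm], syy)
    np.testing.assert_allclose(cc, cc_perm, atol=1e-10)


def test_cca_rejects_non_pd():
    sxx = np.array([[1.0, 1.0], [1.0, 1.0]])
    with pytest.raises(ValueError, match="positive definite"):
        canonical_correlations(sxx, np.zeros((2, 2)), np.eye(2))


def test_cca_oracle_individual_level():
    # one seeded replicate of the summary-vs-individual-level equivalence;
    # the 20-seed version lives in the acceptance suite
    from sklearn.cross_decomposition import CCA as SkCCA

    from test_acceptance import _cca_pair

    r_summary, r_individual = _cca_pair(seed=0)
    assert r_summary == pytest.approx(r_individual, abs=0.02)
    assert isinstance(SkCCA, type)  # oracle import really is sklearn


# ---------------------------------------------------------------------------
# p-values
# ---------------------------------------------------------------------------


def test_cca_pvalue_null_statistic():
    stat, p = cca_pvalue([0.0, 0.0], n=1000, m=2, k=2)
    assert stat == 0.0 and p == 1.0


def test_cca_pvalue_1d_specialization():
    r = 0.12
    n = 500
    stat, p = cca_pvalue([r], n=n, m=1, k=1)
    # m = k = 1 specializes the multiplier to n - 1 - 3/2 = n - 2.5,
    # i.e. the classical ~ -(n-2)*log(1-r^2) single-correlation statistic
    expected_stat = -(n - 2.5) * np.log(1 - r**2)
    approx_stat = -(n - 2) * np.log(1 - r**2)
    assert stat == pytest.approx(expected_stat)
    assert stat == pytest.approx(approx_stat, rel=2e-3)
    assert p == pytest.approx(stats.chi2.sf(expected_stat, 1))


def test_cca_pvalue_monotone_in_r():
    ps = [cca_pvalue([r, 0.05], n=2000, m=3, k=2)[1] for r in (0.05, 0.1, 0.2, 0.4)]
    assert all(a > b for a, b in zip(ps, ps[1:]))


def test_cca_pvalue_small_n_rejected():
    with pytest.raises(ValueError):
        cca_pvalue([0.1], n=5, m=3, k=2)


# ---------------------------------------------------------------------------
# gene blocks and the multi-gene runner
# ---------------------------------------------------------------------------


def _harmonized_pair(tiny_panel):
    rows = [
        ("rs1", "1", 100, "A", "G", 0.10, 0.05, 1000),
        ("rs2", "1", 200, "C", "T", -0.20, 0.05, 1000),
    ]
    rows2 = [(s, c, p, a, b, be * 0.5, se, 800) for s, c, p, a, b, be, se, n in rows]
    t1 = make_table("T1", rows)
    t2 = make_table("T2", rows2)
    return harmonize_traits([t1, t2], tiny_panel)


def test_build_gene_block_shapes(tiny_panel):
    h = _harmonized_pair(tiny_panel)
    block = build_gene_block("G", ["rs1"], h, tiny_panel)
    assert block.sigma_xx.shape == (1, 1) and block.sigma_xx[0, 0] == 1.0
    assert block.sigma_xy.shape == (1, 2)
    block2 = build_gene_block("G", ["rs1", "rs2"], h, tiny_panel)
    assert block2.sigma_xy.shape == (2, 2)


def test_build_gene_block_per_trait_n(tiny_panel):
    h = _harmonized_pair(tiny_panel)
    block = build_gene_block("G", ["rs1"], h, tiny_panel)
    # each trait column normalized with its own n: 0.1/(sqrt(1000)*0.05)
    assert block.sigma_xy[0, 0] == pytest.approx(0.1 / (np.sqrt(1000) * 0.05))
    assert block.sigma_xy[0, 1] == pytest.approx(0.05 / (np.sqrt(800) * 0.05))
    assert block.n_effective == 800  # conservative minimum across traits


def test_run_metacca_bonferroni_threshold(tiny_panel):
    h = _harmonized_pair(tiny_panel)
    blocks = [build_gene_block(f"G{i}", ["rs1"], h, tiny_panel) for i in range(10)]
    syy = TraitCorrelationMatrix(["T1", "T2"], np.array([[1.0, 0.3], [0.3, 1.0]]))
    results = run_metacca(blocks, syy, alpha=0.05)
    assert len(results) == 10
    for r in results:
        assert r.significant == (r.p_value < 0.05 / 10)


def test_run_metacca_planted_gene_smallest_p(small_scenario):
    # the planted genes must dominate the ranking
    from pleioscan import pipeline

    sc = small_scenario
    res = pipeline.run_stages(
        sc.tables, sc.trait_corr, sc.ranges, sc.panel, None,
        vegas_stages=(100,), seed=1,
    )
    top = res.cca_results[0].gene
    assert top in set(sc.truth.pleiotropic_genes)


def test_run_metacca_sorted(small_scenario):
    from pleioscan import pipeline

    sc = small_scenario
    res = pipeline.run_stages(
        sc.tables, sc.trait_corr, sc.ranges, sc.panel, None,
        vegas_stages=(100,), seed=1,
    )
    ps = [r.p_value for r in res.cca_results]
    assert ps == sorted(ps)


def test_run_metacca_empty_errors(corr6):
    with pytest.raises(ValueError):
        run_metacca([], corr6)


def test_run_metacca_failed_gene_skipped(tiny_panel, caplog):
    h = _harmonized_pair(tiny_panel)
    good = build_gene_block("GOOD", ["rs1"], h, tiny_panel)
    bad = GeneBlock(  # n_effective too small for the test statistic
        gene="BAD", snp_ids=["rs1"], sigma_xx=np.eye(1),
        sigma_xy=np.array([[0.1, 0.1]]), n_effective=3,
    )
    syy = TraitCorrelationMatrix(["T1", "T2"], np.eye(2))
    with caplog.at_level("WARNING"):
        results = run_metacca([good, bad], syy)
    assert [r.gene for r in results] == ["GOOD"]
    assert "BAD" in caplog.text
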