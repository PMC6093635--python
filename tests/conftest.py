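import numpy as np
import pandas as pd
import pytest

from pleioscan.io_formats import ReferencePanel, SummaryStatsTable, TraitCorrelationMatrix
from pleioscan.simulate import SimulationConfig, make_scenario


def make_table(trait, rows):
    """rows: list of (snp, chrom, pos, ea, oa, beta, se, n)."""
    df = pd.DataFrame(
        rows, columns=["SNP", "CHR", "POS", "EA", "OA", "BETA", "SE", "N"]
    )
    return SummaryStatsTable(trait, df)


@pytest.fixture
def three_snp_tables():
    rows1 = [
        ("rs1", "1", 100, "A", "G", 0.10, 0.05, 1000),
        ("rs2", "1", 200, "C", "T", -0.20, 0.05, 1000),
        ("rs3", "1", 300, "G", "C", 0.05, 0.05, 1000),  # strand-ambiguous
    ]
    rows2 = [
        ("rs1", "1", 100, "G", "A", 0.30, 0.05, 800),  # swapped alleles
        ("rs2", "1", 200, "C", "T", 0.15, 0.05, 800),
        ("rs3", "1", 300, "G", "C", 0.01, 0.05, 800),
    ]
    return [make_table("T1", rows1), make_table("T2", rows2)]


@pytest.fixture
def tiny_panel():
    rng = np.random.default_rng(7)
    dosages = rng.integers(0, 3, size=(50, 3)).astype(float)
    return ReferencePanel(
        snp_ids=["rs1", "rs2", "rs3"],
        chrom=np.array(["1", "1", "1"], dtype=object),
        pos=np.array([100, 200, 300]),
        dosages=dosages,
    )


@pytest.fixture
def corr6():
    from pleioscan.simulate import DEFAULT_TRAIT_CORR, DEFAULT_TRAIT_NAMES

    return TraitCorrelationMatrix(list(DEFAULT_TRAIT_NAMES), DEFAULT_TRAIT_CORR.copy())


def recovery_config(seed: int, **overrides) -> SimulationConfig:
    """Desk-scale scenario with 5 planted pleiotropic genes."""
    kwargs = dict(
        n_genes=40,
        snps_mean=8.0,
        snps_max=15,
        n_pleio=5,
        n_single=0,
        h2_per_gene=0.01,
        n_cohort=10_000,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_scenario():
    """Shared planted-truth scenario (seed 1) for cross-module tests."""
    return make_scenario(recovery_config(seed=1))
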