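"""Per-gene canonical correlation analysis from summary statistics.

Each gene is summarized by three correlation blocks: SNP-SNP correlations
from a reference panel (sigma_xx), normalized per-trait effect sizes
(sigma_xy, with entry [j, k] = beta_jk / (sqrt(n_k) * se_jk)), and the
phenotypic trait correlation matrix (sigma_yy). The canonical correlations
are the singular values of sigma_xx^{-1/2} sigma_xy sigma_yy^{-1/2}; their
joint significance is assessed with Bartlett's chi-square approximation to
Wilks' lambda and controlled by Bonferroni across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg, stats

from .annotate import HarmonizedStats, compute_ld
from .io_formats import ReferencePanel, TraitCorrelationMatrix

logger = logging.getLogger(__name__)

#: clamp for normalized betas so sigma_xy stays inside the correlation domain
BETA_CLAMP = 0.999


@dataclass
class GeneBlock:
    """A gene's covariance blocks ready for summary-level CCA."""

    gene: str
    snp_ids: list[str]
    sigma_xx: np.ndarray  # (m, m), symmetric, unit diagonal
    sigma_xy: np.ndarray  # (m, K)
    n_effective: int

    @property
    def m(self) -> int:
        return len(self.snp_ids)


@dataclass
class CCAResult:
    gene: str
    canonical_corrs: np.ndarray  # descending, in [0, 1], length min(m, K)
    statistic: float
    p_value: float
    m: int
    significant: bool = False


def normalize_beta(beta, se, n):
    """Normalize a regression coefficient to the correlation scale.

    Returns ``beta / (sqrt(n) * se)`` clamped to [-0.999, 0.999]; accepts
    scalars or arrays. ``se <= 0`` or ``n <= 2`` raise ``ValueError``.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(se <= 0):
        raise ValueError("normalize_beta requires se > 0")
    if np.any(n <= 2):
        raise ValueError("normalize_beta requires n > 2")
    out = np.clip(beta / (np.sqrt(n) * se), -BETA_CLAMP, BETA_CLAMP)
    return float(out) if out.ndim == 0 else out


def build_gene_block(
    gene: str,
    snp_ids: Sequence[str],
    harmonized: HarmonizedStats,
    panel: ReferencePanel,
) -> GeneBlock:
    """Assemble sigma_xx (panel LD) and sigma_xy (normalized betas) for a gene.

    sigma_xy is SNP-major (m x K); each trait column is normalized with its
    own per-record sample size. ``n_effective`` is the minimum n over the
    gene's records across traits (conservative given unequal trait sizes).
    """
    rows = harmonized.rows(snp_ids)
    sigma_xx = compute_ld(panel, snp_ids).r
    sigma_xy = normalize_beta(
        harmonized.beta[rows], harmonized.se[rows], harmonized.n[rows]
    )
    n_effective = int(harmonized.n[rows].min())
    return GeneBlock(
        gene=gene,
        snp_ids=list(snp_ids),
        sigma_xx=sigma_xx,
        sigma_xy=np.atleast_2d(sigma_xy),
        n_effective=n_effective,
    )


def shrink_to_pd(
    S: np.ndarray, factor: float = 0.999, min_eig: float = 1e-8
) -> tuple[np.ndarray, int]:
    """Shrink off-diagonals toward zero until the matrix is positive definite.

    Off-diagonal entries are repeatedly multiplied by ``factor`` until the
    smallest eigenvalue is >= ``min_eig``; the diagonal is untouched.
    Returns the shrunk matrix and the iteration count.
    """
    S = np.asarray(S, dtype=float)
    if not np.allclose(S, S.T, atol=1e-10, rtol=0.0):
        raise ValueError("shrink_to_pd requires a symmetric matrix")
    out = S.copy()
    off_mask = ~np.eye(S.shape[0], dtype=bool)
    iterations = 0
    while np.linalg.eigvalsh(out)[0] < min_eig:
        out[off_mask] *= factor
        iterations += 1
        if iterations > 100_000:  # unreachable for |off-diag| <= 1
            raise RuntimeError("shrink_to_pd failed to converge")
    return out, iterations


def _inv_sqrt(S: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(S)
    if w[0] <= 0:
        raise ValueError("matrix is not positive definite; shrink it first")
    return (v / np.sqrt(w)) @ v.T


def canonical_correlations(
    sigma_xx: np.ndarray, sigma_xy: np.ndarray, sigma_yy: np.ndarray
) -> np.ndarray:
    """Canonical correlations from the three correlation blocks.

    Singular values of ``sigma_xx^{-1/2} @ sigma_xy @ sigma_yy^{-1/2}``,
    clipped to [0, 1] and sorted descending; exactly min(m, K) values.
    Non-positive-definite sigma_xx/sigma_yy raise ``ValueError``.
    """
    sigma_xy = np.atleast_2d(np.asarray(sigma_xy, dtype=float))
    m, k = sigma_xy.shape
    middle = _inv_sqrt(sigma_xx) @ sigma_xy @ _inv_sqrt(sigma_yy)
    sv = linalg.svdvals(middle)
    cc = np.sort(np.clip(sv, 0.0, 1.0))[::-1]
    return cc[: min(m, k)]


def cca_pvalue(
    canonical_corrs: Sequence[float], n: int, m: int, k: int
) -> tuple[float, float]:
    """Joint significance of all canonical correlations (Bartlett / Wilks).

    statistic = -(n - 1 - (m + k + 1)/2) * sum(log(1 - r_i^2)), referred to
    a chi-square with m*k degrees of freedom. Requires ``n > m + k + 1``.
    Returns (statistic, p).
    """
    if n <= m + k + 1:
        raise ValueError(f"sample size n={n} too small for m={m}, k={k}")
    r2 = np.clip(np.square(np.asarray(canonical_corrs, dtype=float)), 0.0, 1.0 - 1e-12)
    statistic = -(n - 1 - (m + k + 1) / 2.0) * float(np.sum(np.log1p(-r2)))
    statistic = max(statistic, 0.0)
    p = float(stats.chi2.sf(statistic, df=m * k))
    return statistic, p


def run_metacca(
    blocks: Sequence[GeneBlock],
    sigma_yy: TraitCorrelationMatrix,
    alpha: float = 0.05,
    shrink_factor: float = 0.999,
    min_eig: float = 1e-8,
) -> list[CCAResult]:
    """Summary-level CCA over genes with Bonferroni control.

    Per gene: shrink sigma_xx (and the shared sigma_yy) to positive
    definiteness, compute canonical correlations and the Bartlett p-value
    with the gene's conservative effective n. The significance flag uses
    the threshold ``alpha / len(blocks)``. A gene that fails (e.g. n too
    small) is logged and skipped, not fatal. Results are sorted by p-value
    then by leading canonical correlation descending.
    """
    if not blocks:
        raise ValueError("run_metacca requires at least one gene block")
    k = sigma_yy.k
    syy, _ = shrink_to_pd(sigma_yy.values, shrink_factor, min_eig)
    threshold = alpha / len(blocks)
    results: list[CCAResult] = []
    for block in blocks:
        try:
            sxx, _ = shrink_to_pd(block.sigma_xx, shrink_factor, min_eig)
            cc = canonical_correlations(sxx, block.sigma_xy, syy)
            statistic, p = cca_pvalue(cc, block.n_effective, block.m, k)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("gene %s skipped in CCA stage: %s", block.gene, exc)
            continue
        results.append(
            CCAResult(
                gene=block.gene,
                canonical_corrs=cc,
                statistic=statistic,
                p_value=p,
                m=block.m,
                significant=p < threshold,
            )
        )
    results.sort(key=lambda r: (r.p_value, -r.canonical_corrs[0]))
    return results
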