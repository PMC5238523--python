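"""Single-SNP association scans and principal-component stratification control.

The scan regresses the pseudo-phenotype (DRP) on each SNP dosage in turn,
with an intercept and the leading principal components of the standardized
genotype matrix as fixed covariates; the two-sided t-test p-value of the
dosage coefficient supplies the -log10(P) weights for the weighted GRM.
The number of PCs is chosen in advance by the Tracy-Widom test on the
eigenvalues of the genotype covariance (Patterson-style normalization with a
moment estimator of the effective marker count); selection is a prefix of the
eigenvalue order, stopping at the first non-significant eigenvalue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grm import CenteredGenotypes
from .tracy_widom import tw1_logsf

__all__ = ["PCAResult", "genotype_pca", "tracy_widom_select", "single_snp_gwas"]


@dataclass
class PCAResult:
    """PC scores and eigenvalues of the standardized-genotype covariance."""

    scores: np.ndarray  # n x K
    eigenvalues: np.ndarray  # descending, length min(n, m') - 1 kept informative
    n_individuals: int
    n_markers: int


def genotype_pca(cg: CenteredGenotypes) -> PCAResult:
    """PCA of column-standardized genotypes.

    Columns are the frequency-centered codes of ``cg`` scaled by
    sqrt(2 p (1 - p)); zero-variance columns (fixed alleles) are dropped.
    Eigenvalues are those of the sample covariance across individuals,
    X X' / m.
    """
    n, m = cg.M.shape
    if n < 3 or m < 2:
        raise ValueError("PCA needs at least 3 individuals and 2 SNPs")
    sd = np.sqrt(2.0 * cg.p * (1.0 - cg.p))
    keep = sd > 0
    X = cg.M[:, keep] / sd[keep]
    # remove the individual-mean so eigenvalues reflect between-individual
    # structure only (the top trivial direction is not informative)
    X = X - X.mean(axis=0)
    # eigendecompose the n x n Gram matrix rather than SVD-ing the n x m
    # data: identical scores/eigenvalues, far cheaper when m >> n
    gram = X @ X.T
    evals, evecs = np.linalg.eigh((gram + gram.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    lam = evals / X.shape[1]
    scores = evecs[:, order] * np.sqrt(evals)
    # the final eigenvalue is numerically zero after centering; drop it
    k = min(n - 1, len(lam))
    return PCAResult(
        scores=scores[:, :k],
        eigenvalues=lam[:k],
        n_individuals=n,
        n_markers=int(keep.sum()),
    )


def _tw_stat(eigs: np.ndarray):
    """Tracy-Widom statistic for the leading eigenvalue of ``eigs``.

    Uses the moment estimator of the effective marker count,
    n_eff = (m + 1) S1^2 / ((m - 1) S2 - S1^2), and the Patterson
    centering/scaling constants.
    """
    m = len(eigs)
    if m < 2:
        return None
    # the sample count behind these eigenvalues (one is lost to centering)
    ms = m + 1
    s1, s2 = eigs.sum(), np.sum(eigs**2)
    denom = (ms - 1) * s2 - s1**2
    if denom <= 0:
        return None
    n_eff = (ms + 1) * s1**2 / denom
    if n_eff <= 1:
        return None
    l1 = m * eigs[0] / s1
    a = np.sqrt(n_eff - 1) + np.sqrt(m)
    mu = a**2 / n_eff
    sigma = (a / n_eff) * (1.0 / np.sqrt(n_eff - 1) + 1.0 / np.sqrt(m)) ** (1.0 / 3.0)
    return (l1 - mu) / sigma


def tracy_widom_select(pca: PCAResult, alpha: float) -> list[int]:
    """Indices of significant leading PCs at level ``alpha``.

    Eigenvalues are tested in descending order against the Tracy-Widom
    (beta=1) distribution, each test conditioning on the removal of the
    previous ones; the selection stops at the first p-value above ``alpha``,
    so it is always a prefix of the eigenvalue order.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    eigs = np.asarray(pca.eigenvalues, dtype=float)
    eigs = eigs[eigs > 1e-12 * max(1.0, eigs.max(initial=0.0))]
    selected: list[int] = []
    log_alpha = np.log(alpha)
    for i in range(len(eigs) - 1):
        stat = _tw_stat(eigs[i:])
        if stat is None:
            break
        if tw1_logsf(stat) <= log_alpha:
            selected.append(i)
        else:
            break
    return selected


def single_snp_gwas(y, dosages, covariate_scores=None) -> pd.DataFrame:
    """Per-SNP least-squares scan of ``y`` on [1, PCs, dosage].

    Returns a DataFrame with columns effect, se, t, p, neglog10p, flagged.
    SNPs whose dosage is collinear with the covariates (including monomorphic
    SNPs) get effect 0, p 1 and ``flagged`` True.  Residual degrees of
    freedom are n - K - 2 (intercept + K PCs + the dosage term).
    """
    y = np.asarray(y, dtype=float)
    Gmat = np.asarray(dosages, dtype=float)
    n, m = Gmat.shape
    if len(y) != n:
        raise ValueError("y and dosage rows are not aligned")
    K = 0 if covariate_scores is None else np.atleast_2d(covariate_scores).shape[1]
    C = np.ones((n, 1))
    if K:
        C = np.hstack([C, np.asarray(covariate_scores, float).reshape(n, K)])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariates (with intercept) are rank deficient")
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    G_r = Gmat - Q @ (Q.T @ Gmat)
    gg = np.einsum("ij,ij->j", G_r, G_r)
    gy = G_r.T @ y_r
    df = n - K - 2
    if df <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    scale = np.median(gg[gg > 0]) if (gg > 0).any() else 1.0
    ok = gg > 1e-12 * scale
    effect = np.zeros(m)
    effect[ok] = gy[ok] / gg[ok]
    rss = np.maximum(y_r @ y_r - effect * gy, 0.0)
    sigma2 = rss / df
    se = np.zeros(m)
    se[ok] = np.sqrt(sigma2[ok] / gg[ok])
    t = np.zeros(m)
    nz = ok & (se > 0)
    t[nz] = effect[nz] / se[nz]
    p = np.ones(m)
    p[nz] = 2.0 * stats.t.sf(np.abs(t[nz]), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "effect": effect,
            "se": se,
            "t": t,
            "p": p,
            "neglog10p": -np.log10(p),
            "flagged": ~ok,
        }
    )
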