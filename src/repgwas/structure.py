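"""Population-structure adjustment: IBS-matrix PCA and genomic control.

Stratification is handled the way large cohort GWAS handle it: principal
components of an identity-by-state (allele-sharing) similarity matrix
enter the association model as covariates, and any residual inflation of
the test statistics is measured — and optionally corrected — with the
genomic-control inflation factor lambda, the median association
chi-square divided by the chi-square(1 df) median 0.45494.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

__all__ = [
    "PcaResult",
    "GcReport",
    "ibs_matrix",
    "pca_scores",
    "genomic_control",
    "CHI2_1DF_MEDIAN",
]

CHI2_1DF_MEDIAN = 0.45494  # median of the 1-df chi-square distribution


@dataclass
class PcaResult:
    """Top-k principal components of a similarity matrix.

    ``scores`` are eigenvectors scaled by the square root of their
    eigenvalues; ``variance_fraction`` is the share of the total positive
    eigenvalue mass captured by the k retained components.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    variance_fraction: float


@dataclass
class GcReport:
    """Genomic-control inflation factor and optionally adjusted p-values."""

    lambda_gc: float
    n_tests: int
    adjusted_p: np.ndarray | None = None


def ibs_matrix(genotypes: np.ndarray) -> np.ndarray:
    """Pairwise identity-by-state similarity from a dosage matrix.

    IBS(i, j) averages the allele-sharing fraction (2 - |x_ik - x_jk|)/2
    over the loci observed in both subjects.  The diagonal is 1; a pair
    with no shared observed locus gets NaN.  Dosage matrices restricted
    to {0, 1, 2} use an indicator-product fast path; arbitrary dosages
    fall back to a per-subject loop.
    """
    X = np.asarray(genotypes, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("genotypes must be an n x m matrix with m >= 1")
    n, m = X.shape
    observed = ~np.isnan(X)
    shared = observed.astype(float) @ observed.T.astype(float)

    vals = X[observed]
    if np.isin(vals, (0.0, 1.0, 2.0)).all():
        ind = [((X == g) & observed).astype(float) for g in (0.0, 1.0, 2.0)]
        absdiff = np.zeros((n, n))
        for g in range(3):
            for h in range(3):
                if g != h:
                    absdiff += abs(g - h) * (ind[g] @ ind[h].T)
    else:
        Z = np.where(observed, X, 0.0)
        absdiff = np.empty((n, n))
        for i in range(n):
            d = np.abs(Z[i] - Z) * (observed[i] & observed)
            absdiff[i] = d.sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (2.0 * shared - absdiff) / (2.0 * shared)
    sim[shared == 0] = np.nan
    np.fill_diagonal(sim, 1.0)
    return sim


def pca_scores(similarity: np.ndarray, k: int = 5) -> PcaResult:
    """Principal components of a similarity matrix.

    The matrix is double-centered (the multidimensional-scaling
    convention, which makes variance fractions well defined) and
    eigendecomposed; scores are the top-k eigenvectors scaled by the
    square root of their (non-negative-clipped) eigenvalues.
    """
    S = np.asarray(similarity, dtype=float)
    n = S.shape[0]
    if S.shape != (n, n):
        raise ValueError("similarity must be square")
    if not np.allclose(S, S.T, equal_nan=True):
        raise ValueError("similarity must be symmetric")
    if k < 1 or k > n:
        raise ValueError(f"k={k} outside [1, {n}]")
    if np.isnan(S).any():
        raise ValueError("similarity contains NaN entries (disjoint pairs)")
    H = np.eye(n) - np.ones((n, n)) / n
    B = H @ S @ H
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    positive = evals[evals > 0]
    top = evals[:k]
    scores = evecs[:, :k] * np.sqrt(np.clip(top, 0.0, None))
    frac = float(np.clip(top, 0.0, None).sum() / positive.sum()) if positive.size else 1.0
    return PcaResult(scores=scores, eigenvalues=evals, variance_fraction=frac)


def genomic_control(
    pvalues: np.ndarray | None = None,
    chisq: np.ndarray | None = None,
    adjust: bool = False,
) -> GcReport:
    """Genomic-control inflation factor from 1-df association statistics.

    lambda = median(chi-square) / 0.45494, reported raw (not clipped at 1).
    With ``adjust=True`` the statistics are divided by lambda and mapped
    back to 1-df p-values.
    """
    if (pvalues is None) == (chisq is None):
        raise ValueError("supply exactly one of pvalues or chisq")
    if chisq is None:
        p = np.asarray(pvalues, dtype=float)
        stats = chi2.isf(p, df=1)
    else:
        stats = np.asarray(chisq, dtype=float)
    stats = stats[np.isfinite(stats)]
    if stats.size == 0:
        raise ValueError("no finite statistics to estimate lambda from")
    lam = float(np.median(stats) / CHI2_1DF_MEDIAN)
    adjusted = None
    if adjust:
        all_stats = chi2.isf(np.asarray(pvalues, float), 1) if chisq is None \
            else np.asarray(chisq, float)
        adjusted = chi2.sf(all_stats / lam, df=1)
    return GcReport(lambda_gc=lam, n_tests=int(stats.size), adjusted_p=adjusted)
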