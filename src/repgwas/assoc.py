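"""Association engines: longitudinal GLS, cross-sectional OLS, interactions.

The longitudinal model regresses the visit-stacked phenotype on baseline
covariates, the SNP dosage, principal-component scores and the visit time
offset, with the within-subject residual vector distributed as
MVN(0, Sigma) for an unstructured t x t covariance Sigma.  Estimation is
iterated feasible GLS: an OLS pass, a method-of-moments update of Sigma
from residual cross-products over pairwise-complete visits, then GLS with
each subject whitened by the submatrix of Sigma for their observed
visits, repeated to convergence.  Missing visits are handled by row
subsetting (valid under MCAR/MAR); subjects missing the baseline visit
are rejected by the dataset container.

Wald z statistics are referred to the standard normal (cohort-scale n),
and the residual variance uses the method-of-moments denominator n, so
the t = 1 longitudinal fit coincides exactly with the cross-sectional
OLS fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.stats import norm

from .dataset import LongitudinalDataset

__all__ = [
    "GlsFit",
    "AssocRecord",
    "fit_gls_longitudinal",
    "fit_ols_cross_sectional",
    "fit_interaction",
    "build_covariates",
    "gwas_scan",
    "records_to_frame",
]

SUGGESTIVE_P = 1e-6  # follow-up / replication threshold


@dataclass
class GlsFit:
    """Result of a (feasible) GLS or OLS fit.

    params/se/z/p are pandas Series indexed by term name; ``sigma`` is
    the estimated (or supplied) within-subject covariance for the
    longitudinal model, a 1 x 1 matrix for cross-sectional fits.
    """

    params: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    sigma: np.ndarray
    n_subjects: int
    n_observations: int
    n_iterations: int
    converged: bool
    ridge: float = 0.0
    model: str = "longitudinal"

    def __post_init__(self) -> None:
        if (self.se <= 0).any():
            raise ValueError("standard errors must be positive")


def _check_rank(D: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # small R diagonal in the QR factorization localizes dependence
        _, rmat = np.linalg.qr(D)
        diag = np.abs(np.diag(rmat))
        tol = diag.max() * max(D.shape) * np.finfo(float).eps
        bad = [names[i] for i in range(len(names)) if i < len(diag) and diag[i] < tol]
        if not bad:
            bad = names
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {D.shape[1]}); "
            f"collinear columns: {bad}"
        )


def _moment_sigma(
    resid: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Sigma_jk = mean of r_ij r_ik over subjects observing visits j and k."""
    r = np.where(mask, resid, 0.0)
    m = mask.astype(float)
    counts = m.T @ m
    if (counts == 0).any():
        j, k = np.argwhere(counts == 0)[0]
        raise ValueError(
            f"no subject observes both visits {j + 1} and {k + 1}; "
            "within-subject covariance is inestimable"
        )
    return (r.T @ r) / counts


def _repair_pd(sigma: np.ndarray) -> tuple[np.ndarray, float]:
    """Ridge a non-positive-definite covariance back to PD."""
    w = np.linalg.eigvalsh(sigma)
    floor = 1e-8 * max(sigma.diagonal().max(), 1.0)
    if w[0] >= floor:
        return sigma, 0.0
    delta = floor - w[0]
    warnings.warn(
        f"within-subject covariance not positive definite "
        f"(min eigenvalue {w[0]:.3g}); adding ridge {delta:.3g}",
        RuntimeWarning,
        stacklevel=3,
    )
    return sigma + delta * np.eye(sigma.shape[0]), delta


def _design_matrix(
    data: LongitudinalDataset,
    snp: np.ndarray | None,
    covariates: pd.DataFrame | np.ndarray | None,
    pcs: np.ndarray | None,
    include_time: bool,
    interaction: tuple[str, np.ndarray] | None,
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Stack observed rows into (D, y, names, subject_idx, visit_idx).

    Subject-level columns (covariates, SNP, PCs) are broadcast across the
    subject's observed visits; the time column varies within subject.
    An interaction is a (name, row-level column) pair already expanded to
    per-(subject, visit) rows.
    """
    n, t = data.Y.shape
    obs = data.mask
    subject_idx, visit_idx = np.nonzero(obs)
    y = data.Y[subject_idx, visit_idx]

    cols: list[np.ndarray] = [np.ones(len(y))]
    names: list[str] = ["intercept"]
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            cnames = list(covariates.columns)
            cvals = covariates.to_numpy(dtype=float)
        else:
            cvals = np.asarray(covariates, dtype=float)
            if cvals.ndim == 1:
                cvals = cvals[:, None]
            cnames = [f"cov{i + 1}" for i in range(cvals.shape[1])]
        # a caller-supplied intercept column replaces the implicit one
        for name, col in zip(cnames, cvals.T):
            if name == "intercept":
                continue
            cols.append(col[subject_idx])
            names.append(name)
    if snp is not None:
        snp = np.asarray(snp, dtype=float)
        if snp.shape != (n,):
            raise ValueError("snp dosage must have one value per subject")
        cols.append(snp[subject_idx])
        names.append("snp")
    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        if pcs.ndim == 1:
            pcs = pcs[:, None]
        for k in range(pcs.shape[1]):
            cols.append(pcs[subject_idx, k])
            names.append(f"PC{k + 1}")
    if include_time:
        cols.append(data.time_offsets[visit_idx])
        names.append("time")
    if interaction is not None:
        iname, icol = interaction
        cols.append(icol)
        names.append(iname)
    D = np.column_stack(cols)
    if np.isnan(D).any():
        bad = [names[j] for j in np.unique(np.nonzero(np.isnan(D))[1])]
        raise ValueError(f"missing values in design columns: {bad}")
    return D, y, names, subject_idx, visit_idx


def _gls_solve(
    D: np.ndarray,
    y: np.ndarray,
    sigma: np.ndarray,
    mask: np.ndarray,
    subject_idx: np.ndarray,
    visit_idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One GLS pass: whiten per missingness pattern, solve, return (coef, cov).

    Subjects sharing an observed-visit pattern are whitened together with
    the Cholesky inverse of the corresponding submatrix of sigma.
    """
    n, t = mask.shape
    k = D.shape[1]
    pattern_code = mask @ (1 << np.arange(t))
    Dw = np.empty_like(D)
    yw = np.empty_like(y)
    # row offsets of each subject's block in the stacked arrays
    row_of = np.zeros(n + 1, dtype=int)
    np.cumsum(mask.sum(axis=1), out=row_of[1:])
    for code in np.unique(pattern_code):
        subjects = np.nonzero(pattern_code == code)[0]
        vis = np.nonzero(mask[subjects[0]])[0]
        m = len(vis)
        sub = sigma[np.ix_(vis, vis)]
        L = np.linalg.cholesky(sub)
        Linv = solve_triangular(L, np.eye(m), lower=True)
        # gather the g blocks of m rows each
        block_rows = (row_of[subjects][:, None] + np.arange(m)).ravel()
        Yb = y[block_rows].reshape(len(subjects), m)
        Db = D[block_rows].reshape(len(subjects), m, k)
        yw[block_rows] = (Yb @ Linv.T).ravel()
        Dw[block_rows] = np.einsum("ij,gjk->gik", Linv, Db).reshape(-1, k)
    xtx = Dw.T @ Dw
    coef = np.linalg.solve(xtx, Dw.T @ yw)
    cov = np.linalg.inv(xtx)
    return coef, cov


def _iterated_fgls(
    D: np.ndarray,
    y: np.ndarray,
    names: list[str],
    mask: np.ndarray,
    subject_idx: np.ndarray,
    visit_idx: np.ndarray,
    sigma: np.ndarray | None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> GlsFit:
    _check_rank(D, names)
    n, t = mask.shape
    ridge_used = 0.0
    if sigma is not None:
        sigma = np.asarray(sigma, dtype=float)
        coef, cov = _gls_solve(D, y, sigma, mask, subject_idx, visit_idx)
        iterations, converged = 0, True
    else:
        coef, *_ = np.linalg.lstsq(D, y, rcond=None)
        sigma = np.eye(t)
        converged = False
        iterations = 0
        resid_mat = np.full((n, t), np.nan)
        for iterations in range(1, max_iter + 1):
            resid = y - D @ coef
            resid_mat[subject_idx, visit_idx] = resid
            new_sigma = _moment_sigma(resid_mat, mask)
            new_sigma, ridge = _repair_pd(new_sigma)
            ridge_used = max(ridge_used, ridge)
            delta = np.abs(new_sigma - sigma).max()
            sigma = new_sigma
            coef, cov = _gls_solve(D, y, sigma, mask, subject_idx, visit_idx)
            if delta < tol:
                converged = True
                break

    se = np.sqrt(np.diag(cov))
    z = coef / se
    p = 2.0 * norm.sf(np.abs(z))
    idx = pd.Index(names)
    return GlsFit(
        params=pd.Series(coef, index=idx),
        se=pd.Series(se, index=idx),
        z=pd.Series(z, index=idx),
        p=pd.Series(np.clip(p, np.nextafter(0, 1), 1.0), index=idx),
        sigma=sigma,
        n_subjects=n,
        n_observations=len(y),
        n_iterations=iterations,
        converged=converged,
        ridge=ridge_used,
    )


def fit_gls_longitudinal(
    data: LongitudinalDataset,
    snp: np.ndarray | None = None,
    covariates: pd.DataFrame | np.ndarray | None = None,
    pcs: np.ndarray | None = None,
    include_time: bool = True,
    sigma: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> GlsFit:
    """Longitudinal GLS with unstructured within-subject covariance.

    Parameters
    ----------
    data : LongitudinalDataset
        Phenotypes, availability mask and visit times.
    snp : array (n,), optional
        Additive dosage; term name "snp".  Defaults to ``data.genotype``.
    covariates : DataFrame or array (n, p), optional
        Baseline covariates broadcast across visits (an "intercept"
        column is always present and deduplicated).
    pcs : array (n, k), optional
        Principal-component scores; terms "PC1"..
    include_time : bool
        Add the visit time offset as a covariate (dropped automatically
        for single-visit data, where it is constant).
    sigma : array (t, t), optional
        Known within-subject covariance: skips estimation and performs a
        single GLS pass.
    """
    if snp is None:
        snp = data.genotype
    if data.n_visits == 1:
        include_time = False
    D, y, names, sidx, vidx = _design_matrix(
        data, snp, covariates, pcs, include_time, None
    )
    fit = _iterated_fgls(
        D, y, names, data.mask, sidx, vidx, sigma, tol=tol, max_iter=max_iter
    )
    fit.model = "longitudinal" if data.n_visits > 1 else "cross-sectional"
    return fit


def fit_ols_cross_sectional(
    data: LongitudinalDataset,
    snp: np.ndarray | None = None,
    covariates: pd.DataFrame | np.ndarray | None = None,
    pcs: np.ndarray | None = None,
) -> GlsFit:
    """OLS on the baseline visit with covariates and PC scores."""
    baseline = LongitudinalDataset(
        ids=data.ids,
        Y=data.Y[:, :1],
        mask=data.mask[:, :1],
        time_offsets=data.time_offsets[:1],
        genotype=data.genotype,
        covariates=data.covariates,
    )
    fit = fit_gls_longitudinal(
        baseline, snp=snp, covariates=covariates, pcs=pcs, include_time=False
    )
    fit.model = "cross-sectional"
    return fit


def fit_interaction(
    data: LongitudinalDataset,
    snp: np.ndarray | None = None,
    environment: str = "sex",
    model: str = "longitudinal",
    covariates: pd.DataFrame | np.ndarray | None = None,
    pcs: np.ndarray | None = None,
) -> GlsFit:
    """Gene-by-environment interaction test.

    Augments the base model with the product of the SNP dosage and the
    environment variable (``sex``/``age`` from the covariates, or the
    visit ``time`` offset) and Wald-tests the product term; the main SNP
    and environment effects stay in the model.
    """
    if snp is None:
        snp = data.genotype
    if snp is None:
        raise ValueError("an SNP dosage vector is required")
    snp = np.asarray(snp, dtype=float)

    if environment == "time":
        if model != "longitudinal" or data.n_visits < 2:
            raise ValueError("time interaction requires the longitudinal model")
        sidx, vidx = np.nonzero(data.mask)
        icol = snp[sidx] * data.time_offsets[vidx]
        D, y, names, sidx, vidx = _design_matrix(
            data, snp, covariates, pcs, True, ("time:snp", icol)
        )
        fit = _iterated_fgls(D, y, names, data.mask, sidx, vidx, None)
        fit.model = "interaction:time"
        return fit

    if covariates is None or environment not in getattr(covariates, "columns", []):
        raise ValueError(
            f"environment variable {environment!r} not found in covariates"
        )
    env = covariates[environment].to_numpy(dtype=float)
    if np.nanstd(env) == 0:
        raise ValueError(
            f"environment {environment!r} is constant; interaction inestimable"
        )
    if model == "longitudinal":
        base_data, include_time = data, data.n_visits > 1
    elif model == "cross-sectional":
        base_data = LongitudinalDataset(
            ids=data.ids, Y=data.Y[:, :1], mask=data.mask[:, :1],
            time_offsets=data.time_offsets[:1], genotype=data.genotype,
        )
        include_time = False
    else:
        raise ValueError(f"unknown model {model!r}")
    sidx, _ = np.nonzero(base_data.mask)
    icol = (snp * env)[sidx]
    D, y, names, sidx, vidx = _design_matrix(
        base_data, snp, covariates, pcs, include_time,
        (f"{environment}:snp", icol),
    )
    fit = _iterated_fgls(D, y, names, base_data.mask, sidx, vidx, None)
    fit.model = f"interaction:{environment}"
    return fit


#: phenotypes whose glucose physiology makes baseline weight a confounder
_WEIGHT_PHENOTYPES = frozenset({"GLU0", "GLU120"})


def build_covariates(raw: pd.DataFrame, phenotype: str) -> pd.DataFrame:
    """Standard covariate matrix for a phenotype.

    Always: intercept, sex, baseline age and age squared; fasting and
    post-load glucose additionally adjust for baseline weight.  ``raw``
    has one row per subject.
    """
    required = ["sex", "age"]
    if phenotype in _WEIGHT_PHENOTYPES:
        required.append("weight")
    missing_cols = [c for c in required if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"missing covariate column(s): {missing_cols}")
    for col in required:
        nulls = raw[col].isna()
        if nulls.any():
            ids = raw.index[nulls].tolist()[:5]
            raise ValueError(
                f"covariate {col!r} missing for {int(nulls.sum())} "
                f"subject(s), e.g. {ids}"
            )
    age = raw["age"].to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise ValueError("age is constant: age^2 would be collinear")
    out = pd.DataFrame(
        {
            "intercept": 1.0,
            "sex": raw["sex"].to_numpy(dtype=float),
            "age": age,
            "age2": age ** 2,
        },
        index=raw.index,
    )
    if phenotype in _WEIGHT_PHENOTYPES:
        out["weight"] = raw["weight"].to_numpy(dtype=float)
    return out


@dataclass
class AssocRecord:
    """One SNP x model association result (GWAS summary row)."""

    snp: str
    chrom: str
    pos: int
    minor_allele: str
    maf: float
    model: str
    beta: float
    se: float
    p: float
    n_subjects: int
    n_observations: int
    note: str = ""


def records_to_frame(records: Iterable[AssocRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def gwas_scan(
    data: LongitudinalDataset,
    genotypes: np.ndarray,
    snp_info: pd.DataFrame,
    model: str = "longitudinal",
    covariates: pd.DataFrame | np.ndarray | None = None,
    pcs: np.ndarray | None = None,
    interaction: str | None = None,
) -> Iterator[AssocRecord]:
    """Per-SNP association scan.

    Parameters
    ----------
    genotypes : array (n_subjects, n_snps)
        Minor-allele dosages, NaN for missing (missing dosages are mean-
        imputed per SNP for the regression, the field's usual convention
        for hard-called data at high call rates).
    snp_info : DataFrame
        Columns snp, chrom, pos, minor_allele (extra columns ignored);
        scan order is (chrom, pos).
    model : "longitudinal" | "cross-sectional"
    interaction : optional environment name; tests the product term.

    Per-SNP failures (monomorphic sites, singular designs) are emitted as
    NA records with a reason note; the scan never aborts.
    """
    genotypes = np.asarray(genotypes, dtype=float)
    order = snp_info.sort_values(["chrom", "pos"], kind="stable").index
    for j in order:
        info = snp_info.loc[j]
        x = genotypes[:, j]
        observed = ~np.isnan(x)
        freq = np.nan if not observed.any() else x[observed].mean() / 2.0
        maf = min(freq, 1.0 - freq) if np.isfinite(freq) else np.nan

        def na_record(reason: str) -> AssocRecord:
            return AssocRecord(
                snp=str(info["snp"]), chrom=str(info["chrom"]),
                pos=int(info["pos"]),
                minor_allele=str(info.get("minor_allele", "")),
                maf=float(maf) if np.isfinite(maf) else float("nan"),
                model=model, beta=float("nan"), se=float("nan"),
                p=float("nan"), n_subjects=int(observed.sum()),
                n_observations=0, note=reason,
            )

        if not observed.any() or np.nanstd(x) == 0:
            yield na_record("monomorphic")
            continue
        xi = np.where(observed, x, x[observed].mean())
        try:
            if interaction is not None:
                fit = fit_interaction(
                    data, snp=xi, environment=interaction, model=model,
                    covariates=covariates, pcs=pcs,
                )
                term = f"{'time' if interaction == 'time' else interaction}:snp"
            elif model == "longitudinal":
                fit = fit_gls_longitudinal(
                    data, snp=xi, covariates=covariates, pcs=pcs
                )
                term = "snp"
            elif model == "cross-sectional":
                fit = fit_ols_cross_sectional(
                    data, snp=xi, covariates=covariates, pcs=pcs
                )
                term = "snp"
            else:
                raise ValueError(f"unknown model {model!r}")
        except (ValueError, np.linalg.LinAlgError) as exc:
            yield na_record(f"fit failed: {exc}")
            continue
        yield AssocRecord(
            snp=str(info["snp"]), chrom=str(info["chrom"]), pos=int(info["pos"]),
            minor_allele=str(info.get("minor_allele", "")), maf=float(maf),
            model=fit.model, beta=float(fit.params[term]),
            se=float(fit.se[term]), p=float(fit.p[term]),
            n_subjects=fit.n_subjects, n_observations=fit.n_observations,
        )
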