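"""Closed-form sample size and power for the repeated-measures design.

For a quantitative trait measured at t visits with a common between-visit
correlation rho, total phenotypic variance sigma_p^2 and SNP effect beta
on a genotype with trinomial variance K, the number of individuals needed
for power 1-phi at two-sided level alpha is

    n = (z_{1-alpha/2} + z_{1-phi})^2 * sigma_p^2 / (K beta^2)
        * (1 + (t-1) rho) / t

When the effect is parameterized by variance explained q (the usual GWAS
convention), K beta^2 = sigma_p^2 * q/(1-q) and the result does not depend
on the allele frequency.  The cross-sectional design is the t=1 special
case; a t-visit design trades genotyping (fewer subjects) for phenotyping
(more measurements).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .genotype import (
    GenotypeDistribution,
    effect_size_from_variance_explained,
    genotype_distribution_from_maf,
    k_statistic,
)

__all__ = [
    "DesignSpec",
    "SampleSizeResult",
    "analytic_sample_size",
    "power_at_n",
    "design_savings",
    "bonferroni_threshold",
]


@dataclass(frozen=True)
class DesignSpec:
    """A repeated-measures study design.

    Attributes
    ----------
    t : int
        Visits per subject (>= 1).
    rho : float
        Common correlation between two visits on the same subject, [0, 1].
    alpha : float
        Two-sided significance level.
    power : float
        Target power 1 - phi.
    q : float
        Fraction of phenotypic variance explained by the SNP.
    maf : float or None
        Allele frequency.  Optional: under the variance-explained
        parameterization the required n is MAF-free.
    sigma_p2 : float
        Total phenotypic variance (default 1).
    """

    t: int
    rho: float
    alpha: float
    power: float
    q: float
    maf: float | None = None
    sigma_p2: float = 1.0

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError(f"t={self.t} must be >= 1")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError(f"rho={self.rho} outside [0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha={self.alpha} outside (0, 1)")
        if not (0.0 < self.power < 1.0):
            raise ValueError(f"power={self.power} outside (0, 1)")
        if not (0.0 <= self.q < 1.0):
            raise ValueError(f"q={self.q} outside [0, 1)")
        if self.sigma_p2 <= 0:
            raise ValueError("sigma_p2 must be positive")


@dataclass(frozen=True)
class SampleSizeResult:
    """Exact (real-valued) and rounded required number of individuals.

    ``n`` is None when the requirement is infinite (zero effect).
    """

    n_exact: float
    n: int | None


def _k_beta2(
    spec: DesignSpec,
    beta: float | None = None,
    dist: GenotypeDistribution | None = None,
) -> float:
    """Signal variance K*beta^2 for the design.

    By default derived from the variance-explained constraint, which makes
    it K*beta^2 = sigma_p2 * q/(1-q) regardless of MAF.  An explicit
    (beta, dist) pair overrides this.
    """
    if beta is not None:
        if dist is None:
            if spec.maf is None:
                raise ValueError("explicit beta requires a distribution or maf")
            dist = genotype_distribution_from_maf(spec.maf)
        return k_statistic(dist) * beta ** 2
    if spec.maf is not None:
        # route through the explicit parameterization; algebraically the
        # MAF cancels, which the tests assert
        b = effect_size_from_variance_explained(spec.q, spec.sigma_p2, spec.maf)
        return k_statistic(genotype_distribution_from_maf(spec.maf)) * b ** 2
    return spec.sigma_p2 * spec.q / (1.0 - spec.q)


def analytic_sample_size(
    spec: DesignSpec,
    beta: float | None = None,
    dist: GenotypeDistribution | None = None,
) -> SampleSizeResult:
    """Required number of individuals for the design.

    Returns both the exact real-valued n and its nearest-integer rounding
    (the rounded value is what gets reported).  A zero effect (beta = 0 or
    a degenerate genotype, K = 0) yields an infinite requirement, returned
    as ``math.inf`` rather than raising.
    """
    kb2 = _k_beta2(spec, beta=beta, dist=dist)
    z = norm.isf(spec.alpha / 2.0) + norm.ppf(spec.power)
    design_factor = (1.0 + (spec.t - 1) * spec.rho) / spec.t
    if kb2 <= 0.0:
        return SampleSizeResult(n_exact=math.inf, n=None)
    n_exact = z ** 2 * spec.sigma_p2 / kb2 * design_factor
    return SampleSizeResult(n_exact=n_exact, n=int(round(n_exact)))


def power_at_n(
    spec: DesignSpec,
    n: float,
    beta: float | None = None,
    dist: GenotypeDistribution | None = None,
) -> float:
    """Power of the Wald test at ``n`` individuals; inverse of the n formula."""
    if n < 0:
        raise ValueError("n must be non-negative")
    kb2 = _k_beta2(spec, beta=beta, dist=dist)
    design_factor = spec.t / (1.0 + (spec.t - 1) * spec.rho)
    ncp = math.sqrt(n * kb2 / spec.sigma_p2 * design_factor)
    return float(norm.cdf(ncp - norm.isf(spec.alpha / 2.0)))


def design_savings(spec: DesignSpec) -> tuple[int, int]:
    """Cost trade-off of the t-visit design versus cross-sectional (t=1).

    Returns ``(genotyping_saved, extra_phenotypes)``: the number of subjects
    that no longer need genotyping, and the number of additional phenotype
    measurements required, with each sample size rounded to the nearest
    integer before differencing.
    """
    if spec.t < 2:
        raise ValueError("savings are defined only for t >= 2")
    n_t = analytic_sample_size(spec).n
    spec1 = DesignSpec(
        t=1, rho=spec.rho, alpha=spec.alpha, power=spec.power,
        q=spec.q, maf=spec.maf, sigma_p2=spec.sigma_p2,
    )
    n_1 = analytic_sample_size(spec1).n
    return (n_1 - n_t, spec.t * n_t - n_1)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Genome-wide significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
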