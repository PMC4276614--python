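"""Trinomial genotype model, the K statistic, and effect-size parameterization.

The additively coded genotype X counts copies of the minor allele
(X in {0, 1, 2}) and follows a trinomial distribution with probabilities
(pi1, pi2, pi3).  Under Hardy-Weinberg equilibrium with minor-allele
frequency p these are ((1-p)^2, 2p(1-p), p^2).

The K statistic

    K = pi1*(pi2 + 2*pi3)^2 + pi2*(pi3 - pi1)^2 + pi3*(1 + pi1 - pi3)^2

equals Var(X) under the trinomial and enters the denominator of the
analytic sample-size formula.  Effect sizes are parameterized by the
fraction q of phenotypic variance explained by the SNP:

    2*beta^2*p*(1-p) / (2*beta^2*p*(1-p) + residual_variance) = q
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GenotypeDistribution",
    "EffectSpec",
    "genotype_distribution_from_maf",
    "k_statistic",
    "effect_size_from_variance_explained",
    "variance_explained_from_effect_size",
    "variance_components_from_design",
]

_TOL = 1e-12


@dataclass(frozen=True)
class GenotypeDistribution:
    """Trinomial distribution of the additively coded genotype.

    Attributes
    ----------
    pi1, pi2, pi3 : float
        Probabilities of 0, 1 and 2 copies of the minor allele.
    maf : float or None
        Minor-allele frequency when the distribution was constructed
        from Hardy-Weinberg equilibrium; None for an arbitrary trinomial.
    """

    pi1: float
    pi2: float
    pi3: float
    maf: float | None = None

    def __post_init__(self) -> None:
        for name, v in (("pi1", self.pi1), ("pi2", self.pi2), ("pi3", self.pi3)):
            if not (-_TOL <= v <= 1 + _TOL):
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = self.pi1 + self.pi2 + self.pi3
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype probabilities sum to {total}, not 1")

    @property
    def mean(self) -> float:
        """E[X] = pi2 + 2*pi3."""
        return self.pi2 + 2.0 * self.pi3

    @property
    def variance(self) -> float:
        """Var(X), identical to the K statistic."""
        return k_statistic(self)


@dataclass(frozen=True)
class EffectSpec:
    """Per-allele effect together with its variance-explained parameterization.

    beta is the phenotype change per copy of the minor allele,
    variance_explained (q) the fraction of total phenotypic variance
    attributable to the SNP, heritability (h2) the fraction due to the SNP
    plus the polygenic background.
    """

    beta: float
    variance_explained: float = 0.0
    heritability: float | None = None

    def __post_init__(self) -> None:
        q = self.variance_explained
        if not (0.0 <= q < 1.0):
            raise ValueError(f"variance_explained={q} must lie in [0, 1)")
        if self.heritability is not None:
            h2 = self.heritability
            if not (0.0 <= h2 < 1.0):
                raise ValueError(f"heritability={h2} must lie in [0, 1)")
            if q > h2 + _TOL:
                raise ValueError(
                    f"variance_explained={q} exceeds heritability={h2}"
                )


def genotype_distribution_from_maf(p: float) -> GenotypeDistribution:
    """HWE trinomial probabilities for allele frequency ``p``.

    Parameters
    ----------
    p : float
        Frequency of the counted (minor) allele, in [0, 1].
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"allele frequency p={p} outside [0, 1]")
    return GenotypeDistribution(
        pi1=(1.0 - p) ** 2, pi2=2.0 * p * (1.0 - p), pi3=p ** 2, maf=p
    )


def k_statistic(dist: GenotypeDistribution) -> float:
    """K = pi1*(pi2+2*pi3)^2 + pi2*(pi3-pi1)^2 + pi3*(1+pi1-pi3)^2.

    Equals the variance of the coded genotype; under HWE, K = 2p(1-p).
    """
    p1, p2, p3 = dist.pi1, dist.pi2, dist.pi3
    return (
        p1 * (p2 + 2.0 * p3) ** 2
        + p2 * (p3 - p1) ** 2
        + p3 * (1.0 + p1 - p3) ** 2
    )


def effect_size_from_variance_explained(
    q: float, residual_variance: float, p: float
) -> float:
    """Solve 2*beta^2*p*(1-p) = residual_variance * q/(1-q) for beta >= 0.

    ``residual_variance`` is the non-SNP phenotypic variance
    (sigma_c^2 + sigma_e^2, plus sigma_g^2 when a polygenic component is
    present).  Returns 0 when q = 0.
    """
    if not (0.0 <= q < 1.0):
        raise ValueError(f"variance explained q={q} must lie in [0, 1)")
    if residual_variance <= 0.0:
        raise ValueError("residual_variance must be positive")
    if q == 0.0:
        return 0.0
    if p <= 0.0 or p >= 1.0:
        raise ValueError(
            f"allele frequency p={p} is monomorphic; cannot explain q={q} > 0"
        )
    snp_var = residual_variance * q / (1.0 - q)
    return math.sqrt(snp_var / (2.0 * p * (1.0 - p)))


def variance_explained_from_effect_size(
    beta: float, residual_variance: float, p: float
) -> float:
    """Inverse map: q implied by (beta, p) given the residual variance."""
    snp_var = 2.0 * beta ** 2 * p * (1.0 - p)
    return snp_var / (snp_var + residual_variance)


def variance_components_from_design(
    q: float,
    h2: float,
    rho: float,
    total_variance: float = 1.0,
) -> tuple[float, float, float]:
    """Variance components (sigma_g2, sigma_c2, sigma_e2) implied by a design.

    With components normalized so sigma_g2 + sigma_c2 + sigma_e2 =
    ``total_variance``, the SNP contributes v = total_variance * q/(1-q)
    and heritability constrains h2 = (v + sigma_g2)/(v + total_variance).
    rho is the share sigma_c2 / total_variance due to the subject-level
    random intercept.

    Raises
    ------
    ValueError
        If h2 < q (polygenic variance would be negative) or
        rho > 1 - sigma_g2/total_variance (residual variance negative).
    """
    if total_variance <= 0:
        raise ValueError("total_variance must be positive")
    if not (0.0 <= q < 1.0) or not (0.0 <= h2 < 1.0) or not (0.0 <= rho <= 1.0):
        raise ValueError("q and h2 must lie in [0,1), rho in [0,1]")
    v = q / (1.0 - q)  # SNP variance in units of total_variance
    sigma_g2 = h2 * (1.0 + v) - v
    if sigma_g2 < -_TOL:
        raise ValueError(
            f"infeasible design: heritability h2={h2} is below the SNP "
            f"variance share q={q} (implied sigma_g2={sigma_g2:.6g} < 0)"
        )
    sigma_g2 = max(sigma_g2, 0.0)
    sigma_c2 = rho
    sigma_e2 = 1.0 - sigma_g2 - sigma_c2
    if sigma_e2 < -_TOL:
        raise ValueError(
            f"infeasible design: rho={rho} exceeds 1 - sigma_g2 = "
            f"{1.0 - sigma_g2:.6g} (implied sigma_e2 < 0)"
        )
    sigma_e2 = max(sigma_e2, 0.0)
    s = total_variance
    return (sigma_g2 * s, sigma_c2 * s, sigma_e2 * s)
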