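"""Direction-aware replication p-values and combined evidence across cohorts.

Replication evidence is oriented to the discovery effect direction: the
one-sided replication p is p/2 when the replication coefficient has the
expected sign and 1 - p/2 otherwise, so discordant directions yield
p > 0.5.  Oriented p-values are then combined by Fisher's method
(-2 sum ln p_i against chi-square with 2k df) or Liptak's weighted-Z
method (z = sum w_i z_i / sqrt(sum w_i^2) with w_i = sqrt(n_i)), the
latter the more efficient when effect sizes are expected to be equal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm

__all__ = [
    "CohortEvidence",
    "CombinedResult",
    "one_sided_p",
    "fisher_combine",
    "liptak_combine",
]


@dataclass(frozen=True)
class CohortEvidence:
    """One cohort's evidence for a SNP: p-value, effect sign, sample size."""

    cohort: str
    p: float
    beta_sign: int
    n: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p={self.p} outside (0, 1]")
        if self.n <= 0:
            raise ValueError("cohort sample size must be positive")


@dataclass
class CombinedResult:
    """Fisher and/or Liptak combination of per-cohort p-values."""

    p_values: tuple[float, ...]
    fisher_statistic: float | None = None
    fisher_p: float | None = None
    liptak_z: float | None = None
    liptak_p: float | None = None
    weights: tuple[float, ...] | None = None


def one_sided_p(beta: float, p_two_sided: float, expected_sign: int) -> float:
    """Orient a two-sided p-value to the expected effect direction.

    Returns p/2 on a sign match, 1 - p/2 on a mismatch, and 0.5 for a
    zero estimate.
    """
    if not (0.0 < p_two_sided <= 1.0):
        raise ValueError(f"p_two_sided={p_two_sided} outside (0, 1]")
    if expected_sign not in (-1, 1):
        raise ValueError("expected_sign must be -1 or +1")
    if beta == 0:
        return 0.5
    if math.copysign(1, beta) == expected_sign:
        return p_two_sided / 2.0
    return 1.0 - p_two_sided / 2.0


def _validate(ps, open_upper: bool) -> np.ndarray:
    p = np.asarray(ps, dtype=float)
    if p.size < 2:
        raise ValueError("need at least two p-values to combine")
    hi_ok = (p < 1.0) if open_upper else (p <= 1.0)
    if not ((p > 0.0) & hi_ok).all():
        interval = "(0, 1)" if open_upper else "(0, 1]"
        raise ValueError(
            f"p-values must lie in {interval} (floor underflowing values "
            "explicitly, e.g. at 1e-300)"
        )
    return p


def fisher_combine(ps, floor: float | None = None) -> CombinedResult:
    """Fisher's method: X2 = -2 sum ln p_i ~ chi-square on 2k df.

    A p of exactly 0 makes the statistic infinite and is rejected; pass
    ``floor`` (e.g. 1e-300) to clip underflowing inputs explicitly.
    """
    p = np.asarray(ps, dtype=float)
    if floor is not None:
        p = np.maximum(p, floor)
    p = _validate(p, open_upper=False)
    x2 = float(-2.0 * np.log(p).sum())
    return CombinedResult(
        p_values=tuple(p),
        fisher_statistic=x2,
        fisher_p=float(chi2.sf(x2, df=2 * p.size)),
    )


def liptak_combine(ps, ns, floor: float | None = None) -> CombinedResult:
    """Liptak's weighted-Z method with weights w_i = sqrt(n_i).

    z = sum w_i z_i / sqrt(sum w_i^2) with z_i the upper-tail normal
    quantile of p_i; combined p = 1 - Phi(z).  Equal weights reduce to
    Stouffer's method.
    """
    p = np.asarray(ps, dtype=float)
    if floor is not None:
        p = np.clip(p, floor, np.nextafter(1.0, 0.0))
    p = _validate(p, open_upper=True)
    n = np.asarray(ns, dtype=float)
    if n.shape != p.shape or (n <= 0).any():
        raise ValueError("sample sizes must be positive, one per p-value")
    w = np.sqrt(n)
    z = float((w * norm.isf(p)).sum() / math.sqrt((w ** 2).sum()))
    return CombinedResult(
        p_values=tuple(p),
        liptak_z=z,
        liptak_p=float(norm.sf(z)),
        weights=tuple(w),
    )
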