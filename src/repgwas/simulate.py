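"""Synthetic longitudinal cohorts and Monte-Carlo power estimation.

The phenotype for subject i at visits j = 1..t is generated from the
random-effects model

    Y_ij = mu + X_i beta + g_i + c_i + e_ij

with X_i an HWE genotype dosage, c_i ~ N(0, sigma_c2) a subject-level
random intercept shared across visits, e_ij ~ N(0, sigma_e2) i.i.d.
measurement noise, and g = (g_1..g_n) an optional polygenic effect with
covariance sigma_g2 * Phi across subjects.  Phi is compound symmetric
with off-diagonal ``kinship_offdiag`` (0.1 emulates remote relatedness at
the population level).  With sigma_g2 = 0 the within-subject correlation
matrix is compound symmetric with correlation
rho = sigma_c2 / (sigma_c2 + sigma_e2).

Cohort sizes, visit spacing (0/2/4 years) and the monotone-dropout
defaults emulate a population cohort followed at two-year intervals with
baseline n 8842 retaining 7568 and 6675 subjects at the later visits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .dataset import LongitudinalDataset

__all__ = [
    "SimulationSpec",
    "KARE_RETENTION",
    "simulate_cohort",
    "monte_carlo_power",
    "monte_carlo_sample_size",
    "MonteCarloPower",
    "SampleSizeSearch",
]

# Baseline-relative retention of the motivating three-visit cohort
# (8842 -> 7568 -> 6675 subjects).
KARE_RETENTION: tuple[float, float, float] = (1.0, 7568 / 8842, 6675 / 8842)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated cohort.

    Attributes
    ----------
    n, t : int
        Subjects and visits per subject.
    maf : float
        Minor-allele frequency of the simulated SNP (HWE genotypes).
    beta : float
        Phenotype change per minor-allele copy.
    sigma_g2, sigma_c2, sigma_e2 : float
        Polygenic, subject-intercept and measurement-noise variances.
    kinship_offdiag : float
        Off-diagonal of the compound-symmetric kinship matrix Phi.
    dropout : tuple of float or None
        Per-visit retention fractions (non-increasing, first = 1);
        None keeps every visit complete.
    intercept : float
        Grand mean mu.
    seed : int
        RNG seed.
    replicates : int
        Monte-Carlo replicate count for power estimation.
    """

    n: int
    t: int = 3
    maf: float = 0.3
    beta: float = 0.0
    sigma_g2: float = 0.0
    sigma_c2: float = 0.4
    sigma_e2: float = 0.6
    kinship_offdiag: float = 0.1
    dropout: tuple[float, ...] | None = None
    intercept: float = 0.0
    seed: int = 0
    replicates: int = 400
    time_offsets: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n < 1 or self.t < 1:
            raise ValueError("n and t must be >= 1")
        if not (0.0 < self.maf < 1.0):
            raise ValueError(f"maf={self.maf} outside (0, 1)")
        for name in ("sigma_g2", "sigma_c2", "sigma_e2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dropout is not None:
            r = self.dropout
            if len(r) != self.t:
                raise ValueError("dropout must give one retention per visit")
            if abs(r[0] - 1.0) > 1e-12:
                raise ValueError("baseline retention must be 1 (complete)")
            if any(b > a + 1e-12 for a, b in zip(r, r[1:])):
                raise ValueError("retention fractions must be non-increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def rho(self) -> float:
        """Within-subject correlation in the no-polygenic model."""
        tot = self.sigma_c2 + self.sigma_e2
        return self.sigma_c2 / tot if tot > 0 else 0.0

    def offsets(self) -> np.ndarray:
        if self.time_offsets is not None:
            if len(self.time_offsets) != self.t:
                raise ValueError("time_offsets length must equal t")
            return np.asarray(self.time_offsets, dtype=float)
        return 2.0 * np.arange(self.t, dtype=float)  # biennial visits


def _polygenic_effect(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw g ~ MVN(0, sigma_g2 * Phi) with compound-symmetric Phi.

    For off-diagonal a >= 0 the draw uses the implicit factorization
    g_i = sigma_g * (sqrt(a) u + sqrt(1-a) v_i) with u, v_i standard
    normal, avoiding an n x n decomposition.  Negative a (valid down to
    -1/(n-1)) falls back to a dense Cholesky.
    """
    a = spec.kinship_offdiag
    sg = math.sqrt(spec.sigma_g2)
    if a >= 0.0:
        if a > 1.0:
            raise ValueError(f"kinship off-diagonal {a} > 1: Phi not PSD")
        shared = rng.standard_normal()
        return sg * (
            math.sqrt(a) * shared
            + math.sqrt(1.0 - a) * rng.standard_normal(spec.n)
        )
    phi = np.full((spec.n, spec.n), a)
    np.fill_diagonal(phi, 1.0)
    w = np.linalg.eigvalsh(phi)
    if w[0] < -1e-10:
        raise ValueError(
            f"kinship matrix is not PSD: smallest eigenvalue {w[0]:.3g}"
        )
    chol = np.linalg.cholesky(phi + 1e-12 * np.eye(spec.n))
    return sg * (chol @ rng.standard_normal(spec.n))


def simulate_cohort(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> LongitudinalDataset:
    """Generate one cohort under the random-effects phenotype model.

    Genotypes are HWE trinomial draws at ``spec.maf``; dropout, when
    requested, is monotone and completely at random (a subject lost at
    visit j is absent from all later visits).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n, t = spec.n, spec.t

    x = rng.binomial(2, spec.maf, size=n).astype(float)
    c = rng.normal(0.0, math.sqrt(spec.sigma_c2), size=n)
    g = (
        _polygenic_effect(spec, rng)
        if spec.sigma_g2 > 0
        else np.zeros(n)
    )
    eps = rng.normal(0.0, math.sqrt(spec.sigma_e2), size=(n, t))
    subject = spec.intercept + x * spec.beta + g + c
    Y = subject[:, None] + eps

    mask = np.ones((n, t), dtype=bool)
    if spec.dropout is not None:
        order = rng.permutation(n)  # rank < retained  => still in at visit j
        rank = np.empty(n, dtype=int)
        rank[order] = np.arange(n)
        for j, r in enumerate(spec.dropout):
            kept = int(round(r * n))
            mask[:, j] = rank < kept
        Y = np.where(mask, Y, np.nan)

    ids = np.array([f"S{i:06d}" for i in range(n)])
    return LongitudinalDataset(
        ids=ids, Y=Y, mask=mask, time_offsets=spec.offsets(), genotype=x
    )


@dataclass
class MonteCarloPower:
    """Rejection fraction with its binomial standard error."""

    power: float
    se: float
    n_replicates: int
    n_failed: int
    analysis: str


def _whitened_design(spec, data, x):
    """Exact GLS whitening by the known total covariance (complete data).

    The covariance of the stacked phenotypes under the generating model is
    I_n (x) A + J_n (x) B with A = (sigma_g2 (1-a) + sigma_c2) J_t
    + sigma_e2 I_t and B = sigma_g2 a J_t / — after within-subject
    whitening by A^{-1/2} the remaining cross-subject part is a rank-one
    perturbation handled in closed form.
    """
    t = spec.t
    a = spec.kinship_offdiag
    J = np.ones((t, t))
    A = (spec.sigma_g2 * (1 - a) + spec.sigma_c2) * J + spec.sigma_e2 * np.eye(t)
    B = spec.sigma_g2 * a * J
    evals, evecs = np.linalg.eigh(A)
    A_isqrt = (evecs / np.sqrt(evals)) @ evecs.T
    C = spec.n * A_isqrt @ B @ A_isqrt
    evals2, evecs2 = np.linalg.eigh(np.eye(t) + C)
    M = (evecs2 / np.sqrt(evals2)) @ evecs2.T - np.eye(t)  # (I+C)^{-1/2} - I

    Yw = data.Y @ A_isqrt.T
    Yw += np.outer(np.ones(spec.n), M @ Yw.mean(axis=0))
    ones = np.ones((spec.n, t))
    Xd = x[:, None] * ones
    onesw = ones @ A_isqrt.T
    onesw += np.outer(np.ones(spec.n), M @ onesw.mean(axis=0))
    Xw = Xd @ A_isqrt.T
    Xw += np.outer(np.ones(spec.n), M @ Xw.mean(axis=0))
    D = np.column_stack([onesw.ravel(), Xw.ravel()])
    return D, Yw.ravel()


def _snp_pvalue(spec: SimulationSpec, data, analysis: str) -> float:
    """Two-sided Wald p for the SNP under the chosen analysis engine."""
    from .assoc import fit_gls_longitudinal

    if analysis == "gls_independent":
        fit = fit_gls_longitudinal(data, snp=data.genotype)
        return float(fit.p["snp"])
    if analysis == "gls_whitened":
        if spec.dropout is not None:
            raise ValueError("whitened analysis requires complete data")
        D, y = _whitened_design(spec, data, data.genotype)
        coef, *_ = np.linalg.lstsq(D, y, rcond=None)
        cov = np.linalg.inv(D.T @ D)
        z = coef[1] / math.sqrt(cov[1, 1])
        return float(2.0 * norm.sf(abs(z)))
    raise ValueError(f"unknown analysis engine: {analysis!r}")


def monte_carlo_power(
    spec: SimulationSpec,
    alpha: float,
    analysis: str = "gls_independent",
) -> MonteCarloPower:
    """Estimate power of the SNP Wald test by simulation.

    Simulates ``spec.replicates`` cohorts (child seeds spawned from
    ``spec.seed``), fits the chosen analysis to each, and reports the
    fraction rejecting at ``alpha`` with its binomial standard error.
    Replicates whose fit fails are excluded and counted.
    """
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.replicates)
    rejected = 0
    failed = 0
    for ss in seeds:
        rng = np.random.default_rng(ss)
        data = simulate_cohort(spec, rng=rng)
        try:
            p = _snp_pvalue(spec, data, analysis)
        except (np.linalg.LinAlgError, ValueError):
            failed += 1
            continue
        if p < alpha:
            rejected += 1
    m = spec.replicates - failed
    if m == 0:
        raise RuntimeError("every Monte-Carlo replicate failed")
    power = rejected / m
    se = math.sqrt(power * (1.0 - power) / m)
    return MonteCarloPower(
        power=power, se=se, n_replicates=m, n_failed=failed, analysis=analysis
    )


@dataclass
class SampleSizeSearch:
    """Monte-Carlo sample-size result with the probed power curve."""

    n: int
    target_power: float
    probed: dict[int, float]
    warning: str | None = None


def monte_carlo_sample_size(
    spec: SimulationSpec,
    alpha: float,
    target_power: float,
    analysis: str = "gls_independent",
    n_init: int | None = None,
    grid_step: int | None = None,
    n_max: int | None = None,
) -> SampleSizeSearch:
    """Smallest n on a bisection grid whose estimated power meets the target.

    The search brackets the target starting from ``n_init`` (by default the
    analytic no-substructure sample size for the spec's implied design) and
    bisects on a grid of ``grid_step`` subjects (default 1% of the starting
    point, floor 10).  Power at every probed n is returned.  If the target
    is not reached by ``n_max`` (default 20x the starting point) the upper
    bracket is returned with a warning.
    """
    if not (0.0 < target_power < 1.0):
        raise ValueError("target power must lie in (0, 1)")
    if n_init is None:
        from .genotype import variance_explained_from_effect_size
        from .power import DesignSpec, analytic_sample_size

        resid = spec.sigma_g2 + spec.sigma_c2 + spec.sigma_e2
        q = variance_explained_from_effect_size(spec.beta, resid, spec.maf)
        if q == 0.0:
            raise ValueError("beta=0: no finite sample size exists")
        design = DesignSpec(
            t=spec.t, rho=spec.rho, alpha=alpha, power=target_power, q=q
        )
        n_init = analytic_sample_size(design).n
    step = grid_step if grid_step is not None else max(10, round(0.01 * n_init))
    if n_max is None:
        n_max = 20 * n_init

    probed: dict[int, float] = {}

    def power_at(n: int) -> float:
        n = max(n, 2)
        if n not in probed:
            probe = SimulationSpec(
                **{**spec.__dict__, "n": n, "seed": spec.seed + n}
            )
            probed[n] = monte_carlo_power(probe, alpha, analysis).power
        return probed[n]

    # bracket the target: hi meets it, lo (if > 2) does not
    lo, hi = 2, n_init
    if power_at(n_init) >= target_power:
        width = step
        while hi - width > 2 and power_at(hi - width) >= target_power:
            hi -= width
            width *= 2
        lo = max(hi - width, 2)
    else:
        width = step
        lo = n_init
        while True:
            hi = min(lo + width, n_max)
            if power_at(hi) >= target_power:
                break
            if hi >= n_max:
                return SampleSizeSearch(
                    n=hi, target_power=target_power, probed=probed,
                    warning="target power not reached by n_max; "
                            "returning upper bracket",
                )
            lo, width = hi, width * 2
    while hi - lo > step:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return SampleSizeSearch(n=hi, target_power=target_power, probed=probed)
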