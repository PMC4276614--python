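"""Simulate a longitudinal cohort and fit the GLS association model.

Generates a three-visit cohort with monotone dropout emulating a real
population cohort (retention 1 / 0.856 / 0.755), a causal SNP, and a
subject-level random intercept, then fits both the longitudinal GLS
model (unstructured within-subject covariance) and the baseline-only
OLS model.
"""

import numpy as np

from repgwas import (
    KARE_RETENTION,
    SimulationSpec,
    fit_gls_longitudinal,
    fit_ols_cross_sectional,
    simulate_cohort,
)

spec = SimulationSpec(
    n=4000, t=3, maf=0.3, beta=0.12,
    sigma_c2=0.4, sigma_e2=0.6,          # between-visit correlation 0.4
    dropout=KARE_RETENTION, seed=2014,
)
data = simulate_cohort(spec)
print(f"cohort: {data.n_subjects} subjects, visits observed "
      f"{data.mask.sum(axis=0).tolist()} (monotone dropout)")

gls = fit_gls_longitudinal(data)
ols = fit_ols_cross_sectional(data)

print(f"\ntrue SNP effect: {spec.beta}")
print(f"longitudinal GLS : beta = {gls.params['snp']:.4f} "
      f"+/- {gls.se['snp']:.4f}, p = {gls.p['snp']:.2e}")
print(f"cross-sectional  : beta = {ols.params['snp']:.4f} "
      f"+/- {ols.se['snp']:.4f}, p = {ols.p['snp']:.2e}")
print(f"\nestimated within-subject covariance (truth: 0.4 off-diagonal):")
print(np.round(gls.sigma, 3))
print("\nReading: both estimates cover the simulated effect, but the")
print("longitudinal fit has the smaller standard error — the repeated")
print("measurements act like extra (correlated) sample size.")
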