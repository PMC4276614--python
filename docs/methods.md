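# Methods

## Phenotype model and design quantities

The generative model for subject *i* over *t* visits is

    Y_i = Z_i α + (X_i β) 1_t + g_i 1_t + c_i 1_t + ε_i

with genotype dosage X_i drawn from a trinomial distribution (HWE by
default), subject random intercept c_i ~ N(0, σ_c²), i.i.d. measurement
noise ε_ij ~ N(0, σ_ε²), and an optional polygenic effect g with
covariance σ_g² Φ across subjects.  With σ_g² = 0 the within-subject
correlation matrix is compound symmetric with correlation
ρ = σ_c²/(σ_c² + σ_ε²).

The K statistic, K = π₁(π₂+2π₃)² + π₂(π₃−π₁)² + π₃(1+π₁−π₃)², is an
algebraic rewrite of Var(X) under the trinomial; the test suite verifies
the identity against direct enumeration and the HWE special case
K = 2p(1−p).  It is exposed for arbitrary trinomials, not only HWE ones.

The analytic sample size uses the squared sum of standard-normal
quantiles, (z_{1−α/2} + z_{1−φ})², the standard normal-approximation form
for a Wald test.  Reported sample sizes are rounded to the **nearest**
integer (not ceiling); the exact real value is always returned alongside,
and the design-savings arithmetic differences the rounded values.  Power
and sample size are exact mutual inverses of one another in the unrounded
quantities.

Effect sizes are parameterized by variance explained q through
2β²p(1−p) = residual_variance · q/(1−q).  Under that constraint
K β² = σ_p² q/(1−q), so the analytic sample size does not depend on the
allele frequency; a property test asserts invariance across MAF 0.05–0.5
to machine precision.  The variance-component solver normalizes
σ_g² + σ_c² + σ_ε² to the total variance (1 by default; an absolute-scale
entry point is provided and scale invariance is tested) and solves the
heritability constraint h² = (v + σ_g²)/(v + 1) with v = q/(1−q),
rejecting infeasible designs (h² < q, or ρ > 1 − σ_g²) with an error
naming the violated constraint.

## Synthetic cohorts

`simulate_cohort` emulates a population cohort phenotyped at biennial
visits (time offsets 0, 2, 4 years for t = 3).  Defaults: MAF 0.3,
σ_c² = 0.4 and σ_ε² = 0.6 (ρ = 0.4, the middle of the observed range of
between-visit phenotype correlations in such cohorts), compound-symmetric
kinship with off-diagonal 0.1 when a polygenic component is requested
(remote population-level relatedness), and optional monotone dropout;
the bundled `KARE_RETENTION = (1, 0.856, 0.755)` reproduces a baseline of
8842 subjects shrinking to 7568 and 6675.

Implementation notes:

- The compound-symmetric polygenic draw uses the shared/idiosyncratic
  factorization g_i = σ_g(√a·u + √(1−a)·v_i), which is exact for
  off-diagonal a ∈ [0, 1] and avoids an n×n decomposition, so cohorts of
  tens of thousands are cheap.  Negative a (valid down to −1/(n−1)) falls
  back to a dense Cholesky with an explicit PSD check that reports the
  offending eigenvalue.
- Dropout is monotone (observed visits form a prefix) and completely at
  random: a single random subject ranking determines who is retained at
  each visit, so retention counts match `round(r_j · n)` exactly.
  Informative dropout is out of scope; inference downstream is valid
  under MCAR/MAR only.
- The simulator emits normal phenotypes.  Real traits needing a log
  transform to reach normality are emulated by exponentiating downstream;
  no skewed-noise generator is provided.  The generator also makes no
  attempt at linkage disequilibrium or a realistic allele-frequency
  spectrum — null-scan SNPs are i.i.d. — so passing calibration tests
  here bounds model behaviour, not artifacts of real LD structure.

`monte_carlo_power` spawns one child seed per replicate from a single
seed sequence (same seed ⇒ bit-identical results), fits the chosen
analysis engine, and reports the rejection fraction with its binomial
standard error; replicates with failed fits are excluded and counted.
Two engines are offered: the default fits the longitudinal GLS treating
subjects as independent (the analysis model used for the real scans); the
`gls_whitened` alternative whitens by the *known* generating covariance
including the polygenic term, using the rank-one structure of the
cross-subject part in closed form (complete balanced data only).  The
sample-size search brackets the analytic value, bisects on a grid
(default step 1 % of the starting n, floor 10 subjects), caps at a
configurable n_max (default 20× the start, returning the upper bracket
with a warning), and reports the power estimate at every probed n.

## GLS association engine

Estimation is iterated feasible GLS rather than REML: (1) OLS on the
stacked observed rows; (2) method-of-moments update
Σ̂_jk = Σ_i r_ij r_ik / n_jk over pairwise-complete visits; (3) GLS with
each subject whitened by the Cholesky inverse of the submatrix of Σ̂ for
their observed visits (subjects sharing a missingness pattern are
whitened as a block); iterate (2)–(3) until max |ΔΣ̂| < 1e-8 or 50
iterations.  At cohort scale the difference from REML is negligible and
no result here depends on it.  A non-positive-definite moment estimate is
repaired with the smallest ridge that restores a positive eigenvalue
floor; the ridge is recorded on the fit and a warning raised.

Wald z statistics are referred to the standard normal, not Student's t —
the intended n is in the thousands.  A deliberate consequence of using
the moment (denominator-n) variance throughout: the t = 1 longitudinal
fit coincides *exactly* with the cross-sectional OLS fit, which the suite
asserts.  At small n the normal reference is very slightly
anticonservative (~0.052 at n = 150), visible in the interaction
calibration test's tolerance.

Covariate columns are broadcast from baseline across a subject's observed
visits; the visit time offset enters as a fixed-effect column (dropped at
t = 1 where it is constant).  Interaction models add the product of the
SNP dosage with sex/age (subject-level) or with the visit time offset
(row-level), always retaining both main effects.  Rank-deficient designs
raise an error naming the collinear columns (via the QR diagonal);
constant environments are rejected as inestimable.  The standard
covariate builder produces intercept, sex, baseline age and age² for
every phenotype, adding baseline weight for fasting/post-load glucose.

Scans iterate SNPs in (chromosome, position) order; monomorphic sites and
failed fits are emitted as NA records with a reason code rather than
aborting.  Missing dosages are mean-imputed per SNP, the usual convention
for hard calls at ≥95 % call rate.

## Structure adjustment

The IBS similarity between two subjects averages the allele-sharing
fraction (2 − |x_i − x_j|)/2 over loci observed in both; pairs with no
shared locus are NaN.  PCA double-centers the IBS matrix first (the
multidimensional-scaling convention) so that eigenvalue mass — and hence
the reported variance fraction over positive eigenvalues — is well
defined; scores are eigenvectors scaled by √eigenvalue, top five by
default.  Genomic control uses λ = median(χ²)/0.45494 (the χ²₁ median to
five decimals, hard-coded as a documented constant); λ is reported raw,
never clipped, and the optional correction divides the statistics by λ
before mapping back to 1-df p-values.  The toolkit's intended order is
PC-adjust the scan first, then measure/correct residual inflation with
genomic control; both steps are independently callable.

## Replication combination

Replication p-values are oriented to the discovery effect direction:
p/2 on a sign match, 1 − p/2 otherwise (0.5 for a zero estimate), so
discordant cohorts yield p > 0.5 and actively weaken the combination.
Fisher's statistic −2Σln p is referred to χ² with 2k df; Liptak's
weighted Z uses w_i = √n_i with n_i the per-phenotype baseline cohort
sizes, which reduces to Stouffer's method under equal weights.  Exact
zeros or ones are rejected rather than silently clamped; an explicit
`floor` argument (e.g. 1e-300) is the sanctioned escape hatch.  Note the
mixed convention the combination consumes in the replication workflow:
the discovery p is two-sided while the replication p is one-sided — this
is how such tables are conventionally assembled, and the package follows
the numbers rather than re-deriving a fully one-sided discovery p.

## QC

Filter order within a sweep: sample call rate → SNP call rate → HWE →
MAF → per-sample heterozygosity → pairwise IBS.  Sample-level filters
precede SNP-level ones, mirroring common GWAS practice; because each
removal changes the statistics the later steps see, sweeps repeat until
a full pass removes nothing, making the filter idempotent (the report
accumulates per-step counts across sweeps).  Of an IBS-flagged pair the
lower-call-rate member is removed; ties drop the later sample in file
order — fully deterministic.  HWE defaults to the 1-df χ² goodness-of-fit
test with the conditional exact test behind a flag (validated against
brute-force enumeration).  Heterozygosity is the fraction of non-missing
calls that are heterozygous.  VCF input (diploid GT, via cyvcf2) is
oriented to minor-allele dosage, flipping sites whose ALT frequency
exceeds 0.5 and recording the flip; multi-allelic sites are skipped with
a count.

## Problem sizes and tolerances in the test suite

Monte-Carlo checks run at the sizes a desk validation needs, chosen once:
400 replicates for power calibration at the analytic design point
(binomial s.e. ≈ 0.02, asserted at ±2 s.e.), 120–400 replicates for
monotonicity and null-calibration checks, 2 000–20 000 subjects for
parameter-recovery and covariance-convergence checks with tolerances set
at ~3 Monte-Carlo standard errors of the quantity under test.  Published
two-cohort combination values are asserted at 1 % relative tolerance
because the inputs they are recomputed from are themselves printed at
3 significant figures.  All stochastic tests run under fixed seeds.

## Known limitations

- The closed-form sample size assumes equal visit counts, compound
  symmetry, and no covariate–genotype correlation; unequal designs are
  handled only by simulation.
- Feasible GLS standard errors ignore the sampling variability of Σ̂
  (as does any plug-in GLS); at n in the hundreds and below, inference
  is slightly anticonservative.
- Relatedness enters the *test* only through PCs and genomic control;
  no mixed-model (kinship-random-effect) association engine is provided.
- Binary traits, survival outcomes, dosage-uncertainty (imputation)
  input, X-chromosome coding and multi-allelic sites are out of scope.
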