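# repgwas

Design and analysis toolkit for **repeated-measures (longitudinal) GWAS** of
quantitative traits: how many subjects does a study need when each is
phenotyped at several visits, and how should the resulting correlated
measurements be analyzed?

The package is aimed at statistical geneticists and epidemiologists planning
or analyzing cohort studies in which phenotyping is cheap relative to
genotyping — the setting where measuring each genotyped subject repeatedly
buys power that would otherwise require thousands of additional genomes.

## The model

The phenotype of subject *i* at visits *j* = 1..*t* follows a random-effects
model

```
Y_i = Z_i α + (X_i β) 1_t + g_i 1_t + c_i 1_t + ε_i,
c_i ~ N(0, σ_c²),  ε_i ~ MVN(0, σ_ε² I),  g ~ MVN(0, σ_g² Φ)
```

where *X_i* is the additively coded minor-allele dosage (0/1/2, trinomial
with HWE probabilities (1−p)², 2p(1−p), p²), *c_i* a subject-level random
intercept, and *g* an optional polygenic effect with kinship matrix Φ.
Writing σ_p² = σ_g² + σ_c² + σ_ε² and ρ = σ_c²/σ_p², the number of subjects
needed for power 1−φ at two-sided level α is

```
n = (z_{1−α/2} + z_{1−φ})² · σ_p² / (K β²) · (1 + (t−1)ρ) / t
```

with `K = π₁(π₂+2π₃)² + π₂(π₃−π₁)² + π₃(1+π₁−π₃)²` the variance of the coded
genotype.  When the effect is parameterized by the fraction *q* of variance
explained (`2β²p(1−p) / (2β²p(1−p) + σ_c² + σ_ε²) = q`), `K β² = σ_p²·q/(1−q)`
and the requirement is independent of the allele frequency.

Association analysis uses iterated feasible **GLS with an unstructured t×t
within-subject covariance** (cross-sectional OLS as the *t*=1 special case),
with IBS-matrix principal components as stratification covariates, genomic
control for residual inflation, gene×environment (sex/age/time) interaction
tests, and direction-aware Fisher/Liptak combination of discovery and
replication cohort p-values.

## Worked example

```python
from repgwas import DesignSpec, analytic_sample_size, design_savings

design = DesignSpec(t=3, rho=0.4, alpha=1e-8, power=0.8, q=0.005)
print(analytic_sample_size(design).n)   # 5158
print(design_savings(design))           # (3438, 6878)
```

A SNP explaining 0.5 % of phenotypic variance reaches genome-wide
significance (α = 10⁻⁸) with 80 % power using **5158** subjects measured at
three visits with between-visit correlation 0.4 — versus **8596** measured
once.  The three-visit design saves genotyping for **3438** subjects at the
cost of **6878** extra phenotype measurements.  Running
`python examples/simulate_and_fit.py` closes the loop by simulation:

```
true SNP effect: 0.12
longitudinal GLS : beta = 0.1007 +/- 0.0201, p = 5.47e-07
cross-sectional  : beta = 0.0962 +/- 0.0247, p = 9.82e-05
```

Both fits recover the simulated effect; the longitudinal standard error is
smaller because the repeated measurements act like extra (correlated)
sample size.  The other scripts in `examples/` walk through Monte-Carlo
power checks, genotype QC, IBS-PCA + genomic-control stratification
adjustment, and two-cohort replication combination.

A thin CLI mirrors the library:

```sh
repgwas power calc --t 3 --rho 0.4 --alpha 1e-8 --power 0.8 --q 0.005
repgwas simulate --spec config.yaml --out prefix
repgwas gwas --model long --pheno pheno.tsv --geno study.vcf --out gwas.tsv
repgwas pca / gc / qc / combine ...
```

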