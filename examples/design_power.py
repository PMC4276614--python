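"""How many subjects does a repeated-measures GWAS need?

Computes the closed-form required sample size for a quantitative-trait
GWAS with three biennial visits, compares it with the single-visit
(cross-sectional) requirement, and prints the genotyping/phenotyping
trade-off.
"""

from repgwas import DesignSpec, analytic_sample_size, design_savings, power_at_n

design = DesignSpec(t=3, rho=0.4, alpha=1e-8, power=0.8, q=0.005)

res = analytic_sample_size(design)
saved, extra = design_savings(design)
cross = analytic_sample_size(DesignSpec(t=1, rho=0.4, alpha=1e-8,
                                        power=0.8, q=0.005))

print(f"three-visit design (rho=0.4): n = {res.n}  (exact {res.n_exact:.1f})")
print(f"cross-sectional design:       n = {cross.n}")
print(f"genotyping saved: {saved} subjects; extra phenotype "
      f"measurements: {extra}")
print(f"power check at the rounded n: {power_at_n(design, res.n):.4f}")
print()
print("Reading: a SNP explaining 0.5% of variance reaches genome-wide")
print("significance (alpha=1e-8) with 80% power using ~5.2k subjects if")
print("each is measured three times, versus ~8.6k measured once; the")
print("benefit shrinks as the between-visit correlation rho grows:")
for rho in (0.0, 0.4, 0.8, 1.0):
    n = analytic_sample_size(DesignSpec(t=3, rho=rho, alpha=1e-8,
                                        power=0.8, q=0.005)).n
    print(f"  rho={rho:.1f}: n={n}")
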