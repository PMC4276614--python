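"""GLS/OLS association engine, interactions, covariates, scans."""

import numpy as np
import pandas as pd
import pytest

from repgwas import (
    SimulationSpec,
    build_covariates,
    fit_gls_longitudinal,
    fit_interaction,
    fit_ols_cross_sectional,
    gwas_scan,
    records_to_frame,
    simulate_cohort,
)

from conftest import dataset_from_arrays


def dense_gls_oracle(Y, X_design, sigma):
    """Closed-form GLS on the fully stacked system, hand-rolled.

    Builds the block-diagonal covariance explicitly and solves
    (D' V^-1 D)^-1 D' V^-1 y.  Independent of the package's whitening
    path; usable only at toy scale.
    """
    n, t = Y.shape
    V = np.kron(np.eye(n), sigma)
    D = np.vstack(X_design)
    y = Y.ravel()
    Vinv = np.linalg.inv(V)
    cov = np.linalg.inv(D.T @ Vinv @ D)
    beta = cov @ D.T @ Vinv @ y
    return beta, cov


class TestGlsAgainstDenseOracle:
    def test_known_sigma_toy_system(self):
        """3 subjects x 2 visits with a supplied covariance: the whitened
        solver must match the explicit dense GLS solution."""
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(3, 2))
        x = np.array([0.0, 1.0, 2.0])
        sigma = np.array([[1.0, 0.6], [0.6, 2.0]])
        data = dataset_from_arrays(Y, time_offsets=np.array([0.0, 2.0]))
        fit = fit_gls_longitudinal(data, snp=x, include_time=False, sigma=sigma)

        blocks = [np.column_stack([np.ones(2), np.full(2, xi)]) for xi in x]
        beta, cov = dense_gls_oracle(Y, blocks, sigma)
        assert fit.params.to_numpy() == pytest.approx(beta, abs=1e-10)
        assert fit.se.to_numpy() == pytest.approx(np.sqrt(np.diag(cov)), abs=1e-10)

    def test_identity_sigma_reduces_to_stacked_ols(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(40, 3))
        x = rng.binomial(2, 0.3, size=40).astype(float)
        data = dataset_from_arrays(Y)
        gls = fit_gls_longitudinal(data, snp=x, include_time=True,
                                   sigma=np.eye(3))
        D = np.column_stack([
            np.ones(120),
            np.repeat(x, 3),
            np.tile([0.0, 2.0, 4.0], 40),
        ])
        ols, *_ = np.linalg.lstsq(D, Y.ravel(), rcond=None)
        assert np.abs(gls.params.to_numpy() - ols).max() < 1e-10


class TestCrossSectionalConsistency:
    def test_single_visit_longitudinal_equals_ols(self):
        spec = SimulationSpec(n=300, t=1, maf=0.3, beta=0.2,
                              sigma_c2=0.0, sigma_e2=1.0, seed=2)
        d = simulate_cohort(spec)
        f_long = fit_gls_longitudinal(d)
        f_ols = fit_ols_cross_sectional(d)
        pd.testing.assert_series_equal(f_long.params, f_ols.params)
        pd.testing.assert_series_equal(f_long.p, f_ols.p)

    def test_noise_free_recovery_is_exact(self):
        spec = SimulationSpec(n=60, t=1, maf=0.4, beta=0.7, intercept=1.5,
                              sigma_c2=0.0, sigma_e2=0.0, seed=3)
        d = simulate_cohort(spec)
        # degenerate zero-variance response needs no covariance iteration
        fit = fit_gls_longitudinal(d, sigma=np.eye(1))
        assert fit.params["snp"] == pytest.approx(0.7, abs=1e-10)
        assert fit.params["intercept"] == pytest.approx(1.5, abs=1e-10)

    def test_null_type_one_error_across_snps(self):
        """beta=0 scan: the fraction of p<0.05 is nominal."""
        rng = np.random.default_rng(4)
        n, m = 800, 4000
        y = rng.normal(size=(n, 1))
        data = dataset_from_arrays(y, time_offsets=np.array([0.0]))
        G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        info = pd.DataFrame({"snp": [f"rs{j}" for j in range(m)],
                             "chrom": "1", "pos": np.arange(m)})
        recs = records_to_frame(
            gwas_scan(data, G, info, model="cross-sectional")
        )
        frac = (recs["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.011)  # ~3 binomial s.e.


class TestParameterRecovery:
    def test_beta_confidence_interval_coverage(self):
        """95% CIs for the SNP effect cover the truth in >= 93% of
        simulated cohorts."""
        beta_true, reps = 0.1, 200
        covered = 0
        for s in range(reps):
            spec = SimulationSpec(n=2000, t=3, maf=0.3, beta=beta_true,
                                  sigma_c2=0.4, sigma_e2=0.6, seed=1000 + s)
            fit = fit_gls_longitudinal(simulate_cohort(spec))
            lo = fit.params["snp"] - 1.96 * fit.se["snp"]
            hi = fit.params["snp"] + 1.96 * fit.se["snp"]
            covered += lo <= beta_true <= hi
        assert covered / reps >= 0.93

    def test_sigma_converges_to_compound_symmetric_truth(self):
        spec = SimulationSpec(n=20000, t=3, maf=0.3, beta=0.1,
                              sigma_c2=0.4, sigma_e2=0.6, seed=5)
        fit = fit_gls_longitudinal(simulate_cohort(spec))
        truth = 0.4 * np.ones((3, 3)) + 0.6 * np.eye(3)
        # element-wise MC s.e. of a covariance moment at n=20000 is ~0.01
        assert np.abs(fit.sigma - truth).max() < 0.03
        assert fit.converged

    def test_longitudinal_beats_cross_sectional_on_average(self):
        """With rho < 1 and a real effect, repeated measures yield smaller
        p-values on average (mean log-p over many simulated SNPs)."""
        logp_long, logp_cross = [], []
        for s in range(200):
            spec = SimulationSpec(n=300, t=3, maf=0.3, beta=0.15,
                                  sigma_c2=0.4, sigma_e2=0.6, seed=2000 + s)
            d = simulate_cohort(spec)
            logp_long.append(np.log(fit_gls_longitudinal(d).p["snp"]))
            logp_cross.append(np.log(fit_ols_cross_sectional(d).p["snp"]))
        assert np.mean(logp_long) < np.mean(logp_cross)

    def test_wald_z_invariant_to_covariate_rescaling(self):
        spec = SimulationSpec(n=500, t=3, maf=0.3, beta=0.2,
                              sigma_c2=0.4, sigma_e2=0.6, seed=6)
        d = simulate_cohort(spec)
        rng = np.random.default_rng(7)
        cov = pd.DataFrame({"age": rng.uniform(40, 70, 500)})
        f1 = fit_gls_longitudinal(d, covariates=cov)
        f2 = fit_gls_longitudinal(
            d, covariates=pd.DataFrame({"age": 100.0 * cov["age"] - 3000.0})
        )
        assert f1.z["snp"] == pytest.approx(f2.z["snp"], abs=1e-8)


class TestMissingVisits:
    def test_fit_handles_monotone_dropout(self):
        from repgwas import KARE_RETENTION

        spec = SimulationSpec(n=3000, t=3, maf=0.3, beta=0.15, sigma_c2=0.4,
                              sigma_e2=0.6, dropout=KARE_RETENTION, seed=8)
        d = simulate_cohort(spec)
        fit = fit_gls_longitudinal(d)
        assert fit.converged
        assert fit.n_observations < 3 * 3000
        assert fit.params["snp"] == pytest.approx(0.15, abs=3 * fit.se["snp"])

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(9)
        d = dataset_from_arrays(rng.normal(size=(50, 2)))
        x = rng.binomial(2, 0.3, 50).astype(float)
        cov = pd.DataFrame({"dup": x})  # identical to the SNP column
        with pytest.raises(ValueError, match="rank deficient"):
            fit_gls_longitudinal(d, snp=x, covariates=cov, include_time=False)


class TestInteractions:
    @staticmethod
    def _cohort_with_sex(n, beta_int, seed, beta_main=0.1, t=3):
        rng = np.random.default_rng(seed)
        spec = SimulationSpec(n=n, t=t, maf=0.3, beta=beta_main,
                              sigma_c2=0.4, sigma_e2=0.6, seed=seed)
        d = simulate_cohort(spec)
        sex = rng.integers(0, 2, n).astype(float)
        Y = d.Y + (beta_int * sex * d.genotype)[:, None]
        d2 = dataset_from_arrays(Y, mask=d.mask, genotype=d.genotype)
        return d2, pd.DataFrame({"sex": sex})

    def test_sex_by_snp_effect_recovery(self):
        d, cov = self._cohort_with_sex(5000, beta_int=0.08, seed=10)
        fit = fit_interaction(d, environment="sex", covariates=cov)
        assert fit.model == "interaction:sex"
        est, se = fit.params["sex:snp"], fit.se["sex:snp"]
        assert est == pytest.approx(0.08, abs=2 * se)
        # main effects stay in the model
        assert "snp" in fit.params.index and "sex" in fit.params.index

    def test_interaction_null_calibration(self):
        rejections = 0
        reps = 400
        for s in range(reps):
            d, cov = self._cohort_with_sex(150, beta_int=0.0, seed=3000 + s,
                                           t=2)
            fit = fit_interaction(d, environment="sex", covariates=cov)
            rejections += fit.p["sex:snp"] < 0.05
        # normal-reference p at n=150 runs very slightly anticonservative
        assert rejections / reps == pytest.approx(0.05, abs=0.035)

    def test_time_by_snp_uses_visit_offsets(self):
        spec = SimulationSpec(n=2000, t=3, maf=0.3, beta=0.1, sigma_c2=0.4,
                              sigma_e2=0.6, seed=11)
        d = simulate_cohort(spec)
        slope = 0.05
        Y = d.Y + d.genotype[:, None] * slope * d.time_offsets[None, :]
        d2 = dataset_from_arrays(Y, genotype=d.genotype)
        fit = fit_interaction(d2, environment="time")
        est, se = fit.params["time:snp"], fit.se["time:snp"]
        assert est == pytest.approx(slope, abs=2 * se)
        assert fit.p["time:snp"] < 1e-4

    def test_constant_environment_is_inestimable(self):
        d, cov = self._cohort_with_sex(100, beta_int=0.0, seed=12)
        cov["sex"] = 1.0  # all-male cohort
        with pytest.raises(ValueError, match="constant"):
            fit_interaction(d, environment="sex", covariates=cov)


class TestBuildCovariates:
    @staticmethod
    def _raw(n=10, with_weight=True, seed=0):
        rng = np.random.default_rng(seed)
        d = {"sex": rng.integers(0, 2, n), "age": rng.uniform(40, 70, n)}
        if with_weight:
            d["weight"] = rng.uniform(50, 90, n)
        return pd.DataFrame(d)

    def test_standard_phenotype_gets_four_columns(self):
        cov = build_covariates(self._raw(), "HDL")
        assert list(cov.columns) == ["intercept", "sex", "age", "age2"]
        assert np.allclose(cov["age2"], cov["age"] ** 2)

    @pytest.mark.parametrize("pheno", ["GLU0", "GLU120"])
    def test_glucose_phenotypes_add_weight(self, pheno):
        cov = build_covariates(self._raw(), pheno)
        assert list(cov.columns) == ["intercept", "sex", "age", "age2", "weight"]

    def test_missing_weight_for_glucose_raises(self):
        with pytest.raises(ValueError, match="weight"):
            build_covariates(self._raw(with_weight=False), "GLU0")

    def test_constant_age_raises(self):
        raw = self._raw()
        raw["age"] = 50.0
        with pytest.raises(ValueError, match="age"):
            build_covariates(raw, "HDL")

    def test_missing_values_name_subjects(self):
        raw = self._raw()
        raw.loc[3, "sex"] = np.nan
        with pytest.raises(ValueError, match="sex"):
            build_covariates(raw, "HDL")


class TestGwasScan:
    def test_planted_snp_attains_smallest_p(self):
        rng = np.random.default_rng(13)
        n, m = 3000, 30
        spec = SimulationSpec(n=n, t=3, maf=0.3,
                              beta=np.sqrt(0.01 / 0.99 / (2 * 0.3 * 0.7)),
                              sigma_c2=0.4, sigma_e2=0.6, seed=14)
        d = simulate_cohort(spec)
        G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        G[:, 7] = d.genotype  # the causal SNP
        info = pd.DataFrame({"snp": [f"rs{j}" for j in range(m)],
                             "chrom": "1", "pos": np.arange(m)})
        recs = records_to_frame(gwas_scan(d, G, info, model="longitudinal"))
        assert recs.loc[recs["p"].idxmin(), "snp"] == "rs7"

    def test_failures_become_na_records_not_aborts(self):
        rng = np.random.default_rng(15)
        d = dataset_from_arrays(rng.normal(size=(50, 1)),
                                time_offsets=np.array([0.0]))
        G = rng.binomial(2, 0.3, size=(50, 3)).astype(float)
        G[:, 1] = 0.0  # monomorphic
        info = pd.DataFrame({"snp": ["a", "b", "c"], "chrom": "1",
                             "pos": [1, 2, 3]})
        recs = records_to_frame(gwas_scan(d, G, info, model="cross-sectional"))
        assert len(recs) == 3
        assert recs.set_index("snp").loc["b", "note"] == "monomorphic"
        assert np.isnan(recs.set_index("snp").loc["b", "p"])

    def test_empty_genotype_set_yields_empty_output(self):
        rng = np.random.default_rng(16)
        d = dataset_from_arrays(rng.normal(size=(20, 1)),
                                time_offsets=np.array([0.0]))
        recs = list(gwas_scan(
            d, np.empty((20, 0)),
            pd.DataFrame(columns=["snp", "chrom", "pos"]),
            model="cross-sectional",
        ))
        assert recs == []

    def test_records_ordered_by_position(self):
        rng = np.random.default_rng(17)
        d = dataset_from_arrays(rng.normal(size=(80, 1)),
                                time_offsets=np.array([0.0]))
        G = rng.binomial(2, 0.3, size=(80, 3)).astype(float)
        info = pd.DataFrame({"snp": ["x", "y", "z"], "chrom": ["2", "1", "1"],
                             "pos": [5, 9, 3]})
        recs = records_to_frame(gwas_scan(d, G, info, model="cross-sectional"))
        assert recs["snp"].tolist() == ["z", "y", "x"]
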