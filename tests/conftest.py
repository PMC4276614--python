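import numpy as np
import pandas as pd
import pytest

from repgwas import GenotypeData, LongitudinalDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20140)


@pytest.fixture
def small_cohort():
    """Complete 3-visit cohort with a planted SNP effect, for fit smoke tests."""
    from repgwas import SimulationSpec, simulate_cohort

    spec = SimulationSpec(
        n=400, t=3, maf=0.3, beta=0.25, sigma_c2=0.4, sigma_e2=0.6, seed=42
    )
    return simulate_cohort(spec)


def two_population_genotypes(
    n_per_pop: int = 60,
    n_snps: int = 300,
    fst_shift: float = 0.25,
    seed: int = 0,
):
    """Two subpopulations with systematically divergent allele frequencies.

    Returns (dosages, labels): labels are 0/1 population membership.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.1, 0.5, size=n_snps)
    p1 = np.clip(base - fst_shift / 2, 0.02, 0.98)
    p2 = np.clip(base + fst_shift / 2, 0.02, 0.98)
    g1 = rng.binomial(2, p1, size=(n_per_pop, n_snps))
    g2 = rng.binomial(2, p2, size=(n_per_pop, n_snps))
    X = np.vstack([g1, g2]).astype(float)
    labels = np.repeat([0, 1], n_per_pop)
    return X, labels


def genotype_data_from_matrix(X: np.ndarray) -> GenotypeData:
    n, m = X.shape
    return GenotypeData(
        dosages=X,
        sample_ids=[f"S{i:04d}" for i in range(n)],
        snp_info=pd.DataFrame({
            "snp": [f"rs{j}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1),
            "ref": "A", "alt": "G", "minor_allele": "G", "flipped": False,
        }),
    )


def dataset_from_arrays(Y, mask=None, time_offsets=None, **kw) -> LongitudinalDataset:
    Y = np.asarray(Y, dtype=float)
    n, t = Y.shape
    if mask is None:
        mask = ~np.isnan(Y)
    if time_offsets is None:
        time_offsets = 2.0 * np.arange(t)
    return LongitudinalDataset(
        ids=np.array([f"S{i}" for i in range(n)]),
        Y=Y, mask=mask, time_offsets=time_offsets, **kw,
    )
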