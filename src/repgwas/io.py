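"""Readers/writers for genotype and phenotype tables, and sample/SNP QC.

Genotypes travel as VCF (diploid GT, via cyvcf2) or as an additive-dosage
TSV (header ``id`` plus one column per SNP, values 0/1/2/NA); either way
the in-memory representation is a sample-major float matrix of
minor-allele dosages with NaN for missing calls.  Phenotypes travel as a
long-format TSV with one row per (subject, visit).

QC mirrors standard cohort-GWAS practice: call-rate filters on samples
then SNPs, a Hardy-Weinberg equilibrium filter, a minor-allele-frequency
floor, a per-sample heterozygosity cap, and removal of one member of any
sample pair whose identity-by-state similarity indicates duplication or
close relatedness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .dataset import LongitudinalDataset
from .structure import ibs_matrix

__all__ = [
    "QcThresholds",
    "QcReport",
    "GenotypeData",
    "read_genotypes",
    "write_dosage_tsv",
    "read_phenotypes",
    "write_phenotypes",
    "hwe_test",
    "qc_filter",
]


@dataclass(frozen=True)
class QcThresholds:
    """Filter thresholds; each is a fraction in [0, 1]."""

    snp_call_rate: float = 0.95
    sample_call_rate: float = 0.95
    hwe_p: float = 1e-6
    maf: float = 0.01
    heterozygosity_max: float = 0.30
    ibs_max: float = 0.80

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QcReport:
    """Counts removed at each QC step, in application order."""

    samples_call_rate: int = 0
    snps_call_rate: int = 0
    snps_hwe: int = 0
    snps_maf: int = 0
    samples_heterozygosity: int = 0
    samples_ibs: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass
class GenotypeData:
    """Dosage matrix (samples x SNPs, NaN missing) with SNP metadata."""

    dosages: np.ndarray
    sample_ids: list[str]
    snp_info: pd.DataFrame  # columns: snp, chrom, pos, ref, alt, minor_allele, flipped
    n_multiallelic_skipped: int = 0


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeData:
    """Read genotypes from VCF or dosage TSV into a minor-allele dosage matrix.

    VCF sites where the ALT allele frequency exceeds 0.5 are flipped
    (dosage -> 2 - dosage) so the coding always counts the minor allele;
    the flip is recorded per SNP.  Multi-allelic sites are skipped with a
    count.  ``format`` is inferred from the suffix when omitted.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "dosage_tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeData:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    rows: list[dict] = []
    skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            skipped += 1
            continue
        # gts012=True: 0/1/2 = ALT dosage, 3 = missing
        d = variant.gt_types.astype(float)
        d[d == 3] = np.nan
        observed = ~np.isnan(d)
        alt_freq = d[observed].mean() / 2.0 if observed.any() else 0.0
        flipped = alt_freq > 0.5
        if flipped:
            d = 2.0 - d
            minor = variant.REF
        else:
            minor = variant.ALT[0]
        cols.append(d)
        rows.append({
            "snp": variant.ID or f"{variant.CHROM}:{variant.POS}",
            "chrom": variant.CHROM, "pos": variant.POS,
            "ref": variant.REF, "alt": variant.ALT[0],
            "minor_allele": minor, "flipped": flipped,
        })
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeData(
        dosages=dosages, sample_ids=samples,
        snp_info=pd.DataFrame(rows, columns=[
            "snp", "chrom", "pos", "ref", "alt", "minor_allele", "flipped"
        ]),
        n_multiallelic_skipped=skipped,
    )


def _read_dosage_tsv(path: Path) -> GenotypeData:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"{path}: dosage TSV must have an 'id' column")
    snps = [c for c in df.columns if c != "id"]
    dosages = df[snps].to_numpy(dtype=float)
    info = pd.DataFrame({
        "snp": snps, "chrom": "", "pos": range(1, len(snps) + 1),
        "ref": "", "alt": "", "minor_allele": "", "flipped": False,
    })
    return GenotypeData(
        dosages=dosages, sample_ids=df["id"].tolist(), snp_info=info
    )


def write_dosage_tsv(data: GenotypeData, path: str | Path) -> None:
    df = pd.DataFrame(
        data.dosages, columns=data.snp_info["snp"].tolist()
    )
    df.insert(0, "id", data.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


_PHENO_CORE = ["id", "visit", "time_offset", "value"]


def read_phenotypes(path: str | Path) -> LongitudinalDataset:
    """Read a long-format phenotype table into a LongitudinalDataset.

    Required columns: id, visit (1-based), time_offset, value; any
    further columns are treated as baseline covariates (taken from the
    visit-1 row).  Duplicate (id, visit) rows and non-monotone visit
    times are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = [c for c in _PHENO_CORE if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    dup = df.duplicated(subset=["id", "visit"])
    if dup.any():
        pairs = df.loc[dup, ["id", "visit"]].head().to_records(index=False)
        raise ValueError(f"duplicate (id, visit) rows, e.g. {list(pairs)}")

    visits = np.sort(df["visit"].unique())
    offsets = (
        df.groupby("visit")["time_offset"].first().reindex(visits).to_numpy(float)
    )
    per_visit = df.groupby("visit")["time_offset"].nunique()
    if (per_visit > 1).any():
        raise ValueError("time_offset must be identical within a visit index")
    if not np.all(np.diff(offsets) > 0):
        raise ValueError(f"visit times must be strictly increasing, got {offsets}")

    ids = df.loc[df["visit"] == visits[0], "id"].to_numpy()
    t = len(visits)
    n = len(ids)
    pos = {s: i for i, s in enumerate(ids)}
    vpos = {v: j for j, v in enumerate(visits)}
    unknown = set(df["id"]) - set(ids)
    if unknown:
        raise ValueError(
            f"{len(unknown)} subject(s) lack the baseline visit, "
            f"e.g. {sorted(unknown)[:5]}"
        )
    Y = np.full((n, t), np.nan)
    mask = np.zeros((n, t), dtype=bool)
    for sid, v, val in zip(df["id"], df["visit"], df["value"]):
        Y[pos[sid], vpos[v]] = val
        mask[pos[sid], vpos[v]] = True

    extra = [c for c in df.columns if c not in _PHENO_CORE]
    covariates = None
    if extra:
        base = df[df["visit"] == visits[0]].set_index("id").loc[ids, extra]
        covariates = base.reset_index(drop=True)
    return LongitudinalDataset(
        ids=ids, Y=Y, mask=mask, time_offsets=offsets, covariates=covariates
    )


def write_phenotypes(data: LongitudinalDataset, path: str | Path) -> None:
    data.to_long_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def hwe_test(counts: tuple[int, int, int], exact: bool = False) -> float:
    """Hardy-Weinberg equilibrium p-value from genotype counts (AA, Aa, aa).

    Default is the 1-df chi-square goodness-of-fit test against the HWE
    expectation; ``exact=True`` uses the conditional exact heterozygote
    test.  Monomorphic sites return p = 1.
    """
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    if min(n_aa, n_ab, n_bb) < 0 or n_aa + n_ab + n_bb == 0:
        raise ValueError("genotype counts must be non-negative with total > 0")
    n = n_aa + n_ab + n_bb
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    if not exact:
        expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
        observed = np.array([n_aa, n_ab, n_bb])
        stat = float(((observed - expected) ** 2 / expected).sum())
        return float(chi2.sf(stat, df=1))
    return _hwe_exact(n_aa, n_ab, n_bb)


def _hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE test: sum of heterozygote-count probabilities <= observed's.

    Enumerates the conditional distribution of the heterozygote count
    given the allele counts.
    """
    n = n_aa + n_ab + n_bb
    rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    parity = rare % 2
    hets = range(parity, rare + 1, 2)
    logprob = {}
    for h in hets:
        a = (rare - h) // 2            # rare homozygotes
        b = n - a - h                  # common homozygotes
        lp = (
            math.lgamma(n + 1)
            - math.lgamma(a + 1) - math.lgamma(h + 1) - math.lgamma(b + 1)
            + h * math.log(2)
            + math.lgamma(rare + 1) + math.lgamma(2 * n - rare + 1)
            - math.lgamma(2 * n + 1)
        )
        logprob[h] = lp
    mx = max(logprob.values())
    probs = {h: math.exp(lp - mx) for h, lp in logprob.items()}
    total = sum(probs.values())
    obs = probs[n_ab]
    pval = sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total
    return min(pval, 1.0)


def qc_filter(
    geno: GenotypeData,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[GenotypeData, QcReport]:
    """Apply sample- and SNP-level QC in a fixed, documented order.

    Order within a sweep: sample call rate, SNP call rate, HWE, MAF,
    per-sample heterozygosity, pairwise IBS (the member of a flagged pair
    with the lower call rate is removed; ties fall to the later sample in
    file order).  Because sample removals change the per-SNP statistics
    and vice versa, sweeps repeat until none removes anything, which
    makes the filter idempotent; the report accumulates counts across
    sweeps.  Raises if no sample survives.
    """
    current = geno
    total = QcReport()
    while True:
        current, report = _qc_sweep(current, thresholds)
        for key, v in report.as_dict().items():
            setattr(total, key, getattr(total, key) + v)
        if sum(report.as_dict().values()) == 0:
            return current, total


def _qc_sweep(
    geno: GenotypeData, thresholds: QcThresholds
) -> tuple[GenotypeData, QcReport]:
    X = geno.dosages.copy()
    sample_ids = list(geno.sample_ids)
    info = geno.snp_info.copy()
    report = QcReport()

    def observed() -> np.ndarray:
        return ~np.isnan(X)

    # sample call rate
    keep = observed().mean(axis=1) >= thresholds.sample_call_rate if X.shape[1] else np.ones(len(sample_ids), bool)
    report.samples_call_rate = int((~keep).sum())
    X, sample_ids = X[keep], [s for s, k in zip(sample_ids, keep) if k]

    # SNP call rate
    keep = observed().mean(axis=0) >= thresholds.snp_call_rate
    report.snps_call_rate = int((~keep).sum())
    X, info = X[:, keep], info[keep].reset_index(drop=True)

    # HWE
    if X.shape[1]:
        pvals = np.array([
            hwe_test((
                int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum())
            ))
            for col in X.T
        ])
        keep = pvals >= thresholds.hwe_p
        report.snps_hwe = int((~keep).sum())
        X, info = X[:, keep], info[keep].reset_index(drop=True)

    # MAF
    if X.shape[1]:
        freq = np.nanmean(X, axis=0) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        keep = maf >= thresholds.maf
        report.snps_maf = int((~keep).sum())
        X, info = X[:, keep], info[keep].reset_index(drop=True)

    # heterozygosity (fraction of non-missing calls that are het)
    if X.shape[1]:
        het = (X == 1).sum(axis=1) / np.maximum(observed().sum(axis=1), 1)
        keep = het <= thresholds.heterozygosity_max
        report.samples_heterozygosity = int((~keep).sum())
        X, sample_ids = X[keep], [s for s, k in zip(sample_ids, keep) if k]

    # pairwise IBS
    if X.shape[1] and len(sample_ids) > 1 and thresholds.ibs_max < 1.0:
        sim = ibs_matrix(X)
        call = observed().mean(axis=1)
        drop: set[int] = set()
        n = len(sample_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if i in drop or j in drop:
                    continue
                if np.isfinite(sim[i, j]) and sim[i, j] > thresholds.ibs_max:
                    # remove the lower-call-rate member; tie -> later in file
                    drop.add(j if call[j] <= call[i] else i)
        report.samples_ibs = len(drop)
        keep = np.array([i not in drop for i in range(n)])
        X, sample_ids = X[keep], [s for s, k in zip(sample_ids, keep) if k]

    if not sample_ids:
        raise ValueError("QC removed every sample")
    return (
        GenotypeData(
            dosages=X, sample_ids=sample_ids, snp_info=info,
            n_multiallelic_skipped=geno.n_multiallelic_skipped,
        ),
        report,
    )
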