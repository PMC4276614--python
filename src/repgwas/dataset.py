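"""In-memory container for longitudinal phenotype data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LongitudinalDataset"]


@dataclass
class LongitudinalDataset:
    """Per-subject phenotype vectors over visits, with covariates.

    Attributes
    ----------
    ids : ndarray of str, shape (n,)
        Subject identifiers.
    Y : ndarray, shape (n, t)
        Phenotype matrix; NaN at unobserved visits.
    mask : ndarray of bool, shape (n, t)
        Visit availability.  Every subject must be observed at the
        baseline visit; datasets generated with dropout have monotone
        masks (observed visits form a prefix).
    time_offsets : ndarray, shape (t,)
        Visit times relative to baseline (years).
    genotype : ndarray or None, shape (n,)
        Additive minor-allele dosage for a single SNP, when attached.
    covariates : DataFrame or None
        Baseline covariates, one row per subject, aligned with ``ids``.
    """

    ids: np.ndarray
    Y: np.ndarray
    mask: np.ndarray
    time_offsets: np.ndarray
    genotype: np.ndarray | None = None
    covariates: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.Y = np.asarray(self.Y, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.time_offsets = np.asarray(self.time_offsets, dtype=float)
        n, t = self.Y.shape
        if self.mask.shape != (n, t):
            raise ValueError("mask shape must match Y")
        if self.time_offsets.shape != (t,):
            raise ValueError("time_offsets length must equal the visit count")
        if not self.mask[:, 0].all():
            bad = self.ids[~self.mask[:, 0]]
            raise ValueError(
                f"{len(bad)} subject(s) missing the baseline visit: "
                f"{list(bad[:5])}{'...' if len(bad) > 5 else ''}"
            )
        if self.genotype is not None:
            self.genotype = np.asarray(self.genotype, dtype=float)
            if self.genotype.shape != (n,):
                raise ValueError("genotype must have one dosage per subject")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValueError("covariates must have one row per subject")

    @property
    def n_subjects(self) -> int:
        return self.Y.shape[0]

    @property
    def n_visits(self) -> int:
        return self.Y.shape[1]

    @property
    def n_observations(self) -> int:
        return int(self.mask.sum())

    def with_genotype(self, dosage: np.ndarray) -> "LongitudinalDataset":
        """Copy of the dataset with a SNP dosage vector attached."""
        return LongitudinalDataset(
            ids=self.ids, Y=self.Y, mask=self.mask,
            time_offsets=self.time_offsets,
            genotype=np.asarray(dosage, dtype=float),
            covariates=self.covariates,
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: one row per observed (subject, visit)."""
        n, t = self.Y.shape
        rows = []
        for j in range(t):
            obs = self.mask[:, j]
            df = pd.DataFrame({
                "id": self.ids[obs],
                "visit": j + 1,
                "time_offset": self.time_offsets[j],
                "value": self.Y[obs, j],
            })
            rows.append(df)
        out = pd.concat(rows, ignore_index=True)
        if self.covariates is not None:
            cov = self.covariates.copy()
            cov.insert(0, "id", self.ids)
            out = out.merge(cov, on="id", how="left")
        return out.sort_values(["id", "visit"], kind="stable").reset_index(drop=True)
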