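"""Core in-memory container for case-control genotype data.

Genotypes are stored as minor-allele counts (0, 1, 2) in an int8 matrix of
shape (n_samples, n_snps); missing genotypes are coded as :data:`MISSING`
(-1).  The two alleles of a genotype are jointly observed or jointly
missing, so a single per-genotype missing code suffices.  Phenotypes are
binary: 0 = control, 1 = case.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

#: Sentinel for an unobserved genotype.
MISSING: int = -1

_VALID_GENOTYPES = frozenset({-1, 0, 1, 2})

SNP_META_COLUMNS = ("snp", "chrom", "bp", "a1", "a2")


@dataclass
class TruthEffects:
    """Ground-truth additive log-odds model used to simulate phenotypes.

    ``beta`` holds one log-odds-ratio per SNP (zero for non-causal SNPs);
    ``beta0`` is the intercept calibrated to the requested prevalence.
    """

    beta: np.ndarray
    beta0: float

    @property
    def causal_indices(self) -> np.ndarray:
        return np.flatnonzero(self.beta != 0.0)


@dataclass
class GenotypeDataset:
    """Sample x SNP genotype matrix with phenotype and SNP metadata.

    Parameters
    ----------
    genotypes
        int8 matrix of minor-allele counts; ``MISSING`` marks unobserved
        genotypes.
    phenotype
        int8 vector, 0 = control and 1 = case, one entry per sample.
    snp_meta
        DataFrame with columns ``snp`` (identifier), ``chrom``, ``bp``
        (1-based position), ``a1`` (minor allele), ``a2`` (major allele).
    truth
        Optional simulated effect sizes (present for synthetic data only).
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_meta: pd.DataFrame
    truth: Optional[TruthEffects] = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        n, m = self.genotypes.shape
        if self.phenotype.shape != (n,):
            raise ValueError(
                f"phenotype length {self.phenotype.shape} does not match "
                f"{n} samples"
            )
        if len(self.snp_meta) != m:
            raise ValueError(
                f"snp_meta has {len(self.snp_meta)} rows for {m} SNPs"
            )
        missing_cols = set(SNP_META_COLUMNS) - set(self.snp_meta.columns)
        if missing_cols:
            raise ValueError(f"snp_meta lacks columns {sorted(missing_cols)}")
        bad = set(np.unique(self.genotypes)) - _VALID_GENOTYPES
        if bad:
            raise ValueError(f"invalid genotype codes {sorted(bad)}")
        if not set(np.unique(self.phenotype)) <= {0, 1}:
            raise ValueError("phenotype must be binary 0/1")
        # positions must strictly increase within a chromosome
        for _, grp in self.snp_meta.groupby("chrom", sort=False):
            bp = grp["bp"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise ValueError("bp positions not strictly increasing "
                                 "within a chromosome")
        if self.truth is not None and self.truth.beta.shape != (m,):
            raise ValueError("truth beta length does not match SNP count")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == 0).sum())

    @property
    def case_control_ratio(self) -> float:
        return self.n_cases / self.n_controls

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    # -- subsetting ------------------------------------------------------
    def take_samples(self, idx: np.ndarray) -> "GenotypeDataset":
        idx = np.asarray(idx)
        return replace(
            self,
            genotypes=self.genotypes[idx],
            phenotype=self.phenotype[idx],
        )

    def take_snps(self, idx: np.ndarray) -> "GenotypeDataset":
        idx = np.asarray(idx)
        truth = self.truth
        if truth is not None:
            truth = TruthEffects(beta=truth.beta[idx], beta0=truth.beta0)
        return GenotypeDataset(
            genotypes=self.genotypes[:, idx],
            phenotype=self.phenotype,
            snp_meta=self.snp_meta.iloc[idx].reset_index(drop=True),
            truth=truth,
        )

    def copy(self) -> "GenotypeDataset":
        truth = self.truth
        if truth is not None:
            truth = TruthEffects(beta=truth.beta.copy(), beta0=truth.beta0)
        return GenotypeDataset(
            genotypes=self.genotypes.copy(),
            phenotype=self.phenotype.copy(),
            snp_meta=self.snp_meta.copy(),
            truth=truth,
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.phenotype, other.phenotype)
            and self.snp_meta.reset_index(drop=True).equals(
                other.snp_meta.reset_index(drop=True)
            )
        )
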