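"""Quality control, missing-genotype imputation and genotype coding.

QC applies three filters in a fixed order: (1) drop samples whose missing
rate exceeds ``sample_miss_max``; (2) drop SNPs whose missing rate among
surviving samples exceeds ``snp_miss_max``; (3) drop SNPs whose
Hardy-Weinberg equilibrium p-value, computed in surviving controls only,
falls below ``hwe_p_min``.  The order matters for the rates and is logged.

Imputation strategies
---------------------
``Unkw``  leave missing genotypes in place (treated downstream as their own
          class).
``Maj``   replace each missing genotype with two copies of the most common
          allele (0 minor alleles whenever the major allele is truly major).
``HWc``   draw Binomial(2, q) with q the minor-allele frequency of the
          observed *controls* at that SNP.
``HWa``   as HWc but q estimated from all observed samples.

Codings
-------
``sum``   one additive column per SNP with values {0, 1, 2};
``OHE``   three indicator columns per SNP (AA, Aa, aa);
``raw``   two per-allele binary columns per SNP (genotype g maps to alleles
          ceil(g/2) and floor(g/2));
``OHE4``  four indicator columns per SNP (0-0, 0-1, 1-1, U-U) for
          non-imputed data where U marks an unknown genotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import stats

from .dataset import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

IMPUTATION_STRATEGIES = ("Unkw", "Maj", "HWc", "HWa")
CODING_SCHEMES = ("sum", "OHE", "raw", "OHE4")


@dataclass
class QCThresholds:
    sample_miss_max: float = 0.05
    snp_miss_max: float = 0.02
    hwe_p_min: float = 1e-10

    def __post_init__(self) -> None:
        for v in (self.sample_miss_max, self.snp_miss_max, self.hwe_p_min):
            if not (0.0 <= v <= 1.0):
                raise ValueError("QC thresholds must lie in [0, 1]")


@dataclass
class QCReport:
    samples_in: int
    snps_in: int
    samples_removed: int
    snps_removed_missing: int
    snps_removed_hwe: int

    @property
    def samples_out(self) -> int:
        return self.samples_in - self.samples_removed

    @property
    def snps_out(self) -> int:
        return self.snps_in - self.snps_removed_missing - self.snps_removed_hwe

    def to_dict(self) -> dict:
        return {
            "samples_in": self.samples_in,
            "snps_in": self.snps_in,
            "samples_removed": self.samples_removed,
            "snps_removed_missing": self.snps_removed_missing,
            "snps_removed_hwe": self.snps_removed_hwe,
            "samples_out": self.samples_out,
            "snps_out": self.snps_out,
        }


@dataclass
class FeatureMatrix:
    """Encoded numeric matrix with a feature -> SNP map and a coding tag."""

    values: np.ndarray
    feature_map: List[Tuple[int, str]]  # (snp index, sub-feature label)
    coding: str

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.feature_map):
            raise ValueError("feature_map length does not match columns")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def snp_of_feature(self) -> np.ndarray:
        return np.array([s for s, _ in self.feature_map], dtype=np.int64)


# ---------------------------------------------------------------------------
# Hardy-Weinberg test

def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-squared goodness-of-fit p-value against HWE proportions.

    Counts are (major homozygote, heterozygote, minor homozygote).
    Monomorphic SNPs return p = 1.
    """
    counts = np.array([[n_AA, n_Aa, n_aa]], dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    if counts.sum() == 0:
        raise ValueError("all genotype counts are zero")
    return float(hwe_test_vec(counts)[0])


def hwe_test_vec(counts: np.ndarray) -> np.ndarray:
    """Vectorized HWE test on an (m, 3) array of genotype counts."""
    counts = np.asarray(counts, dtype=np.float64)
    n = counts.sum(axis=1)
    n_safe = np.where(n > 0, n, 1.0)
    # frequency of the allele counted by column order (column 2 = minor hom)
    q = (counts[:, 1] + 2.0 * counts[:, 2]) / (2.0 * n_safe)
    p = 1.0 - q
    expected = np.stack([n * p * p, n * 2.0 * p * q, n * q * q], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (counts - expected) ** 2 / expected
    terms[~np.isfinite(terms)] = 0.0
    chi2 = terms.sum(axis=1)
    pval = stats.chi2.sf(chi2, df=1)
    mono = (q == 0.0) | (q == 1.0) | (n == 0)
    pval[mono] = 1.0
    return pval


def _genotype_counts(genotypes: np.ndarray) -> np.ndarray:
    """Per-SNP counts of genotypes (0, 1, 2), ignoring missing entries."""
    return np.stack(
        [(genotypes == g).sum(axis=0) for g in (0, 1, 2)], axis=1
    ).astype(np.float64)


# ---------------------------------------------------------------------------
# QC

def apply_qc(
    ds: GenotypeDataset, th: QCThresholds | None = None
) -> Tuple[GenotypeDataset, QCReport]:
    """Filter samples then SNPs; HWE is evaluated in surviving controls.

    Raises
    ------
    ValueError
        If no sample or no SNP survives.
    """
    th = th or QCThresholds()
    n, m = ds.genotypes.shape

    miss = ds.missing_mask()
    sample_rate = miss.mean(axis=1)
    keep_samples = sample_rate <= th.sample_miss_max
    ds1 = ds.take_samples(np.flatnonzero(keep_samples))
    samples_removed = int((~keep_samples).sum())

    miss1 = ds1.missing_mask()
    snp_rate = miss1.mean(axis=0) if ds1.n_samples else np.ones(m)
    keep_miss = snp_rate <= th.snp_miss_max
    snps_removed_missing = int((~keep_miss).sum())
    ds2 = ds1.take_snps(np.flatnonzero(keep_miss))

    controls = ds2.genotypes[ds2.phenotype == 0]
    pvals = hwe_test_vec(_genotype_counts(controls))
    keep_hwe = pvals >= th.hwe_p_min
    snps_removed_hwe = int((~keep_hwe).sum())
    ds3 = ds2.take_snps(np.flatnonzero(keep_hwe))

    report = QCReport(
        samples_in=n,
        snps_in=m,
        samples_removed=samples_removed,
        snps_removed_missing=snps_removed_missing,
        snps_removed_hwe=snps_removed_hwe,
    )
    logger.info("QC: %s", report.to_dict())
    if ds3.n_samples == 0 or ds3.n_snps == 0:
        raise ValueError("QC removed every sample or every SNP")
    return ds3, report


# ---------------------------------------------------------------------------
# imputation

def impute(
    ds: GenotypeDataset, strategy: str, seed: int = 0
) -> GenotypeDataset:
    """Fill missing genotypes according to ``strategy``.

    HW draws use one random stream per (seed, SNP index), so the result is
    invariant to sample order.  ``Unkw`` returns the dataset unchanged.
    """
    if strategy not in IMPUTATION_STRATEGIES:
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    if strategy == "Unkw":
        return ds.copy()

    geno = ds.genotypes.copy()
    miss = geno == MISSING
    cols = np.flatnonzero(miss.any(axis=0))
    is_control = ds.phenotype == 0

    for j in cols:
        col = geno[:, j]
        obs = col != MISSING
        if strategy == "Maj":
            n_obs = int(obs.sum())
            if n_obs == 0:
                raise ValueError(f"SNP {j} has no observed genotypes")
            q = col[obs].sum() / (2.0 * n_obs)
            fill = 2 if q > 0.5 else 0
            col[~obs] = fill
        else:
            pool = obs & is_control if strategy == "HWc" else obs
            n_pool = int(pool.sum())
            if n_pool == 0:
                raise ValueError(
                    f"SNP {j}: no informative "
                    f"{'controls' if strategy == 'HWc' else 'samples'}"
                )
            q = col[pool].sum() / (2.0 * n_pool)
            rng = np.random.default_rng([seed, int(j)])
            col[~obs] = rng.binomial(2, q, size=int((~obs).sum()))
        geno[:, j] = col

    out = ds.copy()
    out.genotypes = geno
    return out


# ---------------------------------------------------------------------------
# coding

def encode(ds: GenotypeDataset, coding: str) -> FeatureMatrix:
    """Encode genotypes as a numeric feature matrix.

    ``sum``/``OHE``/``raw`` require fully imputed data; ``OHE4`` accepts
    (and encodes) missing genotypes as the fourth U-U class.
    """
    if coding not in CODING_SCHEMES:
        raise ValueError(f"unknown coding {coding!r}")
    g = ds.genotypes
    n, m = g.shape
    has_missing = bool((g == MISSING).any())
    if coding != "OHE4" and has_missing:
        raise ValueError(
            f"coding {coding!r} requires imputed data (missing genotypes "
            "present); use OHE4 or impute first"
        )

    if coding == "sum":
        values = g.astype(np.float32)
        fmap = [(j, "g") for j in range(m)]
    elif coding == "OHE":
        values = np.zeros((n, 3 * m), dtype=np.float32)
        for k, cls in enumerate((0, 1, 2)):
            values[:, k::3] = (g == cls)
        fmap = [(j, lab) for j in range(m) for lab in ("AA", "Aa", "aa")]
    elif coding == "raw":
        values = np.zeros((n, 2 * m), dtype=np.float32)
        values[:, 0::2] = np.ceil(g / 2.0)
        values[:, 1::2] = np.floor(g / 2.0)
        fmap = [(j, lab) for j in range(m) for lab in ("allele1", "allele2")]
    else:  # OHE4
        values = np.zeros((n, 4 * m), dtype=np.float32)
        for k, cls in enumerate((0, 1, 2, MISSING)):
            values[:, k::4] = (g == cls)
        fmap = [
            (j, lab)
            for j in range(m)
            for lab in ("0-0", "0-1", "1-1", "U-U")
        ]
    return FeatureMatrix(values=values, feature_map=fmap, coding=coding)
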