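"""Per-SNP association screening and union-based preselection.

Four chi-squared association tests are computed per SNP from the
case/control genotype table (missing genotypes are dropped per SNP):

* **genotypic** — Pearson chi-squared on the 2 x 3 case/control-by-genotype
  table (2 df; df shrinks when a genotype class is empty);
* **dominant** — 2 x 2 chi-squared of AA versus Aa+aa (1 df);
* **trend** — Cochran-Armitage trend test with weights (0, 1, 2) (1 df),
  the score test of a logistic regression on the additive coding;
* **allelic** — 2 x 2 chi-squared on allele counts (2N observations, 1 df).

Degenerate tables (a zero-variance margin, e.g. a monomorphic SNP or a
single phenotype class) yield p = 1.  No continuity corrections are used.

Preselection keeps SNPs with MAF strictly above ``maf_min`` and, among
those, forms per-test lists at ``p < p_max``; the union of the four lists
is the retained panel (the intersection is reported as well).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import GenotypeDataset

logger = logging.getLogger(__name__)

TESTS = ("genotypic", "dominant", "trend", "allelic")


@dataclass
class PreselectionResult:
    maf_pass: np.ndarray                 # SNP indices with MAF > maf_min
    per_test_pass: Dict[str, np.ndarray]  # test name -> SNP indices
    union: np.ndarray                    # sorted SNP indices
    intersection: np.ndarray
    maf_min: float
    p_max: float

    def to_dict(self) -> dict:
        return {
            "maf_min": self.maf_min,
            "p_max": self.p_max,
            "n_maf_pass": int(self.maf_pass.size),
            "n_per_test": {t: int(v.size) for t, v in
                           self.per_test_pass.items()},
            "n_union": int(self.union.size),
            "n_intersection": int(self.intersection.size),
        }


def _chi2_2x2(a: np.ndarray, b: np.ndarray, c: np.ndarray,
              d: np.ndarray) -> np.ndarray:
    """Vectorized Pearson chi-squared p-value for 2x2 tables [[a,b],[c,d]]."""
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / denom
    p = np.ones_like(chi2, dtype=np.float64)
    ok = denom > 0
    p[ok] = stats.chi2.sf(chi2[ok], df=1)
    return p


def association_tests(ds: GenotypeDataset) -> pd.DataFrame:
    """Compute per-SNP MAF and the four association p-values.

    Returns a DataFrame with columns ``snp``, ``maf``, ``p_genotypic``,
    ``p_dominant``, ``p_trend``, ``p_allelic`` indexed by SNP order.
    """
    g = ds.genotypes
    y = ds.phenotype.astype(np.float64)
    # per-genotype-class counts by phenotype, via boolean matmuls
    n1 = np.stack([y @ (g == k) for k in (0, 1, 2)], axis=1)       # (m, 3)
    n0 = np.stack([(1.0 - y) @ (g == k) for k in (0, 1, 2)], axis=1)
    ng = n1 + n0                                                    # (m, 3)
    N1 = n1.sum(axis=1)
    N0 = n0.sum(axis=1)
    N = N1 + N0

    n_obs = np.where(N > 0, N, 1.0)
    q = (ng[:, 1] + 2.0 * ng[:, 2]) / (2.0 * n_obs)
    maf = np.minimum(q, 1.0 - q)

    degenerate = (N1 == 0) | (N0 == 0) | (maf == 0.0)

    # genotypic: Pearson on 2x3 with df = nonempty genotype classes - 1
    expected1 = np.outer(N1, np.ones(3)) * ng / n_obs[:, None]
    expected0 = np.outer(N0, np.ones(3)) * ng / n_obs[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (n1 - expected1) ** 2 / expected1
        t0 = (n0 - expected0) ** 2 / expected0
    t1[~np.isfinite(t1)] = 0.0
    t0[~np.isfinite(t0)] = 0.0
    chi2_geno = (t1 + t0).sum(axis=1)
    df_geno = (ng > 0).sum(axis=1) - 1
    p_genotypic = np.ones(ds.n_snps)
    ok = (df_geno >= 1) & ~degenerate
    p_genotypic[ok] = stats.chi2.sf(chi2_geno[ok], df=df_geno[ok])

    # dominant: AA vs (Aa + aa)
    p_dominant = _chi2_2x2(
        n1[:, 0], n1[:, 1] + n1[:, 2], n0[:, 0], n0[:, 1] + n0[:, 2]
    )

    # Cochran-Armitage trend, weights (0, 1, 2)
    w = np.array([0.0, 1.0, 2.0])
    T = ((n1 * N0[:, None] - n0 * N1[:, None]) @ w)
    sw = ng @ w
    sww = ng @ (w * w)
    var = N1 * N0 / n_obs * (n_obs * sww - sw ** 2)
    p_trend = np.ones(ds.n_snps)
    ok = (var > 0) & ~degenerate
    p_trend[ok] = stats.chi2.sf(T[ok] ** 2 / var[ok], df=1)

    # allelic: 2x2 on allele counts
    minor1 = n1[:, 1] + 2.0 * n1[:, 2]
    minor0 = n0[:, 1] + 2.0 * n0[:, 2]
    p_allelic = _chi2_2x2(
        minor1, 2.0 * N1 - minor1, minor0, 2.0 * N0 - minor0
    )

    for p in (p_dominant, p_allelic):
        p[degenerate] = 1.0

    return pd.DataFrame(
        {
            "snp": ds.snp_meta["snp"].to_numpy(),
            "maf": maf,
            "p_genotypic": p_genotypic,
            "p_dominant": p_dominant,
            "p_trend": p_trend,
            "p_allelic": p_allelic,
        }
    )


def preselect(
    table: pd.DataFrame, maf_min: float = 0.01, p_max: float = 1e-4
) -> PreselectionResult:
    """Form the union-of-tests SNP preselection.

    The MAF filter (strict ``>``) is applied first; each test list contains
    the MAF-passing SNPs with ``p < p_max``; union and intersection are
    returned in ascending SNP-index order.  An empty union logs a warning.
    """
    maf_pass = np.flatnonzero(table["maf"].to_numpy() > maf_min)
    per_test: Dict[str, np.ndarray] = {}
    for t in TESTS:
        p = table[f"p_{t}"].to_numpy()
        per_test[t] = maf_pass[p[maf_pass] < p_max]
    union = np.unique(np.concatenate(list(per_test.values())))
    inter = maf_pass
    for v in per_test.values():
        inter = np.intersect1d(inter, v)
    if union.size == 0:
        logger.warning("preselection union is empty "
                       "(maf_min=%g, p_max=%g)", maf_min, p_max)
    return PreselectionResult(
        maf_pass=maf_pass,
        per_test_pass=per_test,
        union=union,
        intersection=inter,
        maf_min=maf_min,
        p_max=p_max,
    )
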