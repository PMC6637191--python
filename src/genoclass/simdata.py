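"""Synthetic case-control genotype data with GWAS-like structure.

The generator emulates the statistical features a genotype-classification
pipeline has to cope with on real immunogenetics panels:

* biallelic SNPs with minor-allele frequencies spanning rare to common,
* local linkage disequilibrium (adjacent SNPs inside a block are highly
  correlated and therefore interchangeable as predictors),
* non-uniform SNP density along the genome, enriched around causal loci
  (custom arrays over-sample known disease regions),
* an additive liability model: the case probability is a logistic function
  of the weighted minor-allele counts at the causal SNPs,
* a case/control ratio around 0.53, and
* missing genotypes whose rate may differ between cases and controls.

Each SNP obeys Hardy-Weinberg equilibrium marginally: the two alleles of an
individual are drawn independently, so the genotype is Binomial(2, q) even
inside LD blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset, TruthEffects

logger = logging.getLogger(__name__)

#: Window (bp) used when enriching SNP density around causal variants.
CAUSAL_WINDOW_BP = 500_000


class CalibrationError(RuntimeError):
    """Raised when the requested case count cannot be reached."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic genotype/phenotype generator.

    Defaults describe a desk-scale dataset: ~5,000 samples at the
    case/control ratio 0.53 of large inflammatory-bowel-disease cohorts,
    1,000 SNPs in 10-SNP LD blocks with within-block allele-copying
    probability 0.5, 20 causal SNPs with odds ratios 1.1-1.5, and a genome
    of five 50 Mb chromosomes.
    """

    n_cases: int = 1733
    n_controls: int = 3267
    n_snps: int = 1000
    n_causal: int = 20
    maf_range: Tuple[float, float] = (0.001, 0.5)
    causal_or_range: Tuple[float, float] = (1.1, 1.5)
    #: causal variants are restricted to common frequencies; rare causal
    #: alleles carry almost no classification signal and GWAS-ascertained
    #: loci are common by construction.
    causal_maf_min: float = 0.05
    ld_rho: float = 0.5
    block_size: int = 10
    density_enrichment: float = 2.0
    miss_rate_controls: float = 0.0
    miss_rate_cases: float = 0.0
    chrom_lengths: List[int] = field(
        default_factory=lambda: [50_000_000] * 5
    )
    seed: int = 0
    #: rejection sampling draws at most this multiple of the requested
    #: sample count before declaring the calibration infeasible.
    max_draw_factor: float = 30.0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal exceeds n_snps")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if min(self.causal_or_range) < 1.0:
            raise ValueError("causal odds ratios must be >= 1")
        for r in (self.miss_rate_controls, self.miss_rate_cases):
            if not (0.0 <= r < 1.0):
                raise ValueError("missing rates must be in [0, 1)")
        if self.density_enrichment < 1.0:
            raise ValueError("density_enrichment must be >= 1")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("need at least one case and one control")


# ---------------------------------------------------------------------------
# SNP placement

def _place_snps(cfg: SimulationConfig, rng: np.random.Generator):
    """Choose chromosome/position for every SNP.

    Causal SNPs are placed uniformly over the genome; the remaining SNPs are
    placed with probability proportional to a per-window weight that equals
    ``density_enrichment`` inside 500 kb windows containing a causal SNP and
    1 elsewhere, reproducing the density excess around disease loci.
    Returns sorted arrays (chrom index, bp, is_causal).
    """
    lengths = np.asarray(cfg.chrom_lengths, dtype=np.int64)
    genome = lengths.sum()

    # causal positions, uniform over the concatenated genome
    flat = rng.integers(1, genome + 1, size=cfg.n_causal)
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    causal_chrom = np.searchsorted(bounds, flat, side="left") - 1
    causal_bp = flat - bounds[causal_chrom]

    # per-window weights
    win_chrom, win_idx, win_len, win_w = [], [], [], []
    causal_windows = {
        (int(c), int((b - 1) // CAUSAL_WINDOW_BP))
        for c, b in zip(causal_chrom, causal_bp)
    }
    for c, L in enumerate(lengths):
        n_win = int(np.ceil(L / CAUSAL_WINDOW_BP))
        for w in range(n_win):
            size = min(CAUSAL_WINDOW_BP, L - w * CAUSAL_WINDOW_BP)
            win_chrom.append(c)
            win_idx.append(w)
            win_len.append(size)
            win_w.append(
                cfg.density_enrichment if (c, w) in causal_windows else 1.0
            )
    win_len = np.asarray(win_len, dtype=np.float64)
    prob = np.asarray(win_w) * win_len
    prob /= prob.sum()

    n_rest = cfg.n_snps - cfg.n_causal
    chosen = rng.choice(len(prob), size=n_rest, p=prob)
    rest_chrom = np.asarray(win_chrom)[chosen]
    offs = rng.integers(0, win_len[chosen].astype(np.int64))
    rest_bp = np.asarray(win_idx)[chosen] * CAUSAL_WINDOW_BP + 1 + offs

    chrom = np.concatenate([causal_chrom, rest_chrom]).astype(np.int64)
    bp = np.concatenate([causal_bp, rest_bp]).astype(np.int64)
    causal = np.zeros(cfg.n_snps, dtype=bool)
    causal[: cfg.n_causal] = True

    # enforce unique positions within a chromosome, then sort
    for _ in range(100):
        key = chrom * (genome + 1) + bp
        _, first = np.unique(key, return_index=True)
        dup = np.setdiff1d(np.arange(cfg.n_snps), first)
        if dup.size == 0:
            break
        bp[dup] = rng.integers(1, lengths[chrom[dup]] + 1)
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not deduplicate SNP positions")

    order = np.lexsort((bp, chrom))
    return chrom[order], bp[order], causal[order]


# ---------------------------------------------------------------------------
# genotype sampling

def _sample_genotypes(
    n: int,
    maf: np.ndarray,
    chrom: np.ndarray,
    block_of: np.ndarray,
    ld_rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw an n x m genotype matrix with first-order allele copying.

    Each individual carries two allele tracks.  Within an LD block the
    allele at SNP j copies the allele at SNP j-1 with probability
    ``ld_rho``, otherwise it is a fresh Bernoulli(maf_j) draw.  Because the
    two tracks stay independent, genotypes remain Binomial(2, q) marginally
    (Hardy-Weinberg), while adjacent SNPs inside a block are positively
    correlated.
    """
    m = maf.size
    geno = np.empty((n, m), dtype=np.int8)
    prev = None
    for j in range(m):
        fresh = (rng.random((n, 2)) < maf[j])
        new_block = (
            j == 0
            or chrom[j] != chrom[j - 1]
            or block_of[j] != block_of[j - 1]
        )
        if new_block or ld_rho == 0.0:
            h = fresh
        else:
            copy = rng.random((n, 2)) < ld_rho
            h = np.where(copy, prev, fresh)
        geno[:, j] = h.sum(axis=1)
        prev = h
    return geno


def _block_index(chrom: np.ndarray, block_size: int) -> np.ndarray:
    """Block id of each SNP: consecutive runs of block_size per chromosome."""
    block = np.empty(chrom.size, dtype=np.int64)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        block[idx] = np.arange(idx.size) // block_size
    return block


def _calibrate_intercept(
    geno: np.ndarray, beta: np.ndarray, target: float
) -> float:
    """Bisect the intercept so mean case probability equals ``target``."""
    eta = geno.astype(np.float64) @ beta

    def prevalence(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + eta)))))

    lo, hi = -30.0, 30.0
    if not (prevalence(lo) <= target <= prevalence(hi)):
        raise CalibrationError(
            f"target prevalence {target:.3f} unreachable by intercept"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if prevalence(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# public API

def simulate_dataset(cfg: SimulationConfig) -> GenotypeDataset:
    """Generate a synthetic case-control genotype dataset.

    Genotypes follow Hardy-Weinberg equilibrium at a MAF drawn uniformly in
    ``cfg.maf_range`` with first-order LD inside blocks; phenotypes are
    drawn by rejection from ``P(case | g) = logistic(b0 + sum_j beta_j
    g_j)`` where ``beta_j = log(OR_j)`` at the causal SNPs and ``b0`` is
    calibrated by bisection so the expected prevalence matches the
    requested case fraction.  Deterministic under ``cfg.seed``.

    Raises
    ------
    CalibrationError
        If the requested case/control counts cannot be collected within
        ``cfg.max_draw_factor`` times the requested sample count.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom, bp, causal = _place_snps(cfg, rng)

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_snps)
    if cfg.n_causal:
        lo = max(cfg.causal_maf_min, cfg.maf_range[0])
        maf[causal] = rng.uniform(
            lo, cfg.maf_range[1], size=int(causal.sum())
        )

    beta = np.zeros(cfg.n_snps)
    if cfg.n_causal:
        ors = rng.uniform(*cfg.causal_or_range, size=int(causal.sum()))
        beta[causal] = np.log(ors)

    block_of = _block_index(chrom, cfg.block_size)
    n_target = cfg.n_cases + cfg.n_controls
    target_prev = cfg.n_cases / n_target

    # calibrate the intercept on an independent genotype sample
    calib = _sample_genotypes(
        min(4000, max(1000, n_target)), maf, chrom, block_of, cfg.ld_rho, rng
    )
    beta0 = _calibrate_intercept(calib, beta, target_prev)

    # rejection sampling of labelled individuals
    kept_g: list[np.ndarray] = []
    kept_y: list[np.ndarray] = []
    need_cases, need_controls = cfg.n_cases, cfg.n_controls
    drawn = 0
    cap = int(cfg.max_draw_factor * n_target)
    chunk = min(max(n_target // 2, 500), 20_000)
    while need_cases > 0 or need_controls > 0:
        if drawn >= cap:
            raise CalibrationError(
                f"drew {drawn} individuals without reaching "
                f"{cfg.n_cases}/{cfg.n_controls} cases/controls"
            )
        g = _sample_genotypes(chunk, maf, chrom, block_of, cfg.ld_rho, rng)
        drawn += chunk
        p = 1.0 / (1.0 + np.exp(-(beta0 + g.astype(np.float64) @ beta)))
        y = (rng.random(chunk) < p).astype(np.int8)
        take_case = np.flatnonzero(y == 1)[:need_cases]
        take_ctrl = np.flatnonzero(y == 0)[:need_controls]
        take = np.sort(np.concatenate([take_case, take_ctrl]))
        kept_g.append(g[take])
        kept_y.append(y[take])
        need_cases -= take_case.size
        need_controls -= take_ctrl.size

    genotypes = np.vstack(kept_g)
    phenotype = np.concatenate(kept_y)
    # shuffle so cases/controls are not grouped by draw order
    perm = rng.permutation(n_target)
    genotypes, phenotype = genotypes[perm], phenotype[perm]

    width = len(str(cfg.n_snps))
    snp_meta = pd.DataFrame(
        {
            "snp": [f"snp{j:0{width}d}" for j in range(cfg.n_snps)],
            "chrom": (chrom + 1).astype(np.int64),
            "bp": bp,
            "a1": "A",
            "a2": "G",
        }
    )
    ds = GenotypeDataset(
        genotypes=genotypes,
        phenotype=phenotype,
        snp_meta=snp_meta,
        truth=TruthEffects(beta=beta, beta0=beta0),
    )
    if cfg.miss_rate_controls > 0 or cfg.miss_rate_cases > 0:
        ds = inject_missingness(
            ds,
            cfg.miss_rate_controls,
            cfg.miss_rate_cases,
            seed=cfg.seed + 1,
        )
    logger.info(
        "simulated %d cases / %d controls, %d SNPs (%d causal)",
        cfg.n_cases, cfg.n_controls, cfg.n_snps, cfg.n_causal,
    )
    return ds


def inject_missingness(
    ds: GenotypeDataset,
    miss_rate_controls: float,
    miss_rate_cases: float,
    seed: int,
) -> GenotypeDataset:
    """Mask genotypes at a class-specific rate.

    Each (sample, SNP) entry becomes MISSING independently with the rate of
    the sample's phenotype class; everything else is untouched.  A
    differential rate makes the missingness indicator itself informative of
    the phenotype — the artefact an unknown-genotype coding can exploit.
    """
    for r in (miss_rate_controls, miss_rate_cases):
        if not (0.0 <= r < 1.0):
            raise ValueError("missing rates must be in [0, 1)")
    if miss_rate_controls == 0.0 and miss_rate_cases == 0.0:
        return ds.copy()
    rng = np.random.default_rng(seed)
    rate = np.where(ds.phenotype == 1, miss_rate_cases, miss_rate_controls)
    mask = rng.random(ds.genotypes.shape) < rate[:, None]
    geno = ds.genotypes.copy()
    geno[mask] = MISSING
    out = ds.copy()
    out.genotypes = geno
    return out
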