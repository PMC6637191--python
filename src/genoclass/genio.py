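"""Read/write genotype data and reference locus lists.

Supports the PLINK 1.9 text+binary triple (.bed/.bim/.fam, SNP-major .bed)
and a simple internal container (NumPy ``.npz`` matrix plus a TSV of SNP
metadata) that round-trips a :class:`GenotypeDataset` without external
tooling.  Reference GWAS locus lists are TSV files with columns
``chrom``, ``bp``, ``or``; each locus is scored by \\|log(OR)\\| (natural
log; the ranking is base-invariant).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset, TruthEffects

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK 1.9, SNP-major

# two-bit PLINK codes -> minor-allele counts
#   00 -> 2 (hom minor/A1), 01 -> MISSING, 10 -> 1 (het), 11 -> 0 (hom major)
_CODE_TO_GENO = np.array([2, MISSING, 1, 0], dtype=np.int8)
_GENO_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

# 256 x 4 lookup: byte value -> genotypes of the four packed samples
_BYTE_LUT = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _s in range(4):
        _BYTE_LUT[_b, _s] = _CODE_TO_GENO[(_b >> (2 * _s)) & 0b11]


class PlinkFormatError(ValueError):
    """Malformed PLINK file (bad magic bytes or inconsistent sizes)."""


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam

def write_plink(ds: GenotypeDataset, prefix: Union[str, Path]) -> None:
    """Write a dataset as a PLINK 1.9 bed/bim/fam triple.

    The .bed is SNP-major; .fam phenotypes use the PLINK convention
    1 = control, 2 = case.
    """
    prefix = Path(prefix)
    n, m = ds.genotypes.shape

    fam = pd.DataFrame(
        {
            "fid": [f"F{i}" for i in range(n)],
            "iid": [f"I{i}" for i in range(n)],
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": ds.phenotype.astype(np.int64) + 1,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)

    bim = pd.DataFrame(
        {
            "chrom": ds.snp_meta["chrom"],
            "snp": ds.snp_meta["snp"],
            "cm": 0,
            "bp": ds.snp_meta["bp"],
            "a1": ds.snp_meta["a1"],
            "a2": ds.snp_meta["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        codes = np.empty(ds.genotypes.shape, dtype=np.uint8)
        for g, c in _GENO_TO_CODE.items():
            codes[ds.genotypes == g] = c
        for j in range(m):
            col = codes[:, j]
            # pad to a byte boundary with the hom-major code (0b00 shifts
            # in naturally as zeros; PLINK readers ignore the padding)
            buf = np.zeros(n_bytes, dtype=np.uint8)
            for s in range(4):
                samp = col[s::4]
                buf[: samp.size] |= samp << (2 * s)
            fh.write(buf.tobytes())


def read_plink(prefix: Union[str, Path]) -> GenotypeDataset:
    """Read a PLINK 1.9 bed/bim/fam triple into a :class:`GenotypeDataset`.

    Samples with an unphenotyped .fam status (0 or -9) are excluded and
    their count logged.
    """
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(ext).exists():
            raise FileNotFoundError(prefix.with_suffix(ext))

    def _read_table(path: Path, names: list) -> pd.DataFrame:
        try:
            return pd.read_csv(path, sep=r"\s+", header=None, names=names)
        except pd.errors.EmptyDataError:
            return pd.DataFrame(columns=names)

    fam = _read_table(
        prefix.with_suffix(".fam"),
        ["fid", "iid", "father", "mother", "sex", "pheno"],
    )
    bim = _read_table(
        prefix.with_suffix(".bim"),
        ["chrom", "snp", "cm", "bp", "a1", "a2"],
    )
    n, m = len(fam), len(bim)

    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{prefix.with_suffix('.bed')}: bad magic bytes "
            f"{raw[:3].hex()} (expected {_BED_MAGIC.hex()})"
        )
    n_bytes = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != n_bytes * m:
        raise PlinkFormatError(
            f"{prefix.with_suffix('.bed')}: {body.size} data bytes, "
            f"expected {n_bytes * m} for {n} samples x {m} SNPs"
        )
    decoded = _BYTE_LUT[body.reshape(m, n_bytes)]  # (m, n_bytes, 4)
    genotypes = decoded.reshape(m, n_bytes * 4)[:, :n].T.copy()

    pheno = fam["pheno"].to_numpy()
    keep = np.isin(pheno, (1, 2))
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("excluded %d unphenotyped samples", dropped)
        genotypes = genotypes[keep]
        pheno = pheno[keep]

    snp_meta = bim[["snp", "chrom", "bp", "a1", "a2"]].copy()
    return GenotypeDataset(
        genotypes=genotypes,
        phenotype=(pheno - 1).astype(np.int8),
        snp_meta=snp_meta,
    )


# ---------------------------------------------------------------------------
# internal container: .npz matrix + TSV metadata

def write_dataset(ds: GenotypeDataset, prefix: Union[str, Path]) -> None:
    """Write the internal container: ``<prefix>.npz`` + ``<prefix>.snps.tsv``."""
    prefix = Path(prefix)
    arrays = {"genotypes": ds.genotypes, "phenotype": ds.phenotype}
    if ds.truth is not None:
        arrays["beta"] = ds.truth.beta
        arrays["beta0"] = np.array([ds.truth.beta0])
    np.savez_compressed(prefix.with_suffix(".npz"), **arrays)
    ds.snp_meta.to_csv(
        prefix.parent / (prefix.name + ".snps.tsv"), sep="\t", index=False
    )


def read_dataset(prefix: Union[str, Path]) -> GenotypeDataset:
    prefix = Path(prefix)
    with np.load(prefix.with_suffix(".npz")) as z:
        genotypes = z["genotypes"]
        phenotype = z["phenotype"]
        truth = None
        if "beta" in z:
            truth = TruthEffects(beta=z["beta"], beta0=float(z["beta0"][0]))
    snp_meta = pd.read_csv(
        prefix.parent / (prefix.name + ".snps.tsv"), sep="\t"
    )
    return GenotypeDataset(genotypes, phenotype, snp_meta, truth)


def write_truth(ds: GenotypeDataset, path: Union[str, Path]) -> None:
    """Write per-SNP true effects as TSV (snp, chrom, bp, beta)."""
    if ds.truth is None:
        raise ValueError("dataset carries no truth effects")
    out = ds.snp_meta[["snp", "chrom", "bp"]].copy()
    out["beta"] = ds.truth.beta
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference locus lists

def read_reference_loci(path: Union[str, Path]) -> pd.DataFrame:
    """Read a GWAS reference locus list (TSV: chrom, bp, or).

    Returns a DataFrame with columns ``chrom``, ``bp``, ``score`` where
    ``score = |log(OR)|``; an odds ratio of 1 scores 0.

    Raises
    ------
    ValueError
        If any odds ratio is <= 0.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"chrom", "bp", "or"}
    if not required <= set(df.columns):
        raise ValueError(f"reference list needs columns {sorted(required)}")
    ors = df["or"].to_numpy(dtype=np.float64)
    if np.any(ors <= 0):
        raise ValueError("odds ratios must be positive")
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "bp": df["bp"].astype(np.int64),
            "score": np.abs(np.log(ors)),
        }
    )
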