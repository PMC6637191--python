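import numpy as np
import pandas as pd
import pytest

from genoclass import GenotypeDataset, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def signal_ds():
    """Small dataset with strong causal signal (ratio ~0.53)."""
    cfg = SimulationConfig(
        n_cases=300,
        n_controls=566,
        n_snps=200,
        n_causal=8,
        causal_or_range=(1.6, 2.5),
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_ds():
    """Dataset without any genotype-phenotype association."""
    cfg = SimulationConfig(
        n_cases=300,
        n_controls=566,
        n_snps=150,
        n_causal=0,
        seed=12,
    )
    return simulate_dataset(cfg)


def make_dataset(genotypes, phenotype, bp=None, chrom=None):
    """Hand-build a GenotypeDataset from raw arrays."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    m = genotypes.shape[1]
    meta = pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else [1] * m,
            "bp": bp if bp is not None else np.arange(1, m + 1) * 1000,
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeDataset(
        genotypes=genotypes,
        phenotype=np.asarray(phenotype, dtype=np.int8),
        snp_meta=meta,
    )


def dataset_from_genotype_counts(case_counts, control_counts):
    """Dataset for one SNP given genotype counts (n0, n1, n2) per class."""
    gen, phen = [], []
    for cls, counts in ((1, case_counts), (0, control_counts)):
        for g, k in zip((0, 1, 2), counts):
            gen.extend([g] * k)
            phen.extend([cls] * k)
    return make_dataset(np.array(gen)[:, None], phen)
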