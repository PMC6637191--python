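# genoclass

Machine-learning classification of case-control genotype data, with an
emphasis on *feature stability*: which genomic loci do different
classifiers, trained on different folds of the data, consistently rank as
important?

The package is aimed at statistical geneticists who want to compare
penalized logistic regression, gradient-boosted trees and neural networks
on SNP panels (e.g. Immunochip-style case-control cohorts), and to measure
how reproducible the resulting importance rankings are — without access to
restricted genotype data: a synthetic-data generator reproduces the
relevant statistical structure (Hardy-Weinberg genotypes, LD blocks,
non-uniform SNP density, additive liability, differential missingness).

## What it computes

* **Simulation** — genotypes `g ∈ {0,1,2}` drawn per SNP from HWE at a MAF
  sampled in a configurable range, with first-order allele copying inside
  LD blocks; phenotypes drawn from the additive logistic model
  `P(case | g) = σ(β₀ + Σⱼ βⱼ gⱼ)` with `βⱼ = log ORⱼ` at causal SNPs and
  `β₀` calibrated by bisection to the requested prevalence.
* **QC / imputation / coding** — missing-rate filters on samples and SNPs,
  a 1-df chi-squared HWE test in controls; imputation by the major allele
  (`Maj`) or a Binomial(2, q̂) HWE draw with q̂ from controls (`HWc`) or all
  samples (`HWa`); codings `sum` (additive 0/1/2), `OHE` (3 indicators per
  SNP), `raw` (2 per-allele features) and `OHE4` (adds an unknown-genotype
  class).
* **Preselection** — per-SNP MAF plus four chi-squared association tests
  (genotypic 2 df, dominant, Cochran-Armitage trend, allelic); the panel
  kept for modelling is the union of the per-test lists at `MAF > 0.01`,
  `p < 10⁻⁴`.
* **Models** — L1/L2/ElasticNet logistic regression, LightGBM boosted
  trees, dense and residual ReLU networks, and a random-weight null model;
  10-fold cross-validated hyper-parameter selection; AUC scoring; an
  unweighted averaging ensemble.
* **Importance and stability** — permutation feature importance (mean AUC
  drop over 10 permutations), |weight| and tree gain; SNP scores
  aggregated to fixed 500 kb loci (maximum over member SNPs, with a 250 kb
  shifted "bis" partition); the robustness statistic

      R = Σᵢ₌₁ˣ aᵢ / (M·x) ∈ [1/M, 1]

  over M ranked lists (aᵢ = appearance counts of the x most frequent loci
  in the M top-x prefixes), Spearman agreement of top-x lists,
  common-loci curves, rank combination across models, and overlap
  percentages against a reference run or a GWAS locus list scored by
  |log OR|.

## Worked example

```python
import numpy as np
from genoclass import (ExperimentConfig, ModelSpec, SimulationConfig,
                       run_experiment)

cfg = ExperimentConfig(
    sim=SimulationConfig(n_cases=693, n_controls=1307, n_snps=500,
                         n_causal=10, causal_or_range=(1.5, 2.5), seed=4),
    models=[ModelSpec("lr_l1", params={"C": 1.0}),
            ModelSpec("gbt", params={"n_estimators": 100}),
            ModelSpec("random")],
    n_refolds=10,
    criteria=("PFI", "weight", "gain"),
    p_max=1e-3,
    robustness_xs=(3, 5, 10),
    seed=4,
)
report = run_experiment(cfg)
for fam in ("lr_l1", "gbt", "random"):
    aucs = [f["models"][fam]["test_auc"] for f in report.folds]
    print(fam, round(float(np.mean(aucs)), 3))
for rec in report.robustness["weight"]:
    print(rec)
```

prints (2,000 samples, 500 SNPs, 10 causal with OR 1.5–2.5, 10 refolds):

```
lr_l1 0.767
gbt 0.713
random 0.482
{'group': 'lr_l1', 'x': 3, 'mean': 0.8111..., 'se': 0.0195..., 'n_pairs': 45}
{'group': 'lr_l1', 'x': 5, 'mean': 0.8533..., 'se': 0.0108..., 'n_pairs': 45}
{'group': 'lr_l1', 'x': 10, 'mean': 1.0, 'se': 0.0, 'n_pairs': 45}
{'group': 'random', 'x': 3, 'mean': 0.6222..., 'se': 0.0201..., 'n_pairs': 45}
{'group': 'random', 'x': 5, 'mean': 0.6800..., 'se': 0.0140..., 'n_pairs': 45}
{'group': 'random', 'x': 10, 'mean': 0.8011..., 'se': 0.0090..., 'n_pairs': 45}
```

The penalized linear model and the boosted trees separate cases from
controls well above chance while the random-weight null stays near
AUC 0.5. The lasso's top loci are highly reproducible across the 45 pairs
of refolds (all ten causal loci sit in every fold's top 10), while the
random model's apparent overlap reflects only the small locus universe and
the SNP-density enrichment around causal windows — the baseline the
robustness analysis is judged against. Rerunning with the same seed
reproduces the serialized report byte for byte.

A thin CLI mirrors the library:

```bash
genoclass simulate --n-snps 1000 --out data/sim
genoclass qc data/sim --out data/sim_qc
genoclass preselect data/sim_qc --out assoc.tsv
genoclass fit data/sim_qc --family lr_l1
genoclass run config.json --out report.json
```

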