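"""End-to-end experiment orchestration.

A run proceeds through fixed stages: load or simulate the genotype data;
optionally subsample controls to a target case/control ratio; QC; impute;
draw stratified train/test refolds; preselect SNPs (on the training split
only by default — ``paper_mode=True`` screens on the full dataset, which
leaks test labels into feature selection and is provided for comparison);
encode; optional hyper-parameter cross-validation; fit each model on the
full training split; test AUC; feature importance; locus rankings on both
the original and the 250 kb-shifted ("bis") partitions; robustness and
overlap summaries.  Every random stage derives its seed deterministically
from the global seed, so a rerun with the same config yields a
byte-identical serialized report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import importance as imp
from . import robustness as rob
from .dataset import GenotypeDataset
from .genio import read_plink
from .models import FittedModel, ModelSpec, auc, fit_model, \
    select_hyperparameters
from .preprocess import FeatureMatrix, QCThresholds, apply_qc, encode, impute
from .preselect import association_tests, preselect
from .simdata import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


# ---------------------------------------------------------------------------
# splitting

def split_train_test(
    ds: GenotypeDataset, frac: float = 2.0 / 3.0, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """Stratified random split; returns (train indices, test indices).

    The train size is round(frac * n); the case count in the train split is
    round(frac * n_cases), realizing the same case/control ratio on both
    subsets exactly rather than in expectation.
    """
    if not (0.0 < frac < 1.0):
        raise ValueError("train fraction must lie in (0, 1)")
    n = ds.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    y = ds.phenotype
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both classes must be present")

    rng = np.random.default_rng(seed)
    cases = rng.permutation(cases)
    controls = rng.permutation(controls)

    n_train = _round_half_up(frac * n)
    n_train_cases = min(_round_half_up(frac * cases.size), n_train)
    n_train_controls = n_train - n_train_cases
    train = np.concatenate(
        [cases[:n_train_cases], controls[:n_train_controls]]
    )
    test = np.concatenate(
        [cases[n_train_cases:], controls[n_train_controls:]]
    )
    return np.sort(train), np.sort(test)


def make_refolds(
    ds: GenotypeDataset,
    n_refolds: int = 10,
    frac: float = 2.0 / 3.0,
    seed: int = 0,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Independent stratified splits with seeds derived from the global one."""
    if n_refolds < 1:
        raise ValueError("n_refolds must be >= 1")
    child = np.random.SeedSequence(seed).generate_state(n_refolds)
    return [
        split_train_test(ds, frac=frac, seed=int(s) % (2 ** 31))
        for s in child
    ]


def subsample_ratio(
    ds: GenotypeDataset, target_ratio: float, seed: int = 0
) -> GenotypeDataset:
    """Remove random controls until cases/controls equals ``target_ratio``.

    Cases are untouched; the target must not be below the current ratio.
    """
    current = ds.case_control_ratio
    if target_ratio < current - 1e-12:
        raise ValueError(
            f"target ratio {target_ratio} below current {current:.4f}"
        )
    keep_controls = _round_half_up(ds.n_cases / target_ratio)
    rng = np.random.default_rng(seed)
    controls = np.flatnonzero(ds.phenotype == 0)
    kept = rng.permutation(controls)[:keep_controls]
    idx = np.sort(np.concatenate([np.flatnonzero(ds.phenotype == 1), kept]))
    return ds.take_samples(idx)


# ---------------------------------------------------------------------------
# config / report

@dataclass
class ExperimentConfig:
    sim: Optional[SimulationConfig] = None
    plink_prefix: Optional[str] = None
    qc: Optional[QCThresholds] = None
    impute_strategy: str = "HWa"
    coding: str = "sum"
    maf_min: float = 0.01
    p_max: float = 1e-4
    train_frac: float = 2.0 / 3.0
    cv_folds: int = 0            # 0 skips hyper-parameter selection
    n_refolds: int = 10
    models: List[ModelSpec] = field(default_factory=list)
    criteria: Tuple[str, ...] = ("PFI",)
    pfi_n_perm: int = 10
    target_ratio: Optional[float] = None
    window_bp: int = imp.WINDOW_BP
    robustness_xs: Tuple[int, ...] = (5, 10, 25, 50)
    paper_mode: bool = False     # preselect on the full dataset (leaky)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sim is None and self.plink_prefix is None:
            raise ValueError("provide a simulation config or a PLINK prefix")
        if not self.models:
            raise ValueError("no model specs")
        if self.n_refolds < 2 and self.robustness_xs:
            raise ValueError("robustness stages need n_refolds >= 2")


@dataclass
class ExperimentReport:
    config_seed: int
    qc: Optional[dict]
    folds: List[dict]            # per fold: preselection tallies, per-model AUC
    robustness: Dict[str, list]  # criterion -> tidy records
    overlaps: Dict[str, list]
    test_scores: Dict[str, List[List[float]]]  # model -> per-fold scores

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        return json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=default,
            separators=(",", ":"),
        )


# ---------------------------------------------------------------------------
# the full run

def _load(cfg: ExperimentConfig) -> GenotypeDataset:
    if cfg.sim is not None:
        return simulate_dataset(cfg.sim)
    return read_plink(cfg.plink_prefix)


def _criteria_for(model: FittedModel, wanted: Sequence[str]) -> List[str]:
    out = []
    for c in wanted:
        if c == "weight" and model.weights is None:
            continue
        if c == "gain" and model.gains is None:
            continue
        out.append(c)
    return out


def run_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """Execute the full pipeline and return a serializable report."""
    stage = "load"
    try:
        ds = _load(cfg)
        if cfg.target_ratio is not None:
            stage = "subsample"
            ds = subsample_ratio(ds, cfg.target_ratio, seed=cfg.seed + 101)
        qc_report = None
        if cfg.qc is not None:
            stage = "qc"
            ds, qc = apply_qc(ds, cfg.qc)
            qc_report = qc.to_dict()
        stage = "impute"
        ds = impute(ds, cfg.impute_strategy, seed=cfg.seed + 202)

        stage = "refolds"
        folds = make_refolds(
            ds, n_refolds=cfg.n_refolds, frac=cfg.train_frac, seed=cfg.seed
        )

        fold_reports: List[dict] = []
        rankings: Dict[str, Dict[Tuple[str, int], imp.LocusRanking]] = {}
        rankings_bis: Dict[str, Dict[Tuple[str, int], imp.LocusRanking]] = {}
        snp_runs: Dict[Tuple[str, str, int], list] = {}
        loci_runs: Dict[Tuple[str, str, int], list] = {}
        test_scores: Dict[str, List[List[float]]] = {}

        for fold_id, (tr, te) in enumerate(folds):
            stage = f"fold{fold_id}:preselect"
            screen_idx = np.arange(ds.n_samples) if cfg.paper_mode else tr
            table = association_tests(ds.take_samples(screen_idx))
            sel = preselect(table, maf_min=cfg.maf_min, p_max=cfg.p_max)
            kept = sel.union if sel.union.size else sel.maf_pass
            sub = ds.take_snps(kept)
            snp_names = sub.snp_meta["snp"].to_numpy()

            stage = f"fold{fold_id}:encode"
            X = encode(sub, cfg.coding)
            ytr, yte = sub.phenotype[tr], sub.phenotype[te]
            Xtr = FeatureMatrix(values=X.values[tr],
                                feature_map=X.feature_map, coding=X.coding)
            Xte = FeatureMatrix(values=X.values[te],
                                feature_map=X.feature_map, coding=X.coding)
            part0 = imp.build_partition(sub.snp_meta, cfg.window_bp, 0)
            part_bis = imp.build_partition(
                sub.snp_meta, cfg.window_bp, cfg.window_bp // 2
            )

            fold_rep = {
                "fold": fold_id,
                "preselection": sel.to_dict(),
                "models": {},
            }
            for spec in cfg.models:
                stage = f"fold{fold_id}:{spec.family}"
                spec_f = dataclasses.replace(
                    spec, seed=(spec.seed + 1000 * fold_id) % (2 ** 31)
                )
                if cfg.cv_folds and spec_f.grid():
                    spec_f = select_hyperparameters(
                        spec_f, Xtr, ytr, k=cfg.cv_folds
                    )
                model = fit_model(spec_f, Xtr, ytr)
                scores = model.predict(Xte)
                test_auc = auc(scores, yte)
                test_scores.setdefault(spec.family, []).append(
                    [float(s) for s in scores]
                )
                fold_rep["models"][spec.family] = {
                    "test_auc": test_auc,
                    "cv_auc_mean": getattr(spec_f, "cv_auc_mean_", None),
                    "cv_auc_sd": getattr(spec_f, "cv_auc_sd_", None),
                    "n_nonzero": model.n_nonzero_weights(),
                    "params": spec_f.params,
                }

                stage = f"fold{fold_id}:{spec.family}:importance"
                for crit in _criteria_for(model, cfg.criteria):
                    if crit == "PFI":
                        fr = imp.pfi(model, Xte, yte,
                                     n_perm=cfg.pfi_n_perm,
                                     seed=cfg.seed + 303 + fold_id)
                    elif crit == "weight":
                        fr = imp.weight_importance(model)
                    else:
                        fr = imp.gain_importance(model)
                    fr.fold = fold_id
                    lr0 = imp.to_locus_ranking(fr, part0)
                    rankings.setdefault(crit, {})[(spec.family, fold_id)] \
                        = lr0
                    rankings_bis.setdefault(crit, {})[
                        (spec.family, fold_id)] = imp.to_locus_ranking(
                            fr, part_bis)
                    key = (spec.family, crit, fold_id)
                    loci_runs[key] = [f"{c}:{w}" for c, w in lr0.loci]
                    snp_score = imp.snp_scores_from_features(fr)
                    order = sorted(snp_score,
                                   key=lambda s: (-snp_score[s], s))
                    snp_runs[key] = [snp_names[s] for s in order]
            fold_reports.append(fold_rep)

        stage = "robustness"
        robustness: Dict[str, list] = {}
        for tag, rks in (("", rankings), ("_bis", rankings_bis)):
            for crit, rk in rks.items():
                if not rk:
                    continue
                xs = [x for x in cfg.robustness_xs
                      if x <= min(len(v) for v in rk.values())]
                if not xs:
                    continue
                df = rob.pairwise_summary(rk, mode="intra", xs=xs,
                                          metric="R")
                robustness[crit + tag] = df.to_dict("records")

        stage = "overlap"
        overlaps: Dict[str, list] = {}
        for crit in cfg.criteria:
            recs = []
            by_model: Dict[str, list] = {}
            for (m, c, f) in sorted(k for k in loci_runs if k[1] == crit):
                by_model.setdefault(m, []).append((f, (m, c, f)))
            for m, runs in by_model.items():
                ref_key = runs[0][1]
                for f, key in runs[1:]:
                    rep = rob.overlap_metrics(
                        run_snps=snp_runs[key],
                        run_loci=loci_runs[key],
                        ref_snps=snp_runs[ref_key],
                        ref_loci=loci_runs[ref_key],
                    )
                    recs.append({"model": m, "fold": f, **rep.to_dict()})
            if recs:
                overlaps[crit] = recs

        return ExperimentReport(
            config_seed=cfg.seed,
            qc=qc_report,
            folds=fold_reports,
            robustness=robustness,
            overlaps=overlaps,
            test_scores=test_scores,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") \
            from exc
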