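"""Feature-importance criteria and aggregation of SNP scores to loci.

Three criteria produce a ranked feature list from a fitted model:

* **PFI** (permutation feature importance): per feature, the test-set AUC
  drop after shuffling that feature's column across samples, averaged over
  ``n_perm`` permutations.  Positive = AUC drop; negative values (noise)
  are kept and rank below zero.
* **weight**: absolute value of the exported linear weight.
* **gain**: the tree library's per-feature split gain.

Loci are fixed 500 kb genomic windows; a locus scores the maximum over its
member SNPs, and multi-column codings first collapse to a SNP score by the
maximum over the SNP's sub-features.  A second partition shifted by 250 kb
("bis") smooths window-boundary bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .models import FittedModel, auc
from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)

WINDOW_BP = 500_000
BIS_SHIFT_BP = 250_000


def _order_desc(ids: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Order by score descending, ties by ascending id."""
    return np.lexsort((ids, -scores))


@dataclass
class FeatureRanking:
    """Ordered (feature id, score) pairs, descending score."""

    feature_ids: np.ndarray
    scores: np.ndarray
    criterion: str
    model_family: str
    fold: Optional[int] = None
    feature_map: Optional[list] = None

    def __post_init__(self) -> None:
        order = _order_desc(np.asarray(self.feature_ids),
                            np.asarray(self.scores, dtype=np.float64))
        self.feature_ids = np.asarray(self.feature_ids)[order]
        self.scores = np.asarray(self.scores, dtype=np.float64)[order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, self.feature_ids.size + 1),
                "id": self.feature_ids,
                "score": self.scores,
                "criterion": self.criterion,
                "model": self.model_family,
                "fold": self.fold,
            }
        )


@dataclass
class LocusPartition:
    """Fixed genomic windows; every SNP maps to exactly one window."""

    window_bp: int
    shift_bp: int
    locus_of_snp: np.ndarray      # per-SNP locus index into `loci`
    loci: List[Tuple[Union[int, str], int]]  # (chrom, window index)

    @property
    def n_loci(self) -> int:
        return len(self.loci)


@dataclass
class LocusRanking:
    """Ordered (locus id, score) pairs; locus score = max member SNP score."""

    loci: List[Tuple]
    scores: np.ndarray
    criterion: str = ""
    model_family: str = ""
    fold: Optional[int] = None

    def __post_init__(self) -> None:
        # descending score, ties by ascending locus id
        idx = sorted(
            range(len(self.loci)),
            key=lambda i: (-self.scores[i], self.loci[i]),
        )
        self.loci = [self.loci[i] for i in idx]
        self.scores = np.asarray(self.scores, dtype=np.float64)[idx]

    def top(self, x: int) -> List[Tuple]:
        return self.loci[:x]

    def __len__(self) -> int:
        return len(self.loci)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.loci) + 1),
                "locus": [f"{c}:{w}" for c, w in self.loci],
                "score": self.scores,
                "criterion": self.criterion,
                "model": self.model_family,
                "fold": self.fold,
            }
        )


# ---------------------------------------------------------------------------
# criteria

def pfi(
    model: FittedModel,
    X_test: Union[FeatureMatrix, np.ndarray],
    y_test: np.ndarray,
    n_perm: int = 10,
    seed: int = 0,
) -> FeatureRanking:
    """Permutation feature importance on the test set.

    Score of feature j = AUC(original) - mean over ``n_perm`` permutations
    of the AUC after shuffling column j across samples.  A constant column
    scores exactly 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = X_test.values if isinstance(X_test, FeatureMatrix) \
        else np.asarray(X_test)
    y_test = np.asarray(y_test)
    rng = np.random.default_rng(seed)
    n, d = values.shape

    base_scores = model.predict(values)
    base = auc(base_scores, y_test)

    # fast path for linear scorers: the permuted score differs from the
    # base linear predictor only in one additive term
    linear = model.weights is not None and model.is_linear
    if linear:
        eta = values @ model.weights + model.intercept

    scores = np.zeros(d)
    work = values.copy()
    for j in range(d):
        col = values[:, j]
        if np.all(col == col[0]):
            scores[j] = 0.0
            # keep the random stream aligned across features
            for _ in range(n_perm):
                rng.permutation(n)
            continue
        drops = []
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if linear:
                eta_p = eta + model.weights[j] * (col[perm] - col)
                drops.append(auc(eta_p, y_test))
            else:
                work[:, j] = col[perm]
                drops.append(auc(model.predict(work), y_test))
        if not linear:
            work[:, j] = col
        scores[j] = base - float(np.mean(drops))

    fmap = X_test.feature_map if isinstance(X_test, FeatureMatrix) \
        else model.feature_map
    return FeatureRanking(
        feature_ids=np.arange(d),
        scores=scores,
        criterion="PFI",
        model_family=model.spec.family,
        feature_map=fmap,
    )


def weight_importance(model: FittedModel) -> FeatureRanking:
    """|weight| ranking for families exporting linear weights."""
    if model.weights is None:
        raise ValueError(
            f"family {model.spec.family!r} exports no weights"
        )
    return FeatureRanking(
        feature_ids=np.arange(model.weights.size),
        scores=np.abs(model.weights),
        criterion="weight",
        model_family=model.spec.family,
        feature_map=model.feature_map,
    )


def gain_importance(model: FittedModel) -> FeatureRanking:
    """Split-gain ranking for tree families."""
    if model.gains is None:
        raise ValueError(
            f"family {model.spec.family!r} exports no gains"
        )
    return FeatureRanking(
        feature_ids=np.arange(model.gains.size),
        scores=model.gains,
        criterion="gain",
        model_family=model.spec.family,
        feature_map=model.feature_map,
    )


CRITERIA = {"PFI": pfi, "weight": weight_importance, "gain": gain_importance}


# ---------------------------------------------------------------------------
# loci

def build_partition(
    snp_meta: pd.DataFrame,
    window_bp: int = WINDOW_BP,
    shift_bp: int = 0,
) -> LocusPartition:
    """Partition the genome into fixed windows.

    Window index of a SNP at 1-based position bp is
    ``floor((bp - 1 + shift_bp) / window_bp)`` within its chromosome.
    """
    bp = snp_meta["bp"].to_numpy()
    if np.any(bp < 1):
        raise ValueError("bp positions must be >= 1")
    win = (bp - 1 + shift_bp) // window_bp
    keys = list(zip(snp_meta["chrom"].tolist(), win.tolist()))
    loci = sorted(set(keys))
    index = {locus: i for i, locus in enumerate(loci)}
    locus_of_snp = np.array([index[k] for k in keys], dtype=np.int64)
    return LocusPartition(
        window_bp=window_bp,
        shift_bp=shift_bp,
        locus_of_snp=locus_of_snp,
        loci=loci,
    )


def snp_scores_from_features(fr: FeatureRanking) -> Dict[int, float]:
    """Collapse multi-column codings to per-SNP scores (max sub-feature)."""
    if fr.feature_map is None:
        # features are SNPs already
        return {int(f): float(s) for f, s in zip(fr.feature_ids, fr.scores)}
    out: Dict[int, float] = {}
    for f, s in zip(fr.feature_ids, fr.scores):
        snp, _label = fr.feature_map[int(f)]
        if snp not in out or s > out[snp]:
            out[snp] = float(s)
    return out


def to_locus_ranking(
    fr: FeatureRanking, part: LocusPartition
) -> LocusRanking:
    """Aggregate a feature ranking to loci (max member-SNP score)."""
    snp_scores = snp_scores_from_features(fr)
    locus_scores: Dict[int, float] = {}
    for snp, s in snp_scores.items():
        if snp < 0 or snp >= part.locus_of_snp.size:
            raise ValueError(f"feature maps to unknown SNP index {snp}")
        li = int(part.locus_of_snp[snp])
        if li not in locus_scores or s > locus_scores[li]:
            locus_scores[li] = s
    loci = [part.loci[li] for li in locus_scores]
    scores = np.array([locus_scores[li] for li in locus_scores])
    return LocusRanking(
        loci=loci,
        scores=scores,
        criterion=fr.criterion,
        model_family=fr.model_family,
        fold=fr.fold,
    )
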