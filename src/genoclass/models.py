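"""Classifier adapters, the random-weight null, CV selection and AUC.

All model families are exposed through one adapter, :class:`FittedModel`,
which maps an encoded feature matrix to case probabilities in [0, 1] and
exports per-feature weights (linear and random families) or split gains
(tree families).  Families:

``lr_l1`` / ``lr_l2`` / ``lr_elasticnet``
    Penalized logistic regression (scikit-learn).  Scores are reproduced
    as ``sigmoid(w . x + b)`` from the exported weights.
``gbt``
    Gradient-boosted decision trees (LightGBM); exports the library's
    per-feature ``gain``.
``nn_dense`` / ``nn_residual``
    Fully connected feed-forward network with ReLU hidden layers of equal
    width and a sigmoid output, trained with Adam and early stopping on a
    held-out validation split.  The residual variant requires an odd
    number of hidden layers: the first layer projects to the hidden width
    and each subsequent pair forms a full pre-activation residual block.
``random``
    i.i.d. standard-normal weights on the input features, no training —
    the null against which feature-importance artefacts are judged.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)

FAMILIES = (
    "lr_l1", "lr_l2", "lr_elasticnet", "gbt",
    "nn_dense", "nn_residual", "random",
)
LINEAR_FAMILIES = ("lr_l1", "lr_l2", "lr_elasticnet")

#: Default hyper-parameter grids (config, not code): penalty strength
#: lambda on a log grid 1e-4..1e2 (C = 1/lambda), ElasticNet mixing
#: {0.1, 0.5, 0.9}; boosted trees capped at 500 with early stopping.
DEFAULT_GRIDS: Dict[str, Dict[str, list]] = {
    "lr_l1": {"C": list(10.0 ** np.arange(-2, 5))},
    "lr_l2": {"C": list(10.0 ** np.arange(-2, 5))},
    "lr_elasticnet": {
        "C": list(10.0 ** np.arange(-2, 5)),
        "l1_ratio": [0.1, 0.5, 0.9],
    },
    "gbt": {"learning_rate": [0.05, 0.1], "num_leaves": [15, 31]},
}


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve: P(random case outscores a random control),
    ties counted 1/2 (Mann-Whitney form)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=np.float64)))


@dataclass
class ModelSpec:
    family: str
    n_hidden: int = 3
    width: int = 64
    params: Dict[str, float] = field(default_factory=dict)
    hyper_grid: Optional[Dict[str, list]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family == "nn_residual" and self.n_hidden % 2 == 0:
            raise ValueError(
                "residual networks require an odd number of hidden layers"
            )

    def grid(self) -> Dict[str, list]:
        if self.hyper_grid is not None:
            return self.hyper_grid
        return DEFAULT_GRIDS.get(self.family, {})


@dataclass
class FittedModel:
    """Uniform adapter over a trained classifier."""

    spec: ModelSpec
    _predict: Callable[[np.ndarray], np.ndarray]
    weights: Optional[np.ndarray] = None
    intercept: float = 0.0
    gains: Optional[np.ndarray] = None
    coding: Optional[str] = None
    feature_map: Optional[list] = None
    cv_auc_mean: Optional[float] = None
    cv_auc_sd: Optional[float] = None

    @property
    def is_linear(self) -> bool:
        return self.spec.family in LINEAR_FAMILIES or \
            self.spec.family == "random"

    def predict(self, X: Union[FeatureMatrix, np.ndarray]) -> np.ndarray:
        values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X)
        return self._predict(values)

    def n_nonzero_weights(self) -> Optional[int]:
        if self.weights is None:
            return None
        return int(np.count_nonzero(self.weights))


def _as_values(X: Union[FeatureMatrix, np.ndarray]) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X)


# ---------------------------------------------------------------------------
# numpy feed-forward network

class _NumpyMLP:
    """ReLU MLP with sigmoid output, Adam, early stopping; optional full
    pre-activation residual blocks (hidden count 1 + 2k)."""

    def __init__(self, n_hidden: int, width: int, residual: bool,
                 seed: int, lr: float = 1e-3, l2: float = 1e-4,
                 batch_size: int = 128, max_epochs: int = 60,
                 patience: int = 8, val_frac: float = 0.1):
        self.n_hidden = n_hidden
        self.width = width
        self.residual = residual
        self.seed = seed
        self.lr = lr
        self.l2 = l2
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_frac = val_frac

    # parameter layout: [W_in, b_in, (per block/layer W, b ...), w_out, b_out]
    def _init_params(self, d: int, rng: np.random.Generator) -> list:
        h = self.width
        params = [rng.normal(0, np.sqrt(2.0 / d), (d, h)), np.zeros(h)]
        n_inner = self.n_hidden - 1
        for _ in range(n_inner):
            params += [rng.normal(0, np.sqrt(2.0 / h), (h, h)), np.zeros(h)]
        params += [rng.normal(0, np.sqrt(2.0 / h), (h, 1)), np.zeros(1)]
        return params

    def _forward(self, X: np.ndarray, params: list):
        cache = []
        z = X @ params[0] + params[1]
        k = 2
        if self.residual:
            n_blocks = (self.n_hidden - 1) // 2
            for _ in range(n_blocks):
                Wa, ba, Wb, bb = params[k:k + 4]
                u = np.maximum(z, 0.0)
                h1 = u @ Wa + ba
                v = np.maximum(h1, 0.0)
                z_new = z + v @ Wb + bb
                cache.append((z, u, h1, v))
                z = z_new
                k += 4
        else:
            for _ in range(self.n_hidden - 1):
                W, b = params[k], params[k + 1]
                a = np.maximum(z, 0.0)
                cache.append((z, a))
                z = a @ W + b
                k += 2
        a_last = np.maximum(z, 0.0)
        o = (a_last @ params[-2] + params[-1]).ravel()
        p = sigmoid(o)
        return p, (z, a_last, cache)

    def _backward(self, X, y, params, p, fwd):
        z_last, a_last, cache = fwd
        n = X.shape[0]
        grads = [np.zeros_like(w) for w in params]
        do = ((p - y) / n)[:, None]
        grads[-2] = a_last.T @ do
        grads[-1] = do.sum(axis=0)
        dz = (do @ params[-2].T) * (z_last > 0)
        if self.residual:
            n_blocks = (self.n_hidden - 1) // 2
            k = 2 + 4 * (n_blocks - 1)
            for blk in range(n_blocks - 1, -1, -1):
                Wa, ba, Wb, bb = params[k:k + 4]
                z_in, u, h1, v = cache[blk]
                grads[k + 2] = v.T @ dz
                grads[k + 3] = dz.sum(axis=0)
                dv = dz @ Wb.T
                dh1 = dv * (h1 > 0)
                grads[k] = u.T @ dh1
                grads[k + 1] = dh1.sum(axis=0)
                dz = dz + (dh1 @ Wa.T) * (z_in > 0)
                k -= 4
        else:
            k = 2 + 2 * (self.n_hidden - 2)
            for lay in range(self.n_hidden - 2, -1, -1):
                W = params[k]
                z_in, a = cache[lay]
                grads[k] = a.T @ dz
                grads[k + 1] = dz.sum(axis=0)
                dz = (dz @ W.T) * (z_in > 0)
                k -= 2
        grads[0] = X.T @ dz
        grads[1] = dz.sum(axis=0)
        if self.l2:
            for i in range(0, len(params), 2):  # weights only, not biases
                grads[i] = grads[i] + self.l2 * params[i]
        return grads

    def fit(self, X: np.ndarray, y: np.ndarray) -> None:
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]

        # stratified validation split for early stopping
        val_idx = []
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            idx = rng.permutation(idx)
            val_idx.append(idx[: max(1, int(round(self.val_frac * idx.size)))])
        val_idx = np.concatenate(val_idx)
        tr_mask = np.ones(n, dtype=bool)
        tr_mask[val_idx] = False
        Xtr, ytr = X[tr_mask], y[tr_mask]
        Xva, yva = X[val_idx], y[val_idx]

        params = self._init_params(X.shape[1], rng)
        m_t = [np.zeros_like(w) for w in params]
        v_t = [np.zeros_like(w) for w in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_auc, best_params, wait = -np.inf, None, 0

        for _epoch in range(self.max_epochs):
            order = rng.permutation(Xtr.shape[0])
            for start in range(0, order.size, self.batch_size):
                idx = order[start:start + self.batch_size]
                p, fwd = self._forward(Xtr[idx], params)
                grads = self._backward(Xtr[idx], ytr[idx], params, p, fwd)
                t += 1
                for i in range(len(params)):
                    m_t[i] = b1 * m_t[i] + (1 - b1) * grads[i]
                    v_t[i] = b2 * v_t[i] + (1 - b2) * grads[i] ** 2
                    mhat = m_t[i] / (1 - b1 ** t)
                    vhat = v_t[i] / (1 - b2 ** t)
                    params[i] = params[i] - self.lr * mhat / (
                        np.sqrt(vhat) + eps)
            p_val, _ = self._forward(Xva, params)
            try:
                val_auc = auc(p_val, yva)
            except ValueError:  # tiny single-class validation split
                val_auc = 0.5
            if val_auc > best_auc + 1e-5:
                best_auc, wait = val_auc, 0
                best_params = [w.copy() for w in params]
            else:
                wait += 1
                if wait >= self.patience:
                    break
        self.params_ = best_params if best_params is not None else params

    def predict(self, X: np.ndarray) -> np.ndarray:
        p, _ = self._forward(np.asarray(X, dtype=np.float64), self.params_)
        return p


# ---------------------------------------------------------------------------
# fitting

def fit_model(
    spec: ModelSpec,
    X: Union[FeatureMatrix, np.ndarray],
    y: np.ndarray,
) -> FittedModel:
    """Train one model family on an encoded matrix.

    Linear and random families are deterministic under the spec seed; the
    stochastic families (gbt, nn) record their seed in the spec.
    """
    values = _as_values(X)
    y = np.asarray(y)
    classes = np.unique(y)
    if not set(classes.tolist()) <= {0, 1}:
        raise ValueError("phenotype must be binary 0/1")
    if spec.family != "random" and classes.size < 2:
        raise ValueError("training requires both classes")

    coding = X.coding if isinstance(X, FeatureMatrix) else None
    fmap = X.feature_map if isinstance(X, FeatureMatrix) else None
    kw = dict(coding=coding, feature_map=fmap)
    p = spec.params

    if spec.family in LINEAR_FAMILIES:
        if spec.family == "lr_l1":
            clf = LogisticRegression(
                l1_ratio=1.0, solver="liblinear", C=p.get("C", 1.0),
                max_iter=2000, random_state=spec.seed, tol=1e-6,
            )
        elif spec.family == "lr_l2":
            clf = LogisticRegression(
                l1_ratio=0.0, solver="lbfgs", C=p.get("C", 1.0),
                max_iter=2000, tol=1e-6,
            )
        else:
            clf = LogisticRegression(
                solver="saga",
                C=p.get("C", 1.0), l1_ratio=p.get("l1_ratio", 0.5),
                max_iter=3000, random_state=spec.seed, tol=1e-5,
            )
        clf.fit(values, y)
        w = clf.coef_[0].copy()
        b = float(clf.intercept_[0])
        return FittedModel(
            spec=spec,
            _predict=lambda V, w=w, b=b: sigmoid(V @ w + b),
            weights=w, intercept=b, **kw,
        )

    if spec.family == "gbt":
        import lightgbm as lgb

        clf = lgb.LGBMClassifier(
            n_estimators=int(p.get("n_estimators", 200)),
            learning_rate=p.get("learning_rate", 0.1),
            num_leaves=int(p.get("num_leaves", 31)),
            min_child_samples=int(p.get("min_child_samples", 20)),
            random_state=spec.seed,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbose=-1,
        )
        clf.fit(values, y)
        booster = clf.booster_
        gains = booster.feature_importance(
            importance_type="gain").astype(np.float64)
        return FittedModel(
            spec=spec,
            _predict=lambda V, b=booster: np.asarray(b.predict(V)),
            gains=gains, **kw,
        )

    if spec.family in ("nn_dense", "nn_residual"):
        net = _NumpyMLP(
            n_hidden=spec.n_hidden,
            width=spec.width,
            residual=spec.family == "nn_residual",
            seed=spec.seed,
            lr=p.get("lr", 1e-3),
            l2=p.get("l2", 1e-4),
            batch_size=int(p.get("batch_size", 128)),
            max_epochs=int(p.get("max_epochs", 60)),
        )
        net.fit(values, y)
        return FittedModel(spec=spec, _predict=net.predict, **kw)

    # random-weight null: no training
    rng = np.random.default_rng(spec.seed)
    w = rng.standard_normal(values.shape[1])
    return FittedModel(
        spec=spec,
        _predict=lambda V, w=w: sigmoid(V @ w),
        weights=w, intercept=0.0, **kw,
    )


def select_hyperparameters(
    spec: ModelSpec,
    X: Union[FeatureMatrix, np.ndarray],
    y: np.ndarray,
    k: int = 10,
) -> ModelSpec:
    """Pick the grid point maximizing mean validation AUC over k stratified
    folds; ties go to the stronger regularization (smaller C first)."""
    grid = spec.grid()
    if not grid:
        return spec
    y = np.asarray(y)
    counts = np.bincount(y, minlength=2)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smaller class count")

    names = sorted(grid)
    points = [dict(zip(names, combo))
              for combo in itertools.product(*(grid[n] for n in names))]
    # strongest regularization first so a tie (strict >) keeps it
    if "C" in names:
        points.sort(key=lambda d: d["C"])

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    splits = list(skf.split(_as_values(X), y))
    values = _as_values(X)

    best_auc, best_sd, best_point = -np.inf, 0.0, points[0]
    for point in points:
        cand = replace(spec, params={**spec.params, **point},
                       hyper_grid=None)
        fold_aucs = []
        for tr, va in splits:
            m = fit_model(cand, values[tr], y[tr])
            fold_aucs.append(auc(m.predict(values[va]), y[va]))
        mean_auc = float(np.mean(fold_aucs))
        if mean_auc > best_auc:
            best_auc, best_point = mean_auc, point
            best_sd = float(np.std(fold_aucs))
    logger.info("%s: selected %s (cv AUC %.4f)",
                spec.family, best_point, best_auc)
    out = replace(spec, params={**spec.params, **best_point})
    # cross-validation summary of the winning point (sklearn-style
    # fitted-attribute naming)
    out.cv_auc_mean_ = best_auc
    out.cv_auc_sd_ = best_sd
    return out


def ensemble_average(
    models: Sequence[FittedModel], X: Union[FeatureMatrix, np.ndarray]
) -> np.ndarray:
    """Unweighted mean of member probabilities (the averaging ensemble)."""
    if len(models) < 2:
        raise ValueError("ensemble needs at least two members")
    codings = {m.coding for m in models if m.coding is not None}
    if isinstance(X, FeatureMatrix):
        codings.add(X.coding)
    if len(codings) > 1:
        raise ValueError(f"members trained on mixed codings: {codings}")
    return np.mean([m.predict(X) for m in models], axis=0)
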