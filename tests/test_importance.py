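import numpy as np
import pandas as pd
import pytest

from genoclass import (
    FeatureMatrix,
    ModelSpec,
    build_partition,
    encode,
    fit_model,
    gain_importance,
    pfi,
    to_locus_ranking,
    weight_importance,
)
from genoclass.importance import FeatureRanking, snp_scores_from_features
from genoclass.models import FittedModel, sigmoid


def linear_model(weights, intercept=0.0, feature_map=None):
    """Hand-built linear scorer for controlled importance tests."""
    w = np.asarray(weights, dtype=np.float64)
    return FittedModel(
        spec=ModelSpec("random"),
        _predict=lambda V: sigmoid(V @ w + intercept),
        weights=w,
        intercept=intercept,
        feature_map=feature_map,
    )


class TestPfi:
    def test_constant_feature_scores_exactly_zero(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.full(200, 3.0), rng.normal(size=200)])
        y = (X[:, 1] > 0).astype(int)
        m = linear_model([5.0, 2.0])
        fr = pfi(m, X, y, n_perm=5, seed=1)
        scores = dict(zip(fr.feature_ids, fr.scores))
        assert scores[0] == 0.0

    def test_zero_weight_feature_scores_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(400, 2))
        y = (X[:, 0] + 0.3 * rng.normal(size=400) > 0).astype(int)
        m = linear_model([2.0, 0.0])
        fr = pfi(m, X, y, n_perm=10, seed=2)
        scores = dict(zip(fr.feature_ids, fr.scores))
        assert scores[1] == pytest.approx(0.0, abs=0.02)
        assert scores[0] > 0.1

    def test_strong_feature_outranks_weak_over_seeds(self):
        rng = np.random.default_rng(7)
        n = 300
        X = rng.normal(size=(n, 2))
        logits = 2.0 * X[:, 0] + 0.4 * X[:, 1]
        y = (rng.random(n) < sigmoid(logits)).astype(int)
        m = linear_model([2.0, 0.4])
        wins = sum(
            pfi(m, X, y, n_perm=10, seed=s).feature_ids[0] == 0
            for s in range(10)
        )
        assert wins >= 9

    def test_nonlinear_model_uses_generic_path(self, signal_ds):
        X = encode(signal_ds, "sum")
        m = fit_model(ModelSpec("gbt", params={"n_estimators": 50}, seed=1),
                      X, signal_ds.phenotype)
        fr = pfi(m, X, signal_ds.phenotype, n_perm=2, seed=3)
        assert fr.scores.max() > 0

    def test_agrees_with_sklearn_permutation_importance(self):
        # dual route: the same fitted logistic model scored by
        # sklearn.inspection.permutation_importance with the AUC scorer
        from sklearn.inspection import permutation_importance
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(11)
        n = 500
        X = rng.normal(size=(n, 4))
        logits = 1.5 * X[:, 0] - 1.0 * X[:, 1] + 0.4 * X[:, 2]
        y = (rng.random(n) < sigmoid(logits)).astype(int)
        clf = LogisticRegression(C=1.0).fit(X, y)

        ours = linear_model(clf.coef_[0], float(clf.intercept_[0]))
        fr = pfi(ours, X, y, n_perm=30, seed=0)
        our_scores = np.empty(4)
        our_scores[fr.feature_ids] = fr.scores

        ref = permutation_importance(
            clf, X, y, scoring="roc_auc", n_repeats=30, random_state=0
        ).importances_mean
        assert np.allclose(our_scores, ref, atol=0.02)
        assert np.array_equal(np.argsort(our_scores),
                              np.argsort(ref))

    def test_n_perm_validation(self):
        m = linear_model([1.0])
        with pytest.raises(ValueError):
            pfi(m, np.zeros((4, 1)), np.array([0, 1, 0, 1]), n_perm=0)


class TestWeightAndGain:
    def test_weight_ranking_by_absolute_value(self):
        m = linear_model([-2.0, 1.0])
        fr = weight_importance(m)
        assert list(fr.feature_ids) == [0, 1]
        assert list(fr.scores) == [2.0, 1.0]

    def test_all_zero_weights_keep_index_order(self):
        m = linear_model([0.0, 0.0, 0.0])
        fr = weight_importance(m)
        assert list(fr.feature_ids) == [0, 1, 2]
        assert (fr.scores == 0).all()

    def test_single_split_tree_gain_ranks_informative_feature(self):
        # one feature separates classes, the other is noise: a single
        # boosted stump must attribute its whole gain to feature 0
        rng = np.random.default_rng(5)
        n = 400
        x0 = rng.integers(0, 3, size=n).astype(float)
        y = (x0 >= 1).astype(int)
        X = np.column_stack([x0, rng.normal(size=n)])
        m = fit_model(
            ModelSpec("gbt", params={"n_estimators": 1, "num_leaves": 2,
                                     "min_child_samples": 5}, seed=0),
            X, y,
        )
        fr = gain_importance(m)
        assert fr.feature_ids[0] == 0
        scores = dict(zip(fr.feature_ids, fr.scores))
        assert scores[1] == 0.0

    def test_capability_errors(self, signal_ds):
        X = encode(signal_ds, "sum")
        gbt = fit_model(ModelSpec("gbt", params={"n_estimators": 10}),
                        X, signal_ds.phenotype)
        with pytest.raises(ValueError, match="weights"):
            weight_importance(gbt)
        lin = linear_model([1.0])
        with pytest.raises(ValueError, match="gains"):
            gain_importance(lin)


class TestPartition:
    def _meta(self, bps, chroms=None):
        m = len(bps)
        return pd.DataFrame(
            {
                "snp": [f"s{j}" for j in range(m)],
                "chrom": chroms or [1] * m,
                "bp": bps,
                "a1": "A",
                "a2": "G",
            }
        )

    def test_window_boundaries(self):
        part = build_partition(self._meta([499_999, 500_001]))
        w = [part.loci[i][1] for i in part.locus_of_snp]
        assert w == [0, 1]

    def test_shift_moves_boundary(self):
        meta = self._meta([400_000])
        w0 = build_partition(meta, shift_bp=0)
        wb = build_partition(meta, shift_bp=250_000)
        assert w0.loci[w0.locus_of_snp[0]][1] == 0
        assert wb.loci[wb.locus_of_snp[0]][1] == 1

    def test_same_window_same_locus(self):
        part = build_partition(self._meta([100, 499_000]))
        assert part.locus_of_snp[0] == part.locus_of_snp[1]
        assert part.n_loci == 1

    def test_chromosomes_never_share_loci(self):
        part = build_partition(self._meta([100, 100], chroms=[1, 2]))
        assert part.n_loci == 2

    def test_nonpositive_bp_rejected(self):
        with pytest.raises(ValueError):
            build_partition(self._meta([0]))


class TestLocusRanking:
    def _ranking(self, scores, feature_map=None):
        return FeatureRanking(
            feature_ids=np.arange(len(scores)),
            scores=np.asarray(scores, dtype=float),
            criterion="weight",
            model_family="lr_l1",
            feature_map=feature_map,
        )

    def _meta(self, bps):
        return pd.DataFrame(
            {
                "snp": [f"s{j}" for j in range(len(bps))],
                "chrom": 1,
                "bp": bps,
                "a1": "A",
                "a2": "G",
            }
        )

    def test_one_snp_per_locus_preserves_order(self):
        part = build_partition(self._meta([100, 600_000, 1_200_000]))
        lr = to_locus_ranking(self._ranking([1.0, 3.0, 2.0]), part)
        assert list(lr.scores) == [3.0, 2.0, 1.0]

    def test_locus_takes_max_member_score(self):
        part = build_partition(self._meta([100, 200]))
        lr = to_locus_ranking(self._ranking([5.0, 3.0]), part)
        assert len(lr) == 1
        assert lr.scores[0] == 5.0

    def test_multicolumn_coding_collapses_by_max(self):
        # 3 OHE columns of one SNP scoring (1, 4, 2) -> SNP score 4
        fmap = [(0, "AA"), (0, "Aa"), (0, "aa")]
        fr = self._ranking([1.0, 4.0, 2.0], feature_map=fmap)
        assert snp_scores_from_features(fr) == {0: 4.0}
        part = build_partition(self._meta([100]))
        lr = to_locus_ranking(fr, part)
        assert lr.scores[0] == 4.0

    def test_equal_scores_in_window_permutation_invariant(self):
        part = build_partition(self._meta([100, 200, 300]))
        a = to_locus_ranking(self._ranking([2.0, 2.0, 1.0]), part)
        b = to_locus_ranking(self._ranking([2.0, 1.0, 2.0]), part)
        assert a.loci == b.loci
        assert np.array_equal(a.scores, b.scores)

    def test_shift_regroups_but_preserves_snp_scores(self):
        meta = self._meta([100, 400_000, 600_000])
        fr = self._ranking([3.0, 2.0, 1.0])
        part0 = build_partition(meta, shift_bp=0)
        partb = build_partition(meta, shift_bp=250_000)
        # the underlying SNP scores are partition-independent
        assert snp_scores_from_features(fr) == {0: 3.0, 1: 2.0, 2: 1.0}
        # but the grouping moves: shift 0 pairs SNPs 0-1, shift 250 kb
        # pairs SNPs 1-2
        assert part0.locus_of_snp[0] == part0.locus_of_snp[1]
        assert partb.locus_of_snp[1] == partb.locus_of_snp[2]
        lr0 = to_locus_ranking(fr, part0)
        lrb = to_locus_ranking(fr, partb)
        assert sorted(lr0.scores.tolist()) == [1.0, 3.0]
        assert sorted(lrb.scores.tolist()) == [2.0, 3.0]

    def test_unmapped_feature_rejected(self):
        fr = self._ranking([1.0, 2.0])
        part = build_partition(self._meta([100]))
        with pytest.raises(ValueError, match="unknown SNP"):
            to_locus_ranking(fr, part)
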