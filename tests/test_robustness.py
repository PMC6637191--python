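import itertools
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from genoclass import (
    combine_rankings,
    intersection_curve,
    overlap_metrics,
    pairwise_summary,
    robustness_R,
    spearman_top,
)
from genoclass.importance import LocusRanking


def oracle_R(lists, x):
    """Brute-force oracle: tally prefix appearances, sum the x largest."""
    tally = {}
    for lst in lists:
        for locus in list(lst)[:x]:
            tally[locus] = tally.get(locus, 0) + 1
    best = sorted(tally.values(), reverse=True)[:x]
    return sum(best) / (len(lists) * x)


def ranking(loci):
    n = len(loci)
    return LocusRanking(loci=list(loci),
                        scores=np.arange(n, 0, -1, dtype=float))


class TestRobustnessR:
    def test_identical_lists_give_one(self):
        lists = [["a", "b", "c", "d"]] * 3
        for x in (1, 2, 4):
            assert robustness_R(lists, x) == 1.0

    @pytest.mark.parametrize("M", [2, 3])
    def test_disjoint_prefixes_give_one_over_M(self, M):
        lists = [[f"{i}_{j}" for j in range(4)] for i in range(M)]
        assert robustness_R(lists, 3) == pytest.approx(1.0 / M)

    def test_counting_example(self):
        # prefixes {A,B,C} and {A,B,D}: counts A:2 B:2 and one of C/D:1
        assert robustness_R([["A", "B", "C"], ["A", "B", "D"]], 3) \
            == pytest.approx(5.0 / 6.0)

    def test_exhaustive_pairs_over_four_loci(self):
        perms = list(itertools.permutations("abcd"))
        for a, b in itertools.product(perms[::3], perms[::3]):
            for x in (1, 2, 3, 4):
                assert robustness_R([a, b], x) == pytest.approx(
                    oracle_R([a, b], x)
                )

    def test_random_triples_over_six_loci_match_oracle(self):
        rng = np.random.default_rng(0)
        loci = list("abcdef")
        for _ in range(500):
            lists = [rng.permutation(loci).tolist() for _ in range(3)]
            x = int(rng.integers(1, 5))
            assert robustness_R(lists, x) == pytest.approx(
                oracle_R(lists, x)
            )

    def test_invariant_to_relabeling_and_list_order(self):
        rng = np.random.default_rng(1)
        loci = list(range(6))
        lists = [rng.permutation(loci).tolist() for _ in range(3)]
        relabel = {l: f"L{l}" for l in loci}
        relabeled = [[relabel[l] for l in lst] for lst in lists]
        for x in (1, 3, 4):
            r = robustness_R(lists, x)
            assert robustness_R(relabeled, x) == pytest.approx(r)
            assert robustness_R(lists[::-1], x) == pytest.approx(r)

    def test_range_bounds(self):
        rng = np.random.default_rng(2)
        loci = list(range(8))
        for _ in range(100):
            lists = [rng.permutation(loci).tolist() for _ in range(3)]
            r = robustness_R(lists, 4)
            assert 1.0 / 3.0 - 1e-12 <= r <= 1.0 + 1e-12

    def test_x_beyond_list_length_rejected(self):
        with pytest.raises(ValueError):
            robustness_R([["a", "b"]], 3)

    def test_accepts_locus_rankings(self):
        a = ranking([("1", 0), ("1", 1), ("2", 0)])
        assert robustness_R([a, a], 2) == 1.0


class TestSpearmanTop:
    def _oracle(self, ra, rb):
        # textbook sum-of-squared-rank-differences formula (no ties)
        d2 = np.sum((np.asarray(ra) - np.asarray(rb)) ** 2)
        n = len(ra)
        return 1 - 6 * d2 / (n * (n ** 2 - 1))

    def test_identical_lists(self):
        a = ["a", "b", "c", "d"]
        assert spearman_top(a, a, 3) == pytest.approx(1.0)

    def test_reversed_common_topx(self):
        a, b = ["a", "b", "c", "d"], ["c", "b", "a", "d"]
        expected = self._oracle([1, 2, 3], [3, 2, 1])
        assert spearman_top(a, b, 3) == pytest.approx(expected)

    def test_disjoint_prefixes_match_padding_oracle(self):
        a, b = ["a", "b", "p"], ["c", "d", "q"]
        # union {a,b,c,d}: ranks in a = (1,2,3,3), in b = (3,3,1,2);
        # ties present, so compare against scipy's rho on those vectors
        ra, rb = [1, 2, 3, 3], [3, 3, 1, 2]
        expected = stats.spearmanr(ra, rb).statistic
        assert spearman_top(a, b, 2) == pytest.approx(expected)

    def test_x_validation(self):
        with pytest.raises(ValueError):
            spearman_top(["a", "b"], ["a", "b"], 1)


class TestIntersectionCurve:
    def test_identical_lists_give_diagonal(self):
        a = ["a", "b", "c", "d"]
        assert np.array_equal(intersection_curve(a, a, 4), [1, 2, 3, 4])

    def test_disjoint_lists_give_zeros(self):
        assert np.array_equal(
            intersection_curve(["a", "b"], ["c", "d"], 2), [0, 0]
        )

    def test_prefix_enumeration_example(self):
        a, b = ["L1", "L2", "L3"], ["L3", "L9", "L1"]
        # enumeration: {L1}∩{L3}=∅; {L1,L2}∩{L3,L9}=∅;
        # {L1,L2,L3}∩{L3,L9,L1}={L1,L3}
        assert np.array_equal(intersection_curve(a, b, 3), [0, 0, 2])

    def test_matches_prefix_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        loci = list(range(15))
        for _ in range(30):
            a = rng.permutation(loci).tolist()
            b = rng.permutation(loci).tolist()
            expected = [
                len(set(a[:x]) & set(b[:x])) for x in range(1, 11)
            ]
            assert np.array_equal(intersection_curve(a, b, 10), expected)

    def test_monotone_with_bounded_increments(self):
        rng = np.random.default_rng(3)
        loci = list(range(20))
        for _ in range(50):
            a = rng.permutation(loci).tolist()
            b = rng.permutation(loci).tolist()
            c = intersection_curve(a, b, 20)
            d = np.diff(np.concatenate([[0], c]))
            assert set(d.tolist()) <= {0, 1, 2}
            assert (c <= np.arange(1, 21)).all()


class TestCombineRankings:
    def test_identical_lists_returned(self):
        a = ["x", "y", "z"]
        assert combine_rankings([a, a, a]) == a

    def test_tie_at_equal_entry_broken_by_id(self):
        # A and B both enter at x=2 with equal rank sums -> id order
        assert combine_rankings([["A", "B", "C"], ["B", "A", "C"]]) \
            == ["A", "B", "C"]

    def test_singleton_common_locus_enters_at_its_worst_rank(self):
        a = ["L", "p", "q"]
        b = ["u", "v", "L"]
        combined = combine_rankings([a, b])
        assert combined[0] == "L"

    def test_rank_sum_orders_non_intersection(self):
        a = ["A", "B", "p"]
        b = ["A", "q", "B"]
        combined = combine_rankings([a, b])
        # A enters at x=1; B at x=3; then p (ranks 3 + 4) and q (4 + 2)
        assert combined[:2] == ["A", "B"]
        assert set(combined[2:]) == {"p", "q"}
        assert combined[2] == "q"  # rank sum 6 < 7

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            combine_rankings([])


class TestPairwiseSummary:
    def _rankings(self, n_folds, models=("lr",), identical=True, seed=0):
        rng = np.random.default_rng(seed)
        loci = [("1", i) for i in range(12)]
        out = {}
        for m in models:
            for f in range(n_folds):
                order = loci if identical else rng.permutation(
                    len(loci)).tolist()
                lst = loci if identical else [loci[i] for i in order]
                out[(m, f)] = ranking(lst)
        return out

    def test_ten_folds_give_45_pairs(self):
        df = pairwise_summary(self._rankings(10), "intra", xs=[5])
        assert df["n_pairs"].iloc[0] == 45

    def test_two_folds_give_one_pair(self):
        df = pairwise_summary(self._rankings(2), "intra", xs=[5])
        assert df["n_pairs"].iloc[0] == 1

    def test_identical_rankings_mean_one_se_zero(self):
        df = pairwise_summary(self._rankings(10), "intra", xs=[3, 6])
        assert (df["mean"] == 1.0).all()
        assert (df["se"] == 0.0).all()

    def test_between_mode_pairs_per_fold(self):
        rk = self._rankings(10, models=("lr", "gbt"), identical=False,
                            seed=4)
        df = pairwise_summary(rk, "between", xs=[5])
        assert df["n_pairs"].iloc[0] == 10
        assert df["group"].iloc[0] == "gbt|lr"

    def test_between_mode_requires_fold_alignment(self):
        rk = self._rankings(3, models=("lr", "gbt"))
        del rk[("gbt", 1)]
        with pytest.raises(ValueError, match="fold"):
            pairwise_summary(rk, "between", xs=[2])

    def test_intra_requires_two_folds(self):
        with pytest.raises(ValueError):
            pairwise_summary(self._rankings(1), "intra", xs=[2])


class TestOverlapMetrics:
    def test_run_against_itself_is_100(self):
        snps = [f"s{i}" for i in range(150)]
        loci = [f"l{i}" for i in range(120)]
        rep = overlap_metrics(snps, loci, snps, loci, gwas_loci=loci)
        assert rep.I_SNP == rep.I_Loci == 100.0
        assert rep.I_topSNP == rep.I_topLoci == 100.0
        assert rep.I_Loci_GWAS == rep.I_topLoci_GWAS == 100.0

    def test_disjoint_runs_are_0(self):
        rep = overlap_metrics(["a"], ["la"], ["b"], ["lb"])
        assert rep.I_SNP == rep.I_Loci == 0.0

    def test_half_shared_top_loci(self):
        run = [f"l{i}" for i in range(100)]
        ref = [f"l{i}" for i in range(50)] + [f"x{i}" for i in range(50)]
        rep = overlap_metrics(run, run, ref, ref, top=100)
        assert rep.I_topLoci == 50.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            overlap_metrics(["a"], ["l"], [], [])
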