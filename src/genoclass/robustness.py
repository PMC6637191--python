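"""Agreement statistics for ranked locus lists.

The central statistic is the robustness

    R = (sum_{i=1..x} a_i) / (M * x)

over M ranked lists: count how often each locus appears among the M top-x
prefixes, take the x loci with the largest appearance counts (ties broken
by ascending locus id), and divide their total appearances by M*x.  R lies
in [1/M, 1]: 1 for identical prefixes, 1/M for pairwise disjoint ones.

Also provided: a Spearman coefficient over the union of two top-x sets
(absent loci padded at rank x+1), the common-loci-versus-x intersection
curve, a rank combination across models (order of appearance in the
intersection of prefixes), per-fold/per-model robustness summaries, and
set-overlap percentages against a reference run or GWAS locus list.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Hashable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .importance import LocusRanking


def _prefix(lst, x: int) -> list:
    items = lst.loci if isinstance(lst, LocusRanking) else list(lst)
    if x > len(items):
        raise ValueError(f"x={x} exceeds list length {len(items)}")
    return list(items[:x])


# ---------------------------------------------------------------------------
# robustness R

def robustness_R(lists: Sequence, x: int) -> float:
    """Robustness of M ranked lists at prefix length x (in [1/M, 1])."""
    if x < 1:
        raise ValueError("x must be >= 1")
    prefixes = [_prefix(q, x) for q in lists]
    M = len(prefixes)
    if M < 1:
        raise ValueError("need at least one list")
    counts = Counter(itertools.chain.from_iterable(prefixes))
    top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:x]
    return sum(c for _, c in top) / (M * x)


def spearman_top(a, b, x: int) -> float:
    """Spearman coefficient over the union of the two top-x sets.

    A locus absent from one list is assigned rank x+1 in that list.
    """
    if x < 2:
        raise ValueError("x must be >= 2")
    ta, tb = _prefix(a, x), _prefix(b, x)
    pos_a = {locus: i + 1 for i, locus in enumerate(ta)}
    pos_b = {locus: i + 1 for i, locus in enumerate(tb)}
    union = sorted(set(ta) | set(tb))
    ra = np.array([pos_a.get(l, x + 1) for l in union], dtype=np.float64)
    rb = np.array([pos_b.get(l, x + 1) for l in union], dtype=np.float64)
    rho = stats.spearmanr(ra, rb).statistic
    return float(rho)


def intersection_curve(a, b, x_max: int) -> np.ndarray:
    """|top-x(a) ∩ top-x(b)| for x = 1..x_max (non-decreasing, <= x)."""
    ta, tb = _prefix(a, x_max), _prefix(b, x_max)
    seen_a: set = set()
    seen_b: set = set()
    curve = np.zeros(x_max, dtype=np.int64)
    common = 0
    for x in range(x_max):
        la, lb = ta[x], tb[x]
        seen_a.add(la)
        seen_b.add(lb)
        if la == lb:
            common += 1
        else:
            if la in seen_b:
                common += 1
            if lb in seen_a:
                common += 1
        curve[x] = common
    return curve


# ---------------------------------------------------------------------------
# combining model rankings

def combine_rankings(lists: Sequence) -> List[Hashable]:
    """Combined locus order: a locus enters at the smallest x at which it
    belongs to every list's top-x.

    Ties at equal x are broken by ascending sum of individual ranks, then
    by locus id; loci never in the full intersection are appended last by
    rank sum (absent loci count as length+1).
    """
    if not lists:
        raise ValueError("no lists to combine")
    items = [list(q.loci) if isinstance(q, LocusRanking) else list(q)
             for q in lists]
    pos = [{locus: i + 1 for i, locus in enumerate(lst)} for lst in items]
    universe = sorted(set(itertools.chain.from_iterable(items)))

    def rank_sum(locus) -> float:
        return sum(p.get(locus, len(lst) + 1)
                   for p, lst in zip(pos, items))

    entry_x: Dict[Hashable, int] = {}
    for locus in universe:
        if all(locus in p for p in pos):
            entry_x[locus] = max(p[locus] for p in pos)

    combined = sorted(
        entry_x,
        key=lambda l: (entry_x[l], rank_sum(l), l),
    )
    rest = sorted(
        (l for l in universe if l not in entry_x),
        key=lambda l: (rank_sum(l), l),
    )
    return combined + rest


# ---------------------------------------------------------------------------
# per-model / per-fold summaries

def pairwise_summary(
    rankings: Mapping[Tuple[str, int], LocusRanking],
    mode: str,
    xs: Sequence[int],
    metric: str = "R",
) -> pd.DataFrame:
    """Mean +/- SE robustness (or Spearman) curves over list pairs.

    ``rankings`` maps (model, fold) to a ranked locus list.  Intra mode
    pairs all C(M, 2) fold couples within each model; between mode pairs
    two models on the same fold (one couple per fold).

    Returns a tidy DataFrame with columns group, x, mean, se, n_pairs.
    """
    if mode not in ("intra", "between"):
        raise ValueError("mode must be 'intra' or 'between'")
    models = sorted({m for m, _ in rankings})
    folds = sorted({f for _, f in rankings})

    groups: Dict[str, List[Tuple[LocusRanking, LocusRanking]]] = {}
    if mode == "intra":
        for m in models:
            mf = [f for f in folds if (m, f) in rankings]
            if len(mf) < 2:
                raise ValueError(f"model {m}: need >= 2 folds")
            groups[m] = [
                (rankings[(m, f1)], rankings[(m, f2)])
                for f1, f2 in itertools.combinations(mf, 2)
            ]
    else:
        for m1, m2 in itertools.combinations(models, 2):
            pairs = []
            for f in folds:
                if (m1, f) not in rankings or (m2, f) not in rankings:
                    raise ValueError(
                        f"fold {f} missing for pair ({m1}, {m2})"
                    )
                pairs.append((rankings[(m1, f)], rankings[(m2, f)]))
            groups[f"{m1}|{m2}"] = pairs

    fn = {
        "R": lambda a, b, x: robustness_R([a, b], x),
        "spearman": spearman_top,
    }[metric]

    rows = []
    for g, pairs in groups.items():
        for x in xs:
            vals = np.array([fn(a, b, x) for a, b in pairs])
            se = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 \
                else 0.0
            rows.append(
                {"group": g, "x": int(x), "mean": float(vals.mean()),
                 "se": float(se), "n_pairs": int(vals.size)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# overlap reports

@dataclass
class OverlapReport:
    """Percentages of shared selections against a reference run."""

    I_SNP: float
    I_Loci: float
    I_topSNP: float
    I_topLoci: float
    I_Loci_GWAS: Optional[float] = None
    I_topLoci_GWAS: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "I_SNP": self.I_SNP,
            "I_Loci": self.I_Loci,
            "I_topSNP": self.I_topSNP,
            "I_topLoci": self.I_topLoci,
            "I_Loci_GWAS": self.I_Loci_GWAS,
            "I_topLoci_GWAS": self.I_topLoci_GWAS,
        }


def _pct_shared(run: set, ref: set) -> float:
    if not run:
        raise ValueError("empty selection")
    return 100.0 * len(run & ref) / len(run)


def overlap_metrics(
    run_snps: Sequence,
    run_loci: Sequence,
    ref_snps: Sequence,
    ref_loci: Sequence,
    top: int = 100,
    gwas_loci: Optional[Sequence] = None,
) -> OverlapReport:
    """Share of a run's selected SNPs/loci present in a reference run.

    ``run_snps``/``run_loci`` are ordered by importance so the top-``top``
    prefix is well defined; GWAS reference lists compare loci only.
    """
    if not ref_snps and not ref_loci:
        raise ValueError("empty reference")
    run_snps, run_loci = list(run_snps), list(run_loci)
    report = OverlapReport(
        I_SNP=_pct_shared(set(run_snps), set(ref_snps)),
        I_Loci=_pct_shared(set(run_loci), set(ref_loci)),
        I_topSNP=_pct_shared(set(run_snps[:top]), set(list(ref_snps)[:top])),
        I_topLoci=_pct_shared(set(run_loci[:top]), set(list(ref_loci)[:top])),
    )
    if gwas_loci is not None:
        gset = set(gwas_loci)
        report.I_Loci_GWAS = _pct_shared(set(run_loci), gset)
        report.I_topLoci_GWAS = _pct_shared(set(run_loci[:top]), gset)
    return report
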