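"""Ranking evaluation against an essential-protein reference.

Implements the standard benchmarks of the essential-protein literature:
top-k% recognition accuracy, the jackknife cumulative-count curve, ROC and
precision-recall curves with trapezoidal AUC (via scikit-learn), and
pairwise top-n set-difference statistics for comparing two methods.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from sklearn import metrics as skmetrics

from .io import EssentialSet, RankedList

DEFAULT_K_PERCENTS = (1, 5, 10, 15, 20, 25)


@dataclasses.dataclass
class EvalReport:
    """Accuracy table, jackknife curve, ROC/PR points and AUC for one
    ranking."""

    topk: dict[float, float]            # k% -> accuracy in [0, 100]
    jackknife: np.ndarray               # cumulative essentials per rank
    roc: tuple[np.ndarray, np.ndarray]  # (fpr, tpr)
    pr: tuple[np.ndarray, np.ndarray]   # (recall, precision)
    auc: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "topk_accuracy_percent": {str(k): round(v, 2)
                                      for k, v in self.topk.items()},
            "auc": self.auc,
            "jackknife_max_rank": int(len(self.jackknife)),
            "jackknife_final_count": int(self.jackknife[-1])
            if len(self.jackknife) else 0,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclasses.dataclass
class RankingDifference:
    """Overlap statistics between the top-n sets of two rankings."""

    top_n: int
    intersection: int
    a_only: int
    b_only: int
    pct_essential_a_only: float
    pct_essential_b_only: float
    a_only_empty: bool
    b_only_empty: bool


def _essential_ids(ess: EssentialSet | set) -> set[str]:
    return ess.proteins if isinstance(ess, EssentialSet) else set(ess)


def topk_cutoff(n: int, k_percent: float) -> int:
    """Number of candidates in the top k%: nearest-integer (half-up)
    rounding of k% of n."""
    return int(np.floor(k_percent / 100.0 * n + 0.5))


def topk_accuracy(ranked: RankedList, ess: EssentialSet | set,
                  k_percent: float) -> float:
    """Percentage of true essentials among the top k% ranked proteins."""
    if len(ranked) == 0:
        raise ValueError("empty ranking")
    m = topk_cutoff(len(ranked), k_percent)
    if m == 0:
        raise ValueError(
            f"top {k_percent}% of {len(ranked)} proteins is an empty set")
    ids = _essential_ids(ess)
    hits = sum(1 for p in ranked.proteins[:m] if p in ids)
    return 100.0 * hits / m


def topk_table(ranked: RankedList, ess: EssentialSet | set,
               k_percents=DEFAULT_K_PERCENTS) -> dict[float, float]:
    return {k: topk_accuracy(ranked, ess, k) for k in k_percents}


def jackknife_curve(ranked: RankedList, ess: EssentialSet | set,
                    max_rank: int) -> np.ndarray:
    """Cumulative count of true essentials within the top r proteins, for
    r = 1..max_rank."""
    if max_rank > len(ranked):
        raise ValueError("max_rank exceeds ranking length")
    ids = _essential_ids(ess)
    hits = np.fromiter((p in ids for p in ranked.proteins[:max_rank]),
                       dtype=int, count=max_rank)
    return np.cumsum(hits)


def roc_pr(ranked: RankedList, ess: EssentialSet | set):
    """ROC and PR curves over the score-induced ordering, plus trapezoidal
    ROC AUC. Requires both classes in the reference."""
    ids = _essential_ids(ess)
    y = np.array([p in ids for p in ranked.proteins], dtype=int)
    if y.all() or not y.any():
        raise ValueError("reference contains a single class; "
                         "ROC is undefined")
    scores = ranked.scores
    fpr, tpr, _ = skmetrics.roc_curve(y, scores)
    precision, recall, _ = skmetrics.precision_recall_curve(y, scores)
    auc = float(skmetrics.auc(fpr, tpr))
    return (fpr, tpr), (recall, precision), auc


def evaluate(ranked: RankedList, ess: EssentialSet | set,
             k_percents=DEFAULT_K_PERCENTS,
             jackknife_max_rank: int | None = None) -> EvalReport:
    """Full evaluation report for one ranking."""
    max_rank = jackknife_max_rank or min(len(ranked), 400)
    roc, pr, auc = roc_pr(ranked, ess)
    return EvalReport(topk=topk_table(ranked, ess, k_percents),
                      jackknife=jackknife_curve(ranked, ess, max_rank),
                      roc=roc, pr=pr, auc=auc)


def ranking_difference(a: RankedList, b: RankedList,
                       ess: EssentialSet | set,
                       top_n: int) -> RankingDifference:
    """Commonality/difference statistics between the top-n sets of two
    rankings: intersection size, exclusive set sizes, and the percentage of
    essentials inside each exclusive set (0 with an emptiness flag when an
    exclusive set is empty)."""
    if len(a) < top_n or len(b) < top_n:
        raise ValueError("both rankings must cover at least top_n entries")
    ids = _essential_ids(ess)
    sa = set(a.proteins[:top_n])
    sb = set(b.proteins[:top_n])
    a_only = sa - sb
    b_only = sb - sa

    def pct(s: set[str]) -> float:
        return 100.0 * sum(1 for p in s if p in ids) / len(s) if s else 0.0

    return RankingDifference(
        top_n=top_n, intersection=len(sa & sb),
        a_only=len(a_only), b_only=len(b_only),
        pct_essential_a_only=pct(a_only),
        pct_essential_b_only=pct(b_only),
        a_only_empty=not a_only, b_only_empty=not b_only)


def write_curve(points: np.ndarray | tuple, path: str | Path,
                header: str) -> None:
    """Write a curve (1-D cumulative counts or an (x, y) pair) as TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#{header}\n")
        if isinstance(points, tuple):
            for x, y in zip(*points):
                fh.write(f"{x:.6f}\t{y:.6f}\n")
        else:
            for r, v in enumerate(points, 1):
                fh.write(f"{r}\t{int(v)}\n")
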