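"""Benchmark metrics for the edge-repair and model-fitting stages.

Covers ROC/AUROC over candidate scores, the rank-based recovery weight of a
removed edge, spurious-addition statistics pooled over removal experiments,
the mean-score rule for flagging often-recovered non-true edges, and ensemble
summaries of fit classifications.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score, roc_curve

from .hill import FitResult
from .network import GeneNetwork

__all__ = [
    "RemovalExperiment",
    "roc_auroc",
    "removed_edge_rank",
    "spurious_fraction",
    "mean_score_spurious",
    "ensemble_summary",
]

Edge = tuple[str, str]


@dataclass(frozen=True)
class RemovalExperiment:
    """One leave-one-out repair run after removing a single true edge."""

    removed_edge: Edge
    candidate_scores: Mapping[Edge, float]
    threshold: float = 0.9

    def __post_init__(self) -> None:
        if self.removed_edge not in self.candidate_scores:
            raise ValueError("removed edge must be among the scored candidates")
        for e, s in self.candidate_scores.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"score for {e} outside [0, 1]: {s}")

    @property
    def added_edges(self) -> frozenset[Edge]:
        return frozenset(
            e for e, s in self.candidate_scores.items() if s >= self.threshold
        )

    def to_frame(self, true_net: GeneNetwork | None = None) -> pd.DataFrame:
        edges = sorted(self.candidate_scores)
        scores = np.array([self.candidate_scores[e] for e in edges])
        ranks = rankdata(-scores, method="average")
        rows = {
            "source": [e[0] for e in edges],
            "target": [e[1] for e in edges],
            "score": scores,
            "rank": ranks,
            "added": scores >= self.threshold,
        }
        if true_net is not None:
            rows["in_true_graph"] = [true_net.has_edge(*e) for e in edges]
        return pd.DataFrame(rows)


def roc_auroc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[np.ndarray, float]:
    """ROC curve points and AUROC for binary labels.

    The AUROC equals the Mann--Whitney probability that a random positive
    outscores a random negative, with ties counted one half.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auroc = float(roc_auc_score(labels, scores))
    return np.column_stack([fpr, tpr]), auroc


def removed_edge_rank(
    exp: RemovalExperiment, net_damaged: GeneNetwork
) -> tuple[float, float]:
    """Descending rank R of the removed edge and its recovery weight.

    The candidates must be exactly the m^2 - |E_I| non-edges of the damaged
    graph; the weight is (m^2 - |E_I| - R) / (m^2 - |E_I|), so a top-ranked
    removed edge gets weight close to 1 and a bottom-ranked one weight 0.
    Ties take the mean rank.
    """
    n_candidates = net_damaged.m**2 - net_damaged.n_edges
    cands = set(exp.candidate_scores)
    if cands != set(net_damaged.non_edges(include_self=True)):
        raise ValueError("candidates must be all non-edges of the damaged graph")
    if exp.removed_edge not in cands:
        raise ValueError("removed edge missing from candidates")
    edges = sorted(cands)
    scores = np.array([exp.candidate_scores[e] for e in edges])
    ranks = rankdata(-scores, method="average")
    R = float(ranks[edges.index(exp.removed_edge)])
    weight = (n_candidates - R) / n_candidates
    return R, weight


def spurious_fraction(experiments: Sequence[RemovalExperiment]) -> float:
    """Pooled fraction of added edges that are not the removed edge.

    Sums, over experiments, the additions other than the removed edge and
    divides by the total number of addable candidates (candidate count minus
    the removed edge, per experiment).
    """
    if not experiments:
        raise ValueError("no experiments given")
    added = sum(len(e.added_edges - {e.removed_edge}) for e in experiments)
    potential = sum(len(e.candidate_scores) - 1 for e in experiments)
    return added / potential if potential else 0.0


def mean_score_spurious(
    experiments: Sequence[RemovalExperiment],
    true_net: GeneNetwork,
    cutoff: float = 0.5,
) -> frozenset[Edge]:
    """Non-true-network pairs whose mean candidate score exceeds ``cutoff``.

    Averages each pair's score over the experiments where it appeared as a
    candidate; pairs in the true network are never flagged. The inequality is
    strict, so a pair sitting exactly at the cutoff is not flagged.
    """
    sums: dict[Edge, float] = {}
    counts: dict[Edge, int] = {}
    for exp in experiments:
        for e, s in exp.candidate_scores.items():
            sums[e] = sums.get(e, 0.0) + s
            counts[e] = counts.get(e, 0) + 1
    flagged = {
        e
        for e in sums
        if not true_net.has_edge(*e) and sums[e] / counts[e] > cutoff
    }
    return frozenset(flagged)


def ensemble_summary(results: Sequence[FitResult]) -> dict[str, int]:
    """Histogram of fit classifications over an ensemble of repeated fits."""
    if not results:
        raise ValueError("no fit results given")
    counts = Counter(r.classification for r in results)
    return dict(counts)
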