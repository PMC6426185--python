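"""Ranking metrics and neighborhood-overlap baselines.

Metrics: average precision / MAP, pairwise AUC (probability that a random
positive outscores a random negative, ties counted half), and
precision@k.  Baselines: common neighbors, Adamic-Adar, Jaccard
coefficient, and the heuristic fixed-restart-vector scheme that assigns
small restart probability to positives and large to negatives.

All metrics depend only on the induced ranking; ties in scores are broken
by ascending node index when an explicit order is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .graph_io import Graph
from .learn import TrainingInstance

__all__ = [
    "RankedResult",
    "average_precision",
    "map_score",
    "auc_pairwise",
    "precision_at_k",
    "common_neighbors",
    "adamic_adar",
    "jaccard",
    "s_rwer_vector",
]


@dataclass
class RankedResult:
    """Nodes ordered by descending score with 0/1 relevance labels."""

    nodes: np.ndarray
    scores: np.ndarray
    relevance: np.ndarray

    @classmethod
    def from_scores(
        cls,
        scores: np.ndarray,
        positives: Iterable[int],
        nodes: Sequence[int] | None = None,
    ) -> "RankedResult":
        """Rank ``nodes`` (default: all indices of ``scores``) by score.

        ``positives`` are the node indices with relevance 1; everything
        else in the evaluation universe counts as a negative.
        """
        scores = np.asarray(scores, dtype=np.float64)
        universe = np.arange(scores.shape[0]) if nodes is None else np.asarray(nodes)
        sub = scores[universe]
        order = np.lexsort((universe, -sub))
        ranked_nodes = universe[order]
        pos = set(int(p) for p in positives)
        rel = np.fromiter((1 if int(v) in pos else 0 for v in ranked_nodes),
                          dtype=np.int64, count=len(ranked_nodes))
        return cls(nodes=ranked_nodes, scores=sub[order], relevance=rel)


def _relevance(ranked) -> np.ndarray:
    if isinstance(ranked, RankedResult):
        return np.asarray(ranked.relevance, dtype=np.int64)
    return np.asarray(ranked, dtype=np.int64)


def average_precision(ranked) -> float:
    """Average precision of a ranked 0/1 relevance sequence.

    AP = mean over the positives of the precision at each positive's rank.

    Raises
    ------
    ValueError
        If no positive is present (AP is undefined).
    """
    rel = _relevance(ranked)
    npos = int(rel.sum())
    if npos == 0:
        raise ValueError("average precision undefined without positives")
    hits = np.cumsum(rel)
    ranks = np.arange(1, rel.shape[0] + 1)
    return float((hits[rel == 1] / ranks[rel == 1]).sum() / npos)


def map_score(ranked_list: Sequence) -> float:
    """Mean of per-query average precisions."""
    aps = [average_precision(r) for r in ranked_list]
    if not aps:
        raise ValueError("mean average precision needs at least one query")
    return float(np.mean(aps))


def auc_pairwise(pos_scores, neg_scores) -> float:
    """Fraction of (positive, negative) pairs with pos > neg; ties count 0.5.

    Computed via the rank-sum (Mann-Whitney U) identity, O((p+q) log(p+q)).
    """
    pos = np.asarray(pos_scores, dtype=np.float64)
    neg = np.asarray(neg_scores, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def precision_at_k(ranked, k: int) -> float:
    """Fraction of positives among the top k (denominator stays k even if
    fewer than k items were ranked)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rel = _relevance(ranked)
    return float(rel[:k].sum() / k)


def common_neighbors(g: Graph, x: int, y: int) -> int:
    """Number of shared neighbors (undirected sense)."""
    return len(g.undirected_neighbors(x) & g.undirected_neighbors(y))


def adamic_adar(g: Graph, x: int, y: int) -> float:
    """Sum of 1/ln(degree) over shared neighbors (undirected sense).

    Shared neighbors of degree <= 1 are skipped (cannot occur without
    self-loops, but ln 1 = 0 must never reach the denominator).
    """
    total = 0.0
    for z in g.undirected_neighbors(x) & g.undirected_neighbors(y):
        dz = len(g.undirected_neighbors(z))
        if dz > 1:
            total += 1.0 / log(dz)
    return total


def jaccard(g: Graph, x: int, y: int) -> float:
    """|intersection| / |union| of the two neighbor sets (0 when both empty)."""
    nx_, ny = g.undirected_neighbors(x), g.undirected_neighbors(y)
    union = nx_ | ny
    if not union:
        return 0.0
    return len(nx_ & ny) / len(union)


def s_rwer_vector(
    instance: TrainingInstance,
    n: int,
    default: float = 0.15,
    positive_value: float = 0.1,
    negative_value: float = 0.7,
) -> np.ndarray:
    """Heuristic restart vector: low restart on positives, high on negatives.

    Positives get 0.1 (the surfer lingers near nodes the query prefers),
    negatives 0.7 (the surfer flees), everything else the conventional
    ``default``.
    """
    c = np.full(n, float(default))
    c[list(instance.positives)] = positive_value
    c[list(instance.negatives)] = negative_value
    return c
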