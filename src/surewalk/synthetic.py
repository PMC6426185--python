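"""Seedable synthetic scenarios for exercising the full pipeline.

Two generators mirror the two experimental settings the package targets:

* a two-community homophilous network (planted-partition / stochastic
  block model) with binary node labels, standing in for a political-blog
  style network where edges form preferentially within ideological camps;
* a time-stamped collaboration network grown by triangle closing, where
  most new edges connect nodes that were two hops apart — the regime in
  which link-prediction candidates are restricted to 2-hop neighbors.

Both are pure functions of their parameters and an RNG seed, so every
fixture in the test suite is regenerated on the fly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .graph_io import Graph
from .learn import TrainingInstance

__all__ = [
    "LabeledGraphScenario",
    "TemporalGraphScenario",
    "RankingInstance",
    "LinkPredInstance",
    "InstanceRejected",
    "generate_sbm",
    "make_ranking_instance",
    "generate_temporal_collab",
    "make_linkpred_instance",
]


class InstanceRejected(ValueError):
    """The query node cannot yield a valid training/evaluation instance."""


@dataclass
class LabeledGraphScenario:
    """Two-block labeled graph: ``labels[i]`` is the community (0 or 1)."""

    graph: Graph
    labels: np.ndarray
    params: dict
    rng_seed: int


@dataclass
class TemporalGraphScenario:
    """Grown graph with per-edge creation times and provenance.

    ``src/dst/time`` describe edges in creation order (timestamps are
    non-decreasing step indices).  ``mode[i]`` is ``"growth"`` (a new node
    attaching), ``"closure"`` (triangle-closing edge), or ``"random"``;
    ``two_hop[i]`` records whether the endpoints were exactly two hops
    apart when the edge was created.
    """

    graph: Graph
    src: np.ndarray
    dst: np.ndarray
    time: np.ndarray
    mode: list[str]
    two_hop: np.ndarray
    params: dict
    rng_seed: int

    @property
    def n_edges(self) -> int:
        return len(self.src)


@dataclass
class RankingInstance:
    """Training labels from a query's neighborhood plus held-out test nodes.

    ``test_relevance[i]`` is 1 when ``test_nodes[i]`` shares the query's
    community.
    """

    instance: TrainingInstance
    test_nodes: np.ndarray
    test_relevance: np.ndarray


@dataclass
class LinkPredInstance:
    """Temporal link-prediction split for one query node.

    Positives are 1-hop neighbors gained in the middle time window;
    negatives are sampled nodes at hop distance >= 3 in the training
    graph; candidates are the 2-hop nodes among which future links are
    ranked; ``test_positives`` are candidates the query actually linked to
    after the second cut.
    """

    instance: TrainingInstance
    training_graph: Graph
    candidates: np.ndarray
    test_positives: np.ndarray
    t1: float
    t2: float


def generate_sbm(
    n1: int,
    n2: int,
    p_in: float,
    p_out: float,
    rng_seed: int,
) -> LabeledGraphScenario:
    """Undirected two-block random graph with within/between edge rates.

    Each within-community pair is connected independently with
    probability ``p_in`` and each cross pair with ``p_out``; assortative
    structure requires ``p_in > p_out``.  Deterministic per ``rng_seed``.
    """
    for p in (p_in, p_out):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    G = nx.stochastic_block_model(
        [n1, n2], [[p_in, p_out], [p_out, p_in]], seed=int(rng_seed)
    )
    if G.number_of_edges() == 0:
        raise ValueError("generated graph has no edges; increase sizes or rates")
    rows, cols = [], []
    for u, v in G.edges():
        rows += [u, v]
        cols += [v, u]
    n = n1 + n2
    adj = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    ).tocsr()
    labels = np.concatenate([np.zeros(n1, dtype=np.int64), np.ones(n2, dtype=np.int64)])
    return LabeledGraphScenario(
        graph=Graph(adjacency=adj, directed=False),
        labels=labels,
        params={"n1": n1, "n2": n2, "p_in": p_in, "p_out": p_out},
        rng_seed=int(rng_seed),
    )


def make_ranking_instance(
    scn: LabeledGraphScenario,
    query: int,
    min_degree: int = 5,
) -> RankingInstance:
    """Split a query's neighborhood into same/opposite-community labels.

    Positives are neighbors sharing the query's community, negatives the
    rest of the neighbors; every non-neighbor (except the query) is a test
    node, relevant when it shares the query's community.

    Raises
    ------
    InstanceRejected
        If the query's degree is below ``min_degree`` or either label set
        is empty.
    """
    nbrs = scn.graph.undirected_neighbors(query)
    if len(nbrs) < min_degree:
        raise InstanceRejected(
            f"query {query} has degree {len(nbrs)} < {min_degree}"
        )
    qlab = scn.labels[query]
    P = sorted(v for v in nbrs if scn.labels[v] == qlab)
    N = sorted(v for v in nbrs if scn.labels[v] != qlab)
    if not P or not N:
        raise InstanceRejected(
            f"query {query}: needs neighbors of both communities (|P|={len(P)}, |N|={len(N)})"
        )
    n = scn.graph.n
    test = np.array(sorted(set(range(n)) - nbrs - {query}), dtype=np.int64)
    rel = (scn.labels[test] == qlab).astype(np.int64)
    return RankingInstance(
        instance=TrainingInstance(seed=query, positives=tuple(P), negatives=tuple(N)),
        test_nodes=test,
        test_relevance=rel,
    )


def _two_hop_set(adj: list[set[int]], u: int) -> set[int]:
    out: set[int] = set()
    for v in adj[u]:
        out |= adj[v]
    return out - adj[u] - {u}


def generate_temporal_collab(
    n: int,
    steps: int,
    beta: float,
    rng_seed: int,
    edges_per_step: int = 1,
) -> TemporalGraphScenario:
    """Grow an undirected collaboration-style network by triangle closing.

    Starts from a seed triangle.  At each step a not-yet-active node (if
    any remain) joins by attaching to a uniform existing node; then
    ``edges_per_step`` internal edges are added, each closing a uniform
    open 2-hop pair with probability ``beta`` and otherwise connecting a
    uniform non-adjacent pair.  Timestamps are the step indices, so they
    are non-decreasing in creation order.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    if n < 3:
        raise ValueError("need n >= 3 for the seed triangle")
    rng = np.random.default_rng(rng_seed)
    adj: list[set[int]] = [set() for _ in range(n)]
    src: list[int] = []
    dst: list[int] = []
    time: list[int] = []
    mode: list[str] = []
    two_hop: list[bool] = []

    def add_edge(u, v, t, kind):
        was_two_hop = v in _two_hop_set(adj, u)
        adj[u].add(v)
        adj[v].add(u)
        src.append(u)
        dst.append(v)
        time.append(t)
        mode.append(kind)
        two_hop.append(was_two_hop)

    for u, v in ((0, 1), (1, 2), (0, 2)):
        add_edge(u, v, 0, "seed")
    active = 3

    for t in range(1, steps + 1):
        if active < n:
            target = int(rng.integers(active))
            add_edge(active, target, t, "growth")
            active += 1
        for _ in range(edges_per_step):
            placed = False
            if rng.random() < beta:
                # uniform open 2-hop pair: try a few uniformly drawn anchors
                for _ in range(30):
                    u = int(rng.integers(active))
                    cands = _two_hop_set(adj, u)
                    if cands:
                        v = sorted(cands)[int(rng.integers(len(cands)))]
                        add_edge(u, v, t, "closure")
                        placed = True
                        break
            if not placed:
                for _ in range(60):
                    u = int(rng.integers(active))
                    v = int(rng.integers(active))
                    if u != v and v not in adj[u]:
                        add_edge(u, v, t, "random")
                        placed = True
                        break
            # a nearly complete graph may leave nothing to add this step
    rows = np.array(src + dst, dtype=np.int64)
    cols = np.array(dst + src, dtype=np.int64)
    adj_mat = sp.coo_matrix(
        (np.ones(rows.shape[0]), (rows, cols)), shape=(n, n)
    ).tocsr()
    return TemporalGraphScenario(
        graph=Graph(adjacency=adj_mat, directed=False),
        src=np.array(src, dtype=np.int64),
        dst=np.array(dst, dtype=np.int64),
        time=np.array(time, dtype=np.float64),
        mode=mode,
        two_hop=np.array(two_hop, dtype=bool),
        params={"n": n, "steps": steps, "beta": beta,
                "edges_per_step": edges_per_step},
        rng_seed=int(rng_seed),
    )


def _graph_from_edges(n: int, pairs: Sequence[tuple[int, int]]) -> Graph:
    if not pairs:
        raise InstanceRejected("training graph has no edges")
    rows = np.array([u for u, v in pairs] + [v for u, v in pairs], dtype=np.int64)
    cols = np.array([v for u, v in pairs] + [u for u, v in pairs], dtype=np.int64)
    adj = sp.coo_matrix((np.ones(rows.shape[0]), (rows, cols)), shape=(n, n)).tocsr()
    adj.data[:] = np.minimum(adj.data, 1.0)  # parallel timestamps collapse
    return Graph(adjacency=adj, directed=False)


def make_linkpred_instance(
    scn: TemporalGraphScenario,
    query: int,
    rng_seed: int = 0,
) -> LinkPredInstance:
    """Temporal split of one query's links into train/label/test sets.

    With ``L`` the time span of the query's 1-hop edges, the cuts are
    ``t1 = t_min + 0.3 L`` and ``t2 = t_min + 0.7 L``.  Links after
    ``t2`` whose far endpoint sits exactly two hops from the query in the
    training graph (all edges minus those test links) become test
    positives; neighbors gained in ``(t1, t2]`` are training positives;
    equally many training negatives are drawn uniformly without
    replacement among nodes three or more hops away.
    """
    s = int(query)
    inc = [
        (i, int(scn.src[i] if scn.dst[i] == s else scn.dst[i]))
        for i in range(scn.n_edges)
        if s in (int(scn.src[i]), int(scn.dst[i]))
    ]
    if not inc:
        raise InstanceRejected(f"query {s} has no incident edges")
    times = scn.time[[i for i, _ in inc]]
    t_min, t_max = float(times.min()), float(times.max())
    L = t_max - t_min
    if L <= 0:
        raise InstanceRejected(f"query {s}: all incident edges share one timestamp")
    t1 = t_min + 0.3 * L
    t2 = t_min + 0.7 * L

    test_edge_idx = {i for i, _ in inc if scn.time[i] > t2}
    positives = sorted({v for i, v in inc if t1 < scn.time[i] <= t2})
    if not positives:
        raise InstanceRejected(f"query {s}: no neighbors gained in (t1, t2]")

    n = scn.graph.n
    train_pairs = [
        (int(scn.src[i]), int(scn.dst[i]))
        for i in range(scn.n_edges)
        if i not in test_edge_idx
    ]
    training_graph = _graph_from_edges(n, train_pairs)

    Gtrain = nx.Graph(train_pairs)
    Gtrain.add_nodes_from(range(n))
    dist = nx.single_source_shortest_path_length(Gtrain, s)
    candidates = np.array(sorted(v for v, d in dist.items() if d == 2), dtype=np.int64)
    test_pos = np.array(
        sorted({v for i, v in inc if i in test_edge_idx} & set(candidates.tolist())),
        dtype=np.int64,
    )
    if test_pos.size == 0:
        raise InstanceRejected(f"query {s}: no test links to 2-hop candidates")

    far = sorted(v for v in range(n) if v != s and dist.get(v, n + 3) >= 3)
    if len(far) < len(positives):
        raise InstanceRejected(f"query {s}: too few distance>=3 nodes to sample negatives")
    rng = np.random.default_rng(rng_seed)
    negatives = sorted(rng.choice(far, size=len(positives), replace=False).tolist())

    return LinkPredInstance(
        instance=TrainingInstance(seed=s, positives=tuple(positives),
                                  negatives=tuple(negatives)),
        training_graph=training_graph,
        candidates=candidates,
        test_positives=test_pos,
        t1=t1,
        t2=t2,
    )


def write_temporal_edge_list(scn: TemporalGraphScenario, path: str | Path) -> None:
    """Write ``src dst timestamp`` TSV in creation order."""
    with open(path, "w") as fh:
        for u, v, t in zip(scn.src.tolist(), scn.dst.tolist(), scn.time.tolist()):
            fh.write(f"{u}\t{v}\t{t:g}\n")


def write_instance_json(instance: TrainingInstance, path: str | Path,
                        extra: dict | None = None) -> None:
    payload = {
        "seed": instance.seed,
        "positives": list(instance.positives),
        "negatives": list(instance.negatives),
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=lambda o: np.asarray(o).tolist())
        fh.write("\n")
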