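"""Graph, label, and score input/output, and row normalization.

Graphs are held as SciPy CSR adjacency matrices over contiguous 0-based
node indices.  External node identifiers (strings, or non-contiguous
integers) are mapped on load and the mapping is kept on the :class:`Graph`
so scores and rankings can be written back in the caller's vocabulary.

The transition structure of the random walk is the row-normalized
adjacency ``A_tilde`` with ``A_tilde[i, j] = A[i, j] / sum_j A[i, j]``.
Rows with zero out-degree (dangling nodes) are preserved as all-zero rows
and their indices recorded; the walk semantics for dangling nodes are
resolved in :mod:`surewalk.rwer`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Graph",
    "RowStochasticMatrix",
    "LabelSet",
    "GraphFormatError",
    "read_edge_list",
    "write_edge_list",
    "read_matrix_market",
    "row_normalize",
    "read_labels",
    "write_labels",
    "write_scores",
    "read_scores",
    "rank_nodes",
]


class GraphFormatError(ValueError):
    """Raised for malformed graph, label, or score files."""


@dataclass
class Graph:
    """Weighted graph stored as a CSR adjacency matrix.

    Parameters
    ----------
    adjacency
        ``(n, n)`` CSR matrix with non-negative weights.  For an
        undirected graph the matrix is symmetric.
    directed
        Whether edge direction is meaningful.
    id_map
        Mapping from external node identifier to internal index, present
        only when the input identifiers were not already ``0..n-1``.
    """

    adjacency: sp.csr_matrix
    directed: bool = True
    id_map: dict | None = None

    def __post_init__(self) -> None:
        a = sp.csr_matrix(self.adjacency)
        a.sum_duplicates()
        a.eliminate_zeros()
        if a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if a.nnz and a.data.min() < 0:
            raise ValueError("edge weights must be non-negative")
        self.adjacency = a

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def m(self) -> int:
        """Number of stored (directed) edges."""
        return self.adjacency.nnz

    def edges(self) -> Iterator[tuple[int, int, float]]:
        coo = self.adjacency.tocoo()
        yield from zip(coo.row.tolist(), coo.col.tolist(), coo.data.tolist())

    def out_degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def undirected_neighbors(self, i: int) -> set[int]:
        """Neighbor set in the undirected sense (union of in/out), no self."""
        out = set(self.adjacency.indices[self.adjacency.indptr[i]:self.adjacency.indptr[i + 1]].tolist())
        csc = self.adjacency.tocsc()
        inc = set(csc.indices[csc.indptr[i]:csc.indptr[i + 1]].tolist())
        nbrs = out | inc
        nbrs.discard(i)
        return nbrs

    def inverse_id_map(self) -> dict:
        if self.id_map is None:
            return {}
        return {v: k for k, v in self.id_map.items()}


@dataclass
class RowStochasticMatrix:
    """Row-normalized adjacency with a record of dangling nodes.

    Every row with positive out-degree sums to 1 (within 1e-12); rows of
    dangling nodes are all-zero and their indices are listed in
    ``dangling``.
    """

    matrix: sp.csr_matrix
    dangling: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class LabelSet:
    """Positive and negative node-index sets from side information."""

    positives: frozenset[int]
    negatives: frozenset[int]

    def __post_init__(self) -> None:
        self.positives = frozenset(int(i) for i in self.positives)
        self.negatives = frozenset(int(i) for i in self.negatives)
        if self.positives & self.negatives:
            raise ValueError("a node cannot be both positive and negative")

    def validate_for_query(self, query: int) -> None:
        if query in self.positives or query in self.negatives:
            raise ValueError(f"query node {query} must not appear among the labels")


def _parse_node_token(tok: str):
    """Return an int when the token is a plain decimal integer, else the string."""
    try:
        return int(tok)
    except ValueError:
        return tok


def _build_id_map(raw_ids: set) -> tuple[dict | None, int]:
    """Map raw identifiers to contiguous 0-based indices.

    Integer identifiers forming exactly ``0..max`` are used as-is (no map);
    anything else is mapped in sorted order (ints before strings).
    """
    if all(isinstance(i, int) for i in raw_ids):
        hi = max(raw_ids)
        lo = min(raw_ids)
        if lo >= 0 and raw_ids == set(range(hi + 1)):
            return None, hi + 1
        ordered = sorted(raw_ids)
    else:
        ordered = sorted(raw_ids, key=lambda x: (isinstance(x, str), x))
    return {k: i for i, k in enumerate(ordered)}, len(ordered)


def read_edge_list(path: str | Path, directed: bool = True) -> Graph:
    """Read a TSV/whitespace edge list ``src dst [weight]`` into a Graph.

    Missing weights default to 1.  Duplicate ``(src, dst)`` pairs are
    summed.  For ``directed=False`` every edge is mirrored, so the stored
    adjacency is symmetric (self-loops are not doubled).

    Raises
    ------
    GraphFormatError
        On malformed lines (with the line number) or negative weights.
    """
    srcs: list = []
    dsts: list = []
    wts: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 'src dst [weight]', got {line!r}"
                )
            u, v = _parse_node_token(parts[0]), _parse_node_token(parts[1])
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise GraphFormatError(
                        f"{path}:{lineno}: bad weight {parts[2]!r}"
                    ) from exc
            else:
                w = 1.0
            if w < 0:
                raise GraphFormatError(f"{path}:{lineno}: negative weight {w}")
            srcs.append(u)
            dsts.append(v)
            wts.append(w)
    if not srcs:
        raise GraphFormatError(f"{path}: no edges found")

    id_map, n = _build_id_map(set(srcs) | set(dsts))
    if id_map is not None:
        srcs = [id_map[u] for u in srcs]
        dsts = [id_map[v] for v in dsts]
    rows = np.asarray(srcs, dtype=np.int64)
    cols = np.asarray(dsts, dtype=np.int64)
    data = np.asarray(wts, dtype=np.float64)
    if not directed:
        off = rows != cols  # do not double self-loops
        rows = np.concatenate([rows, cols[off]])
        cols = np.concatenate([cols, np.asarray(srcs, dtype=np.int64)[off]])
        data = np.concatenate([data, data[off]])
    adj = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    return Graph(adjacency=adj, directed=directed, id_map=id_map)


def write_edge_list(g: Graph, path: str | Path) -> None:
    """Write the graph as a TSV edge list using external identifiers.

    For undirected graphs each symmetric pair is written once (u <= v).
    """
    inv = g.inverse_id_map()
    with open(path, "w") as fh:
        for u, v, w in g.edges():
            if not g.directed and u > v:
                continue
            eu = inv.get(u, u)
            ev = inv.get(v, v)
            fh.write(f"{eu}\t{ev}\t{w:.17g}\n")


def read_matrix_market(path: str | Path, directed: bool = True) -> Graph:
    """Read a coordinate-format sparse matrix (Matrix Market) as a Graph."""
    from scipy.io import mmread

    a = sp.csr_matrix(mmread(str(path)))
    if a.nnz and a.data.min() < 0:
        raise GraphFormatError(f"{path}: negative weights not allowed")
    if not directed:
        a = a.maximum(a.T) if (a != a.T).nnz else a
    return Graph(adjacency=a, directed=directed)


def row_normalize(g: Graph) -> RowStochasticMatrix:
    """Scale every row of the adjacency to sum 1 (dangling rows kept zero)."""
    if g.m == 0:
        raise ValueError("graph has no edges")
    deg = g.out_degrees()
    dangling = np.flatnonzero(deg == 0)
    inv = np.zeros_like(deg)
    nz = deg > 0
    inv[nz] = 1.0 / deg[nz]
    mat = sp.diags(inv) @ g.adjacency
    return RowStochasticMatrix(matrix=sp.csr_matrix(mat), dangling=dangling)


def read_labels(path: str | Path, n: int | None = None,
                id_map: Mapping | None = None) -> LabelSet:
    """Read a label TSV of lines ``node-id  +1|-1`` into a LabelSet."""
    pos: set[int] = set()
    neg: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2 or parts[1] not in ("+1", "1", "-1"):
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 'node-id +1|-1', got {line!r}"
                )
            raw = _parse_node_token(parts[0])
            if id_map:
                if raw not in id_map:
                    raise GraphFormatError(f"{path}:{lineno}: unknown node {raw!r}")
                idx = id_map[raw]
            else:
                if not isinstance(raw, int):
                    raise GraphFormatError(
                        f"{path}:{lineno}: string node id {raw!r} requires an id map"
                    )
                idx = raw
            if n is not None and not (0 <= idx < n):
                raise GraphFormatError(
                    f"{path}:{lineno}: node {raw!r} outside [0, {n})"
                )
            (pos if parts[1] in ("+1", "1") else neg).add(idx)
    return LabelSet(positives=frozenset(pos), negatives=frozenset(neg))


def write_labels(labels: LabelSet, path: str | Path,
                 inverse_map: Mapping | None = None) -> None:
    inv = inverse_map or {}
    with open(path, "w") as fh:
        for i in sorted(labels.positives):
            fh.write(f"{inv.get(i, i)}\t+1\n")
        for i in sorted(labels.negatives):
            fh.write(f"{inv.get(i, i)}\t-1\n")


def rank_nodes(scores: np.ndarray, nodes: Sequence[int] | None = None) -> np.ndarray:
    """Order nodes by descending score, ties broken by ascending node index."""
    scores = np.asarray(scores, dtype=np.float64)
    idx = np.arange(scores.shape[0]) if nodes is None else np.asarray(nodes)
    order = np.lexsort((idx, -scores))
    return idx[order]


def write_scores(path: str | Path, scores: np.ndarray,
                 inverse_map: Mapping | None = None) -> None:
    """Write ``node-id  score  rank`` TSV (rank 1 = highest score)."""
    inv = inverse_map or {}
    order = rank_nodes(scores)
    rank_of = np.empty(len(order), dtype=np.int64)
    rank_of[order] = np.arange(1, len(order) + 1)
    with open(path, "w") as fh:
        for i, s in enumerate(np.asarray(scores, dtype=np.float64)):
            fh.write(f"{inv.get(i, i)}\t{s:.17g}\t{rank_of[i]}\n")


def read_scores(path: str | Path, id_map: Mapping | None = None) -> np.ndarray:
    """Read a score TSV back into a dense vector indexed by node."""
    entries: dict[int, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise GraphFormatError(f"{path}:{lineno}: expected 'node score ...'")
            raw = _parse_node_token(parts[0])
            idx = id_map[raw] if id_map else int(raw)
            entries[idx] = float(parts[1])
    n = max(entries) + 1
    out = np.zeros(n)
    for i, s in entries.items():
        out[i] = s
    return out
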