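"""Graph and bipartite-graph data model with shared linear-algebra views.

Networks are undirected simple graphs. Node labels are arbitrary strings
mapped to contiguous 0-based indices in order of first appearance; every
downstream result carries the label map so reports can use original
identifiers. Bipartite networks (drug-target, disease-gene, ...) are held
as an r x k biadjacency matrix B and expanded on demand to the monopartite
adjacency [[0, B], [B^T, 0]].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "BipartiteGraph",
    "LaplacianSpectrum",
    "CandidatePairSet",
    "read_edge_list",
    "read_bipartite_edge_list",
    "write_edge_list",
    "expand_biadjacency",
    "laplacian_spectrum",
    "transition_matrix",
    "candidate_pairs",
]

# Relative eigenvalue cutoff below which a Laplacian mode is treated as null
# space when forming the pseudoinverse.
PINV_RTOL = 1e-10


class GraphParseError(ValueError):
    """Raised for malformed or degenerate edge-list input."""


@dataclass
class Graph:
    """Undirected simple graph with string labels and contiguous indices.

    Parameters
    ----------
    node_labels : sequence of str
        Distinct labels; position defines the node index.
    edges : set of (int, int)
        Unordered index pairs stored with i < j; no self-loops.
    partition : array of int, optional
        Per-node partition id (0 = row side, 1 = column side) when the
        graph came from a bipartite expansion; None otherwise.
    """

    node_labels: list[str]
    edges: set[tuple[int, int]]
    partition: np.ndarray | None = None
    index_map: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.node_labels = list(self.node_labels)
        if len(set(self.node_labels)) != len(self.node_labels):
            raise GraphParseError("duplicate node labels")
        self.index_map = {lab: i for i, lab in enumerate(self.node_labels)}
        canon = set()
        for i, j in self.edges:
            if i == j:
                raise GraphParseError(f"self-loop on node index {i}")
            if not (0 <= i < self.n and 0 <= j < self.n):
                raise GraphParseError(f"edge ({i},{j}) out of range")
            canon.add((min(i, j), max(i, j)))
        self.edges = canon
        self._adj_cache: sp.csr_matrix | None = None

    # -- basic views ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.node_labels)

    @property
    def m(self) -> int:
        return len(self.edges)

    @property
    def A(self) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency matrix (CSR)."""
        if self._adj_cache is None:
            if self.edges:
                rows, cols = zip(*self.edges)
                r = np.array(rows + cols)
                c = np.array(cols + rows)
                data = np.ones(len(r))
                self._adj_cache = sp.csr_matrix(
                    (data, (r, c)), shape=(self.n, self.n)
                )
            else:
                self._adj_cache = sp.csr_matrix((self.n, self.n))
        return self._adj_cache

    def adjacency_dense(self) -> np.ndarray:
        return self.A.toarray()

    @property
    def k(self) -> np.ndarray:
        """Degree vector."""
        return np.asarray(self.A.sum(axis=1)).ravel()

    def neighbors(self, i: int) -> np.ndarray:
        return self.A.indices[self.A.indptr[i] : self.A.indptr[i + 1]]

    def neighbor_sets(self) -> list[set[int]]:
        return [set(self.neighbors(i)) for i in range(self.n)]

    def has_edge(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.edges

    def edge_labels(self) -> set[tuple[str, str]]:
        return {
            (self.node_labels[i], self.node_labels[j]) for i, j in self.edges
        }

    def subgraph_without_edges(
        self, removed: Iterable[tuple[int, int]]
    ) -> "Graph":
        """Same node set, with the given edges removed (for CV folds)."""
        drop = {(min(i, j), max(i, j)) for i, j in removed}
        return Graph(
            node_labels=self.node_labels,
            edges=self.edges - drop,
            partition=self.partition,
        )

    @classmethod
    def from_label_edges(
        cls,
        label_edges: Iterable[tuple[str, str]],
        node_labels: Sequence[str] | None = None,
    ) -> "Graph":
        """Build from label pairs, indexing labels by first appearance."""
        labels: list[str] = list(node_labels) if node_labels else []
        index = {lab: i for i, lab in enumerate(labels)}
        edges = set()
        for a, b in label_edges:
            for lab in (a, b):
                if lab not in index:
                    index[lab] = len(labels)
                    labels.append(lab)
            if a == b:
                continue
            i, j = index[a], index[b]
            edges.add((min(i, j), max(i, j)))
        return cls(node_labels=labels, edges=edges)


@dataclass
class BipartiteGraph:
    """Two disjoint node sets with an r x k biadjacency relation."""

    row_labels: list[str]
    col_labels: list[str]
    cross_edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        overlap = set(self.row_labels) & set(self.col_labels)
        if overlap:
            raise GraphParseError(
                f"labels appear on both sides: {sorted(overlap)[:5]}"
            )
        row_ix = {lab: i for i, lab in enumerate(self.row_labels)}
        col_ix = {lab: i for i, lab in enumerate(self.col_labels)}
        for a, b in self.cross_edges:
            if a not in row_ix or b not in col_ix:
                raise GraphParseError(f"edge ({a},{b}) not row x col")

    @property
    def r(self) -> int:
        return len(self.row_labels)

    @property
    def k(self) -> int:
        return len(self.col_labels)

    @property
    def B(self) -> sp.csr_matrix:
        row_ix = {lab: i for i, lab in enumerate(self.row_labels)}
        col_ix = {lab: i for i, lab in enumerate(self.col_labels)}
        if not self.cross_edges:
            return sp.csr_matrix((self.r, self.k))
        rows, cols = zip(*[(row_ix[a], col_ix[b]) for a, b in self.cross_edges])
        return sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(self.r, self.k)
        )


@dataclass
class LaplacianSpectrum:
    """Eigendecomposition of L = D - A and the Moore-Penrose pseudoinverse.

    ``node_vectors`` holds the spectral coordinates v^i = sqrt(Lambda+) U^T e_i
    (columns indexed by node), whose inner products reproduce L+ entries and
    therefore effective resistances and commute times.
    """

    L: np.ndarray
    L_plus: np.ndarray
    U: np.ndarray
    eigenvalues: np.ndarray

    def node_vectors(self) -> np.ndarray:
        lam = self.eigenvalues
        cutoff = PINV_RTOL * max(lam.max(), 1.0)
        inv = np.where(lam > cutoff, 1.0 / np.maximum(lam, cutoff), 0.0)
        return np.sqrt(inv)[:, None] * self.U.T

    def effective_resistance(self, i: int, j: int) -> float:
        lp = self.L_plus
        return float(lp[i, i] + lp[j, j] - 2.0 * lp[i, j])


@dataclass
class CandidatePairSet:
    """Ordered list of node-index pairs eligible for scoring."""

    pairs: list[tuple[int, int]]
    mode: str = "supplied-list"

    def __post_init__(self) -> None:
        canon = [(min(i, j), max(i, j)) for i, j in self.pairs]
        if len(set(canon)) != len(canon):
            raise ValueError("duplicate candidate pairs")
        self.pairs = canon

    def __len__(self) -> int:
        return len(self.pairs)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.pairs:
            return np.array([], dtype=int), np.array([], dtype=int)
        arr = np.asarray(self.pairs, dtype=int)
        return arr[:, 0], arr[:, 1]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _parse_lines(path) -> list[tuple[int, list[str]]]:
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) < 2:
                raise GraphParseError(
                    f"{path}:{lineno}: expected >=2 tokens, got {len(toks)}"
                )
            out.append((lineno, toks))
    return out


def read_edge_list(path) -> Graph:
    """Read a whitespace-delimited undirected edge list.

    Lines starting with '#' are comments; columns beyond the second are
    ignored; duplicate edges are merged; self-loop lines are dropped with
    a warning. An input yielding an empty graph is an error.
    """
    labels: list[str] = []
    index: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    for lineno, toks in _parse_lines(path):
        a, b = toks[0], toks[1]
        if a == b:
            warnings.warn(f"{path}:{lineno}: self-loop '{a}' dropped")
            continue
        for lab in (a, b):
            if lab not in index:
                index[lab] = len(labels)
                labels.append(lab)
        i, j = index[a], index[b]
        edges.add((min(i, j), max(i, j)))
    if not edges:
        raise GraphParseError(f"{path}: no usable edges")
    return Graph(node_labels=labels, edges=edges)


def read_bipartite_edge_list(path) -> BipartiteGraph:
    """Read a two-column cross-type edge list (first column = row side).

    A label appearing on both sides is an ambiguity error.
    """
    rows: list[str] = []
    cols: list[str] = []
    row_seen: set[str] = set()
    col_seen: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for lineno, toks in _parse_lines(path):
        a, b = toks[0], toks[1]
        if a in col_seen or b in row_seen or a == b:
            raise GraphParseError(
                f"{path}:{lineno}: label appears on both sides"
            )
        if a not in row_seen:
            row_seen.add(a)
            rows.append(a)
        if b not in col_seen:
            col_seen.add(b)
            cols.append(b)
        edges.add((a, b))
    if not edges:
        raise GraphParseError(f"{path}: no usable edges")
    return BipartiteGraph(row_labels=rows, col_labels=cols, cross_edges=edges)


def write_edge_list(g: Graph, path) -> None:
    """Write the canonical tab-delimited edge list (sorted label pairs)."""
    lines = sorted(
        tuple(sorted((g.node_labels[i], g.node_labels[j])))
        for i, j in g.edges
    )
    with open(path, "w") as fh:
        for a, b in lines:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Structural operations
# ---------------------------------------------------------------------------

def expand_biadjacency(bg: BipartiteGraph) -> Graph:
    """Expand an r x k biadjacency into the (r+k)-node adjacency.

    Row nodes occupy indices 0..r-1, column nodes r..r+k-1; the resulting
    Graph records partition membership so candidate generation can stay
    cross-partition.
    """
    if not bg.cross_edges:
        raise GraphParseError("empty bipartite graph")
    labels = list(bg.row_labels) + list(bg.col_labels)
    row_ix = {lab: i for i, lab in enumerate(bg.row_labels)}
    col_ix = {lab: bg.r + i for i, lab in enumerate(bg.col_labels)}
    edges = {(row_ix[a], col_ix[b]) for a, b in bg.cross_edges}
    partition = np.concatenate(
        [np.zeros(bg.r, dtype=int), np.ones(bg.k, dtype=int)]
    )
    return Graph(node_labels=labels, edges=edges, partition=partition)


def laplacian_spectrum(g: Graph) -> LaplacianSpectrum:
    """Eigendecompose L = D - A and form the pseudoinverse L+.

    Eigenvalues below ``PINV_RTOL * lambda_max`` are treated as zero modes
    (one per connected component), so disconnected graphs are handled: L+
    of a block-diagonal Laplacian is block-diagonal with zero cross-component
    entries.
    """
    if g.n < 2:
        raise ValueError("need at least two nodes")
    A = g.adjacency_dense()
    L = np.diag(g.k) - A
    lam, U = np.linalg.eigh(L)
    lam = np.clip(lam, 0.0, None)
    cutoff = PINV_RTOL * max(lam.max(), 1.0)
    inv = np.where(lam > cutoff, 1.0 / np.maximum(lam, cutoff), 0.0)
    L_plus = (U * inv) @ U.T
    return LaplacianSpectrum(L=L, L_plus=L_plus, U=U, eigenvalues=lam)


def transition_matrix(g: Graph) -> np.ndarray:
    """Row-stochastic random-walk matrix: row i is A_i / k_i.

    Isolated nodes get an all-zero row (no teleportation), so walk-based
    scores involving nodes with no training links are 0.
    """
    A = g.adjacency_dense()
    k = g.k
    with np.errstate(divide="ignore", invalid="ignore"):
        M = np.where(k[:, None] > 0, A / np.maximum(k, 1)[:, None], 0.0)
    return M


def candidate_pairs(
    g: Graph,
    mode: str = "all-non-adjacent",
    exclude: Iterable[tuple[int, int]] = (),
    pairs: Iterable[tuple[int, int]] | None = None,
) -> CandidatePairSet:
    """Enumerate scoring-eligible node pairs in deterministic order.

    Modes: ``all-non-adjacent`` (complement of the edge set),
    ``supplied-list`` (validate given pairs), ``cross-partition-only``
    (non-adjacent row x column pairs of an expanded bipartite graph).
    """
    excl = {(min(i, j), max(i, j)) for i, j in exclude}
    if mode == "supplied-list":
        if pairs is None:
            raise ValueError("supplied-list mode needs pairs")
        out = [
            (min(i, j), max(i, j))
            for i, j in pairs
            if not g.has_edge(i, j) and (min(i, j), max(i, j)) not in excl
        ]
        return CandidatePairSet(pairs=out, mode=mode)
    if mode == "all-non-adjacent":
        out = [
            (i, j)
            for i in range(g.n)
            for j in range(i + 1, g.n)
            if (i, j) not in g.edges and (i, j) not in excl
        ]
        return CandidatePairSet(pairs=out, mode=mode)
    if mode == "cross-partition-only":
        if g.partition is None:
            raise ValueError("graph has no partition information")
        part = g.partition
        out = [
            (i, j)
            for i in range(g.n)
            for j in range(i + 1, g.n)
            if part[i] != part[j]
            and (i, j) not in g.edges
            and (i, j) not in excl
        ]
        return CandidatePairSet(pairs=out, mode=mode)
    raise ValueError(f"unknown candidate mode: {mode!r}")
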