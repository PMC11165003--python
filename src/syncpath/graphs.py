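"""Weighted-graph ingestion, Laplacian construction and full eigendecomposition.

The synchronization-transition predictor needs the *complete* spectrum of the
graph Laplacian ``L = D - A`` together with an orthonormal eigenbasis, plus a
grouping of (numerically) degenerate eigenvalues into contiguous blocks.  Only
connected, undirected, nonnegatively weighted graphs without self-loops are
admitted: for a disconnected graph the algebraic connectivity vanishes and
every predicted coupling threshold is infinite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import scipy.io
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph

__all__ = [
    "GraphFormatError",
    "WeightedGraph",
    "EigenBlock",
    "LaplacianSpectrum",
    "read_graph",
    "write_graph",
    "laplacian_of",
    "eigendecompose",
]

#: Largest graph for which a dense full eigendecomposition is attempted.  The
#: method needs the whole spectrum, so partial iterative solvers are not a
#: substitute; beyond this size we refuse with a clear message.
MAX_DENSE_N = 20_000

_SYMMETRY_RTOL = 1e-12


class GraphFormatError(ValueError):
    """Raised for malformed, asymmetric, negative, self-looped or disconnected input."""


@dataclass
class WeightedGraph:
    """An undirected weighted graph: external node labels + adjacency matrix.

    ``weights`` is a symmetric nonnegative ``N x N`` array with zero diagonal.
    Node identity is carried by ``node_labels`` (strings, in the order of the
    matrix rows); all internal indexing is contiguous and 0-based.
    """

    node_labels: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.node_labels)
        if n < 2:
            raise GraphFormatError(f"graph must have at least 2 nodes, got {n}")
        if self.weights.shape != (n, n):
            raise GraphFormatError(
                f"adjacency shape {self.weights.shape} does not match {n} labels"
            )
        if len(set(self.node_labels)) != n:
            raise GraphFormatError("duplicate node labels")
        scale = max(1.0, float(np.abs(self.weights).max()))
        if not np.allclose(self.weights, self.weights.T, rtol=0, atol=_SYMMETRY_RTOL * scale):
            raise GraphFormatError("adjacency matrix is asymmetric beyond tolerance")
        self.weights = 0.5 * (self.weights + self.weights.T)
        if np.any(np.diag(self.weights) != 0.0):
            raise GraphFormatError("self-loops are not allowed")
        if np.any(self.weights < 0):
            raise GraphFormatError("negative edge weights are not allowed")
        if not self._connected():
            raise GraphFormatError("graph is disconnected")

    def _connected(self) -> bool:
        ncomp, _ = scipy.sparse.csgraph.connected_components(
            scipy.sparse.csr_matrix(self.weights), directed=False
        )
        return ncomp == 1

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def index_of(self, label: str) -> int:
        return self.node_labels.index(label)

    def labels_for(self, indices: Sequence[int]) -> set[str]:
        return {self.node_labels[i] for i in indices}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        n = self.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                w = self.weights[i, j]
                if w != 0.0:
                    g.add_edge(self.node_labels[i], self.node_labels[j], weight=float(w))
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "WeightedGraph":
        labels = [str(u) for u in g.nodes()]
        n = len(labels)
        idx = {u: i for i, u in enumerate(g.nodes())}
        a = np.zeros((n, n))
        for u, v, data in g.edges(data=True):
            if u == v:
                raise GraphFormatError(f"self-loop at node {u!r}")
            w = float(data.get("weight", 1.0))
            a[idx[u], idx[v]] = w
            a[idx[v], idx[u]] = w
        return cls(labels, a)


@dataclass(frozen=True)
class EigenBlock:
    """A maximal run of numerically equal eigenvalues (0-based inclusive indices)."""

    lo: int
    hi: int
    value: float

    @property
    def size(self) -> int:
        return self.hi - self.lo + 1


@dataclass
class LaplacianSpectrum:
    """Full eigendecomposition of a graph Laplacian.

    ``eigenvalues`` are nondecreasing with ``eigenvalues[0] == 0``; the columns
    of ``vectors`` are the matching orthonormal eigenvectors; ``blocks`` groups
    degenerate eigenvalues into maximal chains.
    """

    eigenvalues: np.ndarray
    vectors: np.ndarray
    blocks: list[EigenBlock]
    node_labels: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.eigenvalues)

    @property
    def lambda2(self) -> float:
        return float(self.eigenvalues[1])

    def block_at(self, index: int) -> EigenBlock:
        """The degenerate block containing the (0-based) eigenvalue ``index``."""
        for b in self.blocks:
            if b.lo <= index <= b.hi:
                return b
        raise IndexError(f"eigenvalue index {index} out of range")


def _parse_edgelist(path: Path) -> WeightedGraph:
    edges: dict[tuple[str, str], float] = {}
    nodes: list[str] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise GraphFormatError(f"{path}:{lineno}: expected 'u v [w]', got {raw!r}")
        u, v = parts[0], parts[1]
        try:
            w = float(parts[2]) if len(parts) == 3 else 1.0
        except ValueError as exc:
            raise GraphFormatError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
        if u == v:
            raise GraphFormatError(f"{path}:{lineno}: self-loop at node {u!r}")
        for x in (u, v):
            if x not in seen:
                seen.add(x)
                nodes.append(x)
        key = (u, v) if u <= v else (v, u)
        if key in edges:
            if not math.isclose(edges[key], w, rel_tol=1e-12, abs_tol=0.0):
                raise GraphFormatError(
                    f"{path}:{lineno}: conflicting duplicate weight for edge {u}-{v}: "
                    f"{edges[key]} vs {w}"
                )
        else:
            edges[key] = w
    if not nodes:
        raise GraphFormatError(f"{path}: no edges found")
    idx = {u: i for i, u in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for (u, v), w in edges.items():
        a[idx[u], idx[v]] = w
        a[idx[v], idx[u]] = w
    return WeightedGraph(nodes, a)


def _parse_matrix_market(path: Path) -> WeightedGraph:
    try:
        m = scipy.io.mmread(str(path))
    except Exception as exc:
        raise GraphFormatError(f"{path}: not a valid Matrix Market file: {exc}") from exc
    a = np.asarray(m.todense() if scipy.sparse.issparse(m) else m, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise GraphFormatError(f"{path}: adjacency must be square, got {a.shape}")
    labels = [str(i + 1) for i in range(a.shape[0])]
    return WeightedGraph(labels, a)


def _parse_graphml(path: Path) -> WeightedGraph:
    try:
        g = nx.read_graphml(str(path))
    except Exception as exc:
        raise GraphFormatError(f"{path}: not valid GraphML: {exc}") from exc
    if g.is_directed():
        g = g.to_undirected()
    return WeightedGraph.from_networkx(g)


_READERS = {
    "edgelist": _parse_edgelist,
    "matrix-market": _parse_matrix_market,
    "graphml": _parse_graphml,
}


def read_graph(path: str | Path, format: str = "edgelist") -> WeightedGraph:
    """Read an undirected weighted graph.

    Supported dialects: whitespace-separated edge lists ``u v [w]`` with ``#``
    comments, Matrix Market coordinate files holding the adjacency matrix, and
    GraphML with an optional ``weight`` edge attribute (default 1.0).
    """
    path = Path(path)
    if format not in _READERS:
        raise GraphFormatError(f"unknown graph format {format!r}; choose from {sorted(_READERS)}")
    if not path.exists():
        raise GraphFormatError(f"no such file: {path}")
    return _READERS[format](path)


def write_graph(g: WeightedGraph, path: str | Path, format: str = "edgelist") -> None:
    """Write ``g`` so that :func:`read_graph` reproduces it exactly."""
    path = Path(path)
    if format == "edgelist":
        lines = ["# u v w"]
        n = g.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                w = g.weights[i, j]
                if w != 0.0:
                    lines.append(f"{g.node_labels[i]}\t{g.node_labels[j]}\t{float(w)!r}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "matrix-market":
        sp = scipy.sparse.coo_matrix(g.weights)
        with open(path, "wb") as fh:  # mmwrite appends .mtx to bare paths
            scipy.io.mmwrite(fh, sp, symmetry="symmetric")
    elif format == "graphml":
        nx.write_graphml(g.to_networkx(), str(path))
    else:
        raise GraphFormatError(f"unknown graph format {format!r}")


def laplacian_of(g: WeightedGraph) -> np.ndarray:
    """The combinatorial Laplacian ``L = D - A`` (symmetric, zero row sums)."""
    a = g.weights
    return np.diag(a.sum(axis=1)) - a


def _group_blocks(eigenvalues: np.ndarray, grouping_tol: float) -> list[EigenBlock]:
    """Chain consecutive eigenvalues whose gap is below the relative tolerance."""
    blocks: list[EigenBlock] = []
    lo = 0
    n = len(eigenvalues)
    for i in range(1, n + 1):
        if i == n or (
            eigenvalues[i] - eigenvalues[i - 1]
            > grouping_tol * max(1.0, abs(eigenvalues[i]))
        ):
            blocks.append(EigenBlock(lo, i - 1, float(np.mean(eigenvalues[lo:i]))))
            lo = i
    return blocks


def eigendecompose(g: WeightedGraph, grouping_tol: float = 1e-8) -> LaplacianSpectrum:
    """Full symmetric eigendecomposition of the Laplacian with degeneracy grouping.

    Eigenvalues come out nondecreasing with an orthonormal eigenvector matrix
    (columns are eigenvectors); consecutive eigenvalues with a gap below
    ``grouping_tol * max(1, lambda)`` are chained into one degenerate block.
    """
    n = g.n_nodes
    if n > MAX_DENSE_N:
        raise ValueError(
            f"graph has {n} nodes; full dense eigendecomposition is limited to "
            f"{MAX_DENSE_N} (the method needs the complete spectrum, so a partial "
            "iterative solver is not a substitute)"
        )
    lam, vec = scipy.linalg.eigh(laplacian_of(g))
    lam[0] = 0.0  # exact by zero-row-sum; eigh returns O(eps*||L||) here
    lam = np.maximum(lam, 0.0)
    blocks = _group_blocks(lam, grouping_tol)
    if blocks[0].size != 1:
        raise GraphFormatError("multiple near-zero eigenvalues: graph is (nearly) disconnected")
    # pin the trivial eigenvector to +1/sqrt(N)
    if vec[0, 0] < 0:
        vec[:, 0] = -vec[:, 0]
    return LaplacianSpectrum(lam, vec, blocks, list(g.node_labels))
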