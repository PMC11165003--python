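"""Generators for networks with planted, analytically known cluster structure.

Two constructions are provided.  The planted-cluster construction starts from
a random connected core and adds ensembles of nodes that all attach, with unit
weight, to the *same* group of ``m`` core nodes: each ensemble of size ``k``
is an external equitable cell by construction and contributes ``k - 1``
degenerate Laplacian eigenvalues equal to its external degree ``m`` (for an
internally empty ensemble; an internal clique of weight ``w`` shifts the
localized eigenvalue to ``m + k w``), with eigenvectors supported on the
ensemble.  The orbit-weighted construction builds small graphs whose nodes are
partitioned into fully interchangeable symmetry orbits, the weighted analogue
used for worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .graphs import EigenBlock, GraphFormatError, LaplacianSpectrum, WeightedGraph
from .transition import CellPartition, equitable_cells

__all__ = [
    "ClusterSpec",
    "PlantedGraph",
    "planted_cluster_graph",
    "orbit_weighted_graph",
    "three_orbit_demo_graph",
    "rotate_degenerate_basis",
    "count_localized_eigenvalues",
]


@dataclass(frozen=True)
class ClusterSpec:
    """A planted ensemble: ``size`` nodes sharing ``external_degree`` core anchors."""

    size: int
    external_degree: int
    internal_topology: str = "empty"  # empty | clique
    internal_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("cluster size must be >= 2")
        if self.external_degree < 1:
            raise ValueError("external degree must be >= 1")
        if self.internal_topology not in {"empty", "clique"}:
            raise ValueError(f"unknown internal topology {self.internal_topology!r}")

    @property
    def localized_eigenvalue(self) -> float:
        """The eigenvalue of the ``size - 1`` difference modes planted by this ensemble."""
        if self.internal_topology == "empty":
            return float(self.external_degree)
        return float(self.external_degree + self.size * self.internal_weight)


@dataclass
class PlantedGraph:
    """A generated graph together with its analytically known cell structure."""

    graph: WeightedGraph
    ground_truth: CellPartition
    expected_eigenvalues: dict[frozenset, tuple[float, int]]
    seed: int
    specs: list[ClusterSpec] = field(default_factory=list)

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "clusters": [
                {
                    "nodes": sorted(nodes, key=lambda s: int(s)),
                    "localized_eigenvalue": val,
                    "multiplicity": mult,
                }
                for nodes, (val, mult) in self.expected_eigenvalues.items()
            ],
            "specs": [
                {
                    "size": s.size,
                    "external_degree": s.external_degree,
                    "internal_topology": s.internal_topology,
                    "internal_weight": s.internal_weight,
                }
                for s in self.specs
            ],
        }


def _connected_er_core(n: int, p: float, rng: np.random.Generator,
                       max_retries: int = 20) -> np.ndarray:
    import scipy.sparse
    import scipy.sparse.csgraph

    for _ in range(max_retries):
        upper = rng.random((n, n)) < p
        a = np.triu(upper, k=1).astype(float)
        a = a + a.T
        ncomp, _ = scipy.sparse.csgraph.connected_components(
            scipy.sparse.csr_matrix(a), directed=False
        )
        if ncomp == 1:
            return a
    raise GraphFormatError(
        f"could not generate a connected Erdos-Renyi core (n={n}, p={p}) "
        f"in {max_retries} attempts"
    )


def planted_cluster_graph(
    core_n: int,
    clusters: list[ClusterSpec],
    p: float | None = None,
    core_adjacency: np.ndarray | None = None,
    seed: int = 0,
    validate: bool = True,
) -> PlantedGraph:
    """Attach planted ensembles to a random (or given) connected core.

    The core is Erdos-Renyi with ``p = 2 ln(core_n) / core_n`` by default
    (connected with high probability; regenerated on disconnection).  Every
    node of an ensemble is attached with unit weight to the same randomly
    chosen group of ``external_degree`` core nodes, so the ensemble is an
    external equitable cell by construction.  With ``validate`` the cell
    partition of the generated graph is recomputed combinatorially and must
    consist of exactly the planted cells plus singletons; an accidental extra
    cell in the random core aborts the fixture.
    """
    rng = np.random.default_rng(seed)
    for spec in clusters:
        if spec.external_degree > core_n:
            raise ValueError(
                f"external degree {spec.external_degree} exceeds core size {core_n}"
            )
    if core_adjacency is not None:
        core = np.asarray(core_adjacency, dtype=float)
        if core.shape != (core_n, core_n):
            raise ValueError("core adjacency shape mismatch")
    else:
        if p is None:
            p = 2.0 * np.log(core_n) / core_n
        core = _connected_er_core(core_n, p, rng)

    n_total = core_n + sum(s.size for s in clusters)
    a = np.zeros((n_total, n_total))
    a[:core_n, :core_n] = core
    labels = [str(i + 1) for i in range(n_total)]

    expected: dict[frozenset, tuple[float, int]] = {}
    cells: list[frozenset] = []
    offset = core_n
    for spec in clusters:
        members = list(range(offset, offset + spec.size))
        offset += spec.size
        anchors = rng.choice(core_n, size=spec.external_degree, replace=False)
        for i in members:
            a[i, anchors] = 1.0
            a[anchors, i] = 1.0
        if spec.internal_topology == "clique":
            for i in members:
                for j in members:
                    if i != j:
                        a[i, j] = spec.internal_weight
        cell = frozenset(labels[i] for i in members)
        cells.append(cell)
        expected[cell] = (spec.localized_eigenvalue, spec.size - 1)

    graph = WeightedGraph(labels, a)
    clustered = set().union(*cells) if cells else set()
    singles = [frozenset({lab}) for lab in labels if lab not in clustered]
    ground_truth = CellPartition(cells=cells + singles)

    if validate:
        found = {c for c in equitable_cells(graph).nontrivial()}
        planted = set(cells)
        if found != planted:
            extra = found - planted
            missing = planted - found
            raise GraphFormatError(
                "generated core carries accidental equitable cells; regenerate "
                f"with a different seed (extra={extra}, missing={missing})"
            )

    return PlantedGraph(graph=graph, ground_truth=ground_truth,
                        expected_eigenvalues=expected, seed=seed,
                        specs=list(clusters))


def orbit_weighted_graph(
    orbit_sizes: list[int],
    inter_orbit_weights: np.ndarray,
    intra_orbit_weights: list[float],
) -> WeightedGraph:
    """A graph whose nodes split into fully interchangeable symmetry orbits.

    All nodes of one orbit carry equal intra-orbit weights and equal weights to
    every node of each other orbit, so an orbit of size ``k`` contributes
    ``k - 1`` degenerate localized eigenvalues (at its strength plus its
    intra-orbit weight).  Deterministic construction; weights must be
    nonnegative and the result connected.
    """
    inter = np.asarray(inter_orbit_weights, dtype=float)
    k = len(orbit_sizes)
    if inter.shape != (k, k):
        raise ValueError("inter_orbit_weights must be a square matrix over orbits")
    if len(intra_orbit_weights) != k:
        raise ValueError("one intra-orbit weight per orbit required")
    if np.any(inter < 0) or any(w < 0 for w in intra_orbit_weights):
        raise ValueError("weights must be nonnegative")
    n = sum(orbit_sizes)
    a = np.zeros((n, n))
    starts = np.cumsum([0] + list(orbit_sizes))
    for oi in range(k):
        si, ei = starts[oi], starts[oi + 1]
        w = intra_orbit_weights[oi]
        a[si:ei, si:ei] = w
        for oj in range(oi + 1, k):
            sj, ej = starts[oj], starts[oj + 1]
            a[si:ei, sj:ej] = inter[oi, oj]
            a[sj:ej, si:ei] = inter[oi, oj]
    np.fill_diagonal(a, 0.0)
    return WeightedGraph([str(i + 1) for i in range(n)], a)


def three_orbit_demo_graph() -> WeightedGraph:
    """An all-to-all weighted 10-node graph with three symmetry orbits.

    Orbits {1,2,3}, {4,5,6} and {7,8,9,10}; the rational weights are chosen so
    that the Laplacian spectrum is exactly {0, 1,1,1, 4,4,4, 6,6,6} and the
    transition is orbit-by-orbit accretion: formation of {7,8,9,10} at
    relative coupling 1/6, growth by {4,5,6} at 1/4, and complete
    synchronization at 1 (in units of nu*).  Synthetic worked-example fixture.
    """
    w1 = Fraction(1, 10)
    w2 = Fraction(37, 70)
    w3 = Fraction(36, 35)
    w12 = Fraction(1, 10)
    w13 = Fraction(1, 10)
    w23 = Fraction(37, 70)
    inter = np.array(
        [[0, float(w12), float(w13)],
         [float(w12), 0, float(w23)],
         [float(w13), float(w23), 0]]
    )
    return orbit_weighted_graph([3, 3, 4], inter, [float(w1), float(w2), float(w3)])


def rotate_degenerate_basis(spec: LaplacianSpectrum, seed: int = 0) -> LaplacianSpectrum:
    """Replace the eigenbasis inside each degenerate block by a random rotation.

    Within every block of size > 1 the eigenvector columns are multiplied by a
    seeded random orthogonal matrix; eigenvalues and blocks are untouched.
    Used to verify that block-boundary detection is basis-invariant.
    """
    rng = np.random.default_rng(seed)
    v = spec.vectors.copy()
    for block in spec.blocks:
        if block.size > 1:
            q, r = np.linalg.qr(rng.standard_normal((block.size, block.size)))
            q *= np.sign(np.diag(r))  # fix the sign convention of the factorization
            v[:, block.lo : block.hi + 1] = v[:, block.lo : block.hi + 1] @ q
    return LaplacianSpectrum(
        eigenvalues=spec.eigenvalues.copy(),
        vectors=v,
        blocks=[EigenBlock(b.lo, b.hi, b.value) for b in spec.blocks],
        node_labels=list(spec.node_labels),
    )


def count_localized_eigenvalues(
    spec: LaplacianSpectrum,
    value: float,
    cluster_labels: set[str],
    value_tol: float = 1e-8,
    support_tol: float = 1e-8,
) -> int:
    """Number of eigenvalues near ``value`` whose eigenvectors live on a cluster.

    Degenerate eigenvectors returned by a solver may mix localized and
    delocalized directions of one eigenspace, so the count is computed as the
    dimension of the subspace of the (near-)eigenspace whose support is
    confined to the cluster: the nullity of the eigenvector rows outside the
    cluster.
    """
    idx = np.flatnonzero(np.abs(spec.eigenvalues - value) <= value_tol)
    if idx.size == 0:
        return 0
    members = [i for i, lab in enumerate(spec.node_labels) if lab in cluster_labels]
    outside = np.setdiff1d(np.arange(spec.n), members)
    sub = spec.vectors[np.ix_(outside, idx)]
    if sub.size == 0:
        return int(idx.size)
    sv = np.linalg.svd(sub, compute_uv=False)
    rank = int(np.sum(sv > support_tol * max(1.0, sv[0] if sv.size else 1.0)))
    return int(idx.size - rank)
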