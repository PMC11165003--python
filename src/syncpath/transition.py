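"""Spectral prediction of the cluster-synchronization transition.

Given the full Laplacian eigendecomposition of a connected graph, the ordered
sequence of synchronization events is read off the cumulative eigenvector
matrices

    S_n[i, j] = sum_{k >= n} (v_k[j] - v_k[i])^2 ,

inspected at degenerate-block boundaries in decreasing eigenvalue order.  An
off-diagonal entry equal to 2 flags a node pair that has identical components
on *every* eigenvector below the block, i.e. a pair that synchronizes once the
block's eigenvalue crosses the stability threshold: the cluster synchronizes
at coupling ``d = nu* / lambda_block`` where ``nu*`` is the Master Stability
Function intercept of the node dynamics.

The combinatorial counterpart (equivalent by the localization theorem) is the
external equitable cell: a node set whose members have identical connections,
with identical weights, to every node outside the set.  :func:`equitable_cells`
computes these directly from the Laplacian rows and :func:`verify_plan` cross-
checks every predicted cluster against that condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable

import numpy as np

from .graphs import LaplacianSpectrum, WeightedGraph, laplacian_of

if TYPE_CHECKING:  # pragma: no cover
    from .msf import MSFClassification

__all__ = [
    "ClusterEvent",
    "TransitionPlan",
    "CellPartition",
    "PlanViolation",
    "PlanReport",
    "e_matrix",
    "s_matrix_at",
    "detect_transition",
    "scale_plan",
    "equitable_cells",
    "verify_plan",
    "cluster_census",
    "plan_to_json",
    "plan_from_json",
]

PLAN_SCHEMA_VERSION = 1

#: Default tolerance on |S - 2| for declaring an entry "equal to 2".  For a
#: genuine cell pair the deviation from 2 is pure eigensolver noise (measured
#: <= ~3e-14 at N = 1000), while the nearest impostor pair -- two bulk nodes on
#: which all eigenvectors below the block are *nearly* constant -- can come as
#: close as ~1e-10 on graphs with strongly localized low modes.  1e-11 sits
#: between the two with two to three decades of margin on either side.
DEFAULT_ENTRY_TOL = 1e-11


@dataclass(frozen=True)
class ClusterEvent:
    """One event of the transition: a node set locking at a critical coupling."""

    nodes: frozenset[str]
    block_eigenvalue: float
    relative_coupling: float  # 1 / lambda_block, in units of nu*
    event_type: str  # formation | merge | growth | complete
    merged_from: tuple[frozenset[str], ...] = ()
    absolute_coupling: float | None = None
    reachable: bool = True

    def __post_init__(self) -> None:
        if len(self.nodes) < 2:
            raise ValueError("a cluster event involves at least 2 nodes")
        if self.event_type not in {"formation", "merge", "growth", "complete"}:
            raise ValueError(f"unknown event type {self.event_type!r}")


@dataclass
class TransitionPlan:
    """Ordered sequence of cluster events (nondecreasing relative coupling)."""

    events: list[ClusterEvent]
    node_labels: list[str]
    class_info: "MSFClassification | None" = None

    def __post_init__(self) -> None:
        rc = [e.relative_coupling for e in self.events]
        if any(b < a - 1e-15 for a, b in zip(rc, rc[1:])):
            raise ValueError("events must be ordered by nondecreasing relative coupling")
        if self.events:
            final = self.events[-1]
            if final.event_type != "complete" or final.nodes != frozenset(self.node_labels):
                raise ValueError("the final event must be the all-node complete event")

    @property
    def complete_event(self) -> ClusterEvent:
        return self.events[-1]

    def cluster_events(self) -> list[ClusterEvent]:
        """All events except the final complete one."""
        return self.events[:-1]


@dataclass
class CellPartition:
    """Partition of the nodes into external equitable cells (singletons included)."""

    cells: list[frozenset[str]]

    def nontrivial(self) -> list[frozenset[str]]:
        return [c for c in self.cells if len(c) >= 2]

    def cell_of(self, label: str) -> frozenset[str]:
        for c in self.cells:
            if label in c:
                return c
        raise KeyError(label)


@dataclass(frozen=True)
class PlanViolation:
    event_nodes: frozenset[str]
    pair: tuple[str, str]
    outside_node: str
    difference: float


@dataclass
class PlanReport:
    violations: list[PlanViolation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def e_matrix(spec: LaplacianSpectrum, i: int) -> np.ndarray:
    """Squared component-difference matrix of the ``i``-th eigenvector (1-based).

    Entry ``(j, k)`` is ``(v_i[j] - v_i[k])**2``; symmetric, zero diagonal,
    entries in [0, 2].  For ``i = 1`` the eigenvector is constant and the
    matrix vanishes identically.
    """
    if not 1 <= i <= spec.n:
        raise IndexError(f"eigenvector index {i} out of range 1..{spec.n}")
    v = spec.vectors[:, i - 1]
    d = v[:, None] - v[None, :]
    return d * d


def s_matrix_at(spec: LaplacianSpectrum, n: int) -> np.ndarray:
    """Cumulative matrix ``S_n = sum_{k>=n} E_{lambda_k}`` (1-based ``n``).

    Computed directly from the tail of the eigenvector matrix via a Gram
    product rather than by materializing the individual E matrices.
    """
    if not 1 <= n <= spec.n:
        raise IndexError(f"eigenvalue index {n} out of range 1..{spec.n}")
    tail = spec.vectors[:, n - 1 :]
    gram = tail @ tail.T
    c = np.diag(gram).copy()
    s = c[:, None] + c[None, :] - 2.0 * gram
    np.fill_diagonal(s, 0.0)
    return np.maximum(s, 0.0)


class _DSU:
    """Union-find over 0..n-1 with path compression."""

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)

    def components(self) -> dict[int, list[int]]:
        comps: dict[int, list[int]] = {}
        for i in range(len(self.parent)):
            comps.setdefault(self.find(i), []).append(i)
        return comps


def detect_transition(
    spec: LaplacianSpectrum, entry_tol: float = DEFAULT_ENTRY_TOL
) -> TransitionPlan:
    """Predict the ordered sequence of cluster-synchronization events.

    Degenerate eigenvalue blocks are visited in decreasing eigenvalue order; at
    each block boundary the cumulative matrix ``S`` is inspected for entries
    equal to 2 (within ``entry_tol``) that join node pairs not already
    clustered together.  Pairs are merged into clusters by transitive closure,
    and each new or enlarged cluster is emitted as an event at relative
    coupling ``1 / lambda_block``.  The final event is always the complete
    all-node synchronization at ``lambda_2``.

    Detection happens only at block *boundaries* because partial sums inside a
    degenerate block depend on the arbitrary choice of eigenbasis, while the
    boundary sum is determined by the block's spectral projector alone.
    """
    n = spec.n
    labels = spec.node_labels or [str(i + 1) for i in range(n)]
    v = spec.vectors
    dsu = _DSU(n)
    events: list[ClusterEvent] = []

    gram = np.zeros((n, n))
    for block in reversed(spec.blocks[1:]):  # skip the lambda_1 = 0 block
        vb = v[:, block.lo : block.hi + 1]
        gram += vb @ vb.T
        c = np.diag(gram).copy()
        s = c[:, None] + c[None, :] - 2.0 * gram

        ii, jj = np.nonzero(np.triu(np.abs(s - 2.0) <= entry_tol, k=1))
        if ii.size == 0:
            continue
        before = {i: dsu.find(i) for i in range(n)}
        old_members: dict[int, list[int]] = {}
        for i in range(n):
            old_members.setdefault(before[i], []).append(i)
        touched = False
        for i, j in zip(ii, jj):
            if before[i] != before[j]:
                touched = True
            dsu.union(int(i), int(j))
        if not touched:
            continue

        block_events: list[ClusterEvent] = []
        for root, members in dsu.components().items():
            if len(members) < 2:
                continue
            old_roots = {before[m] for m in members}
            if len(old_roots) == 1 and len(old_members[next(iter(old_roots))]) == len(members):
                continue  # unchanged cluster
            _check_equivalence(s, members, entry_tol)
            priors = tuple(
                frozenset(labels[m] for m in old_members[r])
                for r in sorted(old_roots)
                if len(old_members[r]) >= 2
            )
            nodes = frozenset(labels[m] for m in members)
            if block.lo == 1 and len(members) == n:
                etype = "complete"
            elif not priors:
                etype = "formation"
            elif len(priors) >= 2:
                etype = "merge"
            else:
                etype = "growth"
            block_events.append(
                ClusterEvent(
                    nodes=nodes,
                    block_eigenvalue=block.value,
                    relative_coupling=1.0 / block.value,
                    event_type=etype,
                    merged_from=priors,
                )
            )
        block_events.sort(key=lambda e: _label_key(min(e.nodes, key=_label_key)))
        events.extend(block_events)

    if not events or events[-1].event_type != "complete":
        raise RuntimeError(
            "no complete all-node event detected at the lambda_2 block; the S_2 "
            "identity failed beyond tolerance (check the eigendecomposition)"
        )
    return TransitionPlan(events=events, node_labels=list(labels))


def _label_key(label: str):
    return (0, int(label)) if label.isdigit() else (1, label)


def _check_equivalence(s: np.ndarray, members: list[int], entry_tol: float) -> None:
    """The 'entry equals 2' relation must be transitive on each cluster."""
    idx = np.array(members)
    sub = s[np.ix_(idx, idx)]
    off = np.abs(sub - 2.0)
    np.fill_diagonal(off, 0.0)
    worst = off.max()
    # |S - 2| is a squared distance between truncated eigenvector rows, so a
    # transitive chain of L near-2 pairs bounds every same-cluster pair by
    # (L-1)^2 * tol; anything beyond that signals numerically broken
    # transitivity rather than chaining slack
    bound = 4.0 * len(members) ** 2 * entry_tol
    if worst > bound:
        raise RuntimeError(
            f"the entry-equals-2 relation is not an equivalence relation at this "
            f"tolerance: same-cluster pair deviates from 2 by {worst:.3e}, beyond "
            f"the transitive-chaining bound {bound:.3e} (entry_tol={entry_tol:.1e})"
        )


def scale_plan(plan: TransitionPlan, msf: "MSFClassification | float") -> TransitionPlan:
    """Attach absolute couplings ``d = nu* / lambda`` to a relative plan.

    ``msf`` may be an :class:`~syncpath.msf.MSFClassification` (Class II or
    III) or a bare ``nu*`` value (treated as Class II).  For Class III
    systems, events whose coupling violates the upper stability bound
    ``d_max = nu2* / lambda_N`` are flagged unreachable.
    """
    from .msf import MSFClassification  # deferred import, avoids a cycle

    if isinstance(msf, MSFClassification):
        if msf.class_label == "I":
            raise ValueError("Class I systems defy synchronization: no finite threshold exists")
        nu_star = msf.nu_star if msf.class_label == "II" else msf.nu1_star
        nu2 = msf.nu2_star if msf.class_label == "III" else None
        class_info = msf
    else:
        nu_star = float(msf)
        nu2 = None
        class_info = None
    if nu_star is None or nu_star <= 0:
        raise ValueError(
            f"nu* must be positive, got {nu_star!r} (a periodic unit has nu* = 0 "
            "and synchronizes at infinitesimal coupling)"
        )
    lambda_max = max(e.block_eigenvalue for e in plan.events)
    d_max = nu2 / lambda_max if nu2 is not None else None
    events = []
    for e in plan.events:
        d = nu_star * e.relative_coupling
        reachable = True if d_max is None else d < d_max
        events.append(replace(e, absolute_coupling=d, reachable=reachable))
    return TransitionPlan(events=events, node_labels=list(plan.node_labels),
                          class_info=class_info)


def _strength_groups(strengths: np.ndarray, tol: float) -> list[list[int]]:
    order = np.argsort(strengths)
    groups: list[list[int]] = [[int(order[0])]]
    for a, b in zip(order, order[1:]):
        if strengths[b] - strengths[a] <= tol:
            groups[-1].append(int(b))
        else:
            groups.append([int(b)])
    return groups


def equitable_cells(g: WeightedGraph, weight_tol: float = 1e-9) -> CellPartition:
    """Partition the nodes into external equitable cells.

    Starts from the pairwise relation ``i ~ j`` iff the Laplacian rows of ``i``
    and ``j`` agree on every column outside ``{i, j}`` (within ``weight_tol``),
    takes connected components of that relation as candidate cells, then
    iteratively splits any candidate violating the cell condition by grouping
    members on their external-row signature until a fixed point.  The pair
    relation is not guaranteed transitive, hence the refinement loop.
    """
    lap = laplacian_of(g)
    a = g.weights
    n = g.n_nodes
    labels = g.node_labels

    dsu = _DSU(n)
    for group in _strength_groups(a.sum(axis=1), weight_tol):
        for ai in range(len(group)):
            for bi in range(ai + 1, len(group)):
                i, j = group[ai], group[bi]
                diff = np.abs(lap[i] - lap[j])
                diff[i] = diff[j] = 0.0
                if diff.max() <= weight_tol:
                    dsu.union(i, j)

    cells = [members for members in dsu.components().values()]
    # refinement: split any candidate cell violating the external-row condition
    for _ in range(n):
        changed = False
        refined: list[list[int]] = []
        for cell in cells:
            if len(cell) < 2 or _is_cell(a, cell, weight_tol):
                refined.append(cell)
                continue
            changed = True
            refined.extend(_split_by_signature(a, cell, weight_tol))
        cells = refined
        if not changed:
            break

    cells_sets = [frozenset(labels[i] for i in cell) for cell in cells]
    cells_sets.sort(key=lambda c: _label_key(min(c, key=_label_key)))
    return CellPartition(cells=cells_sets)


def _is_cell(a: np.ndarray, cell: list[int], tol: float) -> bool:
    outside = np.setdiff1d(np.arange(a.shape[0]), cell)
    if outside.size == 0:
        return True
    rows = a[np.ix_(cell, outside)]
    return np.abs(rows - rows[0]).max() <= tol


def _split_by_signature(a: np.ndarray, cell: list[int], tol: float) -> list[list[int]]:
    outside = np.setdiff1d(np.arange(a.shape[0]), cell)
    remaining = list(cell)
    parts: list[list[int]] = []
    while remaining:
        rep = remaining[0]
        part = [p for p in remaining
                if np.abs(a[p, outside] - a[rep, outside]).max() <= tol]
        parts.append(part)
        remaining = [p for p in remaining if p not in part]
    return parts


def verify_plan(
    plan: TransitionPlan, g: WeightedGraph, weight_tol: float = 1e-9
) -> PlanReport:
    """Check every non-complete event against the external equitable condition.

    Each predicted cluster must receive identical input from every outside
    node: for nodes ``p, q`` in the cluster and ``j`` outside, ``L_pj = L_qj``.
    Violations indicate tolerance trouble in detection, not a valid plan.
    """
    a = g.weights
    idx = {lab: i for i, lab in enumerate(g.node_labels)}
    report = PlanReport()
    for event in plan.cluster_events():
        members = sorted(idx[lab] for lab in event.nodes)
        outside = np.setdiff1d(np.arange(g.n_nodes), members)
        if outside.size == 0:
            continue
        rows = a[np.ix_(members, outside)]
        diffs = np.abs(rows - rows[0])
        bad = np.argwhere(diffs > weight_tol)
        for mi, oi in bad:
            report.violations.append(
                PlanViolation(
                    event_nodes=event.nodes,
                    pair=(g.node_labels[members[0]], g.node_labels[members[mi]]),
                    outside_node=g.node_labels[outside[oi]],
                    difference=float(diffs[mi, oi]),
                )
            )
    return report


def cluster_census(
    plan: TransitionPlan,
    g: WeightedGraph | None = None,
    weight_tol: float = 1e-9,
) -> dict:
    """Summary of the distinct synchronized clusters formed before complete sync.

    Events are nested-or-merging, so the pre-complete state is the partition
    generated by all non-complete events; the census reports the number of
    clusters, their size histogram and the total number of clustered nodes.
    When the graph is supplied, candidate clusters failing the external
    equitable condition (numerical impostors on graphs with strongly localized
    low modes) are excluded first.
    """
    events = plan.cluster_events()
    if g is not None:
        bad = {v.event_nodes for v in verify_plan(plan, g, weight_tol).violations}
        events = [e for e in events if e.nodes not in bad]
    labels = sorted({lab for e in events for lab in e.nodes})
    index = {lab: i for i, lab in enumerate(labels)}
    dsu = _DSU(len(labels))
    for e in events:
        members = sorted(index[lab] for lab in e.nodes)
        for other in members[1:]:
            dsu.union(members[0], other)
    comps = [m for m in dsu.components().values() if len(m) >= 1]
    sizes = sorted((len(m) for m in comps), reverse=True)
    histogram: dict[int, int] = {}
    for s in sizes:
        histogram[s] = histogram.get(s, 0) + 1
    return {
        "n_clusters": len(sizes),
        "n_clustered_nodes": sum(sizes),
        "size_histogram": histogram,
    }


def plan_to_json(plan: TransitionPlan) -> str:
    """Serialize a plan (schema-versioned JSON)."""
    payload = {
        "schema_version": PLAN_SCHEMA_VERSION,
        "node_labels": plan.node_labels,
        "events": [
            {
                "nodes": sorted(e.nodes, key=_label_key),
                "block_eigenvalue": e.block_eigenvalue,
                "relative_coupling": e.relative_coupling,
                "absolute_coupling": e.absolute_coupling,
                "event_type": e.event_type,
                "merged_from": [sorted(m, key=_label_key) for m in e.merged_from],
                "reachable": e.reachable,
            }
            for e in plan.events
        ],
    }
    return json.dumps(payload, indent=2)


def plan_from_json(text: str) -> TransitionPlan:
    payload = json.loads(text)
    if payload.get("schema_version") != PLAN_SCHEMA_VERSION:
        raise ValueError(f"unsupported plan schema: {payload.get('schema_version')!r}")
    events = [
        ClusterEvent(
            nodes=frozenset(e["nodes"]),
            block_eigenvalue=e["block_eigenvalue"],
            relative_coupling=e["relative_coupling"],
            absolute_coupling=e.get("absolute_coupling"),
            event_type=e["event_type"],
            merged_from=tuple(frozenset(m) for m in e["merged_from"]),
            reachable=e.get("reachable", True),
        )
        for e in payload["events"]
    ]
    return TransitionPlan(events=events, node_labels=payload["node_labels"])
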