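"""Marker-adjacency (synteny) graph across assemblies.

Each assembly is a set of paths through the universe of single-copy
orthologous markers: per contig, the complete single-copy markers sorted
by position form a path, and every pair of immediate neighbors
contributes one count to the weight of the corresponding undirected
edge. Across many assemblies, markers that share a chromosome arm stay
densely connected even though within-arm order is shuffled by
rearrangement, so connected components of the graph recover the arms
(Muller elements in drosophilids).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .models import MarkerTable


def build_adjacency(
    tables: Sequence[MarkerTable],
    marker_universe: Optional[Set[str]] = None,
    pair_mode: str = "immediate",
) -> nx.Graph:
    """Build the weighted undirected marker-adjacency graph.

    Per assembly, only ``complete_single`` markers are used; per contig
    they are sorted by start (ties by end, then id) and each consecutive
    pair increments the edge weight by one. Only immediate neighbors
    form edges — no transitive pairs. ``pair_mode="drop_long_contigs"``
    instead discards contigs carrying three or more markers (an
    alternative, stricter reading of the construction).

    Graph attributes: ``n_assemblies``, ``observed`` (markers seen
    complete-single in at least one assembly).
    """
    if not tables:
        raise ValueError("at least one marker table is required")
    if pair_mode not in ("immediate", "drop_long_contigs"):
        raise ValueError(f"unknown pair_mode {pair_mode!r}")

    G = nx.Graph(n_assemblies=len(tables))
    observed: Set[str] = set()
    for table in tables:
        singles = [
            r
            for r in table.by_status("complete_single")
            if r.start is not None
        ]
        seen_ids: Set[str] = set()
        for r in singles:
            if r.marker_id in seen_ids:
                raise ValueError(
                    f"{table.assembly_id}: marker {r.marker_id} appears more "
                    "than once as complete_single (status inconsistency)"
                )
            seen_ids.add(r.marker_id)
        observed |= seen_ids
        by_contig: Dict[str, List] = {}
        for r in singles:
            by_contig.setdefault(r.contig, []).append(r)
        for recs in by_contig.values():
            if pair_mode == "drop_long_contigs" and len(recs) >= 3:
                continue
            recs.sort(key=lambda r: (r.start, r.end, r.marker_id))
            for a, b in zip(recs, recs[1:]):
                u, v = a.marker_id, b.marker_id
                w = G.get_edge_data(u, v, {}).get("weight", 0)
                G.add_edge(u, v, weight=w + 1)

    nodes = marker_universe if marker_universe is not None else observed
    G.add_nodes_from(nodes)
    G.graph["observed"] = observed
    return G


@dataclass
class ClusterAssignment:
    labels: Dict[str, str]  # marker id -> cluster label
    n_clusters: int
    reference: Optional[Dict[str, str]] = None  # e.g. true arm of each marker

    def members(self) -> Dict[str, Set[str]]:
        out: Dict[str, Set[str]] = {}
        for marker, label in self.labels.items():
            out.setdefault(label, set()).add(marker)
        return out


def components(graph: nx.Graph, min_weight: int = 1) -> ClusterAssignment:
    """Connected components over edges of weight >= ``min_weight``.

    Only observed markers are labeled; an isolated observed marker is a
    singleton cluster. Cluster labels are deterministic: the smallest
    member marker id.
    """
    if min_weight < 1:
        raise ValueError("min_weight must be >= 1")
    observed: Set[str] = graph.graph.get("observed", set(graph.nodes))
    H = nx.Graph()
    H.add_nodes_from(observed)
    for u, v, data in graph.edges(data=True):
        if data.get("weight", 0) >= min_weight and u in observed and v in observed:
            H.add_edge(u, v)
    labels: Dict[str, str] = {}
    n = 0
    for comp in nx.connected_components(H):
        label = min(comp)
        n += 1
        for marker in comp:
            labels[marker] = label
    return ClusterAssignment(labels=labels, n_clusters=n)


@dataclass(frozen=True)
class LayoutParams:
    """Force-directed layout settings (ForceAtlas2-style defaults)."""

    tolerance: float = 1.0
    gravity: float = 1.0
    iterations: int = 3000
    seed: int = 0
    scaling: float = 2.0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def layout(
    graph: nx.Graph, params: LayoutParams = LayoutParams()
) -> Dict[str, Tuple[float, float]]:
    """ForceAtlas2-style force-directed 2-D layout of the observed markers.

    Forces follow the ForceAtlas2 model: linear attraction along edges
    proportional to edge weight, repulsion proportional to
    (degree+1)(degree+1)/distance between all node pairs, and gravity
    pulling every node toward the origin. Step sizes adapt via the
    swinging/traction heuristic controlled by ``tolerance``. Exact
    (non-approximated) repulsion; deterministic under ``seed``.
    """
    observed = sorted(graph.graph.get("observed", set(graph.nodes)))
    if not observed:
        raise ValueError("graph has no observed nodes")
    idx = {m: i for i, m in enumerate(observed)}
    n = len(observed)

    rows, cols, weights = [], [], []
    for u, v, data in graph.edges(data=True):
        if u in idx and v in idx:
            rows.append(idx[u])
            cols.append(idx[v])
            weights.append(float(data.get("weight", 1)))
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    weights = np.asarray(weights, dtype=float)

    deg = np.zeros(n)
    np.add.at(deg, rows, 1)
    np.add.at(deg, cols, 1)
    mass = deg + 1.0

    rng = np.random.default_rng(params.seed)
    pos = rng.uniform(-1.0, 1.0, size=(n, 2)) * max(1.0, np.sqrt(n))
    prev_force = np.zeros_like(pos)
    speed = 1.0
    eps = 1e-9

    for _ in range(params.iterations):
        force = np.zeros_like(pos)
        # repulsion (exact pairwise)
        delta = pos[:, None, :] - pos[None, :, :]
        dist2 = np.einsum("ijk,ijk->ij", delta, delta) + eps
        rep = params.scaling * (mass[:, None] * mass[None, :]) / dist2
        np.fill_diagonal(rep, 0.0)
        force += np.einsum("ij,ijk->ik", rep, delta)
        # attraction: F = w * d along each edge
        if len(rows):
            d = pos[rows] - pos[cols]
            pull = weights[:, None] * d
            np.add.at(force, rows, -pull)
            np.add.at(force, cols, pull)
        # gravity toward origin
        r = np.sqrt(np.einsum("ij,ij->i", pos, pos)) + eps
        force -= params.gravity * mass[:, None] * pos / r[:, None]

        swing = np.linalg.norm(force - prev_force, axis=1)
        traction = 0.5 * np.linalg.norm(force + prev_force, axis=1)
        global_swing = float(np.dot(mass, swing)) + eps
        global_traction = float(np.dot(mass, traction)) + eps
        target = params.tolerance * global_traction / global_swing
        speed = min(target, 1.5 * speed) if speed > 0 else target
        node_speed = 0.1 * speed / (1.0 + speed * np.sqrt(swing))
        pos = pos + force * node_speed[:, None]
        prev_force = force

    return {m: (float(pos[i, 0]), float(pos[i, 1])) for m, i in idx.items()}


def adjacency_matrix(
    graph: nx.Graph, marker_order: Optional[Sequence[str]] = None
) -> Tuple[np.ndarray, List[str]]:
    """Dense symmetric weight matrix in sorted (or given) marker order."""
    order = list(marker_order) if marker_order is not None else sorted(graph.nodes)
    idx = {m: i for i, m in enumerate(order)}
    M = np.zeros((len(order), len(order)), dtype=np.int64)
    for u, v, data in graph.edges(data=True):
        if u in idx and v in idx:
            M[idx[u], idx[v]] = M[idx[v], idx[u]] = data.get("weight", 1)
    return M, order
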