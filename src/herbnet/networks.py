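"""Bipartite compound-target / target-disease / target-pathway networks and
the degree-based topology statistics reported for them.

Networks are undirected simple bipartite graphs: evidence multiplicity is an
edge attribute upstream, never a multi-edge, and degree counts distinct
neighbors. networkx backs the representation; the wrapper enforces the
bipartite invariants (disjoint partitions, endpoints on the correct side).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import InputError, PartitionConflictError
from .io import InteractionRecord

__all__ = [
    "BipartiteNetwork",
    "NetworkSummary",
    "build_bipartite",
    "network_summary",
    "nodes_with_min_degree",
    "per_herb_disease_counts",
]


@dataclass(frozen=True)
class BipartiteNetwork:
    left: frozenset[str]
    right: frozenset[str]
    edges: frozenset[tuple[str, str]]
    left_kind: str = "compound"
    right_kind: str = "target"
    node_attrs: Mapping[str, Mapping] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.left & self.right
        if overlap:
            raise PartitionConflictError(
                f"ids on both sides of the bipartition: {sorted(overlap)}"
            )
        for l, r in self.edges:
            if l not in self.left or r not in self.right:
                raise InputError(f"edge ({l!r}, {r!r}) has an endpoint outside its partition")

    @property
    def edge_kind(self) -> str:
        return f"{self.left_kind}-{self.right_kind}"

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.left, bipartite=0, partition=self.left_kind)
        g.add_nodes_from(self.right, bipartite=1, partition=self.right_kind)
        g.add_edges_from(self.edges)
        return g

    def degree(self, node_id: str) -> int:
        """Number of distinct neighbors of a node."""
        if node_id in self.left:
            return sum(1 for l, _ in self.edges if l == node_id)
        if node_id in self.right:
            return sum(1 for _, r in self.edges if r == node_id)
        raise InputError(f"unknown node {node_id!r}")

    def neighbors(self, node_id: str) -> set[str]:
        if node_id in self.left:
            return {r for l, r in self.edges if l == node_id}
        if node_id in self.right:
            return {l for l, r in self.edges if r == node_id}
        raise InputError(f"unknown node {node_id!r}")


@dataclass(frozen=True)
class NetworkSummary:
    n_left: int
    n_right: int
    n_nodes: int
    n_edges: int
    degree_table: tuple[tuple[str, int], ...]  # sorted by (-degree, id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.degree_table, columns=["node", "degree"])


def build_bipartite(
    edges: Sequence[InteractionRecord],
    left_kind: str,
    right_kind: str,
    *,
    extra_left: Iterable[str] = (),
    extra_right: Iterable[str] = (),
    node_attrs: Mapping[str, Mapping] | None = None,
) -> BipartiteNetwork:
    """Build a simple bipartite network from interaction records.

    Nodes are exactly the edge endpoints unless isolated nodes are injected
    explicitly through ``extra_left``/``extra_right``; duplicate pairs
    collapse. All records must carry the kind ``f"{left_kind}-{right_kind}"``.
    """
    want = f"{left_kind}-{right_kind}"
    pairs: set[tuple[str, str]] = set()
    for rec in edges:
        if rec.kind != want:
            raise InputError(f"edge kind {rec.kind!r} does not match network kind {want!r}")
        pairs.add((rec.left_id, rec.right_id))
    left = frozenset(p[0] for p in pairs) | frozenset(extra_left)
    right = frozenset(p[1] for p in pairs) | frozenset(extra_right)
    return BipartiteNetwork(
        left=left,
        right=right,
        edges=frozenset(pairs),
        left_kind=left_kind,
        right_kind=right_kind,
        node_attrs=dict(node_attrs or {}),
    )


def degree(net: BipartiteNetwork, node_id: str) -> int:
    return net.degree(node_id)


def network_summary(net: BipartiteNetwork) -> NetworkSummary:
    degs = {n: 0 for n in net.left | net.right}
    for l, r in net.edges:
        degs[l] += 1
        degs[r] += 1
    table = tuple(sorted(degs.items(), key=lambda kv: (-kv[1], kv[0])))
    return NetworkSummary(
        n_left=len(net.left),
        n_right=len(net.right),
        n_nodes=len(net.left) + len(net.right),
        n_edges=len(net.edges),
        degree_table=table,
    )


def nodes_with_min_degree(net: BipartiteNetwork, partition: str, k: int) -> list[str]:
    """Nodes on one side ('left' or 'right') with degree >= k, sorted by (-degree, id)."""
    if k < 0:
        raise InputError("k must be >= 0")
    if partition not in ("left", "right"):
        raise InputError("partition must be 'left' or 'right'")
    side = net.left if partition == "left" else net.right
    degs = {n: 0 for n in side}
    idx = 0 if partition == "left" else 1
    for e in net.edges:
        degs[e[idx]] += 1
    keep = [(n, d) for n, d in degs.items() if d >= k]
    keep.sort(key=lambda kv: (-kv[1], kv[0]))
    return [n for n, _ in keep]


def targets_hit_by_min_herbs(net: BipartiteNetwork, k: int) -> list[str]:
    """Targets adjacent to compounds from at least ``k`` distinct herbs.

    Alternative reading of "at least k interactions with compounds of the
    different herbs"; requires compound nodes to carry ``herb_ids`` attrs.
    """
    out = []
    for t in net.right:
        herbs: set[str] = set()
        for c in net.neighbors(t):
            attrs = net.node_attrs.get(c, {})
            herbs |= set(attrs.get("herb_ids", ()))
        if len(herbs) >= k:
            out.append(t)
    return sorted(out)


def per_herb_disease_counts(
    ct_net: BipartiteNetwork,
    td_edges: Sequence[InteractionRecord],
) -> pd.DataFrame:
    """Per-disease, per-herb counts of annotated targets reachable in the C-T network.

    A target counts for herb h and disease d iff it is annotated to d and is
    adjacent to at least one compound of herb h. Each disease also gets a
    ``__total__`` row with its distinct annotated-target count (any herb).
    Compound nodes must carry ``herb_ids`` in ``ct_net.node_attrs``.
    """
    herb_targets: dict[str, set[str]] = {}
    all_herbs: set[str] = set()
    for c in ct_net.left:
        attrs = ct_net.node_attrs.get(c, {})
        herbs = attrs.get("herb_ids")
        if not herbs:
            raise InputError(f"compound {c!r} carries no herb membership attribute")
        all_herbs.update(herbs)
        for h in herbs:
            herb_targets.setdefault(h, set()).update(ct_net.neighbors(c))

    disease_targets: dict[str, set[str]] = {}
    for rec in td_edges:
        if rec.kind != "target-disease":
            raise InputError(f"expected target-disease edges, got {rec.kind!r}")
        if rec.left_id in ct_net.right:
            disease_targets.setdefault(rec.right_id, set()).add(rec.left_id)

    diseases = sorted({rec.right_id for rec in td_edges})
    rows = []
    for d in diseases:
        annotated = disease_targets.get(d, set())
        for h in sorted(all_herbs):
            rows.append({
                "disease": d,
                "herb": h,
                "n_targets": len(annotated & herb_targets.get(h, set())),
            })
        rows.append({"disease": d, "herb": "__total__", "n_targets": len(annotated)})
    return pd.DataFrame(rows, columns=["disease", "herb", "n_targets"])
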