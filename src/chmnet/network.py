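"""Co-prescription network: construction, centrality, clustering, core herbs.

The network is an undirected graph over herb codes whose edges are the
top-ranked association rules; edge weight is pair support.  Communities are
found by deterministic greedy modularity agglomeration (Clauset-Newman-Moore
style) with a lexicographic tie-break, so results are reproducible without a
seed and invariant to the order nodes or rules are supplied.  Core herbs are
the per-community maximisers of (degree, prevalence, name).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .arm import AssociationRule

__all__ = [
    "build_network",
    "degree_centrality",
    "detect_clusters",
    "identify_core",
    "modularity",
    "ClusterAssignment",
]


def build_network(
    rules: Sequence[AssociationRule],
    prevalence: Mapping[str, float] | None = None,
    herb_types: Mapping[str, str] | None = None,
    indications: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Undirected rule graph: one edge per unordered pair.

    Duplicate directions collapse onto a single edge carrying the pair
    support, the representative (higher) confidence, and the lift.  Node
    attributes: ``prevalence`` (single-herb support, NaN when unknown),
    ``herb_type``, ``indication``.
    """
    if not rules:
        raise ValueError("cannot build a network from zero rules")
    prevalence = prevalence or {}
    herb_types = herb_types or {}
    indications = indications or {}
    g = nx.Graph()
    for r in sorted(rules, key=lambda r: (r.pair, r.antecedent)):
        a, b = r.pair
        if a == b:
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], r.confidence)
        else:
            g.add_edge(a, b, support=r.support, confidence=r.confidence, lift=r.lift)
    for node in sorted(g.nodes):
        g.nodes[node]["prevalence"] = float(prevalence.get(node, float("nan")))
        g.nodes[node]["herb_type"] = herb_types.get(node, "unknown")
        g.nodes[node]["indication"] = indications.get(node, "")
    return g


def degree_centrality(g: nx.Graph) -> dict[str, int]:
    """Raw (unweighted) degree per node: the count of incident edges."""
    return {n: int(d) for n, d in g.degree()}


@dataclass
class ClusterAssignment:
    """A hard partition of network nodes with quality and annotations."""

    membership: dict[str, int]
    modularity: float
    labels: dict[int, str] = field(default_factory=dict)
    cores: dict[int, str] = field(default_factory=dict)

    @property
    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, cid in self.membership.items():
            out.setdefault(cid, []).append(node)
        return {cid: sorted(nodes) for cid, nodes in out.items()}

    @property
    def n_clusters(self) -> int:
        return len(set(self.membership.values()))


def modularity(g: nx.Graph, communities: Sequence[set], weight: str | None = "support") -> float:
    """Newman weighted modularity Q of a partition (networkx implementation)."""
    return nx.community.modularity(g, communities, weight=weight)


def _greedy_modularity(g: nx.Graph, weight: str | None) -> list[set]:
    """Deterministic CNM-style agglomeration from singletons.

    Only communities joined by an edge are merge candidates (merging
    disconnected communities always lowers Q).  Among merges within 1e-12 of
    the best modularity gain, the pair whose (lexicographically smallest
    member, smallest member of the partner) is lowest is merged, making the
    outcome independent of node or edge input order.  Merging stops when no
    merge increases Q.
    """
    nodes = sorted(g.nodes)
    if not nodes:
        return []
    two_m = 2.0 * sum(d.get(weight, 1.0) if weight else 1.0 for _, _, d in g.edges(data=True))
    if two_m == 0:  # edgeless graph: all singletons
        return [{n} for n in nodes]

    comm: dict[str, set] = {n: {n} for n in nodes}  # community key = smallest member
    # a[c]: community's share of total degree; e[(c1,c2)]: inter-community edge share
    a = {
        n: sum((d.get(weight, 1.0) if weight else 1.0) for _, _, d in g.edges(n, data=True)) / two_m
        for n in nodes
    }
    e: dict[tuple[str, str], float] = {}
    for u, v, d in g.edges(data=True):
        w = d.get(weight, 1.0) if weight else 1.0
        key = (u, v) if u <= v else (v, u)
        e[key] = e.get(key, 0.0) + w / two_m

    while True:
        best_dq, best_pair = 1e-12, None
        # sorted iteration => on a dQ tie (within 1e-12) the lexicographically
        # smallest community pair is kept
        for (c1, c2), eij in sorted(e.items()):
            dq = 2.0 * (eij - a[c1] * a[c2])
            if dq > best_dq + 1e-12:
                best_dq, best_pair = dq, (c1, c2)
        if best_pair is None:
            break
        c1, c2 = best_pair  # c1 < c2: merged community keeps key c1
        comm[c1] |= comm.pop(c2)
        a[c1] += a.pop(c2)
        merged: dict[tuple[str, str], float] = {}
        for (x, y), val in e.items():
            x = c1 if x == c2 else x
            y = c1 if y == c2 else y
            if x == y:
                continue
            key = (x, y) if x <= y else (y, x)
            merged[key] = merged.get(key, 0.0) + val
        e = merged
    return [comm[k] for k in sorted(comm)]


def detect_clusters(
    g: nx.Graph, weight: str | None = "support", method: str = "greedy"
) -> ClusterAssignment:
    """Partition the network into communities.

    Connected components can never merge (no joining edge), so isolated dyads
    fall out as their own clusters.  Cluster ids are 1..k ordered by
    descending size then smallest member name.  ``method`` is ``"greedy"``
    (default, deterministic) or ``"louvain"`` (networkx, seeded).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if method == "greedy":
        communities = _greedy_modularity(g, weight)
    elif method == "louvain":
        communities = [set(c) for c in nx.community.louvain_communities(g, weight=weight, seed=0)]
    else:
        raise ValueError(f"unknown method {method!r}; use 'greedy' or 'louvain'")
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    membership = {node: cid for cid, nodes in enumerate(communities, start=1) for node in nodes}
    q = modularity(g, communities, weight=weight) if g.number_of_edges() else 0.0
    labels = {cid: f"cluster-{cid}" for cid in range(1, len(communities) + 1)}
    return ClusterAssignment(membership=membership, modularity=float(q), labels=labels)


def identify_core(g: nx.Graph, assignment: ClusterAssignment) -> dict[int, str]:
    """Per-cluster core herb: max degree, then max prevalence, then name.

    Operationalises the qualitative criterion that the herb with the highest
    prevalence and most connections anchors its community.
    """
    missing = set(g.nodes) - set(assignment.membership)
    if missing:
        raise ValueError(f"assignment does not cover nodes: {sorted(missing)}")
    deg = degree_centrality(g)

    def score(node: str) -> tuple:
        prev = g.nodes[node].get("prevalence", float("nan"))
        prev = prev if prev == prev else -1.0  # missing prevalence sorts last
        return (-deg[node], -prev, node)

    cores = {
        cid: min(nodes, key=score) for cid, nodes in assignment.clusters.items()
    }
    assignment.cores = dict(sorted(cores.items()))
    return assignment.cores
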