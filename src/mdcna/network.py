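"""Residue interaction networks, communities and betweenness hubs.

A residue network has one node per residue of the filtered DCCM and one edge
per surviving correlation.  Edges carry two weights: the correlation
magnitude |C_ij| (used when scoring partitions by modularity) and a path
weight -log|C_ij| (so strongly correlated pairs are *close*, and shortest
paths follow chains of strong correlation).

Communities come from Girvan-Newman clustering: repeatedly remove the edge
with the highest weighted edge betweenness and, among the partitions so
produced, keep the one with maximal Newman-Girvan modularity.  Hub residues
are nominated by node-betweenness centrality with a nearest-rank percentile
threshold; a threshold computed on one profile can be applied to another,
which is how a wild-type network's threshold is imposed on a mutant's.

Ties (equal betweenness within 1e-9) are always broken toward the
lexicographically smallest node/edge label, so results do not depend on node
input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .dccm import FilteredCorrelation

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityPartition",
    "CentralityProfile",
    "build_network",
    "girvan_newman",
    "node_betweenness",
    "edge_betweenness",
    "centrality_threshold",
    "nearest_rank_threshold",
    "annotate_residues",
    "network_to_edge_table",
]

_CLAMP = 1.0 - 1e-12
_TIE_TOL = 1e-9


def build_network(fc: FilteredCorrelation) -> nx.Graph:
    """Residue graph from a filtered DCCM.

    One edge per unmasked off-diagonal pair, with attributes ``corr``
    (= |C_ij|) and ``path_weight`` (= -log |C_ij|).  |C| = 1 is clamped just
    below 1 (a zero path length would break shortest-path semantics).
    Residues that lose all their correlations remain as isolated nodes.
    """
    if not fc.keep.any():
        raise ValueError("filtered correlation matrix has no surviving entries")
    g = nx.Graph()
    g.add_nodes_from(fc.residue_labels)
    n = len(fc.residue_labels)
    clamped = 0
    for i in range(n):
        for j in range(i + 1, n):
            if not fc.keep[i, j]:
                continue
            c = abs(fc.values[i, j])
            if c >= 1.0:
                c = _CLAMP
                clamped += 1
            g.add_edge(
                fc.residue_labels[i],
                fc.residue_labels[j],
                corr=float(abs(fc.values[i, j])),
                path_weight=float(-np.log(c)),
            )
    if clamped:
        logger.warning("clamped %d |C|=1 edges to %s for path weights", clamped, _CLAMP)
    return g


@dataclass(frozen=True)
class CommunityPartition:
    """A total partition of network nodes into communities.

    Communities are numbered 0.. in order of decreasing size (ties by first
    label).  ``coupling`` holds, for each pair of communities, the summed
    |C_ij| over network edges cut between them.
    """

    membership: dict  # node -> community id
    sizes: tuple  # residues per community
    coupling: dict  # (id_a, id_b) with a < b -> summed |C| across cut edges
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(self.sizes)

    @property
    def total_coupling(self) -> float:
        return float(sum(self.coupling.values()))

    def community_nodes(self, cid: int) -> list:
        return sorted(n for n, c in self.membership.items() if c == cid)


def _components_partition(g: nx.Graph) -> list[tuple]:
    comps = [tuple(sorted(c)) for c in nx.connected_components(g)]
    comps.sort()
    return comps


def _finish_partition(network: nx.Graph, communities: list[tuple], q: float) -> CommunityPartition:
    ordered = sorted(communities, key=lambda c: (-len(c), c))
    membership = {node: cid for cid, comm in enumerate(ordered) for node in comm}
    coupling: dict = {}
    for u, v, data in network.edges(data=True):
        a, b = membership[u], membership[v]
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        coupling[key] = coupling.get(key, 0.0) + data["corr"]
    return CommunityPartition(membership, tuple(len(c) for c in ordered), coupling, q)


def _norm_edge(e) -> tuple:
    u, v = e
    return (u, v) if u <= v else (v, u)


def girvan_newman(network: nx.Graph) -> CommunityPartition:
    """Girvan-Newman community detection with modularity-based selection.

    The full dendrogram is produced by iteratively removing the edge with the
    highest weighted edge betweenness (shortest paths over ``path_weight``);
    every time the component count grows, the partition is scored by
    Newman-Girvan modularity with ``corr`` edge weights, and the best-scoring
    partition is returned.  Edge betweenness is recomputed only within the
    component that lost an edge.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    if network.number_of_edges() == 0:
        raise ValueError("network has no edges")
    h = network.copy()
    current = _components_partition(h)
    best_q = nx.community.modularity(network, current, weight="corr")
    best = current
    eb = {
        _norm_edge(e): v
        for e, v in nx.edge_betweenness_centrality(
            h, normalized=False, weight="path_weight"
        ).items()
    }
    while h.number_of_edges():
        top = max(eb.values())
        u, v = min(e for e, val in eb.items() if val >= top - _TIE_TOL)
        comp_before = nx.node_connected_component(h, u)
        h.remove_edge(u, v)
        for e in [e for e in eb if e[0] in comp_before or e[1] in comp_before]:
            del eb[e]
        seen: set = set()
        for node in (u, v):
            comp = nx.node_connected_component(h, node)
            if node in seen:
                continue
            seen |= comp
            sub = h.subgraph(comp)
            if sub.number_of_edges():
                eb.update(
                    (_norm_edge(e), val)
                    for e, val in nx.edge_betweenness_centrality(
                        sub, normalized=False, weight="path_weight"
                    ).items()
                )
        parts = _components_partition(h)
        if len(parts) > len(current):
            current = parts
            q = nx.community.modularity(network, parts, weight="corr")
            logger.debug("split -> %d communities, Q=%.6f", len(parts), q)
            if q > best_q + 1e-12:
                best_q, best = q, parts
    return _finish_partition(network, best, best_q)


@dataclass(frozen=True)
class CentralityProfile:
    """Node-betweenness values, optionally with a percentile threshold.

    ``high_set`` holds the nodes strictly above ``threshold``; by the
    nearest-rank construction, at least the configured fraction of values
    lies at or below the threshold.
    """

    centrality: dict  # node -> betweenness (>= 0)
    percentile: float | None = None
    threshold: float | None = None
    high_set: tuple = ()

    def values(self) -> np.ndarray:
        return np.array([self.centrality[n] for n in sorted(self.centrality)])


def node_betweenness(network: nx.Graph) -> CentralityProfile:
    """Weighted node-betweenness centrality for every residue.

    For each node, the number of shortest paths (over ``path_weight``)
    between all other node pairs that pass through it; degenerate shortest
    paths contribute fractionally (Brandes accumulation) and disconnected
    pairs contribute nothing.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    values = nx.betweenness_centrality(network, normalized=False, weight="path_weight")
    return CentralityProfile({n: float(v) for n, v in values.items()})


def edge_betweenness(network: nx.Graph) -> dict:
    """Weighted edge betweenness (same path convention as node betweenness)."""
    eb = nx.edge_betweenness_centrality(network, normalized=False, weight="path_weight")
    return {_norm_edge(e): float(v) for e, v in eb.items()}


def nearest_rank_threshold(values, percentile: float) -> float:
    """Nearest-rank percentile: smallest value with >= percentile% at or below."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("empty profile")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    return float(np.percentile(values, percentile, method="inverted_cdf"))


def centrality_threshold(profile: CentralityProfile, percentile: float = 98.5,
                         reference: CentralityProfile | None = None) -> CentralityProfile:
    """Attach a percentile threshold and the resulting high-centrality set.

    The threshold is the nearest-rank percentile of ``reference`` (default:
    the profile itself); the high set contains nodes strictly above it.
    Passing a wild-type profile as ``reference`` applies the wild-type
    threshold to a mutant profile.
    """
    source = profile if reference is None else reference
    thr = nearest_rank_threshold(source.centrality.values(), percentile)
    high = tuple(sorted(n for n, v in profile.centrality.items() if v > thr))
    return CentralityProfile(dict(profile.centrality), float(percentile), thr, high)


def annotate_residues(partition: CommunityPartition, profile: CentralityProfile,
                      annotations: dict) -> pd.DataFrame:
    """Cross-reference named residue sets with communities and hub status.

    ``annotations`` maps a set name (e.g. "R-spine") to residue labels or
    bare residue numbers.  For each set the report lists the community ids
    spanned, the members of the high-centrality set, and any residues absent
    from the network (reported, not fatal).
    """
    by_number: dict = {}
    for node in partition.membership:
        digits = "".join(ch for ch in str(node) if ch.isdigit())
        if digits:
            by_number.setdefault(int(digits), node)
    rows = []
    for name in sorted(annotations):
        members = annotations[name]
        mapped, unmapped = [], []
        for m in members:
            if m in partition.membership:
                mapped.append(m)
            elif isinstance(m, (int, np.integer)) and int(m) in by_number:
                mapped.append(by_number[int(m)])
            else:
                unmapped.append(str(m))
        comms = sorted({partition.membership[m] for m in mapped})
        high = sorted(set(mapped) & set(profile.high_set))
        rows.append(
            {
                "set": name,
                "n_named": len(members),
                "n_mapped": len(mapped),
                "communities": ",".join(str(c) for c in comms),
                "n_communities": len(comms),
                "high_centrality_members": ",".join(str(h) for h in high),
                "n_high": len(high),
                "unmapped": ",".join(unmapped),
            }
        )
    return pd.DataFrame(rows)


def network_to_edge_table(network: nx.Graph) -> pd.DataFrame:
    """Edge list (node1, node2, |C|, path_weight) sorted for determinism."""
    rows = [
        {"node1": e[0], "node2": e[1], "correlation": d["corr"],
         "path_weight": d["path_weight"]}
        for *e, d in (
            (u, v, data) if u <= v else (v, u, data)
            for u, v, data in network.edges(data=True)
        )
    ]
    rows.sort(key=lambda r: (r["node1"], r["node2"]))
    return pd.DataFrame(rows, columns=["node1", "node2", "correlation", "path_weight"])
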