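"""Independent brute-force oracles used to validate the implementation.

Each oracle computes the same quantity as the library by a deliberately
different route (exhaustive enumeration, double loops, grid search) so that
agreement is evidence of correctness rather than of shared code.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_betweenness(g: nx.Graph, weight: str = "path_weight"):
    """Node and edge betweenness by enumerating every simple path.

    For each node pair, all simple paths are listed, the minimal total
    weight identified, and every minimal path contributes 1/sigma to its
    interior nodes and edges (sigma = number of minimal paths).
    """
    node_bt = {v: 0.0 for v in g}
    edge_bt = {tuple(sorted(e)): 0.0 for e in g.edges}
    for s, t in itertools.combinations(sorted(g), 2):
        weighted = []
        for path in nx.all_simple_paths(g, s, t):
            w = sum(g[u][v][weight] for u, v in zip(path, path[1:]))
            weighted.append((w, path))
        if not weighted:
            continue
        best = min(w for w, _ in weighted)
        shortest = [p for w, p in weighted if w - best <= 1e-12]
        sigma = len(shortest)
        for p in shortest:
            for v in p[1:-1]:
                node_bt[v] += 1.0 / sigma
            for u, v in zip(p, p[1:]):
                edge_bt[tuple(sorted((u, v)))] += 1.0 / sigma
    return node_bt, edge_bt


def random_connected_graph(rng: np.random.Generator, max_nodes: int = 12,
                           max_edges: int = 20) -> nx.Graph:
    """A random connected weighted graph with distinct continuous weights."""
    n = int(rng.integers(3, max_nodes + 1))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    order = list(rng.permutation(n))
    for a, b in zip(order, order[1:]):  # random spanning tree
        g.add_edge(int(a), int(b))
    candidates = [
        (i, j) for i in range(n) for j in range(i + 1, n) if not g.has_edge(i, j)
    ]
    rng.shuffle(candidates)
    for i, j in candidates[: max(0, int(rng.integers(0, max_edges)) - (n - 1))]:
        g.add_edge(i, j)
    for u, v in g.edges:
        g[u][v]["path_weight"] = float(rng.uniform(0.1, 2.0))
        g[u][v]["corr"] = float(np.exp(-g[u][v]["path_weight"]))
    return g


def brute_force_dccm(coords: np.ndarray) -> np.ndarray:
    """DCCM by an explicit per-pair, per-frame double loop."""
    f, n, _ = coords.shape
    mean = coords.mean(axis=0)
    d = coords - mean
    c = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            num = sum(float(d[k, i] @ d[k, j]) for k in range(f)) / f
            vi = sum(float(d[k, i] @ d[k, i]) for k in range(f)) / f
            vj = sum(float(d[k, j] @ d[k, j]) for k in range(f)) / f
            c[i, j] = num / np.sqrt(vi * vj)
    return c


def brute_force_occupancy(coords: np.ndarray, cutoff: float) -> np.ndarray:
    """Contact occupancy by a per-frame, per-pair recount."""
    f, n, _ = coords.shape
    occ = np.zeros((n, n))
    for k in range(f):
        for i in range(n):
            for j in range(n):
                if np.linalg.norm(coords[k, i] - coords[k, j]) <= cutoff:
                    occ[i, j] += 1
    return occ / f


def grid_min_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimal RMSD over rotations by coarse grid search plus refinement.

    The optimal translation always matches the centroids, so both point sets
    are centred and the search runs over rotation vectors only.  A 26-
    direction x 13-magnitude grid seeds a Nelder-Mead polish; no SVD is
    involved anywhere.
    """
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def cost(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return float(np.sqrt(np.mean(np.sum((mob @ r.T - ref) ** 2, axis=1))))

    directions = [
        np.array(d, dtype=float)
        for d in itertools.product((-1, 0, 1), repeat=3)
        if any(d)
    ]
    best_val, best_rv = cost(np.zeros(3)), np.zeros(3)
    for direction in directions:
        unit = direction / np.linalg.norm(direction)
        for mag in np.linspace(0.25, np.pi, 13):
            rv = unit * mag
            val = cost(rv)
            if val < best_val:
                best_val, best_rv = val, rv
    res = minimize(
        cost, best_rv, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000},
    )
    return float(min(best_val, res.fun))
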