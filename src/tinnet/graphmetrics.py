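"""Global and nodal graph summary measures.

Modularity (Newman-Girvan, maximized by seeded Louvain with restarts),
global/nodal efficiency (mean inverse shortest path; unreachable pairs
contribute 0, keeping values in [0, 1]), and local/global clustering
(degree-<2 nodes have local clustering 0 and are included in the global
average). An exhaustive-partition modularity maximizer serves as an
independent oracle for graphs of at most 10 nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .containers import BinaryGraph

DEFAULT_LOUVAIN_RESTARTS = 20


@dataclass
class Partition:
    """Node -> community assignment with contiguous ids from 0."""

    membership: np.ndarray
    def __post_init__(self) -> None:
        m = np.asarray(self.membership, dtype=int)
        # remap to contiguous ids in order of first appearance
        _, first = np.unique(m, return_index=True)
        order = m[np.sort(first)]
        remap = {c: i for i, c in enumerate(order)}
        self.membership = np.array([remap[c] for c in m], dtype=int)

    @property
    def n_communities(self) -> int:
        return int(self.membership.max()) + 1 if self.membership.size else 0

    @property
    def n_nodes(self) -> int:
        return self.membership.size

    def communities(self) -> list[np.ndarray]:
        return [np.where(self.membership == c)[0]
                for c in range(self.n_communities)]


def modularity(graph: BinaryGraph, partition: Partition) -> float | None:
    """Newman-Girvan Q = sum_c [e_c/m - (d_c/(2m))^2].

    Returns ``None`` (undefined) for edgeless graphs.
    """
    if partition.n_nodes != graph.n_nodes:
        raise ValueError("partition does not cover the graph's nodes")
    m = graph.n_edges
    if m == 0:
        return None
    a = graph.adjacency.astype(float)
    deg = graph.degrees().astype(float)
    q = 0.0
    for nodes in partition.communities():
        e_c = a[np.ix_(nodes, nodes)].sum() / 2.0
        d_c = deg[nodes].sum()
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return float(q)


_GAIN_EPS = 1e-12


def _louvain_one_level(W: np.ndarray, self_w: np.ndarray, m: float,
                       rng: np.random.Generator) -> np.ndarray:
    """One Louvain sweep on a weighted aggregated graph.

    ``W`` holds inter-node weights (zero diagonal), ``self_w`` twice the
    internal weight of each super-node. Moves are accepted only for
    modularity gains above a small epsilon; since every accepted move
    raises Q by at least that amount and Q is bounded, the sweep always
    terminates (a strict > 0 rule can cycle on floating-point ties).
    """
    n = W.shape[0]
    k = W.sum(axis=1) + self_w
    node2com = np.arange(n)
    stot = k.copy()
    order = rng.permutation(n)
    moved = True
    while moved:
        moved = False
        for u in order:
            cu = node2com[u]
            stot[cu] -= k[u]
            nbrs = np.nonzero(W[u])[0]
            w2c: dict[int, float] = {}
            for v in nbrs:
                c = node2com[v]
                w2c[c] = w2c.get(c, 0.0) + W[u, v]
            remove_cost = (-w2c.get(cu, 0.0) / m
                           + k[u] * stot[cu] / (2.0 * m * m))
            best_gain, best = 0.0, cu
            for c, w in w2c.items():
                gain = remove_cost + w / m - k[u] * stot[c] / (2.0 * m * m)
                if gain > best_gain + _GAIN_EPS:
                    best_gain, best = gain, c
            stot[best] += k[u]
            if best != cu:
                node2com[u] = best
                moved = True
    return node2com


def _louvain_run(adj: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = adj.shape[0]
    membership = np.arange(n)
    W = adj.astype(float)
    self_w = np.zeros(W.shape[0])
    m = W.sum() / 2.0
    while True:
        level = _louvain_one_level(W, self_w, m, rng)
        # contiguous community ids in order of first appearance
        _, first = np.unique(level, return_index=True)
        remap = {c: i for i, c in enumerate(level[np.sort(first)])}
        level = np.array([remap[c] for c in level])
        n_comm = level.max() + 1
        if n_comm == W.shape[0]:
            return membership
        membership = level[membership]
        # aggregate: inter-community weights and doubled internal weight
        onehot = np.zeros((W.shape[0], n_comm))
        onehot[np.arange(W.shape[0]), level] = 1.0
        block = onehot.T @ W @ onehot
        self_w = np.diag(block).copy() + onehot.T @ self_w
        W = block
        np.fill_diagonal(W, 0.0)


def louvain_communities(graph: BinaryGraph, seed: int,
                        restarts: int = DEFAULT_LOUVAIN_RESTARTS) -> Partition:
    """Seeded Louvain partition; best of ``restarts`` runs by Q.

    Edgeless graphs get the singleton partition (Q is undefined there
    and reported as missing by :func:`modularity`).
    """
    if graph.n_edges == 0:
        return Partition(np.arange(graph.n_nodes))
    adj = graph.adjacency
    best_q, best = -np.inf, None
    for r in range(restarts):
        rng = np.random.default_rng(seed + r)
        part = Partition(_louvain_run(adj, rng))
        q = modularity(graph, part)
        if q is not None and q > best_q + 1e-15:
            best_q, best = q, part
    return best


def global_efficiency(graph: BinaryGraph) -> float:
    """Mean over unordered pairs of 1/shortest-path-length."""
    if graph.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    inv = _inverse_distances(graph)
    n = graph.n_nodes
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(graph: BinaryGraph, node: int | None = None):
    """Mean over other nodes of 1/distance from ``node``.

    With ``node=None`` returns the full per-node vector.
    """
    inv = _inverse_distances(graph)
    vec = inv.sum(axis=1) / (graph.n_nodes - 1)
    if node is None:
        return vec
    return float(vec[node])


def _inverse_distances(graph: BinaryGraph) -> np.ndarray:
    d = shortest_path(csr_matrix(graph.adjacency), method="D",
                      unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv


def local_clustering(graph: BinaryGraph, node: int | None = None):
    """Fraction of a node's neighbour pairs that are connected.

    Degree-<2 nodes are assigned 0 (a convention that shifts the global
    average on sparse graphs; applied consistently everywhere).
    """
    a = graph.adjacency.astype(np.int64)
    deg = a.sum(axis=1)
    tri = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    if node is None:
        return c
    return float(c[node])


def global_clustering(graph: BinaryGraph) -> float:
    """Unweighted mean of local clustering over all nodes."""
    if graph.n_nodes < 1:
        raise ValueError("need at least 1 node")
    return float(np.mean(local_clustering(graph)))


def _partitions_membership(n: int):
    """Yield all set partitions of n items as membership arrays
    (restricted-growth strings)."""
    a = np.zeros(n, dtype=int)
    b = np.zeros(n, dtype=int)  # b[i] = max(a[:i+1])
    while True:
        yield a.copy()
        # find rightmost position that can be incremented
        j = n - 1
        while j > 0 and a[j] == b[j - 1] + 1:
            j -= 1
        if j == 0:
            return
        a[j] += 1
        b[j] = max(b[j - 1], a[j])
        for k in range(j + 1, n):
            a[k] = 0
            b[k] = b[j]


def brute_force_max_modularity(graph: BinaryGraph) -> tuple[Partition, float]:
    """Exact maximizer of Q over all set partitions (<= 10 nodes)."""
    n = graph.n_nodes
    if n > 10:
        raise ValueError("exhaustive search limited to 10 nodes")
    if graph.n_edges == 0:
        raise ValueError("modularity undefined for edgeless graphs")
    parts = np.array(list(_partitions_membership(n)))
    iu, ju = np.triu_indices(n, 1)
    a = graph.adjacency.astype(float)
    deg = graph.degrees().astype(float)
    m = graph.n_edges
    same = parts[:, iu] == parts[:, ju]  # (n_partitions, n_pairs)
    edge_term = (same * a[iu, ju]).sum(axis=1) / m
    deg_term = (2.0 * (same * (deg[iu] * deg[ju])).sum(axis=1)
                + (deg ** 2).sum()) / (2.0 * m) ** 2
    q = edge_term - deg_term
    best = int(np.argmax(q))
    return Partition(parts[best]), float(q[best])


def metric_record(graph: BinaryGraph, subject: str, session: str,
                  density: float, seed: int,
                  restarts: int = DEFAULT_LOUVAIN_RESTARTS,
                  include_nodal: bool = True) -> pd.DataFrame:
    """Long-format rows (subject, session, density, metric, node, value)
    for one graph: Q, E_glob, C_glob and optionally per-node E/C."""
    part = louvain_communities(graph, seed=seed, restarts=restarts)
    q = modularity(graph, part)
    rows = [
        {"subject": subject, "session": session, "density": density,
         "metric": "Q", "node": "", "value": np.nan if q is None else q},
        {"subject": subject, "session": session, "density": density,
         "metric": "E_glob", "node": "", "value": global_efficiency(graph)},
        {"subject": subject, "session": session, "density": density,
         "metric": "C_glob", "node": "", "value": global_clustering(graph)},
        {"subject": subject, "session": session, "density": density,
         "metric": "n_communities", "node": "",
         "value": float(part.n_communities)},
    ]
    if include_nodal:
        e_nodal = nodal_efficiency(graph)
        c_local = local_clustering(graph)
        for i, lab in enumerate(graph.node_labels):
            rows.append({"subject": subject, "session": session,
                         "density": density, "metric": "E_nodal",
                         "node": lab, "value": float(e_nodal[i])})
            rows.append({"subject": subject, "session": session,
                         "density": density, "metric": "C_local",
                         "node": lab, "value": float(c_local[i])})
    return pd.DataFrame(rows)
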