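"""Global and nodal graph-theory measures on binary undirected networks.

Global measures: mean nodal clustering, global efficiency, Newman modularity
(greedy multilevel optimization with random restarts), characteristic path
length on the largest component, and small-worldness sigma against a
degree-preserving rewired null ensemble. Nodal measures: betweenness,
eigenvector and closeness centrality.

Distances are hop counts from a matrix-based breadth-first search; community
detection runs through igraph's multilevel (Louvain) optimizer, modularity
values and betweenness through standard library definitions. Closeness and
path length are computed within connected components, and disconnected pairs
contribute zero to efficiency — disconnection is expected at low edge
density, so no measure assumes a connected graph.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np

from .idscn_builder import BinaryNetwork


@dataclass
class NullModelConfig:
    """Degree-preserving rewired ensemble for small-worldness."""

    n_nulls: int = 100
    rewires_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nulls < 1:
            raise ValueError("n_nulls must be >= 1")


@dataclass
class GlobalMetrics:
    clustering: float
    efficiency: float
    modularity_q: float
    path_length: float
    small_worldness: float
    largest_component_fraction: float


def _adjacency(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    adj = net.adjacency if isinstance(net, BinaryNetwork) else np.asarray(net)
    return adj.astype(np.int8, copy=False)


def _to_networkx(adj: np.ndarray) -> nx.Graph:
    g = nx.from_numpy_array(adj.astype(int))
    g.add_nodes_from(range(adj.shape[0]))
    return g


def bfs_distance_matrix(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """All-pairs hop distances; unreachable pairs are +inf."""
    adj = _adjacency(net).astype(bool)
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = reached.copy()
    d = 0
    while frontier.any():
        d += 1
        frontier = (frontier @ adj) & ~reached
        dist[frontier] = d
        reached |= frontier
    return dist


def clustering_coefficients(net: BinaryNetwork | np.ndarray) -> tuple[np.ndarray, float]:
    """Nodal c_i = 2 t_i / (k_i (k_i - 1)) and their unweighted mean.

    Nodes of degree < 2 have c_i = 0.
    """
    adj = _adjacency(net).astype(np.float64)
    k = adj.sum(axis=1)
    triangles = np.einsum("ij,jk,ik->i", adj, adj, adj) / 2.0
    denom = k * (k - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return c, float(c.mean())


def global_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Mean inverse hop distance over node pairs (disconnected pairs -> 0)."""
    dist = bfs_distance_matrix(net)
    n = dist.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist[off]
    return float(np.where(np.isfinite(inv), inv, 0.0).mean())


def component_labels(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """Connected-component label per node (labels are representative indices)."""
    dist = bfs_distance_matrix(net)
    reach = np.isfinite(dist)
    return np.argmax(reach, axis=1)


def largest_component_fraction(net: BinaryNetwork | np.ndarray) -> float:
    labels = component_labels(net)
    _, counts = np.unique(labels, return_counts=True)
    return float(counts.max()) / len(labels)


def characteristic_path_length(net: BinaryNetwork | np.ndarray) -> float:
    """Mean geodesic distance over pairs within the largest component."""
    dist = bfs_distance_matrix(net)
    labels = component_labels(net)
    values, counts = np.unique(labels, return_counts=True)
    giant = values[np.argmax(counts)]
    members = np.flatnonzero(labels == giant)
    if len(members) < 2:
        raise ValueError("largest component has fewer than 2 nodes")
    sub = dist[np.ix_(members, members)]
    iu = np.triu_indices(len(members), k=1)
    return float(sub[iu].mean())


def modularity_partition(
    net: BinaryNetwork | np.ndarray,
    n_restarts: int = 20,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Best Newman modularity over seeded multilevel-heuristic restarts.

    Each restart permutes the node order (the heuristic is order dependent)
    and reseeds the optimizer; the highest-Q partition is returned as
    (Q, membership). Deterministic given ``seed``.
    """
    adj = _adjacency(net)
    n = adj.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mask = adj[iu, ju] > 0
    if not mask.any():
        raise ValueError("modularity is undefined for an edgeless graph")
    edges_i, edges_j = iu[mask], ju[mask]
    rng = np.random.default_rng(seed)
    best_q, best_membership = -np.inf, None
    for _ in range(max(1, n_restarts)):
        perm = rng.permutation(n)
        ig.set_random_number_generator(random.Random(int(rng.integers(2**31))))
        g = ig.Graph(
            n=n, edges=list(zip(perm[edges_i].tolist(), perm[edges_j].tolist()))
        )
        communities = g.community_multilevel()
        q = float(communities.modularity)
        if q > best_q:
            best_q = q
            membership = np.asarray(communities.membership)
            best_membership = membership[perm]
    return best_q, best_membership


def modularity_score(net: BinaryNetwork | np.ndarray, membership: np.ndarray) -> float:
    """Newman Q of a given partition: sum_c [e_c/m - (d_c/2m)^2]."""
    adj = _adjacency(net).astype(float)
    m = adj.sum() / 2.0
    if m == 0:
        raise ValueError("modularity is undefined for an edgeless graph")
    membership = np.asarray(membership)
    q = 0.0
    for label in np.unique(membership):
        nodes = membership == label
        e_c = adj[np.ix_(nodes, nodes)].sum() / 2.0
        d_c = adj[nodes].sum()
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return float(q)


def degree_preserving_null(
    net: BinaryNetwork | np.ndarray,
    seed: int | np.random.Generator = 0,
    rewires_per_edge: int = 10,
) -> BinaryNetwork:
    """Rewire by double edge swaps, preserving every node's degree exactly.

    Attempts ``rewires_per_edge * m`` swaps; invalid proposals (shared
    endpoints or existing target edges) are skipped. Connectivity is not
    enforced. Graphs admitting no valid swap (e.g. complete graphs) come
    back unchanged with a warning.
    """
    adj = _adjacency(net).copy()
    density = net.density if isinstance(net, BinaryNetwork) else float(adj.sum()) / max(
        1, adj.shape[0] * (adj.shape[0] - 1)
    )
    iu, ju = np.triu_indices(adj.shape[0], k=1)
    mask = adj[iu, ju] > 0
    edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    m = len(edges)
    if m < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    attempts = rewires_per_edge * m
    pair_idx = rng.integers(0, m, size=(attempts, 2))
    flips = rng.random(attempts) < 0.5
    swaps = 0
    for t in range(attempts):
        e1, e2 = pair_idx[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flips[t]:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = 0
        adj[c, d] = adj[d, c] = 0
        adj[a, d] = adj[d, a] = 1
        adj[c, b] = adj[b, c] = 1
        edges[e1] = (a, d) if a < d else (d, a)
        edges[e2] = (c, b) if c < b else (b, c)
        swaps += 1
    if swaps == 0:
        warnings.warn(
            "no valid degree-preserving swap found; returning the graph unchanged",
            stacklevel=2,
        )
    return BinaryNetwork(adjacency=adj, density=float(density), n_edges=m)


def small_worldness(
    net: BinaryNetwork | np.ndarray,
    null_config: NullModelConfig | None = None,
) -> float:
    """sigma = (C / <C_null>) / (L / <L_null>) against rewired nulls."""
    null_config = null_config or NullModelConfig()
    adj = _adjacency(net)
    labels = component_labels(adj)
    _, counts = np.unique(labels, return_counts=True)
    if counts.max() < 3:
        raise ValueError("largest component must have at least 3 nodes")
    _, c_obs = clustering_coefficients(adj)
    l_obs = characteristic_path_length(adj)
    rng = np.random.default_rng(null_config.seed)
    c_nulls = np.empty(null_config.n_nulls)
    l_nulls = np.empty(null_config.n_nulls)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # unswappable graphs fall through as-is
        for i in range(null_config.n_nulls):
            null = degree_preserving_null(
                adj, seed=rng, rewires_per_edge=null_config.rewires_per_edge
            )
            _, c_nulls[i] = clustering_coefficients(null.adjacency)
            l_nulls[i] = characteristic_path_length(null.adjacency)
    c_null = c_nulls.mean()
    l_null = l_nulls.mean()
    if c_null == 0:
        raise ValueError("null ensemble has zero clustering; sigma undefined")
    return float((c_obs / c_null) / (l_obs / l_null))


def betweenness_centrality(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """Unnormalized geodesic betweenness (each unordered pair counted once)."""
    g = _to_networkx(_adjacency(net))
    values = nx.betweenness_centrality(g, normalized=False)
    return np.array([values[v] for v in range(g.number_of_nodes())])


def eigenvector_centrality(net: BinaryNetwork | np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Leading adjacency eigenvector, nonnegative entries, unit Euclidean norm."""
    adj = _adjacency(net).astype(float)
    n = adj.shape[0]
    if adj.sum() == 0:
        raise ValueError("eigenvector centrality is undefined for an edgeless graph")
    # solve per connected component so the Perron-Frobenius vector is well
    # defined even when two components tie in spectral radius; the vector is
    # supported on the component with the largest leading eigenvalue
    # (first such component on an exact tie).
    labels = component_labels(adj)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for label in np.unique(labels):
        members = np.flatnonzero(labels == label)
        if len(members) < 2:
            continue
        sub = adj[np.ix_(members, members)]
        eigenvalues, eigenvectors = np.linalg.eigh(sub)
        lam = eigenvalues[-1]
        if best is None or lam > best[0] + tol:
            best = (lam, members, eigenvectors[:, -1])
    assert best is not None
    _, members, vec = best
    if vec.sum() < 0:
        vec = -vec
    vec = np.clip(vec, 0.0, None)
    v = np.zeros(n)
    v[members] = vec
    return v / np.linalg.norm(v)


def closeness_centrality(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """Within-component closeness (s-1)/sum(d); isolated nodes get 0."""
    dist = bfs_distance_matrix(net)
    finite = np.isfinite(dist)
    sizes = finite.sum(axis=1)  # component size including self
    sums = np.where(finite, dist, 0.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        closeness = np.where(sizes > 1, (sizes - 1) / sums, 0.0)
    return closeness


def global_metrics(
    net: BinaryNetwork | np.ndarray,
    null_config: NullModelConfig | None = None,
    n_restarts: int = 20,
    seed: int = 0,
) -> GlobalMetrics:
    """All global measures of one binary network in a single record."""
    _, clustering = clustering_coefficients(net)
    q, _ = modularity_partition(net, n_restarts=n_restarts, seed=seed)
    return GlobalMetrics(
        clustering=clustering,
        efficiency=global_efficiency(net),
        modularity_q=q,
        path_length=characteristic_path_length(net),
        small_worldness=small_worldness(net, null_config),
        largest_component_fraction=largest_component_fraction(net),
    )
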