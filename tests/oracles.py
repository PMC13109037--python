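"""Independent brute-force reference implementations used only by tests.

Everything here favors obviousness over speed: explicit loops, exhaustive
enumeration, textbook formulas. These are the oracles the package
implementations are checked against on small inputs.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def random_graph(rng: np.random.Generator, n: int, p: float = 0.4) -> np.ndarray:
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, 1).astype(np.int8)
    return adj + adj.T


def bfs_distances(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in range(n):
                if adj[u, v] and np.isinf(dist[s, v]):
                    dist[s, v] = dist[s, u] + 1
                    queue.append(v)
    return dist


def clustering(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        neigh = [j for j in range(n) if adj[i, j]]
        k = len(neigh)
        if k < 2:
            continue
        triangles = sum(
            adj[u, v] for u, v in itertools.combinations(neigh, 2)
        )
        out[i] = 2.0 * triangles / (k * (k - 1))
    return out


def global_efficiency(adj: np.ndarray) -> float:
    dist = bfs_distances(adj)
    n = adj.shape[0]
    total = 0.0
    for i, j in itertools.combinations(range(n), 2):
        if np.isfinite(dist[i, j]):
            total += 1.0 / dist[i, j]
    return 2.0 * total / (n * (n - 1)) if n > 1 else 0.0


def components(adj: np.ndarray) -> list[set[int]]:
    n = adj.shape[0]
    seen: set[int] = set()
    out = []
    for s in range(n):
        if s in seen:
            continue
        comp = {s}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in range(n):
                if adj[u, v] and v not in comp:
                    comp.add(v)
                    queue.append(v)
        seen |= comp
        out.append(comp)
    return out


def largest_component_fraction(adj: np.ndarray) -> float:
    return max(len(c) for c in components(adj)) / adj.shape[0]


def characteristic_path_length(adj: np.ndarray) -> float:
    giant = max(components(adj), key=len)
    dist = bfs_distances(adj)
    pairs = [dist[i, j] for i, j in itertools.combinations(sorted(giant), 2)]
    return float(np.mean(pairs))


def closeness(adj: np.ndarray) -> np.ndarray:
    dist = bfs_distances(adj)
    comps = components(adj)
    out = np.zeros(adj.shape[0])
    for comp in comps:
        if len(comp) < 2:
            continue
        for v in comp:
            out[v] = (len(comp) - 1) / sum(dist[v, u] for u in comp if u != v)
    return out


def _all_shortest_paths(adj: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    """Every geodesic from s to t, by exhaustive simple-path enumeration."""
    n = adj.shape[0]
    paths: list[tuple[int, ...]] = []

    def extend(path: tuple[int, ...]) -> None:
        last = path[-1]
        if last == t:
            paths.append(path)
            return
        for v in range(n):
            if adj[last, v] and v not in path:
                extend(path + (v,))

    extend((s,))
    if not paths:
        return []
    shortest = min(len(p) for p in paths)
    return [p for p in paths if len(p) == shortest]


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized geodesic betweenness, each unordered pair counted once."""
    n = adj.shape[0]
    out = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        geodesics = _all_shortest_paths(adj, s, t)
        if not geodesics:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in geodesics if v in p)
            out[v] += through / len(geodesics)
    return out


def eigenvector(adj: np.ndarray, iterations: int = 20000) -> np.ndarray:
    """Leading eigenvector by power iteration on the dominant component."""
    comps = [sorted(c) for c in components(adj) if len(c) > 1]
    best_vec, best_lam = None, -np.inf
    for comp in comps:
        sub = adj[np.ix_(comp, comp)].astype(float)
        shift = sub + len(comp) * np.eye(len(comp))  # ensure dominance
        v = np.ones(len(comp))
        for _ in range(iterations):
            v = shift @ v
            v /= np.linalg.norm(v)
        lam = v @ sub @ v
        if lam > best_lam + 1e-12:
            best_lam, best_vec, best_comp = lam, v, comp
    out = np.zeros(adj.shape[0])
    out[best_comp] = np.abs(best_vec)
    return out / np.linalg.norm(out)


def set_partitions(items: list[int]):
    """All partitions of a list (Bell-number enumeration)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [[first] + subset] + smaller[i + 1 :]
        yield [[first]] + smaller


def exhaustive_modularity(adj: np.ndarray) -> float:
    """Maximum Newman Q over every partition of the node set."""
    n = adj.shape[0]
    iu, ju = np.nonzero(np.triu(adj, 1))
    m = len(iu)
    degrees = adj.sum(axis=1).astype(float)
    best = -np.inf
    for part in set_partitions(list(range(n))):
        memb = np.empty(n, dtype=int)
        for c, nodes in enumerate(part):
            memb[nodes] = c
        within = (memb[iu] == memb[ju]).sum() / m
        d_c = np.bincount(memb, weights=degrees)
        best = max(best, within - ((d_c / (2.0 * m)) ** 2).sum())
    return float(best)


def cliffs_delta_pairs(a: np.ndarray, b: np.ndarray) -> float:
    greater = smaller = 0
    for x in a:
        for y in b:
            greater += x > y
            smaller += x < y
    return (greater - smaller) / (len(a) * len(b))


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Step-up BH by the p * m / i formula with a running minimum."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def mann_whitney_exact_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p by enumerating every group assignment (no ties)."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    center = n_a * len(b) / 2.0
    stat_obs = abs(u_obs - center)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        u = sum(1 for x in pooled[mask] for y in pooled[~mask] if x > y)
        count += abs(u - center) >= stat_obs - 1e-12
        total += 1
    return u_obs, count / total


def ancova_f_textbook(y, group, age) -> tuple[float, float]:
    """Classic two-group ANCOVA F for the group term via sums of squares."""
    from scipy import stats

    y = np.asarray(y, float)
    age = np.asarray(age, float)
    group = np.asarray(group)
    levels = sorted(set(group.tolist()))
    masks = [group == g for g in levels]

    def s(x, z, mask):
        return np.sum((x[mask] - x[mask].mean()) * (z[mask] - z[mask].mean()))

    sxx_w = sum(s(age, age, m) for m in masks)
    sxy_w = sum(s(age, y, m) for m in masks)
    syy_w = sum(s(y, y, m) for m in masks)
    sse_full = syy_w - sxy_w**2 / sxx_w
    all_mask = np.ones(len(y), dtype=bool)
    sse_reduced = s(y, y, all_mask) - s(age, y, all_mask) ** 2 / s(age, age, all_mask)
    df = len(y) - 3
    f = (sse_reduced - sse_full) / (sse_full / df)
    return float(f), float(stats.f.sf(f, 1, df))
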