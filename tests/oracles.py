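"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — enumeration and definitional sums —
and shares no code path with the package implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- graphs ---

def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = len(adj)
    dist = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def brute_path_length(adj: np.ndarray) -> tuple[float, float]:
    n = len(adj)
    dist = floyd_warshall(adj)
    vals, total = [], 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            total += 1
            if math.isfinite(dist[i, j]):
                vals.append(dist[i, j])
    if not vals:
        return float("nan"), 1.0
    return sum(vals) / len(vals), 1.0 - len(vals) / total


def brute_global_efficiency(adj: np.ndarray) -> float:
    n = len(adj)
    dist = floyd_warshall(adj)
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(dist[i, j]):
                acc += 1.0 / dist[i, j]
    return acc / (n * (n - 1))


def brute_clustering(adj: np.ndarray) -> np.ndarray:
    n = len(adj)
    out = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v, u]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b]
        )
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def _all_shortest_paths(adj: np.ndarray, dist: np.ndarray, s: int, t: int) -> list[list[int]]:
    if s == t:
        return [[s]]
    if not math.isfinite(dist[s, t]):
        return []
    paths = []
    for v in range(len(adj)):
        if adj[v, t] and dist[s, v] == dist[s, t] - 1:
            for p in _all_shortest_paths(adj, dist, s, v):
                paths.append(p + [t])
    return paths


def brute_betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized, each unordered pair counted once."""
    n = len(adj)
    dist = floyd_warshall(adj)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(adj, dist, s, t)
            if not paths:
                continue
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


# ------------------------------------------------------------- rotations ---

def _rotation_matrices_bfs() -> list[np.ndarray]:
    """Proper cube rotations generated by closure over two 90-degree turns."""
    rx = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]])
    rz = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]])
    found = {tuple(np.eye(3, dtype=int).ravel())}
    frontier = [np.eye(3, dtype=int)]
    while frontier:
        nxt = []
        for m in frontier:
            for g in (rx, rz):
                cand = g @ m
                key = tuple(cand.ravel())
                if key not in found:
                    found.add(key)
                    nxt.append(cand)
        frontier = nxt
    return [np.array(k, dtype=int).reshape(3, 3) for k in sorted(found)]


def rotate_cube_values(values, rot: np.ndarray) -> np.ndarray:
    """Rotate a 27-value cube (x,y,z raster order) by a rotation matrix."""
    values = np.asarray(values, dtype=float)
    out = np.empty(27)
    for x in range(3):
        for y in range(3):
            for z in range(3):
                src = np.array([x, y, z]) - 1
                dst = rot @ src + 1
                out[dst[0] * 9 + dst[1] * 3 + dst[2]] = values[x * 9 + y * 3 + z]
    return out


def pearson_from_sums(a, b) -> float:
    """Pearson correlation computed from its definitional sums."""
    a = list(map(float, a))
    b = list(map(float, b))
    n = len(a)
    sa, sb = sum(a), sum(b)
    saa = sum(x * x for x in a)
    sbb = sum(x * x for x in b)
    sab = sum(x * y for x, y in zip(a, b))
    num = n * sab - sa * sb
    den = math.sqrt((n * saa - sa * sa) * (n * sbb - sb * sb))
    if den == 0:
        return 0.0
    return num / den


def brute_rotation_similarity(a, b) -> float:
    """Max correlation over the 24 proper rotations, by explicit enumeration."""
    rots = _rotation_matrices_bfs()
    assert len(rots) == 24
    return max(pearson_from_sums(a, rotate_cube_values(b, r)) for r in rots)


# ---------------------------------------------------------------- stats ----

def bh_by_hand(pvals, q):
    """Step-up BH rejections computed directly from the rule."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= q * rank / m:
            k_star = rank
    rejected = set(order[:k_star])
    return rejected


def pooled_t_by_hand(x1, x2) -> float:
    """Textbook pooled-variance two-sample t for x1 minus x2."""
    n1, n2 = len(x1), len(x2)
    m1 = sum(x1) / n1
    m2 = sum(x2) / n2
    v1 = sum((v - m1) ** 2 for v in x1) / (n1 - 1)
    v2 = sum((v - m2) ** 2 for v in x2) / (n2 - 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    return (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
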