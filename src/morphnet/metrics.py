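"""Graph-theory measures on binary undirected networks, implemented from scratch.

Conventions (all recorded in run manifests):

* Characteristic path length averages over ordered *reachable* pairs; the
  unreachable fraction is reported alongside.  Disconnected graphs are
  expected at low sparsity.
* Betweenness is unnormalized with each unordered pair counted once
  (Brandes dependency accumulation / 2).
* Small-worldness normalizes clustering and path length by degree-preserving
  edge-swap null networks (seeded).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .construction import BinaryNetwork

__all__ = [
    "GraphMetrics",
    "degree",
    "clustering",
    "path_length",
    "global_efficiency",
    "betweenness",
    "rewire_degree_preserving",
    "small_worldness",
    "compute_metrics",
]


@dataclass
class GraphMetrics:
    nodal_degree: np.ndarray
    nodal_clustering: np.ndarray
    nodal_betweenness: np.ndarray
    mean_DC: float
    mean_CP: float
    LP: float  # nan when no pair is reachable
    unreachable_fraction: float
    E_glob: float
    SW: float
    null_spec: dict = field(default_factory=dict)


def _adj(net) -> np.ndarray:
    a = net.adjacency if isinstance(net, BinaryNetwork) else np.asarray(net)
    a = a.astype(bool)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if a.diagonal().any():
        raise ValueError("adjacency must have a zero diagonal")
    return a


def degree(net) -> np.ndarray:
    """Number of edges per node (row sums)."""
    return _adj(net).sum(axis=1)


def clustering(net) -> np.ndarray:
    """Per-node clustering coefficient: 2 * triangles / k(k-1), 0 when k < 2."""
    a = _adj(net)
    af = a.astype(float)
    k = a.sum(axis=1)
    two_tri = ((af @ af) * af).sum(axis=1)  # = 2 * triangles through node
    cp = np.zeros(len(a))
    ok = k > 1
    cp[ok] = two_tri[ok] / (k[ok] * (k[ok] - 1))
    return cp


def _bfs_distances(a: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths by breadth-first frontier expansion."""
    n = len(a)
    dist = np.full((n, n), np.inf)
    for s in range(n):
        d = dist[s]
        d[s] = 0.0
        frontier = np.zeros(n, dtype=bool)
        frontier[s] = True
        visited = frontier.copy()
        level = 0
        while frontier.any():
            level += 1
            nxt = a[frontier].any(axis=0) & ~visited
            if not nxt.any():
                break
            d[nxt] = level
            visited |= nxt
            frontier = nxt
    return dist


def path_length(net) -> tuple[float, float]:
    """(LP, unreachable_fraction).

    LP is the mean shortest-path length over ordered reachable pairs i != j,
    nan when no pair is reachable.
    """
    a = _adj(net)
    n = len(a)
    if n < 2:
        return float("nan"), 0.0
    dist = _bfs_distances(a)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    n_pairs = n * (n - 1)
    unreachable = 1.0 - finite.sum() / n_pairs
    if not finite.any():
        return float("nan"), unreachable
    return float(dist[finite].mean()), float(unreachable)


def global_efficiency(net) -> float:
    """Mean inverse shortest-path length over all ordered pairs (1/inf = 0)."""
    a = _adj(net)
    n = len(a)
    if n < 2:
        return 0.0
    dist = _bfs_distances(a)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def betweenness(net) -> np.ndarray:
    """Unnormalized betweenness centrality, unordered-pair convention.

    Brandes' dependency-accumulation algorithm; the directed accumulation is
    halved so each unordered (s, t) pair contributes once.
    """
    a = _adj(net)
    n = len(a)
    neighbors = [np.flatnonzero(a[i]) for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        stack: list[int] = []
        preds: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        queue: deque[int] = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in neighbors[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        while stack:
            w = stack.pop()
            coeff = (1.0 + delta[w]) / sigma[w]
            for v in preds[w]:
                delta[v] += sigma[v] * coeff
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0


def rewire_degree_preserving(
    a: np.ndarray, rng: np.random.Generator, n_attempts: int | None = None
) -> np.ndarray:
    """Degree-preserving randomization by repeated double-edge swaps.

    Each attempt picks two edges (a, b), (c, d) and proposes (a, d), (c, b);
    the swap is applied when it creates no self-loop or duplicate edge.
    Defaults to 10 swap attempts per edge.
    """
    a = a.copy()
    iu = np.triu_indices(len(a), k=1)
    mask = a[iu]
    edges = np.column_stack([iu[0][mask], iu[1][mask]])
    m = len(edges)
    if m < 2:
        return a
    if n_attempts is None:
        n_attempts = 10 * m
    for _ in range(n_attempts):
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        x, y = edges[e1]
        u, v = edges[e2]
        if rng.random() < 0.5:
            u, v = v, u
        # propose (x, v) and (u, y)
        if len({x, y, u, v}) < 4:
            continue
        if a[x, v] or a[u, y]:
            continue
        a[x, y] = a[y, x] = False
        a[u, v] = a[v, u] = False
        a[x, v] = a[v, x] = True
        a[u, y] = a[y, u] = True
        edges[e1] = (x, v) if x < v else (v, x)
        edges[e2] = (u, y) if u < y else (y, u)
    return a


def small_worldness(
    net, n_null: int = 20, seed: int | None = None, return_nulls: bool = False
):
    """Clustering/path-length ratio against degree-preserving null networks.

    SW = (CP / CP_null) / (LP / LP_null) with CP_null and LP_null the means
    over ``n_null`` edge-swap randomizations.  LP uses the reachable-pair
    convention throughout.  If rewiring cannot change the graph (e.g. a
    complete graph) the null equals the original and SW = 1.
    """
    a = _adj(net)
    if not a.any():
        raise ValueError("small_worldness requires at least one edge")
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng(seed)
    cp0 = float(clustering(a).mean())
    lp0, _ = path_length(a)
    cp_nulls = np.empty(n_null)
    lp_nulls = np.empty(n_null)
    for i in range(n_null):
        r = rewire_degree_preserving(a, rng)
        cp_nulls[i] = clustering(r).mean()
        lp_nulls[i], _ = path_length(r)
    cp_null = float(cp_nulls.mean())
    lp_null = float(np.nanmean(lp_nulls))
    if cp_null == 0 or lp0 == 0 or not np.isfinite(lp0) or not np.isfinite(lp_null):
        sw = float("nan")
    else:
        sw = (cp0 / cp_null) / (lp0 / lp_null)
    if return_nulls:
        return sw, {"cp_nulls": cp_nulls, "lp_nulls": lp_nulls}
    return sw


def compute_metrics(net, n_null: int = 20, seed: int | None = None) -> GraphMetrics:
    """All global and nodal measures for one binary network."""
    a = _adj(net)
    dc = degree(a)
    cp = clustering(a)
    bc = betweenness(a)
    lp, unreach = path_length(a)
    eg = global_efficiency(a)
    sw = small_worldness(a, n_null=n_null, seed=seed) if a.any() else float("nan")
    return GraphMetrics(
        nodal_degree=dc,
        nodal_clustering=cp,
        nodal_betweenness=bc,
        mean_DC=float(dc.mean()),
        mean_CP=float(cp.mean()),
        LP=lp,
        unreachable_fraction=unreach,
        E_glob=eg,
        SW=sw,
        null_spec={"n_null": n_null, "seed": seed, "swap_attempts_per_edge": 10},
    )
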