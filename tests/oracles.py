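"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (plain-Python BFS/DFS and
exhaustive enumeration) and deliberately avoids the library code paths it
is used to check.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations
from math import comb


def brute_neighbors(edges: list[tuple[str, str]], target: str) -> set[str]:
    """First neighbors by exhaustive edge-list scan (self excluded)."""
    out: set[str] = set()
    for a, b in edges:
        if a == target and b != target:
            out.add(b)
        if b == target and a != target:
            out.add(a)
    return out


def _adjacency(nodes: list[str], edges: list[tuple[str, str]]) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for a, b in edges:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    return adj


def bfs_distances(nodes: list[str], edges: list[tuple[str, str]],
                  source: str) -> dict[str, int]:
    adj = _adjacency(nodes, edges)
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def brute_closeness(nodes: list[str], edges: list[tuple[str, str]]) -> dict[str, float]:
    """(r / sum of distances) * (r / (n-1)) with r = reachable others."""
    n = len(nodes)
    out: dict[str, float] = {}
    for u in nodes:
        dist = bfs_distances(nodes, edges, u)
        others = {v: d for v, d in dist.items() if v != u}
        if not others or n == 1:
            out[u] = 0.0
            continue
        r = len(others)
        out[u] = (r / sum(others.values())) * (r / (n - 1))
    return out


def brute_betweenness(nodes: list[str], edges: list[tuple[str, str]]) -> dict[str, float]:
    """Unnormalized shortest-path betweenness by exhaustive simple-path
    enumeration; each unordered pair counted once."""
    adj = _adjacency(nodes, edges)
    score = {n: 0.0 for n in nodes}

    def all_paths(s: str, t: str, max_len: int) -> list[list[str]]:
        paths: list[list[str]] = []
        stack = [(s, [s])]
        while stack:
            u, path = stack.pop()
            if len(path) - 1 > max_len:
                continue
            if u == t:
                if len(path) - 1 == max_len:
                    paths.append(path)
                continue
            for v in adj[u]:
                if v not in path:
                    stack.append((v, path + [v]))
        return paths

    for s, t in combinations(sorted(nodes), 2):
        dist = bfs_distances(nodes, edges, s)
        if t not in dist:
            continue
        shortest = all_paths(s, t, dist[t])
        sigma = len(shortest)
        for path in shortest:
            for v in path[1:-1]:
                score[v] += 1.0 / sigma
    return score


def brute_diameter_radius(nodes: list[str], edges: list[tuple[str, str]]) -> tuple[int, int]:
    """Eccentricity extrema on the largest component (ties broken by the
    lexicographically smallest sorted node tuple)."""
    remaining = set(nodes)
    comps: list[list[str]] = []
    while remaining:
        seed = next(iter(remaining))
        comp = set(bfs_distances(nodes, edges, seed))
        comps.append(sorted(comp))
        remaining -= comp
    comps.sort(key=lambda c: (-len(c), c))
    comp = comps[0]
    eccs = []
    for u in comp:
        dist = bfs_distances(comp, [e for e in edges if e[0] in comp and e[1] in comp], u)
        eccs.append(max(dist.values()))
    return max(eccs), min(eccs)


def enum_hypergeom_tails(N: int, K: int, n: int) -> dict[int, float]:
    """P(X >= k) for every k, by enumerating all C(N, n) draws."""
    population = list(range(N))
    hits = set(range(K))
    counts: dict[int, int] = {}
    total = 0
    for draw in combinations(population, n):
        k = len(hits.intersection(draw))
        counts[k] = counts.get(k, 0) + 1
        total += 1
    assert total == comb(N, n)
    tails: dict[int, float] = {}
    for k in range(n + 2):
        tails[k] = sum(c for kk, c in counts.items() if kk >= k) / total
    return tails
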