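"""Brute-force graph metric oracles for small graphs (n <= 12).

Everything here is written from first principles on adjacency sets —
hand-rolled BFS and exhaustive geodesic enumeration — so it is independent
of the library code it checks.
"""

from __future__ import annotations

from itertools import combinations


def adjacency(nodes, edges) -> dict:
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def bfs_distances(adj, source) -> dict:
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for v in frontier:
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def all_geodesics(adj, s, t):
    """Every shortest path from s to t, by DFS along decreasing distance."""
    dist_t = bfs_distances(adj, t)
    if s not in dist_t:
        return []
    paths = []

    def walk(v, path):
        if v == t:
            paths.append(path)
            return
        for w in adj[v]:
            if w in dist_t and dist_t[w] == dist_t[v] - 1:
                walk(w, path + [w])

    walk(s, [s])
    return paths


def degree_centrality(adj) -> dict:
    n = len(adj)
    if n <= 1:
        return {v: 0.0 for v in adj}
    return {v: len(adj[v]) / (n - 1) for v in adj}


def closeness_centrality(adj) -> dict:
    """Reachable-set scaling: (r-1)/sum_d * (r-1)/(n-1) for r reachable nodes."""
    n = len(adj)
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        r = len(dist)
        total = sum(dist.values())
        if total == 0 or n <= 1:
            out[v] = 0.0
        else:
            out[v] = ((r - 1) / total) * ((r - 1) / (n - 1))
    return out


def betweenness_centrality(adj) -> dict:
    """Pair-counting betweenness normalized by (n-1)(n-2)/2."""
    n = len(adj)
    bc = {v: 0.0 for v in adj}
    if n < 3:
        return bc
    for s, t in combinations(adj, 2):
        paths = all_geodesics(adj, s, t)
        if not paths:
            continue
        for v in adj:
            if v in (s, t):
                continue
            frac = sum(1 for p in paths if v in p) / len(paths)
            bc[v] += frac
    norm = (n - 1) * (n - 2) / 2.0
    return {v: bc[v] / norm for v in adj}


def clustering_coefficient(adj) -> dict:
    out = {}
    for v in adj:
        k = len(adj[v])
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in combinations(adj[v], 2) if b in adj[a])
        out[v] = links / (k * (k - 1) / 2.0)
    return out


def components(adj):
    seen = set()
    comps = []
    for v in adj:
        if v in seen:
            continue
        comp = set(bfs_distances(adj, v))
        seen |= comp
        comps.append(comp)
    return comps


def diameter_and_aspl(adj):
    """Diameter and mean geodesic length over the largest component."""
    comps = sorted(components(adj), key=len, reverse=True)
    giant = comps[0]
    if len(giant) < 2:
        return 0, 0.0
    sub = {v: adj[v] & giant for v in giant}
    dists = []
    for s, t in combinations(giant, 2):
        dists.append(bfs_distances(sub, s)[t])
    return max(dists), sum(dists) / len(dists)
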