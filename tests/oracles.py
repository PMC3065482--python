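"""Brute-force oracle implementations for small graphs.

Everything here is written by exhaustive enumeration, independent of the
library code it checks: BFS by hand, geodesic counting by depth-bounded
path enumeration, clustering by neighbor-pair counting.
"""

from itertools import combinations


def bfs_distances(adj: dict, source):
    """Single-source BFS distances; adj maps node -> set of neighbors."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def graph_adj(g):
    return {v: set(g.neighbors(v)) for v in g.nodes()}


def mean_geodesic(g):
    """Mean distance over reachable unordered pairs, by per-source BFS."""
    adj = graph_adj(g)
    total = 0
    count = 0
    for u in adj:
        d = bfs_distances(adj, u)
        for v, dv in d.items():
            if v != u:
                total += dv
                count += 1
    if count == 0:
        raise ValueError("no reachable pairs")
    return total / count  # ordered pairs; symmetric, equals unordered mean


def local_clustering_oracle(g, node):
    nbrs = list(g.neighbors(node))
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(1 for a, b in combinations(nbrs, 2) if g.has_edge(a, b))
    return links / (k * (k - 1) / 2)


def closeness_oracle(g):
    """Wasserman–Faust closeness by direct formula."""
    adj = graph_adj(g)
    n = g.number_of_nodes()
    out = {}
    for v in adj:
        d = bfs_distances(adj, v)
        n_c = len(d)  # component size including v
        s = sum(d.values())
        if s == 0 or n <= 1:
            out[v] = 0.0
        else:
            out[v] = ((n_c - 1) / s) * ((n_c - 1) / (n - 1))
    return out


def _count_geodesics(adj, s, t, d_st):
    """Number of shortest s-t paths and, per intermediate node, how many
    pass through it — by exhaustive depth-bounded path enumeration."""
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        if len(path) > d_st:
            return
        for w in adj[u]:
            if w not in path:
                extend(path + [w])

    extend([s])
    shortest = [p for p in paths if len(p) - 1 == d_st]
    through = {}
    for p in shortest:
        for v in p[1:-1]:
            through[v] = through.get(v, 0) + 1
    return len(shortest), through


def betweenness_oracle(g):
    """Normalized betweenness by enumerating every geodesic."""
    adj = graph_adj(g)
    nodes = list(adj)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        d = bfs_distances(adj, s)
        if t not in d:
            continue
        sigma, through = _count_geodesics(adj, s, t, d[t])
        for v, cnt in through.items():
            score[v] += cnt / sigma
    norm = (n - 1) * (n - 2) / 2
    if norm > 0:
        for v in score:
            score[v] /= norm
    return score
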