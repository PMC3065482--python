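"""Topology diagnostics and per-node centralities.

Network-level summaries (mean geodesic distance over reachable pairs,
global clustering as the mean of local clustering coefficients, degree
histogram) and the per-node measures used in the node-level analysis
(degree, closeness, betweenness, HITS authority/hub, local clustering),
plus the small-world assessment of an observed network against a matched
Erdős–Rényi ensemble.

Ensemble-scale summaries run on the adjacency matrix (all-pairs BFS via
scipy.sparse.csgraph, triangle counts via a matrix cube); per-node
centralities delegate to networkx with the conventions fixed here:
closeness uses the Wasserman–Faust component-size scaling, betweenness the
unordered-pair normalization (n-1)(n-2)/2, HITS scores are normalized to
unit maximum.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "average_shortest_path",
    "global_clustering",
    "transitivity",
    "local_clustering",
    "closeness_centrality",
    "betweenness_centrality",
    "hits_scores",
    "degree_distribution",
    "topology_summary",
    "TopologySummary",
    "centrality_table",
    "small_world_assessment",
    "SmallWorldReport",
]

_HITS_TOL = 1e-8


def _adjacency(g: nx.Graph) -> np.ndarray:
    return nx.to_numpy_array(g, dtype=float)


def average_shortest_path(g: nx.Graph) -> float:
    """Mean geodesic distance over all reachable unordered pairs.

    Unreachable pairs are excluded from the mean rather than counted as
    infinite, so the measure is defined on disconnected graphs as long as
    at least one pair is reachable.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("average shortest path needs at least 2 nodes")
    if g.number_of_edges() == 0:
        raise ValueError("average shortest path undefined: no reachable pairs")
    d = shortest_path(nx.to_scipy_sparse_array(g, format="csr"),
                      method="D", unweighted=True, directed=False)
    finite = np.isfinite(d)
    np.fill_diagonal(finite, False)
    return float(d[finite].mean())


def _local_clustering_vector(a: np.ndarray) -> np.ndarray:
    k = a.sum(axis=1)
    triangles = ((a @ a) * a).sum(axis=1) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c


def global_clustering(g: nx.Graph) -> float:
    """Mean of local clustering coefficients (Watts–Strogatz convention).

    Nodes of degree < 2 contribute 0; the empty graph returns 0.
    """
    if g.number_of_nodes() == 0:
        return 0.0
    return float(_local_clustering_vector(_adjacency(g)).mean())


def transitivity(g: nx.Graph) -> float:
    """Alternative global coefficient: 3 x triangles / connected triples."""
    return float(nx.transitivity(g))


def local_clustering(g: nx.Graph, node) -> float:
    """Fraction of a node's neighbor pairs that are themselves connected.

    0 by convention for degree < 2.
    """
    if node not in g:
        raise KeyError(f"node {node!r} not in graph")
    return float(nx.clustering(g, node))


def closeness_centrality(g: nx.Graph) -> dict:
    """Per-node closeness with Wasserman–Faust component scaling.

    For a node in a component of ``n_c`` nodes within a graph of ``n``:
    ``((n_c - 1) / sum of distances) * ((n_c - 1) / (n - 1))``, which lies
    in [0, 1], reduces to the standard form on connected graphs, and gives
    isolated nodes 0.
    """
    return {v: float(c) for v, c in nx.closeness_centrality(g, wf_improved=True).items()}


def betweenness_centrality(g: nx.Graph) -> dict:
    """Brandes betweenness normalized by (n-1)(n-2)/2 unordered pairs."""
    return {v: float(b) for v, b in nx.betweenness_centrality(g, normalized=True).items()}


def hits_scores(g: nx.Graph, tol: float = _HITS_TOL) -> tuple[dict, dict]:
    """HITS (authority, hub) scores, normalized to unit maximum.

    On an undirected graph the mutual-reinforcement recurrence degenerates
    to the dominant adjacency eigenvector, so authority == hub; both are
    returned to keep the two conventional readings available. Computed by
    power iteration on A + I (the shift leaves eigenvectors unchanged but
    makes the Perron eigenvalue strictly dominant, so the iteration also
    converges on bipartite structures), iterated until successive
    max-normalized iterates differ by less than ``tol`` in max norm.
    """
    if g.number_of_edges() == 0:
        raise ValueError("HITS undefined on a graph with no edges")
    nodes = list(g.nodes())
    a = np.ones(len(nodes))
    adj = _adjacency(g)
    for _ in range(100_000):
        nxt = adj @ a + a
        nxt /= nxt.max()
        done = np.abs(nxt - a).max() < tol
        a = nxt
        if done:
            break
    else:
        raise RuntimeError("HITS power iteration failed to converge")
    scores = {v: float(x) for v, x in zip(nodes, a)}
    return scores, dict(scores)


def degree_distribution(g: nx.Graph) -> dict[int, int]:
    """Exact degree histogram: degree -> node count."""
    return dict(Counter(d for _, d in g.degree()))


@dataclass(frozen=True)
class TopologySummary:
    n_nodes: int
    n_edges: int
    avg_shortest_path: float | None
    global_clustering: float
    degree_histogram: dict[int, int] = field(hash=False)

    @property
    def mean_degree(self) -> float:
        return 2 * self.n_edges / self.n_nodes if self.n_nodes else 0.0


def topology_summary(g: nx.Graph) -> TopologySummary:
    """Bundle of the network-level diagnostics for one graph."""
    has_pairs = g.number_of_nodes() >= 2 and g.number_of_edges() >= 1
    return TopologySummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        avg_shortest_path=average_shortest_path(g) if has_pairs else None,
        global_clustering=global_clustering(g),
        degree_histogram=degree_distribution(g),
    )


def centrality_table(g: nx.Graph) -> pd.DataFrame:
    """Tidy per-node table: degree, closeness, betweenness, authority, hub,
    local clustering. Indexed by node; rows sorted by node label."""
    nodes = sorted(g.nodes())
    close = closeness_centrality(g)
    between = betweenness_centrality(g)
    clust = nx.clustering(g)
    if g.number_of_edges() > 0:
        auth, hub = hits_scores(g)
    else:
        auth = hub = {v: 0.0 for v in nodes}
    return pd.DataFrame(
        {
            "degree": [g.degree(v) for v in nodes],
            "closeness": [close[v] for v in nodes],
            "betweenness": [between[v] for v in nodes],
            "authority": [auth[v] for v in nodes],
            "hub": [hub[v] for v in nodes],
            "local_clustering": [float(clust[v]) for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


@dataclass(frozen=True)
class SmallWorldReport:
    """Observed-vs-random diagnostics for the small-world property.

    A network is flagged small-world when it is much more clustered than a
    matched random graph (clustering ratio above threshold) while keeping
    comparably short paths (path ratio below threshold).
    """

    observed_clustering: float
    ensemble_clustering: float
    clustering_ratio: float
    observed_path: float
    ensemble_path: float
    path_ratio: float
    clustering_ratio_threshold: float
    path_ratio_threshold: float
    is_small_world: bool
    n_ensemble: int


def small_world_assessment(
    g: nx.Graph,
    er_ensemble,
    clustering_ratio_threshold: float = 1.5,
    path_ratio_threshold: float = 1.5,
) -> SmallWorldReport:
    """Compare a graph with a matched random ensemble.

    ``er_ensemble`` must be non-empty and matched on node count; the flag
    is ``clustering_ratio > clustering_ratio_threshold and
    path_ratio < path_ratio_threshold``.
    """
    ensemble = list(er_ensemble)
    if not ensemble:
        raise ValueError("empty random ensemble")
    for h in ensemble:
        if h.number_of_nodes() != g.number_of_nodes():
            raise ValueError(
                f"ensemble member has {h.number_of_nodes()} nodes, "
                f"observed graph has {g.number_of_nodes()}"
            )
    obs_c = global_clustering(g)
    obs_l = average_shortest_path(g)
    ens_c = float(np.mean([global_clustering(h) for h in ensemble]))
    ens_l = float(np.mean([average_shortest_path(h) for h in ensemble]))
    c_ratio = obs_c / ens_c if ens_c > 0 else np.inf
    l_ratio = obs_l / ens_l if ens_l > 0 else np.inf
    return SmallWorldReport(
        observed_clustering=obs_c,
        ensemble_clustering=ens_c,
        clustering_ratio=float(c_ratio),
        observed_path=obs_l,
        ensemble_path=ens_l,
        path_ratio=float(l_ratio),
        clustering_ratio_threshold=clustering_ratio_threshold,
        path_ratio_threshold=path_ratio_threshold,
        is_small_world=bool(
            c_ratio > clustering_ratio_threshold and l_ratio < path_ratio_threshold
        ),
        n_ensemble=len(ensemble),
    )
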