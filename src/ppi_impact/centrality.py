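"""Node and edge centrality measures of the interactome.

Eight node measures (degree, closeness, betweenness, eigenvector, Burt
constraint, clustering coefficient, PageRank, HITS hub) and Brandes edge
betweenness.  Conventions, fixed once so downstream features are
scale-consistent:

* betweenness (node and edge): unordered source/target pairs, endpoints
  excluded for nodes, **unnormalized**;
* closeness: component-scaled (Wasserman-Faust) form, finite on
  disconnected interactomes;
* eigenvector and hub: non-negative principal adjacency eigenvector with
  unit Euclidean norm, computed by shifted power iteration (the identity
  shift guarantees convergence on bipartite components without moving the
  Perron vector).  On an undirected graph the HITS hub and authority
  scores coincide with this eigenvector, so ``hub`` is returned identical
  to ``eigenvector``;
* PageRank: uniform teleport, damping 0.85 by default, values sum to 1;
* Burt constraint: p_ij = 1/deg(i) (unweighted), isolated nodes get 0.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .graph_io import Edge, InteractionNetwork, canonical_edge

#: Node measures in fixed feature order.
NODE_MEASURES = (
    "degree",
    "closeness",
    "betweenness",
    "eigenvector",
    "constraint",
    "clustering",
    "pagerank",
    "hub",
)


class ConvergenceError(RuntimeError):
    """An iterative centrality failed to converge within ``max_iter``."""


@dataclass
class CentralityTable:
    """All node centralities (one row per node) and edge betweenness."""

    nodes: pd.DataFrame  # index: protein id; columns: NODE_MEASURES
    edges: pd.Series  # index: canonical edge tuple; values: edge betweenness

    def node_vector(self, node: str) -> np.ndarray:
        return self.nodes.loc[node].to_numpy(dtype=float)


def _require_simple(network: InteractionNetwork, min_nodes: int = 1) -> nx.Graph:
    g = network.graph
    if g.number_of_nodes() < min_nodes:
        raise ValueError(f"graph needs at least {min_nodes} nodes")
    return g


def local_centralities(network: InteractionNetwork) -> pd.DataFrame:
    """Degree centrality deg(v)/(n-1) and the local clustering coefficient."""
    g = _require_simple(network, min_nodes=2)
    nodes = network.nodes
    degree = nx.degree_centrality(g)
    clustering = nx.clustering(g)
    return pd.DataFrame(
        {
            "degree": [degree[v] for v in nodes],
            "clustering": [float(clustering[v]) for v in nodes],
        },
        index=nodes,
    )


def distance_centralities(network: InteractionNetwork) -> pd.DataFrame:
    """Component-scaled closeness and unnormalized node betweenness."""
    g = _require_simple(network)
    nodes = network.nodes
    closeness = nx.closeness_centrality(g, wf_improved=True)
    betweenness = nx.betweenness_centrality(g, normalized=False)
    return pd.DataFrame(
        {
            "closeness": [closeness[v] for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
        },
        index=nodes,
    )


def spectral_centralities(
    network: InteractionNetwork,
    damping: float = 0.85,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Eigenvector centrality, PageRank and the HITS hub score.

    Eigenvector centrality is the non-negative principal eigenvector of the
    adjacency matrix, unit Euclidean norm, from a uniform positive start.
    On disconnected graphs mass concentrates on the spectrally dominant
    component; other components legitimately receive ~0.
    """
    g = _require_simple(network)
    if g.number_of_edges() == 0:
        raise ValueError("spectral centralities need at least one edge")
    if not 0.0 < damping < 1.0:
        raise ValueError(f"damping must be in (0, 1), got {damping}")
    nodes = network.nodes
    n = len(nodes)

    adj = nx.to_scipy_sparse_array(g, nodelist=nodes, dtype=float, format="csr")
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        # (A + I) x: same Perron vector as A, convergent on bipartite graphs
        y = adj @ x + x
        y /= np.linalg.norm(y)
        if np.abs(y - x).sum() < tol:
            x = y
            break
        x = y
    else:
        raise ConvergenceError(
            f"eigenvector centrality did not converge in {max_iter} iterations"
        )
    eigenvector = np.clip(x, 0.0, None)
    eigenvector /= np.linalg.norm(eigenvector)

    try:
        # nx declares convergence at L1 error < n * tol; rescale to honour tol
        pr = nx.pagerank(g, alpha=damping, tol=tol / n, max_iter=max_iter)
    except nx.PowerIterationFailedConvergence as exc:
        raise ConvergenceError(
            f"pagerank did not converge in {max_iter} iterations"
        ) from exc

    return pd.DataFrame(
        {
            "eigenvector": eigenvector,
            "pagerank": [pr[v] for v in nodes],
            "hub": eigenvector,  # HITS hub == authority == adjacency eigenvector
        },
        index=nodes,
    )


def burt_constraint(network: InteractionNetwork) -> pd.Series:
    """Burt's network constraint; isolated nodes get 0 by convention."""
    g = _require_simple(network)
    raw = nx.constraint(g)
    values = {v: (0.0 if np.isnan(c) else float(c)) for v, c in raw.items()}
    return pd.Series(values, name="constraint").reindex(network.nodes)


def edge_betweenness(network: InteractionNetwork) -> pd.Series:
    """Brandes edge betweenness over unordered pairs, unnormalized."""
    g = _require_simple(network)
    raw = nx.edge_betweenness_centrality(g, normalized=False)
    values = {canonical_edge(a, b): float(v) for (a, b), v in raw.items()}
    return pd.Series(values, name="edge_betweenness").reindex(network.edges)


def centrality_table(
    network: InteractionNetwork,
    damping: float = 0.85,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> CentralityTable:
    """Assemble every measure into one deterministic table."""
    local = local_centralities(network)
    dist = distance_centralities(network)
    spectral = spectral_centralities(network, damping=damping, tol=tol, max_iter=max_iter)
    constraint = burt_constraint(network)
    nodes = pd.DataFrame(
        {
            "degree": local["degree"],
            "closeness": dist["closeness"],
            "betweenness": dist["betweenness"],
            "eigenvector": spectral["eigenvector"],
            "constraint": constraint,
            "clustering": local["clustering"],
            "pagerank": spectral["pagerank"],
            "hub": spectral["hub"],
        }
    )[list(NODE_MEASURES)]
    return CentralityTable(nodes=nodes, edges=edge_betweenness(network))


def brute_force_path_oracle(
    network: InteractionNetwork,
) -> tuple[dict[str, float], dict[Edge, float], dict[frozenset[str], int]]:
    """Exact betweenness and distances by explicit shortest-path enumeration.

    Test oracle only: enumerates every shortest path between every unordered
    node pair (guarded to n <= 10).  Returns fractional node betweenness
    (endpoints excluded), fractional edge betweenness, and the finite
    pairwise distance map keyed by unordered pair.
    """
    g = network.graph
    n = g.number_of_nodes()
    if n > 10:
        raise ValueError(f"oracle limited to 10 nodes, got {n}")
    adj = {v: sorted(g.neighbors(v)) for v in g.nodes}
    nodes = sorted(adj)

    node_b = {v: 0.0 for v in nodes}
    edge_b: dict[Edge, float] = {canonical_edge(a, b): 0.0 for a, b in g.edges}
    distances: dict[frozenset[str], int] = {}

    for i, s in enumerate(nodes):
        dist, paths = _all_shortest_paths_from(adj, s)
        for t in nodes[i + 1 :]:
            if t not in dist:
                continue
            distances[frozenset((s, t))] = dist[t]
            st_paths = paths[t]
            weight = 1.0 / len(st_paths)
            for path in st_paths:
                for v in path[1:-1]:
                    node_b[v] += weight
                for a, b in zip(path, path[1:]):
                    edge_b[canonical_edge(a, b)] += weight
    return node_b, edge_b, distances


def _all_shortest_paths_from(
    adj: dict[str, list[str]], source: str
) -> tuple[dict[str, int], dict[str, list[list[str]]]]:
    """BFS from ``source`` returning distances and every shortest path."""
    dist = {source: 0}
    paths: dict[str, list[list[str]]] = {source: [[source]]}
    queue: deque[str] = deque([source])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                paths[w] = [p + [w] for p in paths[v]]
                queue.append(w)
            elif dist[w] == dist[v] + 1:
                paths[w].extend(p + [w] for p in paths[v])
    return dist, paths
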