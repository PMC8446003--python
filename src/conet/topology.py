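"""Topology of inferred interaction networks.

Degree statistics per guild, Louvain community detection with Newman-Girvan
modularity, shortest-path metrics and the cumulative degree distribution.
Because the interaction networks are strictly bipartite, the global
clustering coefficient is zero by construction — computing it anyway acts as
a structural sanity check.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .screen import InteractionNetwork

__all__ = [
    "NetworkTopology",
    "degree_stats",
    "detect_communities",
    "modularity",
    "path_metrics",
    "cumulative_degree_distribution",
    "describe",
]

#: Fixed seed for Louvain so repeated runs give identical partitions.
LOUVAIN_SEED = 1789


def _as_graph(network) -> nx.Graph:
    if isinstance(network, InteractionNetwork):
        return network.to_graph()
    if isinstance(network, nx.Graph):
        return network
    raise TypeError(f"expected InteractionNetwork or networkx Graph, got {type(network)!r}")


def degree_stats(network: InteractionNetwork, guild: str) -> tuple[float, float, dict[str, int]]:
    """Mean +/- standard error of node degree over one guild.

    ``guild`` is ``"predator"`` or ``"prey"``. Isolated (degree-0) screened
    nodes count. Dispersion is the standard error of the mean (sd/sqrt(n),
    sample sd with n-1); a single-node guild has se 0.
    """
    if guild == "predator":
        nodes = sorted(network.predator_nodes)
    elif guild == "prey":
        nodes = sorted(network.prey_nodes)
    else:
        raise ValueError(f"guild must be 'predator' or 'prey', got {guild!r}")
    if not nodes:
        raise ValueError(f"no nodes in guild {guild!r}")
    g = network.to_graph()
    degrees = {n: g.degree(n) for n in nodes}
    vals = np.array(list(degrees.values()), dtype=float)
    mean = float(vals.mean())
    se = 0.0 if len(vals) == 1 else float(vals.std(ddof=1) / np.sqrt(len(vals)))
    return mean, se, degrees


def detect_communities(network, seed: int = LOUVAIN_SEED, resolution: float = 1.0) -> dict[str, int]:
    """Louvain modularity maximization on the undirected bipartite graph.

    Deterministic for a fixed seed; community ids are renumbered by each
    community's lexicographically smallest member so the labelling is stable.
    """
    g = _as_graph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty network")
    comms = nx.community.louvain_communities(g, seed=seed, resolution=resolution)
    comms = sorted(comms, key=lambda c: min(str(n) for n in c))
    return {node: i for i, comm in enumerate(comms) for node in comm}


def modularity(network, partition: dict[str, int]) -> float:
    """Newman-Girvan modularity Q of a node partition.

    Q = sum_c (e_c/m - (d_c/2m)^2) over communities c, on the undirected
    graph with m edges.
    """
    g = _as_graph(network)
    if g.number_of_edges() == 0:
        raise ValueError("modularity is undefined for an edgeless graph (m = 0)")
    missing = set(g.nodes) - set(partition)
    if missing:
        raise ValueError(f"partition does not cover node(s): {sorted(missing)[:3]}")
    groups: dict[int, set] = {}
    for node, cid in partition.items():
        if node in g:
            groups.setdefault(cid, set()).add(node)
    return float(nx.community.modularity(g, list(groups.values())))


def path_metrics(network) -> tuple[float, int, float]:
    """(average path length, diameter, global clustering coefficient).

    Shortest paths are computed within connected components and averaged over
    all reachable pairs; the diameter is the largest eccentricity over
    components. Clustering is the transitivity 3*triangles/triples (zero for
    any bipartite graph). Degenerate graphs with no reachable pair report
    (nan, 0, 0.0).
    """
    g = _as_graph(network)
    total = 0.0
    n_pairs = 0
    diameter = 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            for d in dists.values():
                if d > 0:
                    total += d
                    n_pairs += 1
                    diameter = max(diameter, d)
    avg = total / n_pairs if n_pairs else float("nan")
    clustering = float(nx.transitivity(g)) if g.number_of_nodes() else 0.0
    return avg, diameter, clustering


def cumulative_degree_distribution(network) -> dict[int, float]:
    """P(k) = fraction of nodes with degree >= k, for k = 0..max degree."""
    g = _as_graph(network)
    n = g.number_of_nodes()
    if n == 0:
        return {0: 1.0}
    degrees = np.array([d for _, d in g.degree()])
    return {k: float(np.mean(degrees >= k)) for k in range(int(degrees.max()) + 1)}


@dataclass
class NetworkTopology:
    """Bundle of topology descriptors for one interaction network."""

    degree_mean: dict[str, float]
    degree_se: dict[str, float]
    degrees: dict[str, int]
    partition: dict[str, int]
    modularity_q: float
    average_path_length: float
    diameter: int
    clustering_coefficient: float
    cumulative_degree_distribution: dict[int, float]

    def summary_rows(self) -> list[tuple[str, float]]:
        rows = [
            ("modularity_q", self.modularity_q),
            ("n_communities", float(len(set(self.partition.values())))),
            ("average_path_length", self.average_path_length),
            ("diameter", float(self.diameter)),
            ("clustering_coefficient", self.clustering_coefficient),
        ]
        for guild in sorted(self.degree_mean):
            rows.append((f"degree_mean_{guild}", self.degree_mean[guild]))
            rows.append((f"degree_se_{guild}", self.degree_se[guild]))
        return rows


def describe(network: InteractionNetwork, seed: int = LOUVAIN_SEED) -> NetworkTopology:
    """Compute the full topology description of an inferred network."""
    if network.n_edges == 0:
        raise ValueError("topology description requires at least one edge")
    degree_mean, degree_se, degrees = {}, {}, {}
    for guild in ("predator", "prey"):
        m, se, d = degree_stats(network, guild)
        degree_mean[guild], degree_se[guild] = m, se
        degrees.update(d)
    partition = detect_communities(network, seed=seed)
    q = modularity(network, partition)
    apl, diam, cc = path_metrics(network)
    return NetworkTopology(
        degree_mean=degree_mean,
        degree_se=degree_se,
        degrees=degrees,
        partition=partition,
        modularity_q=q,
        average_path_length=apl,
        diameter=diam,
        clustering_coefficient=cc,
        cumulative_degree_distribution=cumulative_degree_distribution(network),
    )
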