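"""Global and local graph measures on binary undirected networks.

Global: mean clustering coefficient C, characteristic path length L,
global efficiency E_glob (mean inverse distance, Latora-Marchiori),
mean local efficiency E_loc, modularity Q (Louvain, seeded restarts),
and small-worldness -- both the literal ratio C/L and the normalized
sigma = (C/<C_rand>)/(L/<L_rand>) against degree-preserving rewired
surrogates, where sigma > 1 indicates small-world organization.

Local: degree, betweenness (Brandes, raw unordered-pair counts) and
nodal efficiency (mean inverse distance from a node to all others).

Disconnected networks are supported throughout: path-based quantities
average over reachable pairs (with a warning) and inverse distances treat
unreachable pairs as 0 contribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .network import BinaryNetwork, round_half_up


@dataclass(frozen=True)
class NullModelConfig:
    """Degree-preserving surrogate ensemble for small-world sigma."""

    n_null: int = 100
    rewires_per_edge: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")


@dataclass
class GlobalMetrics:
    clustering_C: float
    path_length_L: float
    efficiency_global_Eg: float
    efficiency_local_Eloc: float
    modularity_Q: float
    small_world_ratio: float            # literal C/L
    small_world_sigma: float | None     # normalized; None if not computed
    inverse_path_length: float          # 1/L, the literal reading of E_glob
    sparsity: float
    connected: bool


@dataclass
class NodalMetrics:
    degree: np.ndarray
    betweenness: np.ndarray
    nodal_efficiency: np.ndarray


def to_graph(net: BinaryNetwork) -> nx.Graph:
    g = nx.from_numpy_array(net.adjacency)
    # drop weight attributes: the network is unweighted by construction
    for _, _, d in g.edges(data=True):
        d.clear()
    return g


# ---------------------------------------------------------------------------
# Clustering and distances
# ---------------------------------------------------------------------------

def clustering_coefficients(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node C_i = 2 t_i / (k_i (k_i - 1)) and the mean over all nodes.

    Nodes with degree < 2 have C_i = 0.
    """
    cc = nx.clustering(to_graph(net))
    per_node = np.array([cc[i] for i in range(net.n_nodes)], dtype=float)
    return per_node, float(per_node.mean())


def shortest_path_matrix(net: BinaryNetwork) -> np.ndarray:
    """All-pairs unweighted BFS distances; np.inf marks unreachable pairs."""
    return _csgraph_shortest_path(net.adjacency, method="D", unweighted=True)


def characteristic_path_length(net: BinaryNetwork,
                               dist: np.ndarray | None = None) -> float:
    """Mean shortest-path distance over reachable ordered pairs i != j.

    On a disconnected network the mean is taken over reachable pairs
    only, with a warning.
    """
    d = shortest_path_matrix(net) if dist is None else dist
    off = ~np.eye(net.n_nodes, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise ValueError("no finite node pair: empty or single-node graph")
    if finite.sum() < off.sum():
        warnings.warn("disconnected network: L computed on reachable pairs",
                      stacklevel=2)
    return float(d[finite].mean())


def global_efficiency(net: BinaryNetwork,
                      dist: np.ndarray | None = None) -> float:
    """Mean of 1/d_ij over ordered pairs i != j, with 1/inf = 0."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("global efficiency undefined for fewer than 2 nodes")
    d = shortest_path_matrix(net) if dist is None else dist
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].mean())


def _subnetwork(net: BinaryNetwork, nodes: np.ndarray) -> BinaryNetwork:
    sub = net.adjacency[np.ix_(nodes, nodes)]
    return BinaryNetwork(sub, net.sparsity)


def local_efficiency(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    """E_loc(i): global efficiency of the subgraph induced by i's
    neighbors; 0 when i has fewer than 2 neighbors. Returns per-node
    values and their mean.
    """
    n = net.n_nodes
    per_node = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(net.adjacency[i])[0]
        if len(nbrs) >= 2:
            per_node[i] = global_efficiency(_subnetwork(net, nbrs))
    return per_node, float(per_node.mean())


# ---------------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------------

def modularity(net: BinaryNetwork, seed: int = 0,
               restarts: int = 20) -> tuple[float, np.ndarray]:
    """Louvain optimization of Newman-Girvan Q; best of seeded restarts.

    Returns (Q, community id per node). Deterministic given (seed,
    restarts).
    """
    if net.n_edges < 1:
        raise ValueError("modularity undefined for an empty graph")
    g = to_graph(net)
    best_q, best_parts = -np.inf, None
    for r in range(restarts):
        parts = nx.community.louvain_communities(g, seed=seed + r)
        q = nx.community.modularity(g, parts)
        if q > best_q:
            best_q, best_parts = q, parts
    labels = np.empty(net.n_nodes, dtype=int)
    for cid, members in enumerate(sorted(best_parts, key=min)):
        labels[list(members)] = cid
    return float(best_q), labels


# ---------------------------------------------------------------------------
# Small-worldness
# ---------------------------------------------------------------------------

def small_worldness(net: BinaryNetwork,
                    null_config: NullModelConfig | None = None
                    ) -> tuple[float, float]:
    """(ratio, sigma): the literal C/L ratio and the normalized
    small-world index sigma = (C/<C_rand>) / (L/<L_rand>).

    <C_rand> and <L_rand> average over ``n_null`` degree-preserving
    surrogates produced by Maslov-Sneppen double-edge swaps. sigma is the
    quantity to compare against 1; the raw C/L ratio is reported for
    completeness but has no natural scale.
    """
    cfg = null_config or NullModelConfig()
    dist = shortest_path_matrix(net)
    _, c = clustering_coefficients(net)
    length = characteristic_path_length(net, dist)
    ratio = c / length
    m = net.n_edges
    if m < 2:
        raise ValueError("degenerate null: fewer than 2 swappable edges")
    g = to_graph(net)
    rng_seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_null)
    c_rand = np.empty(cfg.n_null)
    l_rand = np.empty(cfg.n_null)
    for k in range(cfg.n_null):
        surrogate = g.copy()
        nswap = cfg.rewires_per_edge * m
        try:
            nx.double_edge_swap(surrogate, nswap=nswap, max_tries=50 * nswap,
                                seed=int(rng_seeds[k] % (2 ** 31)))
        except nx.NetworkXAlgorithmError:
            pass  # swap budget exhausted; use the partially rewired graph
        adj = nx.to_numpy_array(surrogate, nodelist=range(net.n_nodes),
                                dtype=np.int8)
        snet = BinaryNetwork(adj, net.sparsity)
        _, c_rand[k] = clustering_coefficients(snet)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            l_rand[k] = characteristic_path_length(snet)
    c_bar, l_bar = float(c_rand.mean()), float(l_rand.mean())
    if c_bar <= 0:
        raise ValueError("degenerate null: surrogate clustering is zero")
    sigma = (c / c_bar) / (length / l_bar)
    return float(ratio), float(sigma)


# ---------------------------------------------------------------------------
# Local (nodal) measures
# ---------------------------------------------------------------------------

def degree_centrality(net: BinaryNetwork) -> np.ndarray:
    """Edge count per node (adjacency row sums)."""
    return net.adjacency.sum(axis=1).astype(int)


def betweenness_centrality(net: BinaryNetwork,
                           normalized: bool = False) -> np.ndarray:
    """Brandes betweenness over unweighted shortest paths.

    Raw unordered-pair counts by default (star center on n nodes scores
    (n-1)(n-2)/2); the normalized variant divides by that maximum.
    """
    bc = nx.betweenness_centrality(to_graph(net), normalized=normalized)
    return np.array([bc[i] for i in range(net.n_nodes)], dtype=float)


def nodal_efficiency(net: BinaryNetwork,
                     dist: np.ndarray | None = None) -> np.ndarray:
    """E_nodal(i) = mean over j != i of 1/d_ij, with 1/inf = 0."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("nodal efficiency undefined for fewer than 2 nodes")
    d = shortest_path_matrix(net) if dist is None else dist
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return inv.sum(axis=1) / (n - 1)


def top_fraction_nodes(values: np.ndarray, fraction: float) -> np.ndarray:
    """Indices of the round(fraction * n) highest-valued nodes.

    Ties at the cutoff are broken by ascending node index; the returned
    indices are sorted ascending. Used for hub selection (e.g. the 30%
    of nodes with the highest degree centrality).
    """
    values = np.asarray(values)
    n = len(values)
    if n == 0:
        raise ValueError("empty input")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    m = round_half_up(fraction * n)
    order = np.lexsort((np.arange(n), -values))[:m]
    return np.sort(order)


# ---------------------------------------------------------------------------
# Bundled computation
# ---------------------------------------------------------------------------

def global_metrics(net: BinaryNetwork, seed: int = 0,
                   null_config: NullModelConfig | None = None,
                   compute_sigma: bool = False,
                   modularity_restarts: int = 20) -> GlobalMetrics:
    """All global measures of one network.

    Small-world sigma needs a surrogate ensemble and is therefore opt-in
    (``compute_sigma``); the literal C/L ratio is always reported.
    """
    dist = shortest_path_matrix(net)
    connected = bool(np.isfinite(dist).all())
    with warnings.catch_warnings():
        if not connected:
            warnings.simplefilter("ignore")
        _, c = clustering_coefficients(net)
        length = characteristic_path_length(net, dist)
        eg = global_efficiency(net, dist)
        _, eloc = local_efficiency(net)
        q, _ = modularity(net, seed=seed, restarts=modularity_restarts)
        sigma = None
        if compute_sigma:
            cfg = null_config or NullModelConfig(seed=seed)
            _, sigma = small_worldness(net, cfg)
    return GlobalMetrics(
        clustering_C=c,
        path_length_L=length,
        efficiency_global_Eg=eg,
        efficiency_local_Eloc=eloc,
        modularity_Q=q,
        small_world_ratio=c / length,
        small_world_sigma=sigma,
        inverse_path_length=1.0 / length,
        sparsity=net.sparsity,
        connected=connected,
    )


def nodal_metrics(net: BinaryNetwork) -> NodalMetrics:
    dist = shortest_path_matrix(net)
    return NodalMetrics(
        degree=degree_centrality(net),
        betweenness=betweenness_centrality(net),
        nodal_efficiency=nodal_efficiency(net, dist),
    )
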