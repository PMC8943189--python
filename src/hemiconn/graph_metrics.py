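"""Weighted undirected graph-topology measures for hemispheric connectomes.

Conventions (chosen for compatibility with the GRETNA-style analyses these
measures emulate):

* Edge length is the reciprocal of the raw streamline-count weight; weights
  are NOT normalized, so efficiency values inherit the weight scale
  (hemispheric networks land in the thousands).
* Paths between disconnected nodes have infinite length and contribute zero
  efficiency.
* Weighted clustering is the Onnela geometric-mean form with weights
  normalized by the global maximum weight.
* The characteristic path length used for small-worldness averages over
  connected pairs only, because degree-preserving null graphs may
  disconnect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .core_io import Connectome

__all__ = [
    "MetricSet",
    "weight_to_distance",
    "shortest_path_matrix",
    "global_efficiency",
    "nodal_efficiency",
    "local_efficiency",
    "degree_strength",
    "assortativity",
    "clustering_onnela",
    "hierarchy",
    "rich_club",
    "betweenness",
    "small_worldness",
    "metric_set",
]

logger = logging.getLogger(__name__)


def _weights(conn) -> np.ndarray:
    return conn.weights if isinstance(conn, Connectome) else np.asarray(conn, dtype=float)


def weight_to_distance(conn) -> np.ndarray:
    """Edge-length matrix: 1/w for w>0, 0 marking 'no direct link'."""
    w = _weights(conn)
    with np.errstate(divide="ignore"):
        dist = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return dist


def shortest_path_matrix(conn) -> np.ndarray:
    """All-pairs shortest path lengths over reciprocal-weight edges.

    Symmetric, zero diagonal, np.inf for disconnected pairs.
    """
    lengths = weight_to_distance(conn)
    graph = csr_matrix(lengths)
    d = _csgraph_shortest_path(graph, method="D", directed=False)
    np.fill_diagonal(d, 0.0)
    return d


def global_efficiency(conn) -> float:
    """Mean inverse shortest-path length over all ordered node pairs."""
    w = _weights(conn)
    n = w.shape[0]
    if n < 2:
        return 0.0
    d = shortest_path_matrix(w)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(conn) -> np.ndarray:
    """Per-node mean inverse shortest-path length to every other node."""
    w = _weights(conn)
    n = w.shape[0]
    d = shortest_path_matrix(w)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return inv.sum(axis=1) / max(n - 1, 1)


def local_efficiency(conn) -> tuple[float, np.ndarray]:
    """(network mean, nodal vector) of neighborhood efficiency.

    The nodal value is the global efficiency of the subgraph induced by the
    node's neighbors (original weights, the node itself removed); nodes with
    fewer than two neighbors score zero.
    """
    w = _weights(conn)
    n = w.shape[0]
    nodal = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(w[i] > 0)
        if len(nb) < 2:
            continue
        nodal[i] = global_efficiency(w[np.ix_(nb, nb)])
    return float(nodal.mean()) if n else 0.0, nodal


def degree_strength(conn) -> tuple[np.ndarray, np.ndarray]:
    """(degree, strength): count and sum of nonzero incident weights."""
    w = _weights(conn)
    return (w > 0).sum(axis=1).astype(int), w.sum(axis=1)


def assortativity(conn) -> float:
    """Degree assortativity: Pearson correlation of endpoint degrees over
    the edge list (each undirected edge contributes both orientations).
    NaN when endpoint degrees have zero variance."""
    w = _weights(conn)
    deg = (w > 0).sum(axis=1)
    iu, ju = np.nonzero(np.triu(w, k=1))
    if len(iu) == 0:
        return float("nan")
    x = np.concatenate([deg[iu], deg[ju]]).astype(float)
    y = np.concatenate([deg[ju], deg[iu]]).astype(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def clustering_onnela(conn) -> np.ndarray:
    """Onnela weighted clustering, weights normalized by the global max.

    C_i = (1 / (k_i (k_i - 1))) * sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3) with
    w' = w / max(w); zero for degree < 2.
    """
    w = _weights(conn)
    wmax = w.max()
    if wmax == 0:
        return np.zeros(w.shape[0])
    cube = np.cbrt(w / wmax)
    paths = np.diag(cube @ cube @ cube)
    deg = (w > 0).sum(axis=1)
    denom = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, paths / np.where(denom > 0, denom, 1), 0.0)
    return c


def hierarchy(conn) -> float:
    """Hierarchy exponent beta from C ~ k^(-beta).

    Least-squares slope of log clustering on log degree over nodes with
    degree >= 2 and positive clustering; NaN with fewer than 3 eligible
    nodes (including the degenerate all-equal case where the slope is 0).
    """
    w = _weights(conn)
    deg = (w > 0).sum(axis=1)
    c = clustering_onnela(w)
    ok = (deg >= 2) & (c > 0)
    if ok.sum() < 3:
        return float("nan")
    logk = np.log(deg[ok].astype(float))
    logc = np.log(c[ok])
    if np.ptp(logk) == 0:
        return 0.0 if np.ptp(logc) == 0 else float("nan")
    slope = np.polyfit(logk, logc, 1)[0]
    return float(-slope)


def rich_club(conn) -> dict[int, float]:
    """Weighted rich-club coefficient per degree level k.

    phi_w(k) = (total weight among nodes with degree > k) divided by the sum
    of the E_{>k} largest edge weights in the whole graph, E_{>k} being the
    number of edges among those rich nodes.  Levels with no rich edges are
    omitted.
    """
    w = _weights(conn)
    deg = (w > 0).sum(axis=1)
    iu, ju = np.nonzero(np.triu(w, k=1))
    if len(iu) == 0:
        return {}
    edge_w = w[iu, ju]
    ranked = np.sort(edge_w)[::-1]
    cum_top = np.concatenate([[0.0], np.cumsum(ranked)])
    out: dict[int, float] = {}
    for k in range(int(deg.max())):
        rich = deg > k
        mask = rich[iu] & rich[ju]
        e_rich = int(mask.sum())
        if e_rich == 0:
            continue
        out[k] = float(edge_w[mask].sum() / cum_top[e_rich])
    return out


def _length_graph(w: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(w.shape[0]))
    iu, ju = np.nonzero(np.triu(w, k=1))
    g.add_weighted_edges_from(
        ((int(i), int(j), 1.0 / w[i, j]) for i, j in zip(iu, ju)), weight="length"
    )
    return g


def betweenness(conn) -> np.ndarray:
    """Weighted betweenness (Brandes) over reciprocal-weight lengths,
    endpoints excluded, unnormalized pair counts."""
    w = _weights(conn)
    bc = nx.betweenness_centrality(_length_graph(w), normalized=False, weight="length")
    return np.array([bc[i] for i in range(w.shape[0])])


def _char_path_length(w: np.ndarray) -> float:
    """Mean shortest-path length over connected off-diagonal pairs."""
    d = shortest_path_matrix(w)
    mask = np.isfinite(d) & ~np.eye(d.shape[0], dtype=bool)
    if not mask.any():
        return float("nan")
    return float(d[mask].mean())


def _rewired_null(w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Degree-preserving Maslov-Sneppen rewiring with the weight multiset
    randomly reassigned to the rewired edges."""
    g = nx.from_numpy_array((w > 0).astype(int))
    n_edges = g.number_of_edges()
    if n_edges < 2:
        return w.copy()
    try:
        nx.double_edge_swap(
            g,
            nswap=10 * n_edges,
            max_tries=200 * n_edges,
            seed=int(rng.integers(2**31)),
        )
    except nx.NetworkXException as err:  # swap budget exhausted on rigid graphs
        logger.warning("degree-preserving rewiring incomplete: %s", err)
    weights = w[np.triu_indices_from(w, k=1)]
    weights = weights[weights > 0]
    rng.shuffle(weights)
    null = np.zeros_like(w)
    for (i, j), wt in zip(g.edges(), weights):
        null[i, j] = null[j, i] = wt
    return null


def small_worldness(
    conn, n_rand: int = 100, seed: int | np.random.Generator | None = 0
) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) against degree-preserving weighted nulls.

    gamma = C/<C_null>, lambda = L/<L_null>, sigma = gamma/lambda, with C the
    mean Onnela clustering and L the characteristic path length over
    connected pairs.
    """
    w = _weights(conn)
    if n_rand < 1:
        return float("nan"), float("nan"), float("nan")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c_obs = float(clustering_onnela(w).mean())
    l_obs = _char_path_length(w)
    c_null = np.empty(n_rand)
    l_null = np.empty(n_rand)
    for r in range(n_rand):
        null = _rewired_null(w, rng)
        c_null[r] = clustering_onnela(null).mean()
        l_null[r] = _char_path_length(null)
    gamma = c_obs / c_null.mean() if c_null.mean() > 0 else float("nan")
    lam = l_obs / np.nanmean(l_null) if np.nanmean(l_null) > 0 else float("nan")
    return float(gamma), float(lam), float(gamma / lam)


@dataclass
class MetricSet:
    """Per-connectome global and nodal topology measures."""

    global_efficiency: float
    local_efficiency: float
    nodal_efficiency: np.ndarray
    local_efficiency_nodal: np.ndarray
    degree: np.ndarray
    strength: np.ndarray
    betweenness: np.ndarray
    clustering: np.ndarray
    assortativity: float
    hierarchy_beta: float
    rich_club: dict[int, float]
    small_world: tuple[float, float, float]  # (gamma, lambda, sigma)

    SCALARS = (
        "global_efficiency",
        "local_efficiency",
        "assortativity",
        "hierarchy_beta",
        "small_world_gamma",
        "small_world_lambda",
        "small_world_sigma",
        "mean_degree",
        "mean_strength",
        "mean_betweenness",
    )

    def scalar_row(self) -> dict[str, float]:
        """Flat scalar summary used in per-subject metric tables."""
        gamma, lam, sigma = self.small_world
        return {
            "global_efficiency": self.global_efficiency,
            "local_efficiency": self.local_efficiency,
            "assortativity": self.assortativity,
            "hierarchy_beta": self.hierarchy_beta,
            "small_world_gamma": gamma,
            "small_world_lambda": lam,
            "small_world_sigma": sigma,
            "mean_degree": float(self.degree.mean()),
            "mean_strength": float(self.strength.mean()),
            "mean_betweenness": float(self.betweenness.mean()),
        }


def metric_set(conn, n_rand: int = 100, seed: int | np.random.Generator | None = 0) -> MetricSet:
    """Assemble every topology measure; deterministic given the seed.

    Component failures (degenerate graphs) propagate as NaN markers.
    """
    w = _weights(conn)
    loc_mean, loc_nodal = local_efficiency(w)
    deg, stren = degree_strength(w)
    try:
        sw = small_worldness(w, n_rand=n_rand, seed=seed)
    except Exception as err:  # degenerate topology
        logger.warning("small-worldness failed: %s", err)
        sw = (float("nan"),) * 3
    return MetricSet(
        global_efficiency=global_efficiency(w),
        local_efficiency=loc_mean,
        nodal_efficiency=nodal_efficiency(w),
        local_efficiency_nodal=loc_nodal,
        degree=deg,
        strength=stren,
        betweenness=betweenness(w),
        clustering=clustering_onnela(w),
        assortativity=assortativity(w),
        hierarchy_beta=hierarchy(w),
        rich_club=rich_club(w),
        small_world=sw,
    )
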