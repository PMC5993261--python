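"""Static and state-level graph measures of functional networks.

An adjacency matrix is built by thresholding a node x node correlation
matrix at FDR-corrected edgewise significance (Benjamini-Hochberg on
the correlation-to-t p-values). On the surviving binary mask we compute
the local clustering coefficient C_i = 2 T_i / (k_i (k_i - 1)) (T_i =
edges among the neighbors of i), the average shortest path length
PL = mean hop distance over ordered reachable node pairs, and global
efficiency = 1/PL. On retained signed weights we compute network/node
strength (sums of |w|) and the distance-weighted network cost: each
edge costs the Euclidean distance between its nodes' centroids (mm)
times the absolute connection weight. Hubs are nodes whose metric
exceeds the sample mean by more than 1.5 standard deviations.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import shortest_path
from statsmodels.stats.multitest import multipletests

from .windows import unvectorize_upper

__all__ = [
    "AdjacencyMatrix", "GraphMetrics", "correlation_pvalues",
    "fdr_threshold_adjacency", "clustering_coefficient",
    "average_path_length", "strength_and_cost", "identify_hubs",
    "centroid_to_state_graph", "graph_metrics",
]


@dataclass
class AdjacencyMatrix:
    """Symmetric weighted adjacency plus the significance/threshold mask."""
    weights: np.ndarray
    mask: np.ndarray                       # boolean, surviving edges
    node_meta: pd.DataFrame | None = None
    n_samples: int | None = None
    threshold_rule: str = ""

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("adjacency weights must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.weights = 0.5 * (W + W.T)
        self.mask = np.asarray(self.mask, dtype=bool)
        np.fill_diagonal(self.mask, False)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def binary(self) -> np.ndarray:
        return self.mask.astype(int)

    def masked_weights(self) -> np.ndarray:
        return np.where(self.mask, self.weights, 0.0)

    @property
    def total_connections(self) -> int:
        return int(self.mask.sum() // 2)


@dataclass
class GraphMetrics:
    """All graph measures for one adjacency matrix."""
    cc_per_node: np.ndarray
    mean_cc: float
    path_length: float
    global_efficiency: float
    reachability_fraction: float
    total_connections: int
    network_strength: float
    node_strength: np.ndarray
    network_cost: float | None
    node_cost: np.ndarray | None
    degree: np.ndarray
    hub_set: list
    hub_metric: str


def correlation_pvalues(corr: np.ndarray, n_samples: int) -> np.ndarray:
    """Two-sided p-values for each off-diagonal correlation.

    Uses the exact t transform ``t = r sqrt((n-2)/(1-r^2))`` with
    ``n - 2`` degrees of freedom; ``|r| = 1`` maps to p = 0.
    """
    r = np.clip(np.asarray(corr, dtype=float), -1.0, 1.0)
    df = n_samples - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.abs(r) >= 1.0] = 0.0
    np.fill_diagonal(p, 1.0)
    return p


def fdr_threshold_adjacency(corr: np.ndarray, n_samples: int,
                            alpha: float = 0.05,
                            node_meta: pd.DataFrame | None = None
                            ) -> AdjacencyMatrix:
    """Benjamini-Hochberg edge selection on a correlation matrix.

    The n(n-1)/2 unique edges are tested jointly; surviving edges keep
    their correlation weight, all others are zeroed.
    """
    corr = np.asarray(corr, dtype=float)
    if np.nanmax(np.abs(corr)) > 1 + 1e-12:
        raise ValueError("correlation entries must lie in [-1, 1]")
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4 for edgewise inference")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    n = corr.shape[0]
    p = correlation_pvalues(corr, n_samples)
    iu = np.triu_indices(n, k=1)
    reject, _, _, _ = multipletests(p[iu], alpha=alpha, method="fdr_bh")
    mask = np.zeros((n, n), dtype=bool)
    mask[iu] = reject
    mask |= mask.T
    W = np.where(mask, corr, 0.0)
    np.fill_diagonal(W, 0.0)
    return AdjacencyMatrix(weights=W, mask=mask, node_meta=node_meta,
                           n_samples=n_samples,
                           threshold_rule=f"fdr_bh(alpha={alpha})")


def clustering_coefficient(adj_binary: np.ndarray):
    """Local clustering coefficient per node, and its mean.

    ``C_i = 2 T_i / (k_i (k_i - 1))`` with T_i the number of edges
    among the neighbors of i; nodes of degree < 2 get C_i = 0.
    """
    A = _as_binary(adj_binary)
    k = A.sum(axis=1)
    tri = np.diag(A @ A @ A) / 2.0  # triangles through each node
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(denom > 0, 2.0 * tri / denom, 0.0)
    return C, float(C.mean())


def average_path_length(adj_binary: np.ndarray):
    """Mean unweighted shortest-path length over reachable ordered pairs.

    Returns ``(path_length, global_efficiency, reachability_fraction)``.
    On a complete graph PL = 1 exactly; a graph with no edges yields
    NaN path length and reachability 0 (with a warning).
    """
    A = _as_binary(adj_binary)
    n = A.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    D = shortest_path(A, method="D", unweighted=True, directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    n_pairs = n * (n - 1)
    reach = finite.sum() / n_pairs
    if finite.sum() == 0:
        warnings.warn("graph has no edges; path length undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan"), float("nan"), 0.0
    pl = float(D[finite].mean())
    return pl, 1.0 / pl, float(reach)


def strength_and_cost(adj: AdjacencyMatrix):
    """Absolute-weight strength and distance-weighted cost.

    ``network_strength`` sums |w| over unique surviving edges;
    ``node_strength_i`` sums over edges incident to i. Each edge's cost
    is the Euclidean centroid distance (mm) times |w|; node cost sums
    incident edge costs, so node costs add up to twice the network
    cost.

    Returns ``(network_strength, node_strength, network_cost,
    node_cost)``.
    """
    W = np.abs(adj.masked_weights())
    node_strength = W.sum(axis=1)
    network_strength = float(W.sum() / 2.0)
    if adj.node_meta is None:
        raise ValueError("node_meta with centroid coordinates is required "
                         "for cost computation")
    coords = adj.node_meta[["x", "y", "z"]].to_numpy(dtype=float)
    bad = np.where(~np.isfinite(coords).all(axis=1))[0]
    if bad.size:
        names = adj.node_meta["node_id"].iloc[bad].tolist()
        raise ValueError(f"missing centroid coordinates for node(s) {names}")
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cost_matrix = dist * W
    node_cost = cost_matrix.sum(axis=1)
    network_cost = float(cost_matrix.sum() / 2.0)
    return network_strength, node_strength, network_cost, node_cost


def identify_hubs(node_metric, sd_multiplier: float = 1.5) -> list:
    """Nodes whose metric exceeds mean + ``sd_multiplier`` sample SDs.

    Returns the (0-based) node indices. Zero-variance input yields an
    empty hub set with a warning.
    """
    v = np.asarray(node_metric, dtype=float)
    if v.size < 3:
        raise ValueError("hub identification needs at least 3 nodes")
    if not np.all(np.isfinite(v)):
        raise ValueError("node metric contains non-finite values")
    sd = v.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance in node metric; no hubs identified",
                      RuntimeWarning, stacklevel=2)
        return []
    return np.where(v > v.mean() + sd_multiplier * sd)[0].tolist()


def centroid_to_state_graph(centroid_edge_vector, node_meta=None,
                            edge_threshold_rule: str = "top_percent:10"
                            ) -> AdjacencyMatrix:
    """Unvectorize a state centroid into a thresholded weighted adjacency.

    ``edge_threshold_rule`` is either ``"abs:<cutoff>"`` (keep edges
    with |w| > cutoff) or ``"top_percent:<q>"`` (keep the ceil(q% of
    edges) largest by |w|).
    """
    v = np.asarray(centroid_edge_vector, dtype=float)
    n_nodes = None
    if node_meta is not None:
        n_nodes = len(node_meta)
    W = unvectorize_upper(v, n_nodes=n_nodes)
    absv = np.abs(v)
    kind, _, arg = edge_threshold_rule.partition(":")
    if kind == "abs":
        keep = absv > float(arg)
    elif kind == "top_percent":
        q = float(arg)
        if not 0 < q <= 100:
            raise ValueError("top_percent must lie in (0, 100]")
        n_keep = int(np.ceil(q / 100.0 * v.size))
        order = np.argsort(-absv, kind="stable")
        keep = np.zeros(v.size, dtype=bool)
        keep[order[:n_keep]] = True
    else:
        raise ValueError(f"unknown edge threshold rule {edge_threshold_rule!r}")
    mask = unvectorize_upper(keep.astype(float),
                             n_nodes=W.shape[0]).astype(bool)
    return AdjacencyMatrix(weights=np.where(mask, W, 0.0), mask=mask,
                           node_meta=node_meta,
                           threshold_rule=edge_threshold_rule)


def graph_metrics(adj: AdjacencyMatrix, sd_multiplier: float = 1.5,
                  hub_metric: str = "node_strength") -> GraphMetrics:
    """All graph measures for one adjacency: CC, PL, strength, cost, hubs.

    ``hub_metric`` names the node vector fed to hub detection:
    ``"degree"``, ``"node_strength"`` or ``"node_cost"``.
    """
    A = adj.binary()
    cc, mean_cc = clustering_coefficient(A)
    pl, geff, reach = average_path_length(A)
    degree = A.sum(axis=1)
    if adj.node_meta is not None and \
            np.isfinite(adj.node_meta[["x", "y", "z"]].to_numpy(float)).all():
        ns, node_s, nc, node_c = strength_and_cost(adj)
    else:
        W = np.abs(adj.masked_weights())
        node_s, ns = W.sum(axis=1), float(W.sum() / 2.0)
        nc, node_c = None, None
    vectors = {"degree": degree.astype(float), "node_strength": node_s,
               "node_cost": node_c}
    if hub_metric not in vectors or vectors[hub_metric] is None:
        raise ValueError(f"hub metric {hub_metric!r} unavailable")
    hubs = identify_hubs(vectors[hub_metric], sd_multiplier=sd_multiplier) \
        if adj.n_nodes >= 3 else []
    return GraphMetrics(
        cc_per_node=cc, mean_cc=mean_cc, path_length=pl,
        global_efficiency=geff, reachability_fraction=reach,
        total_connections=adj.total_connections, network_strength=ns,
        node_strength=node_s, network_cost=nc, node_cost=node_c,
        degree=degree, hub_set=hubs, hub_metric=hub_metric)


def _as_binary(adj) -> np.ndarray:
    A = np.asarray(adj)
    if A.dtype == bool:
        A = A.astype(int)
    A = (A != 0).astype(int)
    if not np.array_equal(A, A.T):
        raise ValueError("binary adjacency must be symmetric")
    np.fill_diagonal(A, 0)
    return A
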