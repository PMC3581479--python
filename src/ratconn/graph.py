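"""Weighted undirected brain graphs and small-world metrics.

Graphs are built from symmetric connectivity matrices (functional
correlation or tract-based FA weights); self-connections and — by default
— negative-weight edges are discarded. Global metrics: mean Onnela local
clustering coefficient, characteristic path length with edge length
1/weight, and small-worldness, each normalized against surrogate networks
obtained by random permutation of edge weights.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra


@dataclass
class WeightedGraph:
    """Node ids plus a dense symmetric non-negative weight matrix.

    ``weights[i, j] > 0`` means an edge; the diagonal is always zero.
    """

    nodes: np.ndarray
    weights: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def edge_index(self):
        """Upper-triangular (i, j) indices of present edges."""
        iu, ju = np.triu_indices(self.n_nodes, 1)
        present = self.weights[iu, ju] > 0
        return iu[present], ju[present]


@dataclass
class GraphMetrics:
    """Raw and surrogate-normalized global graph measures."""

    clustering: float
    path_length: float
    clustering_norm: float
    path_length_norm: float
    small_worldness: float
    unreachable_fraction: float = 0.0

    def to_dict(self) -> dict:
        return {
            "clustering": self.clustering,
            "path_length": self.path_length,
            "clustering_norm": self.clustering_norm,
            "path_length_norm": self.path_length_norm,
            "small_worldness": self.small_worldness,
            "unreachable_fraction": self.unreachable_fraction,
        }


def build_graph(matrix, nodes=None, drop_negative: bool = True) -> WeightedGraph:
    """Weighted graph from a symmetric matrix.

    Diagonal entries (self-connections) are discarded regardless of
    magnitude; NaNs are treated as absent edges; with ``drop_negative``
    (the default) non-positive weights are removed rather than
    thresholded, so all remaining edges carry their original weight.
    """
    m = np.asarray(matrix, dtype=float).copy()
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    finite = np.isfinite(m) & np.isfinite(m.T)
    if not np.allclose(m[finite & finite.T], m.T[finite & finite.T], atol=1e-10):
        raise ValueError("matrix must be symmetric (tolerance 1e-10)")
    m[~np.isfinite(m)] = 0.0
    np.fill_diagonal(m, 0.0)
    if drop_negative:
        m[m < 0] = 0.0
    elif (m < 0).any():
        raise ValueError("negative weights present; set drop_negative=True")
    m[m == -0.0] = 0.0
    if nodes is None:
        nodes = np.arange(m.shape[0])
    return WeightedGraph(nodes=np.asarray(nodes), weights=m)


def clustering_onnela(g: WeightedGraph):
    """Onnela weighted local clustering coefficients and their mean.

    Weights are first normalized by the maximum weight. For node i with
    degree k_i >= 2::

        C_i = sum_{j,k} (w_ij w_jk w_ik)^(1/3) / (k_i (k_i - 1))

    Nodes of degree < 2 contribute C_i = 0 to the mean.
    """
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    w = g.weights
    wmax = w.max()
    if wmax == 0:
        return np.zeros(g.n_nodes), 0.0
    cube = np.cbrt(w / wmax)
    num = np.diagonal(cube @ cube @ cube)  # 2 * sum of weighted triangles at i
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    local = np.divide(num, denom, out=np.zeros(g.n_nodes), where=denom > 0)
    return local, float(local.mean())


def char_path_length(g: WeightedGraph):
    """Average shortest-path length with edge length = 1/weight.

    The mean runs over all ordered node pairs (i != j); unreachable pairs
    are excluded and their fraction reported.

    Returns
    -------
    (float, float)
        Characteristic path length and the fraction of unreachable pairs.
    """
    n = g.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    with np.errstate(divide="ignore"):
        lengths = np.where(g.weights > 0, 1.0 / g.weights, 0.0)
    dist = dijkstra(csr_array(lengths), directed=False)
    off = ~np.eye(n, dtype=bool)
    d = dist[off]
    reachable = np.isfinite(d)
    frac_unreachable = float(1 - reachable.mean())
    if not reachable.any():
        return float("inf"), frac_unreachable
    return float(d[reachable].mean()), frac_unreachable


def permute_edge_weights(g: WeightedGraph, rng) -> WeightedGraph:
    """Surrogate: shuffle weights across the existing edge slots.

    Edge positions (topology) are preserved; only the weight values are
    permuted among them.
    """
    iu, ju = g.edge_index()
    vals = g.weights[iu, ju]
    perm = rng.permutation(len(vals))
    w = np.zeros_like(g.weights)
    w[iu, ju] = vals[perm]
    w += w.T
    return WeightedGraph(nodes=g.nodes, weights=w)


def rewire_full(g: WeightedGraph, rng) -> WeightedGraph:
    """Surrogate: place the multiset of weights on uniformly random pairs.

    Keeps the number of edges and the weight multiset, not the topology.
    """
    n = g.n_nodes
    iu, ju = np.triu_indices(n, 1)
    vals = g.weights[g.edge_index()]
    slots = rng.choice(len(iu), size=len(vals), replace=False)
    w = np.zeros_like(g.weights)
    w[iu[slots], ju[slots]] = rng.permutation(vals)
    w += w.T
    return WeightedGraph(nodes=g.nodes, weights=w)


def normalize_and_smallworld(
    g: WeightedGraph,
    n_surrogates: int = 1000,
    seed: int | None = None,
    surrogate: str = "permute",
) -> GraphMetrics:
    """Surrogate-normalized clustering, path length and small-worldness.

    ``clustering_norm = C / mean(C_surrogate)`` and likewise for the path
    length; ``small_worldness`` is their ratio. Surrogates either permute
    weights over the retained edge slots (default, density and topology
    preserved) or fully rewire (``surrogate="full-rewire"``).
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    make = {"permute": permute_edge_weights, "full-rewire": rewire_full}[surrogate]
    rng = np.random.default_rng(seed)
    _, c = clustering_onnela(g)
    pl, frac = char_path_length(g)
    c_sur = np.empty(n_surrogates)
    l_sur = np.empty(n_surrogates)
    for s in range(n_surrogates):
        gs = make(g, rng)
        _, c_sur[s] = clustering_onnela(gs)
        l_sur[s], _ = char_path_length(gs)
    c_norm = c / c_sur.mean()
    l_norm = pl / l_sur.mean()
    return GraphMetrics(
        clustering=c, path_length=pl, clustering_norm=float(c_norm),
        path_length_norm=float(l_norm),
        small_worldness=float(c_norm / l_norm), unreachable_fraction=frac,
    )
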