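"""Weighted brain networks: construction, thresholding, resection, metrics.

Networks are functional-connectivity graphs over atlas regions (ROIs):
symmetric nonnegative weight matrices with zero diagonal, weights in [0, 1]
after rescaling amplitude-envelope correlations.  Thresholding keeps a
fraction ``theta`` of the strongest links but does *not* binarize, so the
retained weights still carry coupling strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra


@dataclass
class BrainNetwork:
    """Weighted undirected graph over ROIs.

    Attributes
    ----------
    weights : (n, n) float array
        Symmetric, nonnegative, zero diagonal.  A zero entry means
        "no link".
    node_labels : list of str
        Opaque ROI identifiers (no atlas semantics).
    density : float or None
        The link-density fraction ``theta`` this network was thresholded
        at, or None if never thresholded.
    """

    weights: np.ndarray
    node_labels: list = field(default=None)
    density: Optional[float] = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        self.weights = w
        if self.node_labels is None:
            self.node_labels = [f"roi{i}" for i in range(w.shape[0])]
        self.node_labels = list(self.node_labels)
        if len(self.node_labels) != w.shape[0]:
            raise ValueError("node_labels length must match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_links(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1) > 0))

    @property
    def mean_degree(self) -> float:
        """kappa = 2 L / n with L the retained-link count."""
        return 2.0 * self.n_links / self.n_nodes

    def label_indices(self, labels: Iterable[str]) -> np.ndarray:
        lut = {lab: i for i, lab in enumerate(self.node_labels)}
        return np.array([lut[l] for l in labels], dtype=int)

    def to_graph(self) -> nx.Graph:
        """networkx view with 'weight' and 'distance' (= 1/weight) edge attrs."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        ii, jj = np.nonzero(np.triu(self.weights, 1))
        for i, j in zip(ii, jj):
            w = self.weights[i, j]
            g.add_edge(int(i), int(j), weight=float(w), distance=1.0 / float(w))
        return g


@dataclass
class MetricSet:
    """Network metrics of a node set X (a resection area, a seed, or all nodes).

    ``size`` is |X|; ``out_connectivity`` counts links with exactly one
    endpoint in X; ``betweenness``, ``clustering`` and ``efficiency`` are
    averages over X of the per-node values.  For X = whole network only the
    clustering and efficiency averages are defined (out-connectivity and
    betweenness are structural constants there and stored as None).
    """

    size: int
    out_connectivity: Optional[int]
    betweenness: Optional[float]
    clustering: float
    efficiency: float


def rescale_coupling(raw: np.ndarray) -> np.ndarray:
    """Map correlation values r in [-1, 1] linearly onto weights in [0, 1].

    r = -1 (perfect anticorrelation) -> 0, r = 0 (no coupling) -> 0.5,
    r = +1 -> 1.  The diagonal is forced to zero.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < -1) or np.any(raw > 1):
        raise ValueError("correlation values must lie in [-1, 1]")
    out = (raw + 1.0) / 2.0
    if out.ndim == 2 and out.shape[0] == out.shape[1]:
        np.fill_diagonal(out, 0.0)
    return out


def _ranked_links(w: np.ndarray):
    """Off-diagonal upper-triangle links sorted by (weight desc, (i,j) lex asc)."""
    n = w.shape[0]
    ii, jj = np.triu_indices(n, 1)
    ww = w[ii, jj]
    # lexsort: last key is primary
    order = np.lexsort((jj, ii, -ww))
    return ii[order], jj[order], ww[order]


def threshold_network(matrix: np.ndarray, theta: float,
                      node_labels: Sequence[str] = None) -> BrainNetwork:
    """Keep the ``round(theta * n(n-1)/2)`` strongest links; weights retained.

    Ties at the cutoff weight are broken by node-pair lexicographic order so
    results are stable across runs and platforms.
    """
    w = np.asarray(matrix, dtype=float)
    if not 0 < theta <= 1:
        raise ValueError("theta must lie in (0, 1]")
    n = w.shape[0]
    k = int(round(theta * n * (n - 1) / 2))
    ii, jj, ww = _ranked_links(w)
    n_pos = int(np.count_nonzero(ww > 0))
    if k > n_pos:
        warnings.warn(
            f"requested {k} links but only {n_pos} positive weights; "
            "keeping all positive links")
        k = n_pos
    if k == 0:
        raise ValueError("threshold leaves the network with zero links")
    out = np.zeros_like(w)
    sel = slice(0, k)
    out[ii[sel], jj[sel]] = ww[sel]
    out[jj[sel], ii[sel]] = ww[sel]
    np.fill_diagonal(out, 0.0)
    return BrainNetwork(out, node_labels=node_labels, density=theta)


def resect(net: BrainNetwork, ra: Sequence[int]) -> BrainNetwork:
    """Virtual resection: zero every link incident to the node set ``ra``.

    Nodes stay in the graph so that all per-node denominators are unchanged
    between the baseline and the resected network.
    """
    ra = np.asarray(list(ra), dtype=int)
    if ra.size and (ra.min() < 0 or ra.max() >= net.n_nodes):
        raise ValueError("resection set contains unknown nodes")
    if ra.size == net.n_nodes:
        warnings.warn("resection removes every node: degenerate edgeless network")
    w = net.weights.copy()
    w[ra, :] = 0.0
    w[:, ra] = 0.0
    return BrainNetwork(w, node_labels=net.node_labels, density=net.density)


def _pairwise_distances(net: BrainNetwork) -> np.ndarray:
    """Weighted shortest-path distances with link length 1/w."""
    w = net.weights
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    sp = csr_matrix(lengths)
    return dijkstra(sp, directed=False)


def node_efficiency(net: BrainNetwork) -> np.ndarray:
    """Per-node efficiency: mean over j != i of 1/d(i, j).

    Disconnected pairs contribute 0 (1/infinity).
    """
    d = _pairwise_distances(net)
    n = net.n_nodes
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def node_betweenness(net: BrainNetwork) -> np.ndarray:
    """Per-node betweenness centrality on 1/w link lengths (normalized)."""
    g = net.to_graph()
    bc = nx.betweenness_centrality(g, weight="distance", normalized=True)
    return np.array([bc[i] for i in range(net.n_nodes)])


def node_clustering(net: BrainNetwork) -> np.ndarray:
    """Per-node weighted clustering (Onnela geometric-mean triangle intensity)."""
    g = net.to_graph()
    cc = nx.clustering(g, weight="weight")
    return np.array([cc[i] for i in range(net.n_nodes)])


def out_connectivity(net: BrainNetwork, x: Sequence[int]) -> int:
    """Number of links with exactly one endpoint in the node set."""
    x = np.asarray(list(x), dtype=int)
    mask = np.zeros(net.n_nodes, dtype=bool)
    mask[x] = True
    return int(np.count_nonzero(net.weights[np.ix_(mask, ~mask)] > 0))


def node_set_metrics(net: BrainNetwork, x: Sequence[int] = None,
                     _cache: dict = None) -> MetricSet:
    """Metrics of node set ``x`` (default: the whole network).

    ``_cache`` may hold precomputed per-node 'bc', 'cc', 'eff' arrays so that
    several node sets on one network reuse the expensive passes.
    """
    whole = x is None
    if not whole:
        x = np.asarray(list(x), dtype=int)
        if x.size == 0:
            raise ValueError("empty node set")
        if np.unique(x).size != x.size:
            raise ValueError("node set has duplicates")
    cache = _cache if _cache is not None else {}
    if "cc" not in cache:
        cache["cc"] = node_clustering(net)
    if "eff" not in cache:
        cache["eff"] = node_efficiency(net)
    if whole:
        return MetricSet(
            size=net.n_nodes,
            out_connectivity=None,
            betweenness=None,
            clustering=float(cache["cc"].mean()),
            efficiency=float(cache["eff"].mean()),
        )
    if "bc" not in cache:
        cache["bc"] = node_betweenness(net)
    return MetricSet(
        size=int(x.size),
        out_connectivity=out_connectivity(net, x),
        betweenness=float(cache["bc"][x].mean()),
        clustering=float(cache["cc"][x].mean()),
        efficiency=float(cache["eff"][x].mean()),
    )
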