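"""Spatial graphs, Moran's I autocorrelation and tumor-context segmentation.

The bead graph is a Euclidean k-nearest-neighbor graph (default k = 10)
with binary weights, symmetrized by edge union; distance ties are broken
toward the lower bead index so construction is deterministic. Moran's I
is the textbook statistic

    I = (n / sum_ij W_ij) * sum_ij W_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

computed by default on the row-standardized weight matrix, in which case
the leading factor is 1. Positive I means spatially clustered values,
negative I alternating/dispersed values (a perfect checkerboard on a rook
grid gives exactly -1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from tmekit.io import SpatialDataset

logger = logging.getLogger("tmekit")

TUMOR_CONTEXT = "tumor_context"
ADJACENT_CONTEXT = "adjacent_context"
EXCLUDED = "excluded"


@dataclass
class SpatialGraph:
    """Symmetric binary bead adjacency with zero diagonal."""

    weights: sp.csr_matrix
    k: int

    def __post_init__(self):
        w = sp.csr_matrix(self.weights)
        if (abs(w - w.T)).nnz:
            raise ValueError("weight matrix must be symmetric")
        if w.diagonal().any():
            raise ValueError("weight matrix must have zero diagonal")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def build_knn_graph(coords, k: int = 10) -> SpatialGraph:
    """Euclidean kNN graph over bead coordinates, union-symmetrized, binary.

    Ties at the k-th neighbor distance are resolved toward the lower bead
    index, making the graph independent of input ordering up to that rule.
    """
    coords = np.asarray(coords, float)
    n = len(coords)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} beads, got {n}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    dist = cdist(coords, coords)
    np.fill_diagonal(dist, np.inf)
    rows, cols = [], []
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, dist[i]))[:k]  # ties -> lower index
        rows.extend([i] * k)
        cols.extend(order.tolist())
    a = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    w = a.maximum(a.T)
    w.data[:] = 1.0
    return SpatialGraph(weights=w, k=k)


def morans_i(values, graph: SpatialGraph, row_standardize: bool = True) -> float:
    """Moran's I of a value vector over the graph's nodes."""
    x = np.asarray(values, float)
    if len(x) != graph.n_nodes:
        raise ValueError("values length must match graph nodes")
    z = x - x.mean()
    denom = (z ** 2).sum()
    if denom == 0:
        raise ValueError("zero variance: Moran's I is undefined for constant values")
    w = graph.weights.astype(float)
    if row_standardize:
        deg = np.asarray(w.sum(axis=1)).ravel()
        inv = np.where(deg > 0, 1.0 / deg, 0.0)
        w = sp.diags(inv) @ w
    s0 = w.sum()
    num = float(z @ (w @ z))
    return graph.n_nodes / s0 * num / denom


def celltype_autocorrelation(
    dataset: SpatialDataset, graph: SpatialGraph, cell_type: str,
    row_standardize: bool = True,
) -> float:
    """Moran's I of the binary membership indicator of one cell type.

    The caller builds the graph over the same confident (singlet /
    doublet-certain) beads this function scores; pass a pre-filtered
    dataset (see :meth:`SpatialDataset.confident_mask`).
    """
    keep = dataset.confident_mask()
    ds = dataset if keep.all() else dataset.subset_beads(keep)
    if ds.n_beads != graph.n_nodes:
        raise ValueError(
            "graph nodes do not match confident beads; build the graph on the filtered beads"
        )
    indicator = (ds.bead_meta["cell_type"] == cell_type).to_numpy(float)
    if indicator.sum() < 2:
        raise ValueError(f"cell type {cell_type!r} present on fewer than 2 beads")
    return morans_i(indicator, graph, row_standardize=row_standardize)


def segment_contexts(
    dataset: SpatialDataset,
    graph: SpatialGraph,
    tumor_type_label: str,
    density_threshold: float = 0.3,
    smoothing_hops: int = 1,
) -> pd.Series:
    """Partition beads into tumor context vs tumor-adjacent context.

    Per bead, the local tumor fraction is the share of tumor-annotated
    beads within ``smoothing_hops`` graph hops (self inclusive); beads at
    or above ``density_threshold`` become tumor context, the rest
    adjacent context. Reject-class beads are excluded. The graph must be
    built over all beads of the dataset.
    """
    if dataset.n_beads != graph.n_nodes:
        raise ValueError("graph must be built over all beads of the dataset")
    tumor = (dataset.bead_meta["cell_type"] == tumor_type_label).to_numpy(float)
    confident = dataset.confident_mask()
    if tumor[confident].sum() == 0:
        logger.warning("segment_contexts: no %r beads; all adjacent_context", tumor_type_label)
    reach = sp.eye(graph.n_nodes, format="csr")
    hop = graph.weights + sp.eye(graph.n_nodes, format="csr")
    for _ in range(smoothing_hops):
        reach = reach @ hop
    reach = (reach > 0).astype(float)
    frac = np.asarray(reach @ tumor).ravel() / np.asarray(reach.sum(axis=1)).ravel()
    context = np.where(frac >= density_threshold, TUMOR_CONTEXT, ADJACENT_CONTEXT)
    context = np.where(confident, context, EXCLUDED)
    return pd.Series(context, name="context")
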