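"""Ligand-receptor screening by label permutation.

Two modes. For dissociated (scRNA) data the signal strength of a pair
between a sender type A and receiver type B is the product of the mean
normalized ligand expression over A cells and mean receptor expression
over B cells; significance comes from reshuffling the cluster labels
(default 1,000 rounds). For spatial data the score couples expression to
physical adjacency on the bead kNN graph M (binary, symmetric):

    S = sum_{i in A} sum_{j in B} Lexp_i * Rexp_j * M_ij
      - sum_{i in A} sum_{j in B} Rexp_i * Lexp_j * M_ij

The reverse term swaps ligand and receptor, cancelling admixture-driven
signal where both genes are smeared over both types; S is antisymmetric
under swapping (A, B) or (L, R). The null shuffles bead cell-type labels
while expression stays attached to positions (default 2,000 rounds).
P-values are one-sided upper-tail with a +1 pseudo-count; BH adjusts
across all tested (pair, type-pair) rows.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from tmekit.io import ExpressionDataset, LRTable, NormalizedMatrix, SpatialDataset, normalize_depth
from tmekit.spatial import SpatialGraph, build_knn_graph

logger = logging.getLogger("tmekit")

MIN_EXPRESSED_FRACTION = 0.10


def filter_expressed(
    normalized: NormalizedMatrix, cell_types, cell_type: str,
    min_fraction: float = MIN_EXPRESSED_FRACTION,
) -> np.ndarray:
    """Genes detected (count > 0) in at least ``min_fraction`` of a type's cells."""
    types = np.asarray(cell_types, dtype=object)
    idx = np.flatnonzero(types == cell_type)
    if len(idx) == 0:
        raise ValueError(f"cell type {cell_type!r} not present")
    detected = (normalized.values[:, idx] > 0).sum(axis=1)
    frac = np.asarray(detected).ravel() / len(idx)
    return np.asarray(normalized.gene_ids, dtype=object)[frac >= min_fraction]


def _gene_row(normalized: NormalizedMatrix, gene: str) -> np.ndarray:
    idx = np.flatnonzero(np.asarray(normalized.gene_ids, dtype=object) == gene)
    if len(idx) == 0:
        raise KeyError(f"gene {gene!r} not in matrix")
    return np.asarray(normalized.values[int(idx[0])].todense()).ravel()


def lr_score_dissociated(
    normalized: NormalizedMatrix, cell_types, ligand: str, receptor: str,
    sender_type: str, receiver_type: str,
) -> float:
    """Product of mean ligand expression in senders and mean receptor in receivers."""
    types = np.asarray(cell_types, dtype=object)
    senders = types == sender_type
    receivers = types == receiver_type
    if not senders.any() or not receivers.any():
        raise ValueError("sender or receiver type not present")
    lig = _gene_row(normalized, ligand)
    rec = _gene_row(normalized, receptor)
    return float(lig[senders].mean() * rec[receivers].mean())


def permute_dissociated(
    normalized: NormalizedMatrix, cell_types, ligand: str, receptor: str,
    sender_type: str, receiver_type: str, n_perm: int = 1000, seed: int = 0,
) -> float:
    """Upper-tail permutation p of the dissociated score under label shuffling."""
    rng = np.random.default_rng(seed)
    types = np.asarray(cell_types, dtype=object)
    lig = _gene_row(normalized, ligand)
    rec = _gene_row(normalized, receptor)
    senders = types == sender_type
    receivers = types == receiver_type
    s_obs = lig[senders].mean() * rec[receivers].mean()
    n_s, n_r = senders.sum(), receivers.sum()
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(types))
        ps, pr = perm[:n_s], perm[n_s:n_s + n_r]  # disjoint relabeled groups
        if lig[ps].mean() * rec[pr].mean() >= s_obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def lr_score_spatial(
    normalized: NormalizedMatrix, graph: SpatialGraph, bead_types,
    ligand: str, receptor: str, type_a: str, type_b: str,
) -> float:
    """Antisymmetric spatial LR score on the bead graph (sparse evaluation)."""
    types = np.asarray(bead_types, dtype=object)
    if len(types) != graph.n_nodes:
        raise ValueError("bead types must match graph nodes")
    in_a = (types == type_a).astype(float)
    in_b = (types == type_b).astype(float)
    if not in_a.any() or not in_b.any():
        raise ValueError("sender or receiver type not present on the puck")
    lig = _gene_row(normalized, ligand)
    rec = _gene_row(normalized, receptor)
    w = graph.weights
    la, ra = lig * in_a, rec * in_a
    lb, rb = lig * in_b, rec * in_b
    return float(la @ (w @ rb) - ra @ (w @ lb))


def permute_spatial(
    normalized: NormalizedMatrix, graph: SpatialGraph, bead_types,
    ligand: str, receptor: str, type_a: str, type_b: str,
    n_perm: int = 2000, seed: int = 0,
) -> float:
    """Upper-tail permutation p of the spatial score under bead-label shuffling."""
    rng = np.random.default_rng(seed)
    types = np.asarray(bead_types, dtype=object)
    lig = _gene_row(normalized, ligand)
    rec = _gene_row(normalized, receptor)
    coo = graph.weights.tocoo()
    u, v = coo.row, coo.col
    def score(t):
        sel = (t[u] == type_a) & (t[v] == type_b)
        return float((lig[u[sel]] * rec[v[sel]]).sum() - (rec[u[sel]] * lig[v[sel]]).sum())
    s_obs = score(types)
    hits = 0
    for _ in range(n_perm):
        if score(types[rng.permutation(len(types))]) >= s_obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def _prepare(data, graph, scale_constant):
    """Normalize input and extract labels (confident beads only for pucks)."""
    if isinstance(data, SpatialDataset):
        ds = data.subset_beads(data.confident_mask())
        if graph is None:
            graph = build_knn_graph(ds.coords)
        elif graph.n_nodes != ds.n_beads:
            raise ValueError("graph must be built over the confident beads")
        return normalize_depth(ds, scale_constant), ds.bead_meta["cell_type"].to_numpy(object), graph
    if isinstance(data, ExpressionDataset):
        return normalize_depth(data, scale_constant), data.cell_meta["cell_type"].to_numpy(object), None
    raise TypeError("expected ExpressionDataset or SpatialDataset")


def run_lr_screen(
    data,
    lr_table: LRTable,
    mode: str = "dissociated",
    graph: SpatialGraph | None = None,
    type_pairs=None,
    n_perm: int | None = None,
    min_fraction: float = MIN_EXPRESSED_FRACTION,
    scale_constant: float = 1e4,
    seed: int = 0,
) -> pd.DataFrame:
    """Screen every LR pair against every ordered type pair.

    Rows are (pair, sender type, receiver type) combinations whose ligand
    and receptor pass the expression filter in the sender and receiver
    type respectively. One label permutation per round is shared across
    all rows, so the null is computed in ``n_perm`` passes regardless of
    how many pairs are tested. Defaults: 1,000 rounds dissociated, 2,000
    spatial. Returns a DataFrame sorted by q.
    """
    if mode not in ("dissociated", "spatial"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_perm is None:
        n_perm = 1000 if mode == "dissociated" else 2000
    if len(lr_table) == 0:
        return pd.DataFrame(columns=[
            "pair_id", "ligand", "receptor", "sender_type", "receiver_type",
            "score", "p", "q", "n_permutations",
        ])
    normalized, labels, graph = _prepare(data, graph, scale_constant)
    rng = np.random.default_rng(seed)
    observed_types = list(pd.unique(labels))
    if type_pairs is None:
        type_pairs = [
            (a, b) for a in observed_types for b in observed_types
            if mode == "dissociated" or a != b  # S is identically 0 when A == B
        ]

    gene_ids = np.asarray(normalized.gene_ids, dtype=object)
    gene_lut = {g: i for i, g in enumerate(gene_ids)}
    expressed = {
        t: set(filter_expressed(normalized, labels, t, min_fraction))
        for t in observed_types
    }

    rows = []
    for _, pair in lr_table.table.iterrows():
        if pair["ligand"] not in gene_lut or pair["receptor"] not in gene_lut:
            logger.info("pair %r skipped: gene absent from matrix", pair["pair_id"])
            continue
        for a, b in type_pairs:
            if pair["ligand"] in expressed[a] and pair["receptor"] in expressed[b]:
                rows.append((pair["pair_id"], pair["ligand"], pair["receptor"], a, b))
    if not rows:
        return pd.DataFrame(columns=[
            "pair_id", "ligand", "receptor", "sender_type", "receiver_type",
            "score", "p", "q", "n_permutations",
        ])
    res = pd.DataFrame(rows, columns=["pair_id", "ligand", "receptor", "sender_type", "receiver_type"])

    need = sorted({*res["ligand"], *res["receptor"]})
    x = np.asarray(normalized.values[[gene_lut[g] for g in need]].todense())
    sub_lut = {g: i for i, g in enumerate(need)}
    li = res["ligand"].map(sub_lut).to_numpy()
    ri = res["receptor"].map(sub_lut).to_numpy()
    ai = res["sender_type"].to_numpy(object)
    bi = res["receiver_type"].to_numpy(object)
    type_of_row_a = np.array([observed_types.index(t) for t in ai])
    type_of_row_b = np.array([observed_types.index(t) for t in bi])
    tcode = np.array([observed_types.index(t) for t in labels])

    if mode == "dissociated":
        def all_scores(codes):
            onehot = np.zeros((len(codes), len(observed_types)))
            onehot[np.arange(len(codes)), codes] = 1.0
            counts = onehot.sum(axis=0)
            means = (x @ onehot) / np.where(counts > 0, counts, 1.0)
            return means[li, type_of_row_a] * means[ri, type_of_row_b]
    else:
        coo = graph.weights.tocoo()
        u, v = coo.row, coo.col

        def all_scores(codes):
            out = np.empty(len(res))
            tu, tv = codes[u], codes[v]
            for a_c in np.unique(type_of_row_a):
                for b_c in np.unique(type_of_row_b[type_of_row_a == a_c]):
                    sel = np.flatnonzero((tu == a_c) & (tv == b_c))
                    rmask = (type_of_row_a == a_c) & (type_of_row_b == b_c)
                    xu = x[:, u[sel]]
                    xv = x[:, v[sel]]
                    s = (xu[li[rmask]] * xv[ri[rmask]]).sum(axis=1) \
                        - (xu[ri[rmask]] * xv[li[rmask]]).sum(axis=1)
                    out[rmask] = s
            return out

    s_obs = all_scores(tcode)
    hits = np.zeros(len(res), dtype=int)
    for _ in range(n_perm):
        hits += all_scores(tcode[rng.permutation(len(tcode))]) >= s_obs - 1e-12
    res["score"] = s_obs
    res["p"] = (1 + hits) / (n_perm + 1)
    res["q"] = multipletests(res["p"], method="fdr_bh")[1]
    res["n_permutations"] = n_perm
    return res.sort_values(["q", "p"], kind="mergesort").reset_index(drop=True)
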