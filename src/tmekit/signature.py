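"""Derivation and evaluation of a compact malignant-cell gene signature.

The procedure: rank genes by a signed rank-sum Z score between malignant
and non-malignant luminal cells, keep upregulated genes with Z strictly
above a threshold (default 3), then drop any gene detected in at least 5%
of all healthy epithelial cells. The surviving genes form the signature;
cells are called malignant when their mean signature expression strictly
exceeds a score threshold (default 0.1), and bulk cohorts are evaluated
by ROC AUC of the per-sample mean signature expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from tmekit.io import NormalizedMatrix
from tmekit.scoring import EXACT_MAX_N, ranksum_p

logger = logging.getLogger("tmekit")


@dataclass
class TumorSignature:
    genes: list
    z_threshold: float = 3.0
    healthy_fraction_max: float = 0.05
    score_threshold: float = 0.1
    table: pd.DataFrame | None = field(default=None, repr=False)


def rank_markers(normalized: NormalizedMatrix, cells_a, cells_b) -> pd.DataFrame:
    """Per-gene two-sided rank-sum test of group A vs group B.

    Returns a DataFrame indexed by gene with columns ``z`` (signed
    standard-normal quantile of the p-value, positive when A > B), ``p``,
    and the detection fractions ``frac_a`` / ``frac_b`` (share of cells
    with expression > 0). Genes all-zero in both groups get Z = 0. Small
    groups (both n <= 8) use exact enumeration.
    """
    cells_a = np.asarray(cells_a)
    cells_b = np.asarray(cells_b)
    if cells_a.dtype == bool:
        cells_a = np.flatnonzero(cells_a)
    if cells_b.dtype == bool:
        cells_b = np.flatnonzero(cells_b)
    if len(cells_a) == 0 or len(cells_b) == 0:
        raise ValueError("both groups must be non-empty")
    xa = np.asarray(normalized.values[:, cells_a].todense())
    xb = np.asarray(normalized.values[:, cells_b].todense())
    mean_diff = xa.mean(axis=1) - xb.mean(axis=1)

    if len(cells_a) <= EXACT_MAX_N and len(cells_b) <= EXACT_MAX_N:
        pvals = np.array([ranksum_p(xa[g], xb[g]) for g in range(xa.shape[0])])
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = scipy.stats.mannwhitneyu(
                xa, xb, axis=1, alternative="two-sided",
                method="asymptotic", use_continuity=True,
            )
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    constant = np.ptp(np.hstack([xa, xb]), axis=1) == 0
    pvals = np.where(constant, 1.0, np.clip(pvals, 1e-300, 1.0))
    z = scipy.stats.norm.isf(pvals / 2.0) * np.sign(mean_diff)
    z = np.where(mean_diff == 0, 0.0, z)
    return pd.DataFrame({
        "z": z,
        "p": pvals,
        "mean_a": xa.mean(axis=1),
        "mean_b": xb.mean(axis=1),
        "frac_a": (xa > 0).mean(axis=1),
        "frac_b": (xb > 0).mean(axis=1),
    }, index=pd.Index(normalized.gene_ids, name="gene"))


def derive_signature(
    markers: pd.DataFrame,
    healthy_epithelial_fractions: pd.Series,
    z_threshold: float = 3.0,
    healthy_fraction_max: float = 0.05,
    score_threshold: float = 0.1,
) -> TumorSignature:
    """Select signature genes from a malignant-vs-luminal marker table.

    Keeps genes upregulated in the malignant group with Z strictly above
    ``z_threshold`` and detection in healthy epithelial cells strictly
    below ``healthy_fraction_max``; ordered by descending Z. An empty
    result is returned with a warning, not raised.
    """
    hf = healthy_epithelial_fractions.reindex(markers.index)
    keep = (markers["z"] > z_threshold) & (hf < healthy_fraction_max)
    table = markers.loc[keep].copy()
    table["healthy_fraction"] = hf.loc[keep]
    table = table.sort_values("z", ascending=False, kind="mergesort")
    if table.empty:
        logger.warning("derive_signature: no genes pass the filters")
    return TumorSignature(
        genes=list(table.index),
        z_threshold=z_threshold,
        healthy_fraction_max=healthy_fraction_max,
        score_threshold=score_threshold,
        table=table,
    )


def classify_cells(cell_scores, score_threshold: float = 0.1) -> np.ndarray:
    """Call a cell malignant iff its signature score strictly exceeds the threshold."""
    return np.asarray(cell_scores, float) > score_threshold


def evaluate_bulk_auc(
    bulk: pd.DataFrame,
    labels,
    signature: TumorSignature,
    positive_label: str = "tumor",
    standardize: bool = False,
) -> tuple[float, pd.DataFrame]:
    """ROC AUC of mean signature expression on a labeled bulk cohort.

    Per-sample score = mean expression of the signature genes present in
    the matrix (optionally z-scored per gene first). AUC is the
    Mann-Whitney concordance probability with ties counted 1/2; the ROC
    points cover every distinct score threshold.
    """
    labels = np.asarray(labels, dtype=object)
    present = [g for g in signature.genes if g in bulk.index]
    if not present:
        raise ValueError("no signature genes present in the bulk matrix")
    if len(present) < len(signature.genes):
        logger.warning(
            "evaluate_bulk_auc: %d signature gene(s) absent from bulk matrix",
            len(signature.genes) - len(present),
        )
    expr = bulk.loc[present]
    if standardize:
        mu = expr.mean(axis=1)
        sd = expr.std(axis=1, ddof=0).replace(0.0, 1.0)
        expr = expr.sub(mu, axis=0).div(sd, axis=0)
    scores = expr.mean(axis=0).to_numpy(float)
    pos = scores[labels == positive_label]
    neg = scores[labels != positive_label]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")

    # AUC as rank-based concordance: U / (n_pos * n_neg), ties count 1/2
    ranks = scipy.stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    auc = u / (len(pos) * len(neg))

    thresholds = np.concatenate([[np.inf], np.sort(np.unique(scores))[::-1]])
    # score >= threshold is called positive, so the curve reaches (1, 1)
    tpr = [np.mean(pos >= t) if np.isfinite(t) else 0.0 for t in thresholds]
    fpr = [np.mean(neg >= t) if np.isfinite(t) else 0.0 for t in thresholds]
    roc = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return float(auc), roc
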