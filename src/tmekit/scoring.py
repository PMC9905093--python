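"""Gene-set signature scores, rank-sum group comparisons and
inter-sample expression distances.

A signature score is the plain arithmetic mean of depth-normalized
expression over the genes of a set — first per cell, then per sample as
the mean across that sample's cells. Group differences are assessed with
the two-sided Wilcoxon rank-sum (Mann-Whitney) test: exact by full label
enumeration when both groups have at most ``EXACT_MAX_N`` samples,
otherwise the normal approximation with tie and continuity correction.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from tmekit.io import GeneSet, NormalizedMatrix, normalize_depth

logger = logging.getLogger("tmekit")

EXACT_MAX_N = 8


def ranksum_p(a, b, exact_max: int = EXACT_MAX_N) -> float:
    """Two-sided rank-sum p-value for samples ``a`` vs ``b``.

    Exact enumeration of all C(n1+n2, n1) label assignments (valid under
    ties) when both groups are small; otherwise the normal approximation
    with tie and continuity corrections.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if n1 <= exact_max and n2 <= exact_max:
        pooled = np.concatenate([a, b])
        ranks = scipy.stats.rankdata(pooled)
        mu = n1 * n2 / 2.0
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return hits / total
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    res = scipy.stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def score_cells(normalized: NormalizedMatrix, gene_set: GeneSet) -> np.ndarray:
    """Per-cell signature score: mean normalized expression of the set's genes.

    Genes missing from the matrix are dropped with a warning; zero overlap
    is an error.
    """
    present = [g for g in gene_set.genes if g in set(normalized.gene_ids)]
    missing = [g for g in gene_set.genes if g not in set(normalized.gene_ids)]
    if missing:
        logger.warning(
            "gene set %r: %d gene(s) absent from matrix: %s",
            gene_set.name, len(missing), ", ".join(map(str, missing)),
        )
    if not present:
        raise ValueError(f"no genes of set {gene_set.name!r} are present in the matrix")
    idx = normalized.gene_index(present)
    sub = normalized.values[idx]
    return np.asarray(sub.mean(axis=0)).ravel()


def score_samples(cell_scores, cell_meta: pd.DataFrame, stratify_by=None) -> pd.DataFrame:
    """Sample-level scores: exact mean of member-cell scores per (sample x strata)."""
    df = pd.DataFrame({"score": np.asarray(cell_scores, float)})
    keys = ["sample_id"] + (list(stratify_by) if stratify_by else [])
    for k in keys:
        df[k] = cell_meta[k].to_numpy()
    if "fraction" in cell_meta.columns and "fraction" not in keys:
        df["fraction"] = cell_meta["fraction"].to_numpy()
    group_keys = keys + (["fraction"] if "fraction" in df.columns and "fraction" not in keys else [])
    out = (
        df.groupby(group_keys, sort=True, observed=True)
        .agg(score=("score", "mean"), n_cells=("score", "size"))
        .reset_index()
    )
    return out


def compare_groups(sample_scores, group_labels, exact_max: int = EXACT_MAX_N) -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests between groups of sample scores."""
    scores = np.asarray(sample_scores, float)
    labels = np.asarray(group_labels, dtype=object)
    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for ga, gb in combinations(groups, 2):
        a, b = scores[labels == ga], scores[labels == gb]
        if len(a) == 0 or len(b) == 0:
            logger.warning("pair (%s, %s) skipped: empty group", ga, gb)
            continue
        rows.append({
            "group_a": ga, "group_b": gb, "n_a": len(a), "n_b": len(b),
            "p": ranksum_p(a, b, exact_max=exact_max),
        })
    return pd.DataFrame(rows)


def sample_expression_distance(
    dataset,
    cell_types=None,
    min_cells: int = 10,
    scale_constant: float = 1e4,
) -> pd.DataFrame:
    """Inter-sample expression distances within each tissue fraction.

    For each cell type, distance(sample a, sample b) = 1 - Pearson
    correlation of their mean depth-normalized profiles (computed from
    samples with at least ``min_cells`` cells of the type). Per sample
    pair, type distances are averaged weighted by the pair's minimum cell
    count per type. Fractions with fewer than two samples are omitted.
    """
    normalized = normalize_depth(dataset, scale_constant)
    meta = dataset.cell_meta
    if cell_types is None:
        cell_types = sorted(meta["cell_type"].unique())
    dense = np.asarray(normalized.values.todense())

    profiles = {}  # (sample, type) -> (mean profile, n_cells)
    for (sample, ctype), idx in meta.groupby(["sample_id", "cell_type"], observed=True).indices.items():
        if ctype in cell_types and len(idx) >= min_cells:
            profiles[(sample, ctype)] = (dense[:, idx].mean(axis=1), len(idx))

    sample_fraction = meta.drop_duplicates("sample_id").set_index("sample_id")["fraction"]
    rows = []
    for fraction in sample_fraction.unique():
        samples = sorted(sample_fraction.index[sample_fraction == fraction])
        if len(samples) < 2:
            logger.warning("fraction %r has <2 samples; omitted", fraction)
            continue
        for sa, sb in combinations(samples, 2):
            dists, weights = [], []
            for ctype in cell_types:
                if (sa, ctype) in profiles and (sb, ctype) in profiles:
                    pa, na = profiles[(sa, ctype)]
                    pb, nb = profiles[(sb, ctype)]
                    if pa.std() == 0 or pb.std() == 0:
                        continue  # correlation undefined for flat profiles
                    r = np.corrcoef(pa, pb)[0, 1]
                    dists.append(1.0 - r)
                    weights.append(min(na, nb))
            if dists:
                rows.append({
                    "fraction": fraction, "sample_a": sa, "sample_b": sb,
                    "distance": float(np.average(dists, weights=weights)),
                })
    return pd.DataFrame(rows)
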