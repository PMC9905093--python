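"""Ground-truth validation experiments for the whole pipeline.

Every stage of the package is checked against an independent oracle or a
simulation with planted truth: brute-force evaluation of the spatial LR
score, exact sign identities, permutation-test calibration under
exchangeable nulls, planted-effect power and false-discovery control for
the admixture-corrected context DE, simplex-recovery of the deconvolution,
Moran's I closed-form cases, and the strict thresholds of the
tumor-signature procedure. The functions here are called both by the test
suite and by ``scripts/acceptance.py``; each takes a seed and returns
plain numbers.

Problem sizes are chosen so the full battery runs in minutes on one CPU:
pucks of a few hundred to ~1,000 beads, gene panels of 100-400 genes, and
permutation counts matching the method defaults scaled to the round count
of each experiment.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from tmekit.de import (
    context_de,
    correct_profile,
    estimate_admixture,
    nb_pseudobulk_test,
    pseudobulk,
    tile_units,
)
from tmekit.io import LRTable, normalize_depth
from tmekit.lr import lr_score_spatial, permute_dissociated, permute_spatial, run_lr_screen
from tmekit.scoring import ranksum_p
from tmekit.signature import TumorSignature, derive_signature, evaluate_bulk_auc, rank_markers
from tmekit.simulate import (
    Domain,
    PlantedEffect,
    PlantedLR,
    PuckLayout,
    nb_sample,
    simulate_profiles,
    simulate_puck,
    simulate_scrna,
)
from tmekit.spatial import SpatialGraph, build_knn_graph, morans_i


# ---------------------------------------------------------------------------
# spatial LR score: oracle equivalence and antisymmetry


def _random_instance(rng, n):
    coords = rng.uniform(0, 100, size=(n, 2))
    expr = rng.gamma(1.0, 2.0, size=(2, n))
    types = rng.choice(["A", "B", "C"], size=n)
    types[0], types[1] = "A", "B"  # both tested types always present
    graph = build_knn_graph(coords, k=min(8, n - 1))
    return expr, types, graph


def _score_direct(expr_l, expr_r, w_dense, in_a, in_b):
    """Direct formula evaluation, one explicit loop over sender beads."""
    s = 0.0
    for i in np.flatnonzero(in_a):
        row = w_dense[i] * in_b
        s += expr_l[i] * float(row @ expr_r) - expr_r[i] * float(row @ expr_l)
    return s


def spatial_score_oracle_gap(n_pucks: int = 200, max_beads: int = 300, seed: int = 0) -> float:
    """Max |sparse score - direct double-sum| over random pucks (proportion scale)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pucks):
        n = int(rng.integers(30, max_beads + 1))
        expr, types, graph = _random_instance(rng, n)
        nm = _normalized_from_matrix(expr)
        s_fast = lr_score_spatial(nm, graph, types, "L", "R", "A", "B")
        dense = np.asarray(nm.values.todense())
        s_direct = _score_direct(dense[0], dense[1], graph.weights.toarray(),
                                 types == "A", types == "B")
        worst = max(worst, abs(s_fast - s_direct))
    return worst


def _normalized_from_matrix(expr):
    from tmekit.io import NormalizedMatrix

    expr = np.asarray(expr, float)
    totals = expr.sum(axis=0)
    totals[totals == 0] = 1.0
    return NormalizedMatrix(
        values=sp.csr_matrix(expr / totals),
        gene_ids=np.array(["L", "R"], dtype=object),
        scale_constant=1.0,
    )


def antisymmetry_max_violation(n_instances: int = 1000, seed: int = 1) -> float:
    """Max |S(A,B;L,R) + S(A,B;R,L)| and |S(A,B) + S(B,A)| over random instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(8, 40))
        expr, types, graph = _random_instance(rng, n)
        nm = _normalized_from_matrix(expr)
        s = lr_score_spatial(nm, graph, types, "L", "R", "A", "B")
        scale = max(1.0, abs(s))
        worst = max(
            worst,
            abs(s + lr_score_spatial(nm, graph, types, "R", "L", "A", "B")) / scale,
            abs(s + lr_score_spatial(nm, graph, types, "L", "R", "B", "A")) / scale,
        )
    return worst


# ---------------------------------------------------------------------------
# permutation-test calibration


def lr_calibration_dissociated(n_rounds: int = 2000, n_perm: int = 199,
                               n_cells: int = 60, seed: int = 0) -> float:
    """Type-I error of the dissociated LR permutation test at alpha = 0.05.

    Null data: identical type profiles, so cluster labels are exchangeable.
    """
    profiles = simulate_profiles(30, 3, n_markers_per_type=2, marker_fold=1.0, seed=seed)
    hits = 0
    for r in range(n_rounds):
        ds, _ = simulate_scrna(profiles, samples_per_fraction=1,
                               cells_per_sample=n_cells, fractions=("tumor",),
                               seed=seed * 1000 + r + 1)
        nm = normalize_depth(ds)
        p = permute_dissociated(nm, ds.cell_meta["cell_type"], "g0001", "g0002",
                                "type1", "type2", n_perm=n_perm, seed=r)
        hits += p <= 0.05
    return hits / n_rounds


def lr_calibration_spatial(n_rounds: int = 2000, n_perm: int = 199, seed: int = 0) -> float:
    """Type-I error of the spatial LR permutation test at alpha = 0.05."""
    profiles = simulate_profiles(30, 3, n_markers_per_type=2, marker_fold=1.0, seed=seed)
    hits = 0
    for r in range(n_rounds):
        puck, _ = simulate_puck(profiles, layout=PuckLayout(width=220, height=220, spacing=25),
                                seed=seed * 1000 + r + 1)
        kept = puck.subset_beads(puck.confident_mask())
        graph = build_knn_graph(kept.coords, k=10)
        nm = normalize_depth(kept)
        p = permute_spatial(nm, graph, kept.bead_meta["cell_type"], "g0001", "g0002",
                            "type1", "type2", n_perm=n_perm, seed=r)
        hits += p <= 0.05
    return hits / n_rounds


def context_de_calibration(n_rounds: int = 200, n_genes: int = 150, seed: int = 0) -> float:
    """Type-I error of the NB pseudo-bulk test at alpha = 0.05 on null data."""
    rng = np.random.default_rng(seed)
    hits = total = 0
    for _ in range(n_rounds):
        base = rng.lognormal(2.0, 1.0, size=n_genes)
        lib = rng.lognormal(0.0, 0.2, size=8)
        y = nb_sample(rng, np.outer(base, lib), 0.2)
        res = nb_pseudobulk_test(pd.DataFrame(y[:, :4]), pd.DataFrame(y[:, 4:]))
        hits += int((res["p"] <= 0.05).sum())
        total += n_genes
    return hits / total


# ---------------------------------------------------------------------------
# planted ligand-receptor power


def planted_lr_study(n_pucks: int = 50, n_pairs: int = 100, n_planted: int = 10,
                     n_perm: int = 999, seed: int = 0) -> dict:
    """Detect planted co-localized LR pairs among decoys on simulated pucks.

    Returns the fraction of planted pairs reaching q < 0.05 and the mean
    number of significant decoys among the top 10 rows by q.
    """
    profiles = simulate_profiles(2 * n_pairs + 20, 3, n_markers_per_type=5,
                                 marker_fold=4.0, seed=seed)
    free = [g for g in profiles.gene_ids
            if all(g not in m for m in profiles.marker_genes.values())]
    lig, rec = free[:n_pairs], free[n_pairs:2 * n_pairs]
    table = LRTable(pd.DataFrame({
        "ligand": lig, "receptor": rec,
        "pair_id": [f"p{i}" for i in range(n_pairs)],
    }))
    planted_ids = {f"p{i}" for i in range(n_planted)}
    planted = tuple(PlantedLR(lig[i], rec[i], "type1", "type2", strength=4.0)
                    for i in range(n_planted))
    layout = PuckLayout(width=420, height=420, spacing=20)
    detected = 0
    decoys_top10 = []
    for r in range(n_pucks):
        puck, _ = simulate_puck(profiles, layout=layout, planted_lr=planted,
                                umi_per_bead=800, seed=seed * 10_000 + r + 1)
        res = run_lr_screen(puck, table, mode="spatial",
                            type_pairs=[("type1", "type2")], n_perm=n_perm, seed=r)
        sig = res[res["q"] < 0.05]
        detected += len(set(sig["pair_id"]) & planted_ids)
        top10 = res.head(10)
        decoys_top10.append(int(((~top10["pair_id"].isin(planted_ids))
                                 & (top10["q"] < 0.05)).sum()))
    return {
        "detection_rate": detected / (n_pucks * n_planted),
        "mean_significant_decoys_top10": float(np.mean(decoys_top10)),
        "max_significant_decoys_top10": int(np.max(decoys_top10)),
    }


# ---------------------------------------------------------------------------
# admixture-corrected context DE


def _confound_setup(seed):
    profiles = simulate_profiles(400, 3, n_markers_per_type=20, marker_fold=8.0, seed=seed)
    layout = PuckLayout(domains=[
        Domain("tumor_context", (0.0, 0.5), {"type1": 0.7, "type2": 0.3}),
        Domain("adjacent_context", (0.5, 1.0), {"type3": 0.7, "type2": 0.3}),
    ])
    reference = pd.DataFrame({t: profiles.profile(t) for t in profiles.type_names},
                             index=profiles.gene_ids)
    return profiles, layout, reference


def _context_de_run(profiles, layout, reference, planted, seed, corrected):
    puck, truth = simulate_puck(profiles, layout=layout, planted_context_de=planted,
                                umi_per_bead=800, seed=seed)
    units = tile_units(puck.coords, truth.extras["domain"])
    pb = pseudobulk(puck, units, "type2")
    mats = {}
    for ctx in ("tumor_context", "adjacent_context"):
        cols = {}
        for u, p in pb.items():
            if not u.startswith(ctx):
                continue
            if corrected:
                fit = estimate_admixture(p.counts, reference, "type2")
                cols[u] = correct_profile(p.counts, fit)
            else:
                cols[u] = p.counts
        mats[ctx] = pd.DataFrame(cols)
    return context_de(mats)


def admixture_confound_study(n_pucks: int = 8, seed: int = 0) -> dict:
    """Neighbor-marker false positives with and without admixture correction.

    Pucks where the target type is unchanged between contexts but its
    neighborhood differs (tumor-type neighbors on one side, another type on
    the other). Reports the fraction of the tumor-type's marker genes
    flagged at q < 0.05 by the uncorrected and the corrected analysis.
    """
    profiles, layout, reference = _confound_setup(seed)
    markers = profiles.marker_genes["type1"]
    unc, cor = [], []
    for r in range(n_pucks):
        s = seed * 1000 + r + 1
        res_u = _context_de_run(profiles, layout, reference, (), s, corrected=False)
        res_c = _context_de_run(profiles, layout, reference, (), s, corrected=True)
        unc.append((res_u.loc[markers, "q"] < 0.05).mean())
        cor.append((res_c.loc[markers, "q"] < 0.05).mean())
    return {
        "uncorrected_neighbor_marker_flag_rate": float(np.mean(unc)),
        "corrected_neighbor_marker_flag_rate": float(np.mean(cor)),
    }


def planted_context_effect_study(n_pucks: int = 8, n_planted: int = 50,
                                 log2fc: float = 2.0, seed: int = 0) -> dict:
    """Power and FDR of the corrected context DE for planted 4-fold effects."""
    profiles, layout, reference = _confound_setup(seed)
    rng = np.random.default_rng(seed + 77)
    free = [g for g in profiles.gene_ids
            if all(g not in m for m in profiles.marker_genes.values())]
    planted_genes = list(rng.choice(free, n_planted, replace=False))
    planted = tuple(PlantedEffect(g, "type2", "tumor_context", log2fc)
                    for g in planted_genes)
    tp = fp = 0
    for r in range(n_pucks):
        res = _context_de_run(profiles, layout, reference, planted,
                              seed * 1000 + r + 1, corrected=True)
        disc = set(res.index[res["q"] < 0.05])
        tp += len(disc & set(planted_genes))
        fp += len(disc - set(planted_genes))
    return {
        "power": tp / (n_pucks * n_planted),
        "empirical_fdr": fp / max(tp + fp, 1),
    }


def corrected_vs_uncorrected_shrinkage(n_pucks: int = 20, seed: int = 0) -> float:
    """Ratio of corrected to uncorrected median |log2FC| of neighbor markers."""
    profiles, layout, reference = _confound_setup(seed)
    markers = profiles.marker_genes["type1"]
    ratios = []
    for r in range(n_pucks):
        s = seed * 1000 + r + 1
        res_u = _context_de_run(profiles, layout, reference, (), s, corrected=False)
        res_c = _context_de_run(profiles, layout, reference, (), s, corrected=True)
        ratios.append(res_c.loc[markers, "log2fc"].abs().median()
                      / res_u.loc[markers, "log2fc"].abs().median())
    return float(np.median(ratios))


# ---------------------------------------------------------------------------
# deconvolution recovery


def _deconv_reference(seed, n_genes=200, n_types=4):
    profiles = simulate_profiles(n_genes, n_types, n_markers_per_type=12,
                                 marker_fold=8.0, seed=seed)
    return pd.DataFrame({t: profiles.profile(t) for t in profiles.type_names},
                        index=profiles.gene_ids), profiles


def deconvolution_noiseless_error(n_mixtures: int = 20, seed: int = 0) -> float:
    """Max absolute weight error on noiseless simplex mixtures."""
    reference, _ = _deconv_reference(seed)
    cols = reference.columns
    P = reference.to_numpy() / reference.to_numpy().sum(axis=0)
    rng = np.random.default_rng(seed + 1)
    worst = 0.0
    for _ in range(n_mixtures):
        w = rng.dirichlet(np.ones(len(cols)))
        y = pd.Series(P @ w, index=reference.index)
        fit = estimate_admixture(y, reference, cols[0], robust_trim=None)
        worst = max(worst, float(np.abs(fit.weights.to_numpy() - w).max()))
    return worst


def deconvolution_nb_rmse(n_fits: int = 100, total_counts: float = 1e5,
                          n_beads: int = 100, seed: int = 0) -> float:
    """Weight RMSE when the mixture is observed as NB counts of given depth.

    The observation is a pseudo-bulk: a sum over ``n_beads`` independent NB
    draws (per-gene dispersion from the profile set), totalling
    ``total_counts`` in expectation — per-bead overdispersion averages out
    with the number of beads, as on a real puck.
    """
    reference, profiles = _deconv_reference(seed)
    cols = reference.columns
    P = reference.to_numpy() / reference.to_numpy().sum(axis=0)
    rng = np.random.default_rng(seed + 2)
    sq = []
    for _ in range(n_fits):
        w = rng.dirichlet(np.ones(len(cols)) * 2.0)
        bead_mean = total_counts / n_beads * (P @ w)
        counts = nb_sample(rng, np.tile(bead_mean, (n_beads, 1)),
                           profiles.dispersion[None, :]).sum(axis=0)
        y = pd.Series(counts, index=reference.index)
        fit = estimate_admixture(y, reference, cols[0], robust_trim=None)
        sq.extend((fit.weights.to_numpy() - w) ** 2)
    return float(np.sqrt(np.mean(sq)))


# ---------------------------------------------------------------------------
# Moran's I


def grid_rook_graph(rows: int, cols: int) -> SpatialGraph:
    n = rows * cols
    w = sp.lil_matrix((n, n))
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if r + 1 < rows:
                w[i, i + cols] = w[i + cols, i] = 1.0
            if c + 1 < cols:
                w[i, i + 1] = w[i + 1, i] = 1.0
    return SpatialGraph(weights=w.tocsr(), k=4)


def moran_checkerboard(side: int = 6) -> float:
    """Moran's I of a perfect checkerboard on a rook grid (exactly -1)."""
    g = grid_rook_graph(side, side)
    values = np.fromfunction(lambda r, c: (r + c) % 2, (side, side)).ravel()
    return morans_i(values, g, row_standardize=True)


def moran_oracle_gap(n_graphs: int = 20, max_nodes: int = 300, seed: int = 0) -> float:
    """Max |sparse Moran's I - direct-formula evaluation| over random graphs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_graphs):
        n = int(rng.integers(30, max_nodes + 1))
        coords = rng.uniform(0, 100, size=(n, 2))
        graph = build_knn_graph(coords, k=6)
        x = rng.normal(size=n)
        for rs in (True, False):
            i_fast = morans_i(x, graph, row_standardize=rs)
            w = graph.weights.toarray().astype(float)
            if rs:
                deg = w.sum(axis=1)
                w = np.divide(w, deg[:, None], out=np.zeros_like(w),
                              where=deg[:, None] > 0)
            z = x - x.mean()
            i_direct = 0.0
            for i in range(n):  # direct formula, row by row
                i_direct += float(w[i] @ z) * z[i]
            i_direct *= n / w.sum() / (z ** 2).sum()
            worst = max(worst, abs(i_fast - i_direct))
    return worst


def clustered_vs_dispersed(n_pairs: int = 100, side: int = 20, seed: int = 0) -> float:
    """Fraction of paired simulations where a clustered indicator out-scores
    the same values randomly dispersed."""
    rng = np.random.default_rng(seed)
    g = grid_rook_graph(side, side)
    wins = 0
    for _ in range(n_pairs):
        r0, c0 = rng.integers(0, side - 8, size=2)
        values = np.zeros((side, side))
        values[r0:r0 + 8, c0:c0 + 8] = 1.0
        flat = values.ravel()
        noise = rng.random(side * side) < 0.05
        clustered = np.clip(flat + noise, 0, 1)
        dispersed = rng.permutation(clustered)
        wins += morans_i(clustered, g) > morans_i(dispersed, g)
    return wins / n_pairs


# ---------------------------------------------------------------------------
# tumor-signature procedure


def signature_fixture_study(seed: int = 0) -> dict:
    """Run the full derivation on a constructed malignant-vs-luminal fixture.

    30 malignant and 30 luminal cells; ten genes strongly up in malignant
    cells (all reach Z > 3), of which exactly two are detected in >= 5% of
    healthy epithelial cells and must be excluded, leaving 8 genes.
    """
    rng = np.random.default_rng(seed)
    n_genes, n_mal, n_lum, n_healthy = 40, 30, 30, 200
    counts = rng.poisson(5.0, size=(n_genes, n_mal + n_lum))
    counts[:10, :n_mal] += 40  # candidate signature genes, up in malignant
    from tmekit.io import ExpressionDataset

    meta = pd.DataFrame({
        "sample_id": ["s1"] * (n_mal + n_lum),
        "fraction": ["tumor"] * (n_mal + n_lum),
        "cell_type": ["malignant"] * n_mal + ["luminal"] * n_lum,
    })
    ds = ExpressionDataset(counts=sp.csr_matrix(counts),
                           gene_ids=np.array([f"g{i}" for i in range(n_genes)], dtype=object),
                           cell_meta=meta)
    nm = normalize_depth(ds, scale_constant=counts.sum(axis=0).mean())
    markers = rank_markers(nm, np.arange(n_mal), np.arange(n_mal, n_mal + n_lum))

    # healthy epithelium: genes g0/g1 common (30% of cells), the rest rare
    healthy = np.zeros((n_genes, n_healthy), dtype=int)
    healthy[0] = rng.random(n_healthy) < 0.30
    healthy[1] = rng.random(n_healthy) < 0.30
    healthy[2:10] = rng.random((8, n_healthy)) < 0.01
    healthy_frac = pd.Series((healthy > 0).mean(axis=1),
                             index=[f"g{i}" for i in range(n_genes)])
    sig = derive_signature(markers, healthy_frac)
    return {
        "n_candidates_z3": int((markers["z"] > 3).sum()),
        "n_signature_genes": len(sig.genes),
        "excluded_common_genes": sorted(set([f"g{i}" for i in range(10)]) - set(sig.genes)),
    }


def auc_concordance_exhaustive(max_n: int = 3) -> float:
    """Max |AUC - pairwise concordance| over all small tied score vectors.

    Enumerates every score vector with values in {0, 0.5, 1} for all class
    sizes up to ``max_n`` per class.
    """
    worst = 0.0
    values = [0.0, 0.5, 1.0]
    for n_pos in range(1, max_n + 1):
        for n_neg in range(1, max_n + 1):
            for combo in itertools.product(values, repeat=n_pos + n_neg):
                scores = np.array(combo)
                pos, neg = scores[:n_pos], scores[n_pos:]
                bulk = pd.DataFrame([scores],
                                    index=["g"],
                                    columns=[f"s{i}" for i in range(len(scores))])
                labels = np.array(["tumor"] * n_pos + ["normal"] * n_neg, dtype=object)
                auc, _ = evaluate_bulk_auc(bulk, labels, TumorSignature(genes=["g"]))
                conc = np.mean([1.0 if p > q else 0.5 if p == q else 0.0
                                for p in pos for q in neg])
                worst = max(worst, abs(auc - conc))
    return worst


def bimodal_threshold(scores) -> float:
    """Otsu split of a 1-D score distribution (maximum between-class variance).

    Used to pick a malignant-call threshold on simulated data without
    consulting the ground truth.
    """
    x = np.sort(np.asarray(scores, float))
    n = len(x)
    best, best_t = -np.inf, x[n // 2]
    csum = np.cumsum(x)
    total = csum[-1]
    for i in range(1, n):
        n1, n2 = i, n - i
        mu1, mu2 = csum[i - 1] / n1, (total - csum[i - 1]) / n2
        crit = n1 * n2 * (mu1 - mu2) ** 2
        if crit > best:
            best, best_t = crit, (x[i - 1] + x[i]) / 2.0
    return float(best_t)


# ---------------------------------------------------------------------------
# rank-sum exactness and QC boundaries


def wilcoxon_exact_gap(seed: int = 0) -> float:
    """Max |exact-branch p - exhaustive-enumeration p| over all sizes <= 6."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for n1 in range(1, 7):
        for n2 in range(1, 7):
            for _ in range(3):
                a = rng.integers(0, 5, size=n1).astype(float)
                b = rng.integers(0, 5, size=n2).astype(float)
                pooled = np.concatenate([a, b])
                ranks = scipy.stats.rankdata(pooled)
                mu = n1 * n2 / 2.0
                obs = abs(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0 - mu)
                devs = [abs(sum(ranks[list(c)]) - n1 * (n1 + 1) / 2.0 - mu)
                        for c in itertools.combinations(range(n1 + n2), n1)]
                p_oracle = float(np.mean([d >= obs - 1e-12 for d in devs]))
                worst = max(worst, abs(ranksum_p(a, b) - p_oracle))
    return worst


def qc_boundary_checks() -> dict:
    """Verify every stated QC boundary on toy fixtures; returns pass counts."""
    from tmekit.io import ExpressionDataset, filter_cells_by_umi, filter_doublets
    from tmekit.lr import filter_expressed

    def expr(counts, **meta_kw):
        counts = np.asarray(counts)
        n = counts.shape[1]
        meta = pd.DataFrame({
            "sample_id": ["s"] * n, "fraction": ["tumor"] * n,
            "cell_type": meta_kw.get("cell_type", ["t"] * n),
        })
        if "doublet_score" in meta_kw:
            meta["doublet_score"] = meta_kw["doublet_score"]
        return ExpressionDataset(
            counts=sp.csr_matrix(counts),
            gene_ids=np.array([f"g{i}" for i in range(counts.shape[0])], dtype=object),
            cell_meta=meta)

    checks = {}
    ds = expr([[100, 599, 600, 601]])
    checks["umi_600_keeps_boundary"] = filter_cells_by_umi(ds, 600).n_cells == 2
    ds = expr([[99, 100, 101]])
    checks["umi_100_keeps_boundary"] = filter_cells_by_umi(ds, 100).n_cells == 2
    ds = expr([[1, 1, 1]], doublet_score=[0.1, 0.4, 0.41])
    checks["doublet_04_strictly_above_removed"] = filter_doublets(ds, 0.4).n_cells == 2
    counts = np.zeros((1, 10), dtype=int)
    counts[0, 0] = 3
    ds = expr(np.vstack([counts, np.ones((1, 10), int)]))
    nm = normalize_depth(ds)
    kept = filter_expressed(nm, ds.cell_meta["cell_type"], "t", min_fraction=0.10)
    checks["expression_10pct_inclusive"] = "g0" in kept
    # pseudo-bulk 10-cell minimum: 9 cells excluded, 10 kept
    ds = expr(np.ones((2, 19), dtype=int),
              cell_type=["t"] * 19)
    ds.cell_meta.loc[:8, "sample_id"] = "small"
    ds.cell_meta.loc[9:, "sample_id"] = "big"
    profiles = pseudobulk(ds, ds.cell_meta["sample_id"], "t")
    surviving = {u for u, p in profiles.items() if p.n >= 10}
    checks["pseudobulk_min_10_cells"] = surviving == {"big"}
    return {k: bool(v) for k, v in checks.items()}
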