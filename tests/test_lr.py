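import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tmekit.io import LRTable, normalize_depth
from tmekit.lr import (
    filter_expressed,
    lr_score_dissociated,
    lr_score_spatial,
    permute_dissociated,
    permute_spatial,
    run_lr_screen,
)
from tmekit.spatial import SpatialGraph, build_knn_graph
from tmekit.simulate import PlantedLR, PuckLayout, simulate_profiles, simulate_puck

import scipy.sparse as sp

from conftest import make_expression, make_spatial


def spatial_score_double_loop(expr_l, expr_r, w, in_a, in_b):
    """Direct double-loop evaluation of the antisymmetric spatial score."""
    n = len(expr_l)
    s = 0.0
    for i in range(n):
        if not in_a[i]:
            continue
        for j in range(n):
            if in_b[j] and w[i, j]:
                s += expr_l[i] * expr_r[j] * w[i, j]
                s -= expr_r[i] * expr_l[j] * w[i, j]
    return s


def graph_from_edges(n, edges):
    w = np.zeros((n, n))
    for i, j in edges:
        w[i, j] = w[j, i] = 1.0
    return SpatialGraph(weights=sp.csr_matrix(w), k=1)


class TestFilterExpressed:
    def test_exact_ten_percent_kept(self):
        counts = np.zeros((2, 10), dtype=int)
        counts[0, 0] = 5          # gene 0 in exactly 10% of cells
        counts[1, :] = 1
        ds = make_expression(counts, cell_types=["t"] * 10)
        nm = normalize_depth(ds)
        kept = filter_expressed(nm, ds.cell_meta["cell_type"], "t", min_fraction=0.10)
        assert "g0" in kept and "g1" in kept

    def test_undetected_gene_dropped(self):
        ds = make_expression(np.array([[0, 0], [1, 1]]), cell_types=["t", "t"])
        nm = normalize_depth(ds)
        kept = filter_expressed(nm, ds.cell_meta["cell_type"], "t")
        assert "g0" not in kept

    def test_zero_threshold_keeps_all(self):
        ds = make_expression(np.array([[0, 0], [1, 1]]), cell_types=["t", "t"])
        nm = normalize_depth(ds)
        kept = filter_expressed(nm, ds.cell_meta["cell_type"], "t", min_fraction=0.0)
        assert set(kept) == {"g0", "g1"}


class TestDissociatedScore:
    def test_product_of_means(self):
        # senders express ligand at mean 2, receivers receptor at mean 3
        counts = np.array([[2, 2, 0, 0], [0, 0, 3, 3], [8, 8, 7, 7]])
        ds = make_expression(counts, cell_types=["s", "s", "r", "r"])
        nm = normalize_depth(ds, scale_constant=10)
        s = lr_score_dissociated(nm, ds.cell_meta["cell_type"], "g0", "g1", "s", "r")
        assert s == pytest.approx(2.0 * 3.0)

    def test_absent_ligand_scores_zero(self):
        counts = np.array([[0, 0], [5, 5]])
        ds = make_expression(counts, cell_types=["s", "r"])
        nm = normalize_depth(ds, scale_constant=5)
        assert lr_score_dissociated(nm, ds.cell_meta["cell_type"], "g0", "g1", "s", "r") == 0.0

    def test_invariant_to_shuffling_cells_within_type(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 9, size=(4, 20))
        types = np.array(["s"] * 10 + ["r"] * 10, dtype=object)
        ds = make_expression(counts, cell_types=types)
        nm = normalize_depth(ds)
        s1 = lr_score_dissociated(nm, types, "g0", "g1", "s", "r")
        perm = np.concatenate([rng.permutation(10), 10 + rng.permutation(10)])
        ds2 = make_expression(counts[:, perm], cell_types=types[perm])
        nm2 = normalize_depth(ds2)
        s2 = lr_score_dissociated(nm2, types[perm], "g0", "g1", "s", "r")
        assert s1 == pytest.approx(s2)


class TestSpatialScore:
    def test_single_edge_example(self):
        # A = {a1, a2}, B = {b1}; only edge a1-b1; L(a1)=2, R(b1)=3
        counts = np.array([[2, 0, 0], [0, 0, 3]])  # rows: ligand, receptor
        coords = np.array([[0.0, 0], [10, 0], [1, 0]])
        ds = make_spatial(counts, coords, ["A", "A", "B"])
        g = graph_from_edges(3, [(0, 2)])
        nm = normalize_depth(ds, scale_constant=1)
        # normalize to depth 1: values become proportions; rescale manually
        types = ds.bead_meta["cell_type"]
        s = lr_score_spatial(nm, g, types, "g0", "g1", "A", "B")
        assert s == pytest.approx(1.0)  # both beads fully express one gene
        # the score scales with the square of the normalization constant
        nm2 = normalize_depth(ds, scale_constant=6)
        s2 = lr_score_spatial(nm2, g, types, "g0", "g1", "A", "B")
        assert s2 == pytest.approx(36.0)

    def test_identical_ligand_receptor_fields_cancel(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 10, size=(30, 2))
        x = rng.integers(1, 9, size=30)
        counts = np.vstack([x, x])
        ds = make_spatial(counts, coords, ["A"] * 15 + ["B"] * 15)
        g = build_knn_graph(coords, k=4)
        nm = normalize_depth(ds)
        s = lr_score_spatial(nm, g, ds.bead_meta["cell_type"], "g0", "g1", "A", "B")
        assert s == pytest.approx(0.0, abs=1e-9)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=40, deadline=None)
    def test_antisymmetry_under_type_and_gene_swap(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(8, 20)
        coords = rng.uniform(0, 10, size=(n, 2))
        counts = rng.integers(0, 10, size=(2, n)) + 1
        types = rng.choice(["A", "B"], size=n)
        if len(set(types)) < 2:
            types[0], types[1] = "A", "B"
        ds = make_spatial(counts, coords, types)
        g = build_knn_graph(coords, k=3)
        nm = normalize_depth(ds)
        args = (nm, g, ds.bead_meta["cell_type"])
        s = lr_score_spatial(*args, "g0", "g1", "A", "B")
        tol = dict(rel=1e-9, abs=1e-9)
        assert lr_score_spatial(*args, "g1", "g0", "A", "B") == pytest.approx(-s, **tol)
        assert lr_score_spatial(*args, "g0", "g1", "B", "A") == pytest.approx(-s, **tol)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            n = 60
            coords = rng.uniform(0, 30, size=(n, 2))
            counts = rng.integers(0, 12, size=(2, n))
            types = rng.choice(["A", "B", "C"], size=n)
            ds = make_spatial(counts, coords, types)
            g = build_knn_graph(coords, k=5)
            nm = normalize_depth(ds)
            dense = np.asarray(nm.values.todense())
            s_fast = lr_score_spatial(nm, g, types, "g0", "g1", "A", "B")
            s_slow = spatial_score_double_loop(
                dense[0], dense[1], g.weights.toarray(), types == "A", types == "B")
            assert s_fast == pytest.approx(s_slow, rel=1e-9, abs=1e-9)


class TestPermutationTests:
    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 10, size=(3, 40))
        types = np.array(["s"] * 20 + ["r"] * 20, dtype=object)
        ds = make_expression(counts, cell_types=types)
        nm = normalize_depth(ds)
        p1 = permute_dissociated(nm, types, "g0", "g1", "s", "r", n_perm=99, seed=11)
        p2 = permute_dissociated(nm, types, "g0", "g1", "s", "r", n_perm=99, seed=11)
        assert p1 == p2

    def test_constant_expression_gives_p_one(self):
        counts = np.full((2, 30), 4)
        types = np.array(["s"] * 15 + ["r"] * 15, dtype=object)
        ds = make_expression(counts, cell_types=types)
        nm = normalize_depth(ds)
        p = permute_dissociated(nm, types, "g0", "g1", "s", "r", n_perm=99, seed=0)
        assert p == 1.0

    def test_spatial_seed_reproducible(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 20, size=(50, 2))
        counts = rng.integers(0, 10, size=(2, 50))
        types = rng.choice(["A", "B"], size=50)
        ds = make_spatial(counts, coords, types)
        g = build_knn_graph(coords, k=4)
        nm = normalize_depth(ds)
        p1 = permute_spatial(nm, g, types, "g0", "g1", "A", "B", n_perm=99, seed=5)
        p2 = permute_spatial(nm, g, types, "g0", "g1", "A", "B", n_perm=99, seed=5)
        assert p1 == p2
        assert p1 >= 1 / 100


class TestRunScreen:
    def test_empty_table_returns_empty_result(self, profiles3):
        puck, _ = simulate_puck(profiles3, seed=6)
        out = run_lr_screen(puck, LRTable(pd.DataFrame(
            columns=["ligand", "receptor", "pair_id"])), mode="spatial", n_perm=10)
        assert out.empty

    def test_q_monotone_in_p(self, profiles3):
        puck, _ = simulate_puck(profiles3, seed=7)
        genes = list(profiles3.gene_ids[:8])
        tab = LRTable(pd.DataFrame({
            "ligand": genes[:4], "receptor": genes[4:],
            "pair_id": [f"p{i}" for i in range(4)],
        }))
        out = run_lr_screen(puck, tab, mode="spatial", n_perm=49, seed=8)
        srt = out.sort_values("p")
        assert (np.diff(srt["q"]) >= -1e-12).all()

    def test_planted_pairs_rank_top(self):
        n_pairs = 25
        prof = simulate_profiles(2 * n_pairs + 10, 3, n_markers_per_type=3,
                                 marker_fold=4.0, seed=9)
        free = [g for g in prof.gene_ids
                if all(g not in m for m in prof.marker_genes.values())]
        lig, rec = free[:n_pairs], free[n_pairs:2 * n_pairs]
        tab = LRTable(pd.DataFrame({
            "ligand": lig, "receptor": rec,
            "pair_id": [f"p{i}" for i in range(n_pairs)],
        }))
        planted = tuple(PlantedLR(lig[i], rec[i], "type1", "type2", strength=4.0)
                        for i in range(2))
        hits = 0
        for s in range(5):
            puck, _ = simulate_puck(
                prof, layout=PuckLayout(width=400, height=400, spacing=20),
                planted_lr=planted, umi_per_bead=800, seed=100 + s)
            out = run_lr_screen(puck, tab, mode="spatial",
                                type_pairs=[("type1", "type2")], n_perm=199, seed=s)
            top = list(out.head(2)["pair_id"])
            hits += set(top) == {"p0", "p1"}
        assert hits >= 4

    def test_bead_order_invariance(self, profiles3):
        puck, _ = simulate_puck(profiles3, seed=10)
        genes = list(profiles3.gene_ids[:4])
        tab = LRTable(pd.DataFrame({
            "ligand": genes[:2], "receptor": genes[2:], "pair_id": ["p0", "p1"]}))
        rng = np.random.default_rng(11)
        perm = rng.permutation(puck.n_beads)
        puck_perm = puck.subset_beads(perm)
        out1 = run_lr_screen(puck, tab, mode="spatial", n_perm=49, seed=12)
        out2 = run_lr_screen(puck_perm, tab, mode="spatial", n_perm=49, seed=12)
        key = ["pair_id", "sender_type", "receiver_type"]
        m = out1.set_index(key)["score"].sort_index()
        m2 = out2.set_index(key)["score"].sort_index()
        np.testing.assert_allclose(m.to_numpy(), m2.to_numpy(), atol=1e-9)
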