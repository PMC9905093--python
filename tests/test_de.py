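import logging

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from tmekit.de import (
    context_de,
    correct_profile,
    estimate_admixture,
    fraction_de,
    nb_pseudobulk_test,
    pseudobulk,
    tile_units,
)
from tmekit.simulate import (
    PlantedEffect,
    nb_sample,
    simulate_profiles,
    simulate_puck,
    simulate_scrna,
)

from conftest import make_expression, make_spatial


def grid_simplex_oracle(y, P, step=1e-3):
    """Dense simplex grid search (2 contaminants) then local refinement."""
    best, best_w = np.inf, None
    for w1 in np.arange(0, 1 + step, step):
        w2 = 1 - w1
        r = np.linalg.norm(y - P @ np.array([w1, w2]))
        if r < best:
            best, best_w = r, np.array([w1, w2])
    return best_w


class TestPseudobulk:
    def test_exact_column_sums(self):
        ds = make_expression(np.array([[1, 3], [2, 4]]), cell_types=["t", "t"])
        out = pseudobulk(ds, ["u", "u"], "t")
        assert out["u"].counts.tolist() == [4, 6]
        assert out["u"].n == 2

    def test_other_types_ignored(self):
        ds = make_expression(np.array([[1, 100], [2, 100]]), cell_types=["t", "other"])
        out = pseudobulk(ds, ["u", "u"], "t")
        assert out["u"].counts.tolist() == [1, 2]

    def test_empty_unit_omitted_with_warning(self, caplog):
        ds = make_expression(np.array([[1]]), cell_types=["t"])
        with caplog.at_level(logging.WARNING, logger="tmekit"):
            out = pseudobulk(ds, ["u2"], "absent_type")
        assert out == {}
        assert "omitted" in caplog.text

    def test_spatial_restricted_to_confident_beads(self):
        coords = np.array([[0.0, 0], [1, 0], [2, 0]])
        ds = make_spatial(np.array([[5, 7, 100]]), coords, ["t", "t", "t"],
                          annotation=["singlet", "doublet_certain", "reject"])
        out = pseudobulk(ds, ["u", "u", "u"], "t")
        assert out["u"].counts.tolist() == [12]


class TestEstimateAdmixture:
    def _ref(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(60)]
        base = rng.lognormal(1, 0.6, size=60)
        ref = pd.DataFrame({
            "target": base.copy(), "b": base.copy(), "c": base.copy(),
        }, index=genes)
        ref.iloc[:8, 0] *= 9  # distinct marker blocks
        ref.iloc[8:16, 1] *= 9
        ref.iloc[16:24, 2] *= 9
        return ref

    def test_pure_target_gets_weight_one(self):
        ref = self._ref()
        fit = estimate_admixture(ref["target"] * 1000, ref, "target")
        assert fit.weights["target"] == pytest.approx(1.0, abs=1e-8)
        assert fit.weights.drop("target").abs().max() < 1e-8

    def test_noiseless_mixture_recovered_and_matches_grid_oracle(self):
        ref = self._ref()
        P = ref[["target", "b"]].to_numpy()
        P = P / P.sum(axis=0)
        y = 0.7 * P[:, 0] + 0.3 * P[:, 1]
        fit = estimate_admixture(pd.Series(y, index=ref.index), ref[["target", "b"]], "target")
        assert fit.weights["target"] == pytest.approx(0.7, abs=1e-6)
        assert fit.weights["b"] == pytest.approx(0.3, abs=1e-6)
        oracle = grid_simplex_oracle(y, P)
        assert fit.weights["target"] == pytest.approx(oracle[0], abs=2e-3)

    def test_duplicate_contaminant_triggers_ridge_warning(self, caplog):
        ref = self._ref()
        ref["b2"] = ref["b"]  # exactly collinear
        y = ref["target"] * 0.5 + ref["b"] * 0.5
        with caplog.at_level(logging.WARNING, logger="tmekit"):
            fit = estimate_admixture(y, ref, "target")
        assert fit.ridged
        assert "condition" in caplog.text

    def test_weights_sum_to_one(self):
        ref = self._ref()
        rng = np.random.default_rng(10)
        y = pd.Series(rng.poisson(50 * ref["target"] / ref["target"].sum() + 1.0),
                      index=ref.index, dtype=float)
        fit = estimate_admixture(y, ref, "target")
        assert fit.weights.sum() == pytest.approx(1.0)
        assert (fit.weights >= 0).all()


class TestCorrectProfile:
    def test_zero_contamination_is_identity(self):
        ref = pd.DataFrame({"target": [10.0, 5.0], "b": [1.0, 14.0]}, index=["g0", "g1"])
        y = ref["target"] * 3
        fit = estimate_admixture(y, ref, "target")
        out = correct_profile(y, fit)
        np.testing.assert_array_equal(out.to_numpy(), y.to_numpy())

    def test_floor_at_zero(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(30)]
        base = rng.lognormal(1, 0.5, size=30)
        ref = pd.DataFrame({"target": base.copy(), "b": base.copy()}, index=genes)
        ref.iloc[:5, 1] *= 50  # contaminant markers absent from target
        ref.iloc[5:10, 0] *= 50
        y = pd.Series(np.round(4000 * (0.5 * ref["target"] / ref["target"].sum()
                                       + 0.5 * ref["b"] / ref["b"].sum())), index=genes)
        fit = estimate_admixture(y, ref, "target")
        out = correct_profile(y, fit)
        assert (out >= 0).all()

    def test_noiseless_mixture_correction_recovers_target(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(80)]
        base = rng.lognormal(1.5, 0.5, size=80)
        ref = pd.DataFrame({"target": base.copy(), "b": base.copy()}, index=genes)
        ref.iloc[:10, 0] *= 8
        ref.iloc[10:20, 1] *= 8
        pt = ref["target"] / ref["target"].sum()
        pb = ref["b"] / ref["b"].sum()
        depth = 200_000
        y = pd.Series(np.round(depth * (0.75 * pt + 0.25 * pb)), index=genes)
        fit = estimate_admixture(y, ref, "target")
        out = correct_profile(y, fit)
        expected = depth * 0.75 * pt
        keep = expected >= 10
        np.testing.assert_allclose(out[keep], expected[keep], rtol=0.05)


class TestNbTest:
    def test_pvalues_near_uniform_under_null(self):
        rng = np.random.default_rng(13)
        ps = []
        for _ in range(30):
            base = rng.lognormal(2, 1, size=150)
            mean = np.outer(base, rng.lognormal(0, 0.2, size=8))
            y = nb_sample(rng, mean, 0.2)
            res = nb_pseudobulk_test(pd.DataFrame(y[:, :4]), pd.DataFrame(y[:, 4:]))
            ps.extend(res["p"])
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_q_dominates_p_and_is_monotone(self):
        rng = np.random.default_rng(14)
        base = rng.lognormal(2, 1, size=100)
        y = nb_sample(rng, np.outer(base, np.ones(8) * 2), 0.3)
        res = nb_pseudobulk_test(pd.DataFrame(y[:, :4]), pd.DataFrame(y[:, 4:]))
        assert (res["q"] >= res["p"] - 1e-12).all()
        srt = res.sort_values("p")
        assert (np.diff(srt["q"]) >= -1e-12).all()

    def test_fewer_than_two_replicates_names_tiling_fallback(self):
        df1 = pd.DataFrame({"a": [1, 2]})
        df4 = pd.DataFrame(np.ones((2, 2), int))
        with pytest.raises(ValueError, match="tile_units"):
            nb_pseudobulk_test(df1, df4)


class TestContextDe:
    def test_missing_context_raises(self):
        with pytest.raises(ValueError, match="adjacent_context"):
            context_de({"tumor_context": pd.DataFrame(np.ones((3, 2)))})

    def test_planted_context_effect_recovered_after_correction(self, confound_layout):
        prof = simulate_profiles(400, 3, n_markers_per_type=20, marker_fold=8.0, seed=15)
        rng = np.random.default_rng(16)
        nonmark = [g for g in prof.gene_ids
                   if all(g not in m for m in prof.marker_genes.values())]
        planted = list(rng.choice(nonmark, 40, replace=False))
        effects = tuple(PlantedEffect(g, "type2", "tumor_context", 2.0) for g in planted)
        puck, truth = simulate_puck(prof, layout=confound_layout,
                                    planted_context_de=effects, umi_per_bead=800, seed=17)
        units = tile_units(puck.coords, truth.extras["domain"])
        pb = pseudobulk(puck, units, "type2")
        ref = pd.DataFrame({t: prof.profile(t) for t in prof.type_names},
                           index=prof.gene_ids)
        mats = {}
        for ctx in ("tumor_context", "adjacent_context"):
            mats[ctx] = pd.DataFrame({
                u: correct_profile(p.counts, estimate_admixture(p.counts, ref, "type2"))
                for u, p in pb.items() if u.startswith(ctx)
            })
        res = context_de(mats)
        disc = set(res.index[res["q"] < 0.05])
        assert len(disc & set(planted)) / len(planted) >= 0.8


class TestFractionDe:
    def test_min_cells_boundary_excludes_nine_cell_sample(self, caplog):
        prof = simulate_profiles(50, 2, n_markers_per_type=4, seed=18)
        ds, _ = simulate_scrna(prof, samples_per_fraction=3, cells_per_sample=60,
                               fractions=("tumor", "healthy"), seed=19)
        meta = ds.cell_meta
        # shrink one tumor sample to exactly 9 cells of type1
        sample = "tumor_s1"
        t1 = np.flatnonzero((meta["sample_id"] == sample) & (meta["cell_type"] == "type1"))
        drop = t1[9:]
        keep = np.setdiff1d(np.arange(ds.n_cells), drop)
        ds9 = ds.subset_cells(keep)
        with caplog.at_level(logging.INFO, logger="tmekit"):
            res = fraction_de(ds9, "type1", "tumor", "healthy", min_cells=10)
        assert sample in caplog.text
        assert {"log2fc", "p", "q"} <= set(res.columns)

    def test_too_few_samples_error_lists_excluded(self):
        prof = simulate_profiles(30, 1, n_markers_per_type=2, seed=20)
        ds, _ = simulate_scrna(prof, samples_per_fraction=2, cells_per_sample=5,
                               fractions=("tumor", "healthy"), seed=21)
        with pytest.raises(ValueError, match="excluded"):
            fraction_de(ds, "type1", "tumor", "healthy", min_cells=10)

    def test_planted_fraction_effect_recovered(self):
        prof = simulate_profiles(200, 2, n_markers_per_type=10, marker_fold=4.0, seed=22)
        genes = [g for g in prof.gene_ids
                 if all(g not in m for m in prof.marker_genes.values())][:20]
        effects = tuple(PlantedEffect(g, "type1", "tumor", 2.0) for g in genes)
        ds, _ = simulate_scrna(prof, samples_per_fraction=4, cells_per_sample=300,
                               planted_effects=effects,
                               fractions=("tumor", "healthy"), seed=23)
        res = fraction_de(ds, "type1", "tumor", "healthy")
        disc = set(res.index[(res["q"] < 0.05) & (res["log2fc"] > 0)])
        assert len(disc & set(genes)) / len(genes) >= 0.8


class TestTileUnits:
    def test_quadrants_per_context(self):
        rng = np.random.default_rng(24)
        coords = rng.uniform(0, 10, size=(200, 2))
        contexts = np.where(coords[:, 0] < 5, "tumor_context", "adjacent_context")
        units = tile_units(coords, contexts)
        labels = pd.Series(units).dropna()
        assert len(labels.unique()) == 8
        assert all(":" in u for u in labels.unique())

    def test_excluded_beads_get_none(self):
        coords = np.zeros((3, 2))
        units = tile_units(coords, ["excluded", "excluded", "excluded"])
        assert all(u is None for u in units)
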