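# tmekit

Analysis toolkit for tumor-microenvironment studies that combine dissociated
single-cell RNA-seq with near-cellular spatial transcriptomics (Slide-seqV2
style bead arrays). It packages the bespoke computational stages such a study
needs downstream of alignment, integration and bead decomposition:

* **Gene-set signature scoring** — per-cell scores as plain means of
  depth-normalized expression, per-sample scores as means over cells, group
  comparisons by two-sided Wilcoxon rank-sum tests, and inter-individual
  expression distances (1 − Pearson on per-sample mean profiles, averaged
  across cell types).
* **Tumor-signature derivation** — signed rank-sum Z scores for malignant vs
  non-malignant luminal cells, selection of upregulated genes with Z > 3 that
  are detected in fewer than 5% of healthy epithelial cells, malignant-cell
  calls at a signature-score threshold (default 0.1), and ROC-AUC evaluation
  on labeled bulk cohorts.
* **Spatial statistics** — union-symmetrized Euclidean kNN graphs (k = 10),
  Moran's I autocorrelation of cell-type indicators, and automated
  segmentation of a puck into tumor vs tumor-adjacent contexts.
* **Admixture-corrected context DE** — the transcripts captured by a bead are
  contaminated by neighboring cells of other types, so a naive tumor-context
  vs adjacent-context comparison of one cell type rediscovers its neighbors'
  markers. `tmekit` fits each context's pseudo-bulk as a non-negative linear
  mixture of pure cell-type profiles (robust NNLS), subtracts the estimated
  contaminant counts, and tests the corrected pseudo-bulks with a
  negative-binomial Wald test (moment dispersion shrunk toward a common
  value, median-of-ratios effective library sizes, BH-adjusted q-values).
* **Ligand-receptor screening** — for dissociated data, the product of mean
  ligand expression in the sender type and mean receptor expression in the
  receiver type, with a cluster-label permutation null (1,000 rounds); for
  spatial data, the antisymmetric adjacency-coupled score

  ```
  S = Σᵢ∈A Σⱼ∈B  Lexpᵢ · Rexpⱼ · Mᵢⱼ  −  Σᵢ∈A Σⱼ∈B  Rexpᵢ · Lexpⱼ · Mᵢⱼ
  ```

  on the bead kNN graph M, with a bead-label permutation null (2,000
  rounds). The reverse term cancels admixture-driven co-expression; S flips
  sign exactly under swapping the two types or the two genes.
* **Synthetic data with ground truth** — negative-binomial scRNA cohorts,
  bead arrays with proximity-weighted admixture, and bulk mixtures, with
  planted markers, planted context effects, and planted co-localized LR
  pairs recorded in a truth object, so every stage is testable end to end
  without any download.

## Worked example

Simulate a half-tumor puck in which the target type (`type2`) sits next to
tumor cells (`type1`) on one side and `type3` on the other, with a 4-fold
expression shift planted on three genes of `type2` inside the tumor context
only — then segment contexts, correct for admixture and test:

```python
import pandas as pd
from tmekit.simulate import (simulate_profiles, simulate_puck, Domain,
                             PuckLayout, PlantedEffect)
from tmekit.spatial import build_knn_graph, segment_contexts
from tmekit.de import (tile_units, pseudobulk, estimate_admixture,
                       correct_profile, context_de)

profiles = simulate_profiles(n_genes=400, n_types=3, n_markers_per_type=20,
                             marker_fold=8.0, seed=0)
layout = PuckLayout(domains=[
    Domain("tumor_context", (0.0, 0.5), {"type1": 0.7, "type2": 0.3}),
    Domain("adjacent_context", (0.5, 1.0), {"type3": 0.7, "type2": 0.3}),
])
planted = tuple(PlantedEffect(g, "type2", "tumor_context", 2.0)
                for g in ["g0005", "g0017", "g0042"])
puck, truth = simulate_puck(profiles, layout=layout,
                            planted_context_de=planted,
                            umi_per_bead=800, seed=1)

graph = build_knn_graph(puck.coords, k=10)
contexts = segment_contexts(puck, graph, tumor_type_label="type1")
units = tile_units(puck.coords, contexts.to_numpy())
reference = pd.DataFrame({t: profiles.profile(t) for t in profiles.type_names},
                         index=profiles.gene_ids)
mats = {}
for ctx in ("tumor_context", "adjacent_context"):
    cols = {}
    for unit, prof in pseudobulk(puck, units, "type2").items():
        if unit.startswith(ctx):
            fit = estimate_admixture(prof.counts, reference, "type2")
            cols[unit] = correct_profile(prof.counts, fit)
    mats[ctx] = pd.DataFrame(cols)
result = context_de(mats)
print(result.sort_values("q").head(5)[["log2fc", "p", "q"]].round(4))
```

Output:

```
       log2fc       p       q
g0042  1.7730  0.0000  0.0000
g0005  1.6681  0.0000  0.0000
g0017  1.5485  0.0000  0.0000
g0276  0.6221  0.0031  0.3138
g0309 -0.6299  0.0043  0.3454
```

The three planted genes top the list at q ≈ 0 with log₂ fold changes near
the planted value of 2 (attenuated by the bead admixture); the first
unplanted gene is far from significance. The admixture fit itself reports
interpretable mixing weights — for an adjacent-context tile of `type2`
beads it estimates `{'type1': 0.0, 'type2': 0.802, 'type3': 0.198}`,
matching the simulated 0.7 self-weight plus same-type neighbors. Running
the same comparison **without** `correct_profile` floods the result list
with `type1` marker genes: that contrast is the reason the correction
exists.

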