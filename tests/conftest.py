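import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from tmekit.io import ExpressionDataset, SpatialDataset
from tmekit.simulate import Domain, PuckLayout, simulate_profiles


def make_expression(counts, sample_ids=None, fractions=None, cell_types=None,
                    doublet_scores=None, gene_ids=None):
    """Small dense-count ExpressionDataset builder for fixtures."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    meta = pd.DataFrame({
        "sample_id": sample_ids if sample_ids is not None else ["s1"] * n_cells,
        "fraction": fractions if fractions is not None else ["tumor"] * n_cells,
        "cell_type": cell_types if cell_types is not None else ["typeA"] * n_cells,
    })
    if doublet_scores is not None:
        meta["doublet_score"] = doublet_scores
    return ExpressionDataset(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids if gene_ids is not None else np.array(
            [f"g{i}" for i in range(n_genes)], dtype=object),
        cell_meta=meta,
    )


def make_spatial(counts, coords, cell_types, annotation=None, gene_ids=None):
    counts = np.asarray(counts)
    n_genes, n_beads = counts.shape
    meta = pd.DataFrame({
        "cell_type": cell_types,
        "annotation_class": annotation if annotation is not None else ["singlet"] * n_beads,
    })
    return SpatialDataset(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids if gene_ids is not None else np.array(
            [f"g{i}" for i in range(n_genes)], dtype=object),
        coords=np.asarray(coords, float),
        bead_meta=meta,
    )


@pytest.fixture(scope="session")
def profiles3():
    """Three cell types, 120 genes, clear markers."""
    return simulate_profiles(120, 3, n_markers_per_type=10, marker_fold=8.0, seed=7)


@pytest.fixture(scope="session")
def confound_layout():
    """Half-plane puck: tumor-type neighbors on the left, another type on the right;
    the target type present on both sides at the same proportion."""
    return PuckLayout(domains=[
        Domain("tumor_context", (0.0, 0.5), {"type1": 0.7, "type2": 0.3}),
        Domain("adjacent_context", (0.5, 1.0), {"type3": 0.7, "type2": 0.3}),
    ])


from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")
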