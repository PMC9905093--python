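"""Data model, file I/O, QC filters and depth normalization.

Counts are stored genes x cells (genes as matrix rows, the CellRanger MTX
convention) in sparse CSR form. Metadata travels as a pandas DataFrame with
one row per cell or bead. All on-disk formats are plain text: Matrix Market
for counts, TSV for gene lists / metadata / coordinates, GMT for gene sets.

TSV dialect: UTF-8, header row required, tab-separated without quoting —
a tab inside an identifier is an error, not an escape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("tmekit")

FRACTIONS = ("healthy", "adj_normal", "tumor")
ANNOTATION_CLASSES = ("singlet", "doublet_certain", "reject")

#: beads in these confidence classes enter every spatial analysis
CONFIDENT_CLASSES = ("singlet", "doublet_certain")


class DimensionMismatchError(ValueError):
    """Raised when matrix dimensions disagree with id/metadata lengths."""


def _as_int_csr(counts) -> sp.csr_matrix:
    m = sp.csr_matrix(counts)
    if m.nnz and not np.allclose(m.data, np.round(m.data)):
        raise ValueError("counts must be integers")
    if m.nnz and m.data.min() < 0:
        raise ValueError("counts must be non-negative")
    m.data = np.asarray(np.round(m.data), dtype=np.int64)
    m.eliminate_zeros()
    return m


def _check_unique(ids, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what} must be unique")
    return ids


@dataclass
class ExpressionDataset:
    """Sparse gene x cell counts with per-cell metadata.

    ``cell_meta`` requires columns ``sample_id``, ``fraction`` (one of
    healthy / adj_normal / tumor) and ``cell_type``; ``subtype``,
    ``malignant`` and ``doublet_score`` are optional.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self):
        self.counts = _as_int_csr(self.counts)
        self.gene_ids = _check_unique(self.gene_ids, "gene_ids")
        if self.counts.shape[0] != len(self.gene_ids):
            raise DimensionMismatchError(
                f"{self.counts.shape[0]} matrix rows but {len(self.gene_ids)} gene ids"
            )
        if self.counts.shape[1] != len(self.cell_meta):
            raise DimensionMismatchError(
                f"{self.counts.shape[1]} matrix columns but "
                f"{len(self.cell_meta)} metadata rows"
            )
        for col in ("sample_id", "fraction", "cell_type"):
            if col not in self.cell_meta.columns:
                raise ValueError(f"cell_meta lacks required column {col!r}")
        bad = set(self.cell_meta["fraction"]) - set(FRACTIONS)
        if bad:
            raise ValueError(f"unknown fraction values: {sorted(bad)}")
        self.cell_meta = self.cell_meta.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask_or_idx) -> "ExpressionDataset":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionDataset(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            cell_meta=self.cell_meta.iloc[idx].reset_index(drop=True),
        )


@dataclass
class NormalizedMatrix:
    """Depth-normalized expression: each nonzero column sums to ``scale_constant``."""

    values: sp.csr_matrix
    gene_ids: np.ndarray
    scale_constant: float
    log1p: bool = False

    def gene_index(self, genes) -> np.ndarray:
        lut = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lut[g] for g in genes], dtype=int)


@dataclass
class SpatialDataset:
    """Gene x bead counts with 2-D micron coordinates and per-bead cell-type calls."""

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    coords: np.ndarray  # (n_beads, 2) float microns
    bead_meta: pd.DataFrame  # columns: cell_type, annotation_class

    def __post_init__(self):
        self.counts = _as_int_csr(self.counts)
        self.gene_ids = _check_unique(self.gene_ids, "gene_ids")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.counts.shape[0] != len(self.gene_ids):
            raise DimensionMismatchError("gene ids do not match matrix rows")
        n = self.counts.shape[1]
        if self.coords.shape != (n, 2):
            raise DimensionMismatchError("coords must be (n_beads, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if len(self.bead_meta) != n:
            raise DimensionMismatchError("bead_meta length does not match beads")
        for col in ("cell_type", "annotation_class"):
            if col not in self.bead_meta.columns:
                raise ValueError(f"bead_meta lacks required column {col!r}")
        bad = set(self.bead_meta["annotation_class"]) - set(ANNOTATION_CLASSES)
        if bad:
            raise ValueError(f"unknown annotation classes: {sorted(bad)}")
        self.bead_meta = self.bead_meta.reset_index(drop=True)

    @property
    def n_beads(self) -> int:
        return self.counts.shape[1]

    def confident_mask(self) -> np.ndarray:
        """Boolean mask of singlet / doublet-certain beads."""
        return self.bead_meta["annotation_class"].isin(CONFIDENT_CLASSES).to_numpy()

    def subset_beads(self, mask_or_idx) -> "SpatialDataset":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpatialDataset(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            coords=self.coords[idx],
            bead_meta=self.bead_meta.iloc[idx].reset_index(drop=True),
        )


@dataclass
class GeneSet:
    name: str
    genes: list = field(default_factory=list)

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate genes")


@dataclass
class LRTable:
    """Ligand-receptor pair table with unique pair ids."""

    table: pd.DataFrame  # columns ligand, receptor, pair_id

    def __post_init__(self):
        for col in ("ligand", "receptor", "pair_id"):
            if col not in self.table.columns:
                raise ValueError(f"LR table lacks column {col!r}")
        if self.table["pair_id"].duplicated().any():
            raise ValueError("pair_id values must be unique")
        if (self.table[["ligand", "receptor"]] == "").any().any():
            raise ValueError("ligand/receptor gene names must be non-empty")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# file I/O


def _check_no_tabs(ids, what: str) -> None:
    for x in ids:
        if "\t" in str(x):
            raise ValueError(f"{what} {x!r} contains a tab; tabs in ids are not allowed")


def read_expression(matrix_path, genes_path, meta_path) -> ExpressionDataset:
    """Read an expression dataset from MTX counts + gene and cell-metadata TSVs."""
    counts = scipy.io.mmread(str(matrix_path))
    genes = pd.read_csv(genes_path, sep="\t")
    if "gene_id" not in genes.columns:
        raise ValueError(f"{genes_path}: gene TSV must have a 'gene_id' column")
    meta = pd.read_csv(meta_path, sep="\t")
    if counts.shape[0] != len(genes):
        raise DimensionMismatchError(
            f"{matrix_path}: {counts.shape[0]} rows but {genes_path} has {len(genes)} genes"
        )
    if counts.shape[1] != len(meta):
        raise DimensionMismatchError(
            f"{matrix_path}: {counts.shape[1]} columns but {meta_path} has {len(meta)} rows"
        )
    return ExpressionDataset(counts=counts, gene_ids=genes["gene_id"].to_numpy(), cell_meta=meta)


def write_expression(dataset: ExpressionDataset, out_dir) -> dict:
    """Write dataset as matrix.mtx + genes.tsv + cells.tsv; lossless for counts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _check_no_tabs(dataset.gene_ids, "gene id")
    for col in dataset.cell_meta.columns:
        if dataset.cell_meta[col].dtype == object:
            _check_no_tabs(dataset.cell_meta[col].dropna(), f"metadata value in {col!r}")
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.tsv",
        "cells": out / "cells.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(dataset.counts), field="integer")
    pd.DataFrame({"gene_id": dataset.gene_ids}).to_csv(paths["genes"], sep="\t", index=False)
    dataset.cell_meta.to_csv(paths["cells"], sep="\t", index=False)
    return paths


def read_spatial(matrix_path, genes_path, beads_path) -> SpatialDataset:
    """Read a puck: MTX counts + gene TSV + bead TSV (x, y, cell_type, annotation_class)."""
    counts = scipy.io.mmread(str(matrix_path))
    genes = pd.read_csv(genes_path, sep="\t")
    beads = pd.read_csv(beads_path, sep="\t")
    for col in ("x", "y", "cell_type", "annotation_class"):
        if col not in beads.columns:
            raise ValueError(f"{beads_path}: bead TSV lacks column {col!r}")
    if counts.shape[0] != len(genes):
        raise DimensionMismatchError(f"{matrix_path}: gene count mismatch with {genes_path}")
    if counts.shape[1] != len(beads):
        raise DimensionMismatchError(f"{matrix_path}: bead count mismatch with {beads_path}")
    return SpatialDataset(
        counts=counts,
        gene_ids=genes["gene_id"].to_numpy(),
        coords=beads[["x", "y"]].to_numpy(float),
        bead_meta=beads.drop(columns=["x", "y"]),
    )


def write_spatial(dataset: SpatialDataset, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _check_no_tabs(dataset.gene_ids, "gene id")
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.tsv",
        "beads": out / "beads.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(dataset.counts), field="integer")
    pd.DataFrame({"gene_id": dataset.gene_ids}).to_csv(paths["genes"], sep="\t", index=False)
    beads = dataset.bead_meta.copy()
    beads.insert(0, "x", dataset.coords[:, 0])
    beads.insert(1, "y", dataset.coords[:, 1])
    beads.to_csv(paths["beads"], sep="\t", index=False)
    return paths


def read_gene_sets(gmt_path) -> list:
    """Parse a GMT file: name, description, then genes, tab-separated.

    Duplicate genes within a line are dropped with a warning; a line with
    fewer than three fields is a parse error.
    """
    sets = []
    with open(gmt_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{gmt_path}:{lineno}: GMT line has fewer than 3 fields")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            uniq = list(dict.fromkeys(genes))
            if len(uniq) < len(genes):
                dropped = len(genes) - len(uniq)
                logger.warning(
                    "gene set %r: dropped %d duplicate gene(s)", name, dropped
                )
            sets.append(GeneSet(name=name, genes=uniq))
    return sets


def write_gene_sets(sets, gmt_path, description: str = "tmekit") -> None:
    with open(gmt_path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *s.genes]) + "\n")


def read_lr_table(tsv_path) -> LRTable:
    """Read a ligand-receptor pair table (TSV: ligand, receptor, pair_id)."""
    return LRTable(pd.read_csv(tsv_path, sep="\t"))


# ---------------------------------------------------------------------------
# QC filters and normalization


def filter_cells_by_umi(dataset, min_umi: int):
    """Keep cells/beads with total counts >= ``min_umi``.

    The convention matches the usual QC wording 'removed cells with less
    than N total UMI': the boundary value N itself is kept. Works on both
    ExpressionDataset (default threshold 600 in the scRNA pipeline) and
    SpatialDataset (100 per bead).
    """
    if min_umi < 0:
        raise ValueError("min_umi must be >= 0")
    totals = np.asarray(dataset.counts.sum(axis=0)).ravel()
    keep = totals >= min_umi
    if not keep.any():
        logger.warning("filter_cells_by_umi: no cells pass min_umi=%d", min_umi)
    return dataset.subset_cells(keep) if isinstance(dataset, ExpressionDataset) else dataset.subset_beads(keep)


def filter_doublets(dataset: ExpressionDataset, max_score: float = 0.4) -> ExpressionDataset:
    """Remove cells whose doublet score is strictly above ``max_score``."""
    if "doublet_score" not in dataset.cell_meta.columns or dataset.cell_meta["doublet_score"].isna().any():
        raise ValueError(
            "doublet_score missing for some cells; skip this filter if scores are unavailable"
        )
    scores = dataset.cell_meta["doublet_score"].to_numpy(float)
    return dataset.subset_cells(scores <= max_score)


def normalize_depth(dataset, scale_constant: float = 1e4, log1p: bool = False) -> NormalizedMatrix:
    """Scale each cell column so its total equals ``scale_constant``.

    Zero-depth columns are left at zero with a warning. With ``log1p=True``
    the scaled values are additionally log1p-transformed (off by default;
    downstream signature averages and LR product scores are defined on
    linear expression magnitudes).
    """
    if scale_constant <= 0:
        raise ValueError("scale_constant must be > 0")
    totals = np.asarray(dataset.counts.sum(axis=0)).ravel().astype(float)
    zero = totals == 0
    if zero.any():
        logger.warning("normalize_depth: %d zero-depth column(s) left at zero", zero.sum())
    inv = np.zeros_like(totals)
    inv[~zero] = scale_constant / totals[~zero]
    values = sp.csr_matrix(sp.csr_matrix(dataset.counts, dtype=float).multiply(inv[None, :]))
    if log1p:
        values.data = np.log1p(values.data)
    return NormalizedMatrix(
        values=values, gene_ids=np.asarray(dataset.gene_ids, dtype=object),
        scale_constant=float(scale_constant), log1p=log1p,
    )
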