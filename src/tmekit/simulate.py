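"""Synthetic scRNA-seq, spatial-puck and bulk cohorts with known ground truth.

Counts are negative-binomial with mean ``m`` and dispersion ``phi``
(variance ``m + phi * m**2``; ``phi = 0`` degenerates to Poisson). The puck
generator emulates near-cellular spatial beads: each bead carries one
dominant cell type plus proximity-weighted admixture from neighboring
beads of other types — the central confounder the admixture-corrected DE
is designed to remove. Planted effects (marker genes, fraction- or
context-restricted fold changes, spatially co-localized ligand-receptor
pairs) are recorded in a :class:`SimulationTruth` so recovery can be
checked exactly.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from tmekit.io import ExpressionDataset, SpatialDataset

FRACTIONS = ("healthy", "adj_normal", "tumor")


@dataclass
class CellTypeProfileSet:
    """Per-type mean expression vectors with marker assignments and NB dispersion."""

    gene_ids: np.ndarray
    type_names: list
    means: np.ndarray  # (n_types, n_genes), non-negative
    dispersion: np.ndarray  # (n_genes,) phi >= 0
    marker_genes: dict  # type -> list of gene ids

    def __post_init__(self):
        self.means = np.asarray(self.means, float)
        self.dispersion = np.asarray(self.dispersion, float)
        if (self.means < 0).any():
            raise ValueError("profile means must be non-negative")
        if (self.dispersion < 0).any():
            raise ValueError("dispersion must be >= 0")
        assigned = [g for gs in self.marker_genes.values() for g in gs]
        if len(set(assigned)) != len(assigned):
            raise ValueError("each marker gene must belong to exactly one type")

    def type_index(self, name: str) -> int:
        return self.type_names.index(name)

    def profile(self, name: str) -> np.ndarray:
        return self.means[self.type_index(name)]

    def gene_index(self, gene: str) -> int:
        return int(np.flatnonzero(self.gene_ids == gene)[0])


@dataclass
class PlantedEffect:
    """A fold change planted on one gene of one cell type in one group.

    ``group`` is a fraction name for scRNA simulations or a domain/context
    name for puck simulations.
    """

    gene: str
    cell_type: str
    group: str
    log2fc: float


@dataclass
class PlantedLR:
    """A spatially co-localized ligand-receptor pair.

    ``strength`` is the fold applied to ligand expression in sender-type
    beads that have a receiver-type bead within the admixture kernel
    bandwidth, and to receptor expression in those receivers.
    """

    ligand: str
    receptor: str
    sender_type: str
    receiver_type: str
    strength: float = 4.0


@dataclass
class SimulationTruth:
    planted_de: list = field(default_factory=list)
    admixture_weights: pd.DataFrame | None = None
    planted_lr: list = field(default_factory=list)
    seed: int = 0
    extras: dict = field(default_factory=dict)


def nb_sample(rng: np.random.Generator, mean, phi):
    """Draw NB(mean, phi) counts; phi=0 gives Poisson(mean)."""
    mean = np.asarray(mean, float)
    phi = np.broadcast_to(np.asarray(phi, float), mean.shape)
    lam = np.array(mean, float)
    over = phi > 0
    if over.any():
        # gamma(shape=1/phi, scale=mean*phi) has mean `mean`, var phi*mean^2
        lam[over] = rng.gamma(1.0 / phi[over], mean[over] * phi[over])
    return rng.poisson(lam)


def simulate_profiles(
    n_genes: int,
    n_types: int,
    n_markers_per_type: int = 10,
    marker_fold: float = 8.0,
    base_mean: float = 5.0,
    dispersion: float = 0.3,
    gene_mean_sd: float = 0.5,
    marker_background: float = 1.0,
    seed: int = 0,
) -> CellTypeProfileSet:
    """Build per-type mean profiles with disjoint planted marker genes.

    Every gene gets a lognormal baseline abundance shared across types;
    each type's markers are that baseline times ``marker_fold`` in the
    owning type only, so ``marker_fold=1`` makes all types identical.
    ``marker_background`` scales marker expression in NON-owning types
    (1 = markers merely enriched; ~0 = markers near-silent elsewhere,
    the regime a healthy-tissue exclusion filter expects).
    """
    if n_markers_per_type * n_types > n_genes:
        raise ValueError("more requested markers than genes")
    if marker_fold < 1:
        raise ValueError("marker_fold must be >= 1")
    rng = np.random.default_rng(seed)
    gene_ids = np.array([f"g{i:04d}" for i in range(n_genes)], dtype=object)
    type_names = [f"type{t + 1}" for t in range(n_types)]
    base = base_mean * rng.lognormal(0.0, gene_mean_sd, size=n_genes)
    means = np.tile(base, (n_types, 1))
    marker_idx = rng.choice(n_genes, size=n_markers_per_type * n_types, replace=False)
    marker_genes = {}
    for t, name in enumerate(type_names):
        idx = marker_idx[t * n_markers_per_type : (t + 1) * n_markers_per_type]
        others = [o for o in range(n_types) if o != t]
        means[np.ix_(others, idx)] *= marker_background
        means[t, idx] *= marker_fold
        marker_genes[name] = list(gene_ids[idx])
    phi = np.full(n_genes, float(dispersion))
    return CellTypeProfileSet(
        gene_ids=gene_ids, type_names=type_names, means=means,
        dispersion=phi, marker_genes=marker_genes,
    )


def _effect_folds(profiles, planted_effects, cell_type, group) -> np.ndarray:
    """Multiplicative fold vector for one (type, group) from planted effects."""
    folds = np.ones(len(profiles.gene_ids))
    for eff in planted_effects:
        if eff.cell_type == cell_type and eff.group == group:
            folds[profiles.gene_index(eff.gene)] *= 2.0 ** eff.log2fc
    return folds


def simulate_scrna(
    profiles: CellTypeProfileSet,
    samples_per_fraction: int = 4,
    cells_per_sample: int = 200,
    library_size_lognormal: tuple = (np.log(2000.0), 0.3),
    planted_effects: tuple = (),
    composition: dict | None = None,
    sample_effect_sd=0.0,
    malignant_types: tuple = (),
    fractions: tuple = FRACTIONS,
    seed: int = 0,
) -> tuple[ExpressionDataset, SimulationTruth]:
    """Simulate a multi-sample scRNA-seq cohort across tissue fractions.

    ``sample_effect_sd`` adds per-(sample, gene) lognormal random effects
    and may be a float or a per-fraction dict, so inter-individual
    variability can differ between tumor and healthy samples.
    ``composition`` maps cell type -> probability (uniform by default), or
    fraction -> {cell type: probability} when the mix differs between
    fractions (e.g. no malignant cells in healthy tissue).
    """
    for eff in planted_effects:
        if eff.group not in FRACTIONS:
            raise ValueError(f"unknown fraction {eff.group!r} in planted effect")
        if eff.cell_type not in profiles.type_names:
            raise ValueError(f"unknown cell type {eff.cell_type!r} in planted effect")
    rng = np.random.default_rng(seed)
    types = profiles.type_names

    def comp_for(fraction):
        comp = composition
        if comp is not None and any(isinstance(v, dict) for v in comp.values()):
            comp = comp.get(fraction)
        if comp is None:
            return np.full(len(types), 1.0 / len(types))
        v = np.array([comp.get(t, 0.0) for t in types], float)
        return v / v.sum()

    mu_ln, sd_ln = library_size_lognormal

    blocks, meta_rows = [], []
    for fraction in fractions:
        sd = sample_effect_sd.get(fraction, 0.0) if isinstance(sample_effect_sd, dict) else float(sample_effect_sd)
        for s in range(samples_per_fraction):
            sample_id = f"{fraction}_s{s + 1}"
            sample_eff = rng.lognormal(0.0, sd, size=len(profiles.gene_ids)) if sd > 0 else 1.0
            t_idx = rng.choice(len(types), size=cells_per_sample, p=comp_for(fraction))
            depths = rng.lognormal(mu_ln, sd_ln, size=cells_per_sample)
            folds = np.stack([
                _effect_folds(profiles, planted_effects, t, fraction) for t in types
            ])
            adj = profiles.means * folds * sample_eff  # (n_types, n_genes)
            # scale by the unmodified profile total: planted up-regulation adds
            # transcripts (inflating the cell's library) instead of compressing
            # every other gene
            props = adj / (profiles.means * sample_eff).sum(axis=1, keepdims=True)
            mean = depths[:, None] * props[t_idx]  # (cells, genes)
            counts = nb_sample(rng, mean, profiles.dispersion[None, :])
            blocks.append(sp.csr_matrix(counts.T))
            for j, ti in enumerate(t_idx):
                meta_rows.append({
                    "sample_id": sample_id,
                    "fraction": fraction,
                    "cell_type": types[ti],
                    "malignant": types[ti] in malignant_types,
                    "doublet_score": float(rng.beta(1.5, 12.0)),
                })
    dataset = ExpressionDataset(
        counts=sp.hstack(blocks, format="csr"),
        gene_ids=profiles.gene_ids,
        cell_meta=pd.DataFrame(meta_rows),
    )
    truth = SimulationTruth(planted_de=list(planted_effects), seed=seed)
    return dataset, truth


# ---------------------------------------------------------------------------
# spatial pucks


@dataclass
class Domain:
    """A spatial region defined by an x-interval (as fractions of puck width)."""

    name: str
    x_range: tuple  # (lo, hi) fractions of width, lo inclusive
    composition: dict  # cell type -> probability


@dataclass
class PuckLayout:
    width: float = 600.0  # microns
    height: float = 600.0
    spacing: float = 20.0  # bead pitch
    jitter: float = 0.15  # gaussian jitter as fraction of spacing
    domains: list = field(default_factory=list)
    mode: str = "grid"  # 'grid' (jittered hex) or 'poisson'


@dataclass
class AdmixtureKernel:
    """Gaussian distance kernel, truncated at 3 bandwidths."""

    bandwidth: float = 30.0  # microns
    self_weight: float = 0.7

    def __post_init__(self):
        if not (0 < self.self_weight <= 1):
            raise ValueError("self_weight must be in (0, 1]")


def _bead_positions(layout: PuckLayout, rng) -> np.ndarray:
    if layout.mode == "poisson":
        n = rng.poisson(layout.width * layout.height / layout.spacing ** 2)
        xy = rng.uniform([0, 0], [layout.width, layout.height], size=(n, 2))
        return xy
    dy = layout.spacing * np.sqrt(3) / 2
    rows = np.arange(0, layout.height, dy)
    pts = []
    for r, y in enumerate(rows):
        x0 = (layout.spacing / 2) if r % 2 else 0.0
        xs = np.arange(x0, layout.width, layout.spacing)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    xy = np.vstack(pts)
    xy = xy + rng.normal(0, layout.spacing * layout.jitter, size=xy.shape)
    return np.clip(xy, [0, 0], [layout.width, layout.height])


def simulate_puck(
    profiles: CellTypeProfileSet,
    layout: PuckLayout | None = None,
    admixture: AdmixtureKernel | None = None,
    planted_context_de: tuple = (),
    planted_lr: tuple = (),
    umi_per_bead: float = 500.0,
    umi_sd_ln: float = 0.25,
    doublet_certain_rate: float = 0.05,
    reject_rate: float = 0.0,
    seed: int = 0,
) -> tuple[SpatialDataset, SimulationTruth]:
    """Simulate a spatial bead array (puck) with proximity admixture.

    Each bead gets a dominant cell type drawn from its domain's
    composition; its expected expression is ``self_weight`` times its own
    cell's profile plus the remaining mass spread over neighboring beads'
    profiles with Gaussian distance weights. ``planted_context_de``
    modifies the target type's own profile only inside the named domain;
    ``planted_lr`` boosts ligand/receptor expression in spatially adjacent
    sender/receiver beads. Truth records the realized per-bead admixture
    weights aggregated by cell type.
    """
    rng = np.random.default_rng(seed)
    if layout is None:
        layout = PuckLayout()
    if not layout.domains:
        comp = {t: 1.0 / len(profiles.type_names) for t in profiles.type_names}
        layout.domains = [Domain("all", (0.0, 1.0), comp)]
    if admixture is None:
        admixture = AdmixtureKernel()

    xy = _bead_positions(layout, rng)
    n = len(xy)
    xfrac = xy[:, 0] / layout.width
    domain_idx = np.full(n, -1)
    for d_i, dom in enumerate(layout.domains):
        lo, hi = dom.x_range
        in_dom = (xfrac >= lo) & ((xfrac < hi) | (hi >= 1.0) & (xfrac <= hi))
        domain_idx[in_dom & (domain_idx < 0)] = d_i
    if (domain_idx < 0).any():
        raise ValueError("domains do not cover the puck region")
    for d_i, dom in enumerate(layout.domains):
        if not (domain_idx == d_i).any():
            raise ValueError(f"domain {dom.name!r} contains no beads")

    types = profiles.type_names
    t_idx = np.empty(n, dtype=int)
    for d_i, dom in enumerate(layout.domains):
        members = np.flatnonzero(domain_idx == d_i)
        p = np.array([dom.composition.get(t, 0.0) for t in types], float)
        p = p / p.sum()
        t_idx[members] = rng.choice(len(types), size=len(members), p=p)

    # per-bead own-cell profile: type profile, modified by context effects
    cell_prof = profiles.means[t_idx].copy()  # (n, genes)
    for eff in planted_context_de:
        gi = profiles.gene_index(eff.gene)
        ti = profiles.type_index(eff.cell_type)
        dom_i = [d.name for d in layout.domains].index(eff.group)
        mask = (t_idx == ti) & (domain_idx == dom_i)
        cell_prof[mask, gi] *= 2.0 ** eff.log2fc

    # ligand/receptor boosts on spatially adjacent sender/receiver beads
    dist = cdist(xy, xy)
    lr_masks = []
    for lr in planted_lr:
        s_i, r_i = profiles.type_index(lr.sender_type), profiles.type_index(lr.receiver_type)
        near = (dist <= admixture.bandwidth) & ~np.eye(n, dtype=bool)
        senders = (t_idx == s_i) & (near[:, t_idx == r_i].any(axis=1) if (t_idx == r_i).any() else False)
        adj_to_sender = near[:, senders].any(axis=1) if senders.any() else np.zeros(n, bool)
        receivers = (t_idx == r_i) & adj_to_sender
        cell_prof[senders, profiles.gene_index(lr.ligand)] *= lr.strength
        cell_prof[receivers, profiles.gene_index(lr.receptor)] *= lr.strength
        lr_masks.append({"senders": senders, "receivers": receivers})

    # admixture: Gaussian kernel, truncated at 3 bandwidths, zero self
    h = admixture.bandwidth
    K = np.exp(-0.5 * (dist / h) ** 2)
    K[dist > 3 * h] = 0.0
    np.fill_diagonal(K, 0.0)
    ksum = K.sum(axis=1)
    W = np.zeros((n, n))
    has_nb = ksum > 0
    W[has_nb] = (1.0 - admixture.self_weight) * K[has_nb] / ksum[has_nb, None]
    self_w = np.where(has_nb, admixture.self_weight, 1.0)

    # scale by the unmodified type-profile total so planted effects and LR
    # boosts add transcripts rather than compressing all other genes
    base_totals = profiles.means[t_idx].sum(axis=1, keepdims=True)
    props = cell_prof / base_totals
    mixed = self_w[:, None] * props + W @ props

    depths = umi_per_bead * rng.lognormal(0.0, umi_sd_ln, size=n)
    counts = nb_sample(rng, depths[:, None] * mixed, profiles.dispersion[None, :])

    # truth admixture weights aggregated by contributing cell type
    onehot = np.zeros((n, len(types)))
    onehot[np.arange(n), t_idx] = 1.0
    wtype = W @ onehot
    wtype[np.arange(n), t_idx] += self_w
    truth_w = pd.DataFrame(wtype, columns=types)

    ann = rng.choice(
        ["singlet", "doublet_certain", "reject"], size=n,
        p=[1 - doublet_certain_rate - reject_rate, doublet_certain_rate, reject_rate],
    )
    bead_meta = pd.DataFrame({
        "cell_type": [types[i] for i in t_idx],
        "annotation_class": ann,
        "domain": [layout.domains[i].name for i in domain_idx],
    })
    dataset = SpatialDataset(
        counts=sp.csr_matrix(counts.T), gene_ids=profiles.gene_ids,
        coords=xy, bead_meta=bead_meta,
    )
    truth = SimulationTruth(
        planted_de=list(planted_context_de), admixture_weights=truth_w,
        planted_lr=list(planted_lr), seed=seed,
        extras={"domain": bead_meta["domain"].to_numpy(),
                "dominant_type": bead_meta["cell_type"].to_numpy(),
                "lr_masks": lr_masks,
                "expected_proportions": mixed},
    )
    return dataset, truth


def simulate_bulk_cohort(
    profiles: CellTypeProfileSet,
    n_tumor: int = 20,
    n_normal: int = 20,
    composition_tumor: dict | None = None,
    composition_normal: dict | None = None,
    noise_sd: float = 0.2,
    scale: float = 1e4,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, SimulationTruth]:
    """Simulate bulk tumor/normal cohorts as mixtures of cell-type profiles.

    Each sample is a composition-weighted sum of depth-normalized type
    profiles times per-(gene, sample) lognormal noise of width ``noise_sd``.
    """
    rng = np.random.default_rng(seed)
    types = profiles.type_names

    def comp_vec(comp):
        if comp is None:
            v = np.full(len(types), 1.0 / len(types))
        else:
            v = np.array([comp.get(t, 0.0) for t in types], float)
        if abs(v.sum() - 1.0) > 1e-8:
            raise ValueError("composition must sum to 1")
        return v

    ct, cn = comp_vec(composition_tumor), comp_vec(composition_normal)
    props = profiles.means / profiles.means.sum(axis=1, keepdims=True) * scale
    cols, labels = [], []
    for label, comp, n_s in (("tumor", ct, n_tumor), ("normal", cn, n_normal)):
        base = comp @ props  # (genes,)
        for s in range(n_s):
            noise = rng.lognormal(0.0, noise_sd, size=base.shape) if noise_sd > 0 else 1.0
            cols.append(base * noise)
            labels.append(label)
    samples = [f"{lab}_s{i + 1}" for i, lab in enumerate(labels)]
    bulk = pd.DataFrame(np.column_stack(cols), index=profiles.gene_ids, columns=samples)
    truth = SimulationTruth(seed=seed, extras={
        "composition_tumor": ct, "composition_normal": cn,
    })
    return bulk, np.array(labels, dtype=object), truth
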