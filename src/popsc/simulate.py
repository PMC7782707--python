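"""Negative-binomial UMI count simulator with planted ground truth.

Counts follow a gamma-Poisson (NB) law: for gene g in cell c of type t and
condition d, y ~ NB(mean = baseline_g * type_effect_gt * condition_effect_gtd
* library_factor_c, dispersion phi_g). The generator emulates the structure
of a two-condition (control vs POP) droplet study: several samples per
condition, multiple cell types with condition-dependent proportions,
long-tailed per-gene baseline expression, per-gene dispersions, log-normal
library sizes, mitochondrial genes at a target count fraction, and planted
effects - cell-type markers, condition-specific DEGs, elevated
ligand-receptor pairs, and cells engineered to violate specific QC rules.
Every planted feature is recorded in a ground-truth ledger for recovery
tests. All output is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from popsc.config import CONDITIONS, CONTROL, POP
from popsc.matrix import UmiMatrix, is_mito_symbol


class PlantedDeg(NamedTuple):
    gene: str
    cell_type: str
    log2fc: float  # POP vs control effect within that cell type


class PlantedLR(NamedTuple):
    ligand: str
    receptor: str
    sender: str
    receiver: str
    condition: str  # condition in which the pair is elevated ("POP"/"control"/"both")
    factor: float  # elevation of ligand in sender and receptor in receiver


DEFAULT_CELL_TYPES = ("epithelial", "fibroblast", "smooth_muscle", "endothelial", "macrophage")

# Condition-dependent composition: epithelial expands and smooth muscle
# shrinks in POP while fibroblasts and macrophages stay similar, mirroring
# the qualitative composition shifts seen in prolapsed vaginal-wall tissue.
DEFAULT_PROPORTIONS = {
    CONTROL: (0.10, 0.45, 0.25, 0.10, 0.10),
    POP: (0.22, 0.45, 0.13, 0.10, 0.10),
}

DEFAULT_PLANTED_DEGS = tuple(
    PlantedDeg(f"G{100 + i:04d}", "fibroblast", 1.5 if i < 10 else -1.5) for i in range(20)
)

DEFAULT_PLANTED_LR = (
    PlantedLR("TGFB1", "TGFBR2", "smooth_muscle", "fibroblast", POP, 4.0),
    PlantedLR("IL1B", "IL1R1", "macrophage", "smooth_muscle", POP, 4.0),
)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic dataset.

    The defaults form the desk-scale preset: 1,500 genes, 5 cell types,
    3 control + 3 POP samples of 400 cells each, long-tailed baselines scaled
    to ~4,000 UMIs per cell, per-gene NB dispersions around 0.2, log-normal
    library factors (sigma 0.3), 10 mitochondrial genes at a 5% count
    fraction, 10 planted markers per type, 20 planted fibroblast DEGs and two
    planted POP-specific ligand-receptor pairs.
    """

    n_genes: int = 1500
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    proportions: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    n_samples: dict[str, int] = field(default_factory=lambda: {CONTROL: 3, POP: 3})
    cells_per_sample: int = 400
    mean_counts_per_cell: float = 4000.0
    baseline_sigma: float = 1.2  # log-normal spread of per-gene baseline means
    dispersion_median: float = 0.2
    dispersion_sigma: float = 0.5
    library_sigma: float = 0.3
    n_mito_genes: int = 10
    mito_fraction: float = 0.05
    markers_per_type: int = 10
    marker_log2fc: float = 3.0
    planted_degs: tuple[PlantedDeg, ...] = DEFAULT_PLANTED_DEGS
    planted_lr: tuple[PlantedLR, ...] = DEFAULT_PLANTED_LR
    qc_outliers: dict[str, int] = field(
        default_factory=lambda: {"low_genes": 10, "high_genes": 0, "high_mito": 10}
    )
    min_plant_baseline: float = 0.5  # floor for planted genes so effects are detectable
    plant_baseline: float | None = None  # exact per-cell baseline for planted DEGs
    extra_gene_symbols: tuple[str, ...] = ()
    rng_seed: int = 0
    # bulk companion parameters
    bulk_mean: float = 50.0
    bulk_dispersion: float | None = 0.2
    bulk_planted_degs: tuple[tuple[str, float], ...] = tuple(
        (f"G{100 + i:04d}", 1.5 if i < 10 else -1.5) for i in range(20)
    )
    bulk_library_sigma: float = 0.2

    def __post_init__(self) -> None:
        for cond, props in self.proportions.items():
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
            if len(props) != len(self.cell_types):
                raise ValueError("proportion vector length must match cell types")
            if abs(sum(props) - 1.0) > 1e-8:
                raise ValueError(f"proportions for {cond!r} must sum to 1")
        for plant in self.planted_degs:
            if plant.cell_type not in self.cell_types:
                raise ValueError(f"planted DEG references unknown cell type {plant.cell_type!r}")
            if not np.isfinite(plant.log2fc):
                raise ValueError("planted effects must be finite")
        for plant in self.planted_lr:
            if plant.sender not in self.cell_types or plant.receiver not in self.cell_types:
                raise ValueError("planted LR pair references unknown cell type")
            if plant.factor <= 1.0:
                raise ValueError("LR elevation factors must exceed 1")
        if self.n_mito_genes >= self.n_genes:
            raise ValueError("n_mito_genes must be < n_genes")


@dataclass
class SyntheticTruth:
    """Ground-truth ledger emitted alongside a synthetic dataset."""

    planted_degs: tuple[PlantedDeg, ...]
    planted_lr: tuple[PlantedLR, ...]
    proportions: dict[str, tuple[float, ...]]
    cell_types: pd.Series  # per-cell true type
    qc_fate: pd.Series  # per-cell intended fate: pass/low_genes/high_genes/high_mito
    marker_genes: dict[str, tuple[str, ...]]
    baseline: pd.Series
    dispersion: pd.Series


def _gene_ids(spec: SimulationSpec) -> list[str]:
    """Regular ids G0000.., custom plant symbols substituted in front,
    mitochondrial genes (MT- prefix) at the end."""
    n_regular = spec.n_genes - spec.n_mito_genes
    ids = [f"G{i:04d}" for i in range(n_regular)]
    custom: list[str] = []
    for plant in spec.planted_lr:
        custom.extend([plant.ligand, plant.receptor])
    custom.extend(spec.extra_gene_symbols)
    custom.extend(g for g, *_ in spec.planted_degs if not (g.startswith("G") and g[1:].isdigit()))
    slot = 0
    for name in dict.fromkeys(custom):
        if name in ids:
            continue
        while ids[slot] in custom:
            slot += 1
        ids[slot] = name
        slot += 1
        if slot >= n_regular:
            raise ValueError("too many custom gene symbols for n_genes")
    ids.extend(f"MT-{i + 1}" for i in range(spec.n_mito_genes))
    return ids


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Gamma-Poisson NB draw; phi -> 0 degenerates to Poisson."""
    mean = np.maximum(mean, 0.0)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi < 1e-12
    if np.any(pois):
        out[..., pois] = rng.poisson(mean[..., pois])
    if np.any(~pois):
        shape = 1.0 / phi[~pois]
        lam = rng.gamma(shape, mean[..., ~pois] * phi[~pois])
        out[..., ~pois] = rng.poisson(lam)
    return out


def simulate(spec: SimulationSpec) -> tuple[UmiMatrix, SyntheticTruth]:
    """Draw a synthetic UMI matrix plus its ground-truth ledger."""
    rng = np.random.default_rng(spec.rng_seed)
    gene_ids = _gene_ids(spec)
    G = spec.n_genes
    types = spec.cell_types
    T = len(types)

    baseline = rng.lognormal(0.0, spec.baseline_sigma, G)
    mito_mask = is_mito_symbol(gene_ids)
    # pin mitochondrial genes to the target count fraction, then scale to depth
    non_mito_sum = baseline[~mito_mask].sum()
    target_mito_sum = spec.mito_fraction / (1.0 - spec.mito_fraction) * non_mito_sum
    baseline[mito_mask] *= target_mito_sum / baseline[mito_mask].sum()
    baseline *= spec.mean_counts_per_cell / baseline.sum()

    phi = rng.lognormal(np.log(spec.dispersion_median), spec.dispersion_sigma, G)
    gene_index = pd.Index(gene_ids, name="gene")
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    def _require(gene: str) -> int:
        if gene not in gene_pos:
            raise ValueError(f"planted gene {gene!r} not in the simulated gene set")
        return gene_pos[gene]

    # floor (or pin) planted genes' baselines so their effects are observable
    for plant in spec.planted_degs:
        i = _require(plant.gene)
        if spec.plant_baseline is not None:
            baseline[i] = spec.plant_baseline
        else:
            baseline[i] = max(baseline[i], spec.min_plant_baseline)
    for plant in spec.planted_lr:
        for g in (plant.ligand, plant.receptor):
            i = _require(g)
            baseline[i] = max(baseline[i], spec.min_plant_baseline)

    # per-type marker genes: deterministic picks from unplanted regular genes
    reserved = {p.gene for p in spec.planted_degs}
    for p in spec.planted_lr:
        reserved.update((p.ligand, p.receptor))
    free = [g for g, m in zip(gene_ids, mito_mask) if not m and g not in reserved]
    marker_genes: dict[str, tuple[str, ...]] = {}
    type_effect = np.ones((G, T))
    cursor = 0
    for t, ctype in enumerate(types):
        picks = tuple(free[cursor:cursor + spec.markers_per_type])
        cursor += spec.markers_per_type
        marker_genes[ctype] = picks
        for g in picks:
            i = gene_pos[g]
            baseline[i] = max(baseline[i], spec.min_plant_baseline)
            type_effect[i, t] = 2.0 ** spec.marker_log2fc

    # condition effects per (gene, type, condition)
    cond_effect = {cond: np.ones((G, T)) for cond in CONDITIONS}
    for plant in spec.planted_degs:
        t = types.index(plant.cell_type)
        cond_effect[POP][gene_pos[plant.gene], t] *= 2.0 ** plant.log2fc
    for plant in spec.planted_lr:
        targets = CONDITIONS if plant.condition == "both" else (plant.condition,)
        for cond in targets:
            cond_effect[cond][gene_pos[plant.ligand], types.index(plant.sender)] *= plant.factor
            cond_effect[cond][gene_pos[plant.receptor], types.index(plant.receiver)] *= plant.factor

    # assemble cells sample by sample
    blocks: list[sp.csc_matrix] = []
    cell_ids: list[str] = []
    meta_rows: list[tuple[str, str, str]] = []
    true_types: list[str] = []
    qc_fate: list[str] = []
    mito_rows = np.flatnonzero(mito_mask)

    outlier_plan = [(fate, n) for fate, n in sorted(spec.qc_outliers.items()) if n > 0]
    for fate, _ in outlier_plan:
        if fate not in ("low_genes", "high_genes", "high_mito"):
            raise ValueError(f"unknown QC outlier rule {fate!r}")

    n_samp_total = sum(spec.n_samples.values())
    sample_ordinal = 0
    for cond in CONDITIONS:
        props = np.asarray(spec.proportions[cond], dtype=float)
        for s in range(spec.n_samples.get(cond, 0)):
            sample_id = f"{cond}_s{s + 1}"
            n = spec.cells_per_sample
            type_codes = rng.choice(T, size=n, p=props)
            lib = rng.lognormal(0.0, spec.library_sigma, n)
            fates = ["pass"] * n
            # engineered QC violators, split evenly across samples
            pos = 0
            for fate, total in outlier_plan:
                share = total // n_samp_total + (1 if sample_ordinal < total % n_samp_total else 0)
                for _ in range(min(share, n - pos)):
                    fates[pos] = fate
                    pos += 1
            sample_ordinal += 1
            mean_block = np.empty((n, G))
            for c in range(n):
                t = type_codes[c]
                mu = baseline * type_effect[:, t] * cond_effect[cond][:, t] * lib[c]
                if fates[c] == "low_genes":
                    mu = mu * 0.05  # tiny library -> far below the detected-gene floor
                elif fates[c] == "high_genes":
                    mu = mu * 25.0  # only effective when n_genes exceeds max_genes
                elif fates[c] == "high_mito":
                    mu = mu.copy()
                    mu[mito_rows] *= 8.0  # ~30% mito fraction, well over the cap
                mean_block[c] = mu
            counts = _nb_draw(rng, mean_block, phi)
            blocks.append(sp.csc_matrix(counts.T))
            for c in range(n):
                cell_ids.append(f"{sample_id}_c{c + 1:04d}")
                meta_rows.append((sample_id, cond, types[type_codes[c]]))
                true_types.append(types[type_codes[c]])
                qc_fate.append(fates[c])

    counts = sp.hstack(blocks, format="csr")
    cell_index = pd.Index(cell_ids, name="cell")
    cell_meta = pd.DataFrame(meta_rows, columns=["sample", "condition", "cell_type"],
                             index=cell_index)
    m = UmiMatrix(counts=counts, gene_ids=gene_index, cell_ids=cell_index, cell_meta=cell_meta)
    truth = SyntheticTruth(
        planted_degs=spec.planted_degs,
        planted_lr=spec.planted_lr,
        proportions={c: tuple(spec.proportions[c]) for c in spec.proportions},
        cell_types=pd.Series(true_types, index=cell_index, name="cell_type"),
        qc_fate=pd.Series(qc_fate, index=cell_index, name="qc_fate"),
        marker_genes=marker_genes,
        baseline=pd.Series(baseline, index=gene_index, name="baseline"),
        dispersion=pd.Series(phi, index=gene_index, name="dispersion"),
    )
    return m, truth


def simulate_bulk(
    spec: SimulationSpec, n_replicates: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a bulk gene x replicate NB count table with condition effects.

    ``n_replicates`` applies per condition (>= 2 required). Planted genes
    (``spec.bulk_planted_degs``) take their baseline at ``spec.bulk_mean``
    and their POP columns are scaled by 2**log2fc. Returns (counts table with
    replicate columns named <condition>_r<i>, truth table of planted effects).
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    rng = np.random.default_rng(spec.rng_seed + 1)
    gene_ids = _gene_ids(spec)
    G = spec.n_genes
    baseline = rng.lognormal(np.log(spec.bulk_mean), 1.0, G)
    if spec.bulk_dispersion is None:
        phi = rng.lognormal(np.log(spec.dispersion_median), spec.dispersion_sigma, G)
    else:
        phi = np.full(G, float(spec.bulk_dispersion))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    effect = np.ones(G)
    for gene, log2fc in spec.bulk_planted_degs:
        if gene not in gene_pos:
            raise ValueError(f"planted bulk gene {gene!r} not in the simulated gene set")
        baseline[gene_pos[gene]] = spec.bulk_mean
        effect[gene_pos[gene]] = 2.0 ** log2fc

    cols = {}
    for cond in CONDITIONS:
        mult = effect if cond == POP else np.ones(G)
        for r in range(n_replicates):
            lib = rng.lognormal(0.0, spec.bulk_library_sigma)
            cols[f"{cond}_r{r + 1}"] = _nb_draw(rng, baseline * mult * lib, phi)
    table = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene"))
    truth = pd.DataFrame(
        [(g, fc) for g, fc in spec.bulk_planted_degs], columns=["gene", "log2fc"]
    )
    return table, truth


def bulk_conditions(table: pd.DataFrame) -> np.ndarray:
    """Condition indicator (0 control / 1 POP) from ``simulate_bulk`` column names."""
    return np.array([1.0 if c.startswith(POP) else 0.0 for c in table.columns])
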