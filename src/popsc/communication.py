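"""Permutation-based ligand-receptor cell-cell communication inference.

For every ligand-receptor pair and every ordered (sender, receiver) cell-type
pair, the interaction statistic is the arithmetic mean of the ligand's mean
normalized expression in the sender type and the receptor's mean in the
receiver type. Pairs expressed in fewer than 10% of cells of the relevant
population are filtered out before testing. Significance comes from shuffling
cell-type labels across all cells (one shared shuffle per permutation, reused
for every pair and type pair) with an add-one p-value estimator; conditions
are analyzed separately and compared as interaction graphs whose edge weights
count the significant pairs between each ordered type pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from popsc.config import CONDITIONS, PipelineConfig
from popsc.matrix import NormalizedMatrix

log = logging.getLogger(__name__)

MIN_PERMUTATIONS = 100


class LigandReceptorPair(NamedTuple):
    ligand: str
    receptor: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.ligand}->{self.receptor}"


def _group_means(E: np.ndarray, codes: np.ndarray, n_types: int) -> np.ndarray:
    """Mean expression per gene per type: (G, T). Codes are 0..n_types-1."""
    onehot = np.zeros((codes.size, n_types))
    onehot[np.arange(codes.size), codes] = 1.0
    counts = onehot.sum(axis=0)
    return (E @ onehot) / np.maximum(counts, 1.0)


def expression_fraction(
    nm: NormalizedMatrix, labels: pd.Series, gene: str, cell_type: str
) -> float:
    """Fraction of the type's cells with nonzero normalized expression."""
    labels = pd.Series(np.asarray(labels), index=nm.cell_ids)
    mask = (labels == cell_type).to_numpy()
    if not mask.any():
        raise KeyError(f"unknown cell type {cell_type!r}")
    vec = nm.gene_vector(gene)  # raises KeyError for unknown gene
    return float((vec[mask] > 0).mean())


def interaction_statistic(
    nm: NormalizedMatrix,
    labels: pd.Series,
    pair: LigandReceptorPair,
    sender: str,
    receiver: str,
) -> float:
    """(mean ligand expression in sender + mean receptor expression in receiver) / 2."""
    labels = pd.Series(np.asarray(labels), index=nm.cell_ids)
    lig = nm.gene_vector(pair.ligand)
    rec = nm.gene_vector(pair.receptor)
    s_mask = (labels == sender).to_numpy()
    r_mask = (labels == receiver).to_numpy()
    if not s_mask.any() or not r_mask.any():
        raise KeyError("unknown sender or receiver cell type")
    return float((lig[s_mask].mean() + rec[r_mask].mean()) / 2.0)


def permutation_test(
    nm: NormalizedMatrix,
    labels: pd.Series | None = None,
    pairs: Iterable[LigandReceptorPair] = (),
    cfg: PipelineConfig = PipelineConfig(),
    seed: int | None = None,
    condition: str | None = None,
) -> pd.DataFrame:
    """Permutation test for every (pair, sender, receiver) combination.

    Returns a long DataFrame with columns ligand, receptor, sender, receiver,
    condition, statistic, p_value, tested, significant. Untested (filtered)
    combinations carry NaN p. Pairs whose genes are absent from the matrix are
    skipped with a warning. Deterministic given ``seed``.
    """
    if cfg.n_permutations < MIN_PERMUTATIONS:
        raise ValueError(f"n_permutations must be >= {MIN_PERMUTATIONS} to resolve p-values")
    if labels is None:
        labels = nm.labels()
    labels = pd.Series(np.asarray(labels, dtype=object), index=nm.cell_ids)
    types = sorted(map(str, labels.dropna().unique()))
    if len(types) < 2:
        raise ValueError("permutation test requires at least two cell types")
    codes = pd.Categorical(labels, categories=types).codes.astype(np.int64)
    T = len(types)

    pairs = list(pairs)
    genes_needed: list[str] = []
    usable_pairs: list[LigandReceptorPair] = []
    for pair in pairs:
        if pair.ligand in nm.gene_ids and pair.receptor in nm.gene_ids:
            usable_pairs.append(pair)
            genes_needed.extend(pair)
        else:
            log.warning("pair %s skipped: gene(s) absent from matrix", pair)
    if not usable_pairs:
        raise ValueError("no ligand-receptor pair has both genes in the matrix")
    gene_index = pd.Index(pd.unique(np.asarray(genes_needed)))
    rows = nm.gene_ids.get_indexer(gene_index)
    E = np.asarray(nm.values[rows].todense())

    lig_idx = np.array([gene_index.get_loc(p.ligand) for p in usable_pairs])
    rec_idx = np.array([gene_index.get_loc(p.receptor) for p in usable_pairs])

    frac = _group_means((E > 0).astype(float), codes, T)  # (G, T) expressing fraction
    obs_means = _group_means(E, codes, T)
    # observed statistic per (pair, sender, receiver)
    obs = 0.5 * (obs_means[lig_idx][:, :, None] + obs_means[rec_idx][:, None, :])
    tested = (frac[lig_idx][:, :, None] >= cfg.lr_min_expr_frac) & (
        frac[rec_idx][:, None, :] >= cfg.lr_min_expr_frac
    )

    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    ge_counts = np.zeros_like(obs, dtype=np.int64)
    # tolerance so permutation-invariant statistics count as ties (>= rule)
    tol = 1e-9 * (1.0 + np.abs(obs))
    for _ in range(cfg.n_permutations):
        perm_codes = rng.permutation(codes)
        pm = _group_means(E, perm_codes, T)
        stat = 0.5 * (pm[lig_idx][:, :, None] + pm[rec_idx][:, None, :])
        ge_counts += stat >= obs - tol
    pvals = (1.0 + ge_counts) / (cfg.n_permutations + 1.0)

    records = []
    for i, pair in enumerate(usable_pairs):
        for s in range(T):
            for r in range(T):
                is_tested = bool(tested[i, s, r])
                records.append(
                    (
                        pair.ligand, pair.receptor, types[s], types[r], condition,
                        float(obs[i, s, r]),
                        float(pvals[i, s, r]) if is_tested else np.nan,
                        is_tested,
                        bool(is_tested and pvals[i, s, r] < cfg.lr_alpha),
                    )
                )
    return pd.DataFrame(
        records,
        columns=["ligand", "receptor", "sender", "receiver", "condition",
                 "statistic", "p_value", "tested", "significant"],
    )


def permutation_test_by_condition(
    nm: NormalizedMatrix,
    labels: pd.Series | None = None,
    pairs: Iterable[LigandReceptorPair] = (),
    cfg: PipelineConfig = PipelineConfig(),
    seed: int | None = None,
) -> pd.DataFrame:
    """Run the permutation test separately within each condition."""
    if labels is None:
        labels = nm.labels()
    labels = pd.Series(np.asarray(labels, dtype=object), index=nm.cell_ids)
    cond = nm.cell_meta["condition"].to_numpy()
    frames = []
    base_seed = cfg.rng_seed if seed is None else seed
    for k, level in enumerate(CONDITIONS):
        mask = cond == level
        if not mask.any():
            log.warning("condition %r has no cells; skipped", level)
            continue
        sub = NormalizedMatrix(
            values=nm.values[:, mask],
            gene_ids=nm.gene_ids,
            cell_ids=nm.cell_ids[mask],
            cell_meta=nm.cell_meta.loc[mask],
            provenance=nm.provenance,
        )
        frames.append(
            permutation_test(sub, labels[mask], pairs, cfg,
                             seed=base_seed + k, condition=level)
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class InteractionGraph:
    """Directed cell-type graph; an edge weight counts significant LR pairs."""

    condition: str
    types: tuple[str, ...]
    sig_pairs: dict[tuple[str, str], frozenset[LigandReceptorPair]]

    def weight(self, sender: str, receiver: str) -> int:
        return len(self.sig_pairs.get((sender, receiver), frozenset()))

    def weights(self) -> pd.DataFrame:
        """Square sender x receiver weight matrix."""
        mat = pd.DataFrame(0, index=list(self.types), columns=list(self.types))
        for (s, r), pairs in self.sig_pairs.items():
            mat.loc[s, r] = len(pairs)
        return mat


def build_graph(results: pd.DataFrame, condition: str) -> InteractionGraph:
    """Collapse per-pair results of one condition into an interaction graph."""
    conds = set(results["condition"].dropna().unique())
    if conds - {condition}:
        raise ValueError(f"results mix conditions {sorted(conds)}; expected only {condition!r}")
    types = tuple(sorted(set(results["sender"]) | set(results["receiver"])))
    sig = results[results["significant"]]
    edges: dict[tuple[str, str], set[LigandReceptorPair]] = {}
    for row in sig.itertuples(index=False):
        edges.setdefault((row.sender, row.receiver), set()).add(
            LigandReceptorPair(row.ligand, row.receptor)
        )
    return InteractionGraph(
        condition=condition,
        types=types,
        sig_pairs={k: frozenset(v) for k, v in edges.items()},
    )


def differential_graph(g_pop: InteractionGraph, g_ctrl: InteractionGraph) -> pd.DataFrame:
    """Per-edge weight change (POP - control) with gained and lost pair sets.

    A pair is gained on an edge when significant in POP but not in control,
    lost when the reverse; the two sets are disjoint by construction.
    """
    if set(g_pop.types) != set(g_ctrl.types):
        raise ValueError("graphs cover different cell-type universes")
    rows = []
    for s in g_pop.types:
        for r in g_pop.types:
            pop_pairs = g_pop.sig_pairs.get((s, r), frozenset())
            ctrl_pairs = g_ctrl.sig_pairs.get((s, r), frozenset())
            rows.append(
                (
                    s, r,
                    len(pop_pairs) - len(ctrl_pairs),
                    frozenset(pop_pairs - ctrl_pairs),
                    frozenset(ctrl_pairs - pop_pairs),
                )
            )
    return pd.DataFrame(rows, columns=["sender", "receiver", "weight_change", "gained", "lost"])
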