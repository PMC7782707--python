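"""Gene-set enrichment: Fisher over-representation and preranked GSEA.

Over-representation tests a 2x2 membership table (in-query x in-set over a
declared gene universe) with a two-sided Fisher exact test. Preranked GSEA
computes the weighted Kolmogorov-Smirnov running-sum enrichment score (hit
increments proportional to |score|, uniform miss decrements) and estimates
significance from random gene sets of the same size, add-one corrected, with
the same sign as the observed score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from popsc.config import PipelineConfig

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene symbols."""

    name: str
    members: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            object.__setattr__(self, "members", tuple(dict.fromkeys(self.members)))

    def __len__(self) -> int:
        return len(self.members)


def ora_fisher(
    query,
    sets,
    universe,
    cfg: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Two-sided Fisher exact over-representation test per gene set.

    ``query`` must be a subset of ``universe``; each set is intersected with
    the universe first and skipped (with a warning) when the intersection is
    empty. Returns set_name, mode, overlap, set_size, p_value, significant.
    """
    universe = pd.Index(pd.unique(np.asarray(list(universe), dtype=object)))
    query_set = set(query)
    if len(universe) == 0 or not query_set:
        raise ValueError("query and universe must be nonempty")
    if not query_set <= set(universe):
        raise ValueError("query must be a subset of the universe")
    n_query = len(query_set)
    rows = []
    for gs in sets:
        members = set(gs.members) & set(universe)
        if not members:
            log.warning("gene set %r disjoint from universe; skipped", gs.name)
            continue
        a = len(query_set & members)
        b = n_query - a
        c = len(members) - a
        d = len(universe) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((gs.name, "ora", a, len(members), float(p), bool(p < cfg.enrich_alpha)))
    return pd.DataFrame(
        rows, columns=["set_name", "mode", "overlap", "set_size", "p_value", "significant"]
    )


def enrichment_score(scores_sorted: np.ndarray, hit_positions: np.ndarray,
                     weight_exponent: float = 1.0) -> float:
    """Weighted KS running-sum enrichment score for a ranked list.

    ``scores_sorted`` is the full score vector sorted descending;
    ``hit_positions`` are the 0-based positions of set members within it.
    """
    n = scores_sorted.size
    k = hit_positions.size
    if k == 0:
        raise ValueError("gene set has no members in the ranking")
    w = np.abs(scores_sorted[hit_positions]) ** weight_exponent
    total_w = w.sum()
    if total_w == 0:
        w = np.ones(k)  # all hit scores zero: fall back to unweighted steps
        total_w = float(k)
    if k == n:
        return 1.0
    order = np.argsort(hit_positions)
    pos = hit_positions[order]
    inc = np.cumsum(w[order]) / total_w
    miss = 1.0 / (n - k)
    # running sum attains candidate extrema just after each hit (peak) and
    # just before each hit (trough)
    after = inc - (pos + 1 - np.arange(1, k + 1)) * miss
    before = np.concatenate([[0.0], inc[:-1]]) - (pos - np.arange(k)) * miss
    candidates = np.concatenate([after, before])
    es = candidates[np.argmax(np.abs(candidates))]
    return float(es)


def gsea_preranked(
    ranking: pd.Series,
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
    cfg: PipelineConfig = PipelineConfig(),
) -> dict:
    """Preranked GSEA for one gene set.

    ``ranking`` maps genes to scores (no duplicate genes); ordering is by
    descending score with a deterministic gene-id tie-break. The permutation
    null draws random gene sets of the same size; the p-value is the add-one
    fraction of same-sign permutations with an ES at least as extreme as the
    observed one. Returns a record dict (set_name, mode, es, p_value,
    significant).
    """
    ranking = pd.Series(ranking)
    if ranking.index.has_duplicates:
        raise ValueError("ranking has duplicate genes")
    ranking = ranking.sort_index().sort_values(ascending=False, kind="stable")
    genes = ranking.index
    scores = ranking.to_numpy(dtype=float)
    members = set(gene_set.members) & set(genes)
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} shares no genes with the ranking")
    if len(members) == len(genes) and np.unique(scores).size == 1:
        raise ValueError("degenerate input: constant scores with set = all genes")
    hit_pos = np.flatnonzero(genes.isin(members))
    es = enrichment_score(scores, hit_pos)

    rng = np.random.default_rng(seed)
    k = hit_pos.size
    n = genes.size
    extreme = same_sign = 0
    for _ in range(n_perm):
        perm_pos = rng.choice(n, size=k, replace=False)
        es_perm = enrichment_score(scores, perm_pos)
        if es >= 0:
            same_sign += es_perm >= 0
            extreme += es_perm >= es
        else:
            same_sign += es_perm < 0
            extreme += es_perm <= es
    # one-sided within the same-sign permutation subset, add-one corrected
    p = (1.0 + extreme) / (1.0 + same_sign)
    return {
        "set_name": gene_set.name,
        "mode": "gsea",
        "es": es,
        "n_hits": int(k),
        "p_value": float(p),
        "significant": bool(p < cfg.enrich_alpha),
    }


def de_ranking(de: pd.DataFrame) -> pd.Series:
    """Default preranked metric from a DE table: sign(log2fc) * -log10(p)."""
    score = np.sign(de["log2fc"].to_numpy()) * -np.log10(
        np.clip(de["p_value"].to_numpy(), np.finfo(float).tiny, 1.0)
    )
    return pd.Series(score, index=pd.Index(de["gene"], name="gene"), name="score")


def gsea_collection(
    ranking: pd.Series,
    sets,
    n_perm: int = 1000,
    seed: int = 0,
    cfg: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Run :func:`gsea_preranked` over a collection, skipping disjoint sets."""
    rows = []
    for i, gs in enumerate(sets):
        try:
            rows.append(gsea_preranked(ranking, gs, n_perm=n_perm, seed=seed + i, cfg=cfg))
        except ValueError as exc:
            log.warning("gene set %r skipped: %s", gs.name, exc)
    return pd.DataFrame(rows)
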