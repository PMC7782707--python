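"""One-vs-rest cluster marker detection by two-sided Wilcoxon rank-sum.

Reproduces the familiar FindAllMarkers contract: per cell type, genes are
pre-filtered on detection fraction and log2 fold change, then tested
one-vs-rest; a marker is significant when p < 0.05 with positive fold change.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from popsc.config import PipelineConfig
from popsc.matrix import NormalizedMatrix

log = logging.getLogger(__name__)

EXACT_MAX_N = 12


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact enumeration when n_x + n_y <= 12 with no ties, otherwise the
    tie-corrected normal approximation with continuity correction. Returns
    (U statistic of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires nonempty samples")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= EXACT_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _log2fc_expm1(mean_in: np.ndarray, mean_out: np.ndarray) -> np.ndarray:
    """Fold change on the de-logged scale with a +1 pseudocount, as the
    single-cell toolchain reports it."""
    return np.log2((mean_in + 1.0) / (mean_out + 1.0))


def find_all_markers(
    nm: NormalizedMatrix,
    labels: pd.Series | None = None,
    cfg: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker test for every cell-type label level.

    Returns a DataFrame with columns gene, cell_type, log2fc, pct_in, pct_out,
    p_value, significant, sorted by (cell_type, p_value). Levels with fewer
    than ``cfg.min_cells_per_cluster`` cells are skipped with a warning.
    """
    if labels is None:
        labels = nm.labels()
    labels = pd.Series(np.asarray(labels), index=nm.cell_ids)
    levels = [lv for lv in labels.unique() if pd.notna(lv)]
    if len(levels) < 2:
        raise ValueError("find_all_markers requires at least two label levels")

    X = sp.csr_matrix(nm.values, dtype=np.float64)
    expm1 = X.copy()
    expm1.data = np.expm1(expm1.data)
    nnz = X.copy()
    nnz.data = np.ones_like(nnz.data)

    records = []
    for level in sorted(map(str, levels)):
        in_mask = (labels == level).to_numpy()
        n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
        if n_in < cfg.min_cells_per_cluster:
            log.warning("cell type %r has %d < %d cells; skipped", level, n_in,
                        cfg.min_cells_per_cluster)
            continue
        mean_in = np.asarray(expm1[:, in_mask].sum(axis=1)).ravel() / n_in
        mean_out = np.asarray(expm1[:, ~in_mask].sum(axis=1)).ravel() / n_out
        pct_in = np.asarray(nnz[:, in_mask].sum(axis=1)).ravel() / n_in
        pct_out = np.asarray(nnz[:, ~in_mask].sum(axis=1)).ravel() / n_out
        lfc = _log2fc_expm1(mean_in, mean_out)
        testable = (np.maximum(pct_in, pct_out) >= cfg.marker_min_pct) & (
            np.abs(lfc) >= cfg.marker_min_abs_log2fc
        )
        for g in np.flatnonzero(testable):
            vec = np.asarray(X[g].todense()).ravel()
            _, p = rank_sum_test(vec[in_mask], vec[~in_mask])
            records.append(
                (nm.gene_ids[g], level, lfc[g], pct_in[g], pct_out[g], p,
                 bool(p < cfg.marker_alpha and lfc[g] > 0))
            )
    out = pd.DataFrame(
        records,
        columns=["gene", "cell_type", "log2fc", "pct_in", "pct_out", "p_value", "significant"],
    )
    return out.sort_values(["cell_type", "p_value", "gene"], kind="stable").reset_index(drop=True)
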