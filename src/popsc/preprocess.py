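"""Cell quality control, library-size normalization and HVG selection.

QC keeps cells detecting between ``min_genes`` and ``max_genes`` genes
(inclusive) whose mitochondrial count fraction is strictly below
``max_mito_frac``. Normalization scales each cell to a fixed size factor and
applies ln(1+x). Highly variable genes are ranked by variance standardized
against a polynomial mean-variance trend (vst-style), clipped at sqrt(N).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from popsc.config import PipelineConfig
from popsc.matrix import NormalizedMatrix, UmiMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QcReport:
    """Per-rule removal counts from one QC pass.

    Rule counts record how many input cells fail each rule individually, so
    they can exceed ``n_removed`` when a cell fails several rules at once.
    """

    n_in: int
    n_out: int
    n_low_genes: int
    n_high_genes: int
    n_high_mito: int

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_out


def qc_filter(m: UmiMatrix, cfg: PipelineConfig) -> tuple[UmiMatrix, QcReport]:
    """Apply the three cell-level QC rules; the gene set is left unchanged."""
    detected = m.detected_genes_per_cell()
    mito_frac = m.mito_fraction_per_cell()
    low = detected < cfg.min_genes
    high = detected > cfg.max_genes
    mito = mito_frac >= cfg.max_mito_frac  # "less than" threshold is strict
    keep = ~(low | high | mito)
    report = QcReport(
        n_in=m.n_cells,
        n_out=int(keep.sum()),
        n_low_genes=int(low.sum()),
        n_high_genes=int(high.sum()),
        n_high_mito=int(mito.sum()),
    )
    if report.n_out == 0:
        raise ValueError("QC removed every cell; check thresholds and input")
    return m.subset_cells(keep), report


def normalize(m: UmiMatrix, cfg: PipelineConfig) -> NormalizedMatrix:
    """ln(1 + count / cell_total * size_factor) per entry; zero stays zero."""
    totals = m.counts_per_cell()
    if np.any(totals <= 0):
        raise ValueError("normalize requires every cell to have total count > 0")
    mat = sp.csc_matrix(m.counts, dtype=np.float64)
    # scale columns by size_factor / total, then log1p on stored entries only
    scale = cfg.norm_size_factor / totals
    mat = mat @ sp.diags(scale)
    mat.eliminate_zeros()
    mat.data = np.log1p(mat.data)
    return NormalizedMatrix(
        values=sp.csr_matrix(mat),
        gene_ids=m.gene_ids,
        cell_ids=m.cell_ids,
        cell_meta=m.cell_meta,
        provenance=f"log1p(size_factor={cfg.norm_size_factor:g})",
    )


def hvg_scores(m: UmiMatrix, degree: int = 2) -> pd.Series:
    """Standardized variance per gene under a polynomial mean-variance trend.

    Raw-count variance is regressed (log10-log10) on mean with a degree-2
    polynomial; counts are standardized by the trend-expected SD, clipped at
    sqrt(N), and the variance of the clipped values is the score. Genes with
    zero variance score 0.
    """
    X = sp.csr_matrix(m.counts, dtype=np.float64)
    n = m.n_cells
    mean = np.asarray(X.sum(axis=1)).ravel() / n
    sq = np.asarray(X.multiply(X).sum(axis=1)).ravel()
    var = (sq - n * mean**2) / max(n - 1, 1)
    scores = np.zeros(m.n_genes)
    usable = (var > 0) & (mean > 0)
    if usable.sum() >= degree + 1:
        coef = np.polyfit(np.log10(mean[usable]), np.log10(var[usable]), degree)
        exp_sd = np.sqrt(10 ** np.polyval(coef, np.log10(mean[usable])))
        clip = np.sqrt(n)
        idx = np.flatnonzero(usable)
        mu = mean[usable]
        # accumulate sum and sum of squares of clipped standardized values
        z_zero = np.clip((0.0 - mu) / exp_sd, -clip, clip)
        sums = np.zeros(idx.size)
        sqsums = np.zeros(idx.size)
        nnz = np.diff(X.indptr)[idx]
        for j, g in enumerate(idx):
            row = X.data[X.indptr[g]:X.indptr[g + 1]]
            z = np.clip((row - mu[j]) / exp_sd[j], -clip, clip)
            sums[j] = z.sum() + z_zero[j] * (n - nnz[j])
            sqsums[j] = (z**2).sum() + z_zero[j] ** 2 * (n - nnz[j])
        scores[idx] = (sqsums - sums**2 / n) / max(n - 1, 1)
    elif usable.any():
        scores[usable] = var[usable]  # too few genes for a trend; rank by raw variance
    return pd.Series(scores, index=m.gene_ids, name="hvg_score")


def select_hvg(m: UmiMatrix, cfg: PipelineConfig) -> list[str]:
    """Top ``n_hvg`` genes by standardized variance; ties broken by gene id.

    If fewer than ``n_hvg`` genes have nonzero variance, all of those are
    returned (constant genes are never selected).
    """
    scores = hvg_scores(m)
    positive = scores[scores > 0]
    ranked = positive.sort_index().sort_values(ascending=False, kind="stable")
    n = min(cfg.n_hvg, len(ranked))
    if len(ranked) < cfg.n_hvg:
        log.warning("only %d genes with nonzero variance (< n_hvg=%d)", len(ranked), cfg.n_hvg)
    return list(ranked.index[:n])
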