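"""Pseudobulk construction and negative-binomial likelihood-ratio DE testing.

Droplet scRNA-seq counts are too sparse and zero-inflated for per-cell DE
testing, so raw UMI counts are summed over seeded random groups of
``pseudobulk_group_size`` cells within each (cell type, condition, sample)
stratum and the resulting "pseudobulks" are treated as technical replicates
of an NB count model: y_gi ~ NB(mu_gi, phi_g) with log mu_gi = x_i' beta_g +
log N_i. Dispersions are estimated by Cox-Reid adjusted profile likelihood
(common, then tagwise shrunk toward common); the condition effect is tested
per gene by a chi-square(1) likelihood-ratio test. The same machinery applies
unchanged to plain bulk count tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.special import gammaln

from popsc.config import CONDITIONS, CONTROL, POP, PipelineConfig
from popsc.matrix import UmiMatrix

log = logging.getLogger(__name__)

LN2 = np.log(2.0)
_ETA_CLIP = 50.0


@dataclass
class PseudobulkTable:
    """Gene x replicate summed counts with replicate annotations."""

    counts: np.ndarray  # (G, R) integer
    gene_ids: pd.Index
    replicate_meta: pd.DataFrame  # cell_type, condition, sample, chunk_index, n_cells_summed

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = pd.Index(self.gene_ids, name="gene")
        if self.counts.shape != (len(self.gene_ids), len(self.replicate_meta)):
            raise ValueError("pseudobulk counts shape does not match annotations")
        if (self.replicate_meta["n_cells_summed"] < 1).any():
            raise ValueError("every replicate must sum at least one cell")

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[1]

    def condition_indicator(self) -> np.ndarray:
        """0 for control replicates, 1 for POP."""
        cond = self.replicate_meta["condition"].to_numpy()
        bad = set(cond) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}")
        return (cond == POP).astype(float)


def _chunk_sizes(n: int, group_size: int, min_remainder: int) -> list[int]:
    """Partition ``n`` cells into chunks of ``group_size``; a remainder of at
    least ``min_remainder`` cells becomes its own replicate, a smaller one is
    merged into the last full chunk."""
    k, r = divmod(n, group_size)
    if k == 0:
        return [n]  # caller guarantees n >= min_remainder
    sizes = [group_size] * k
    if r >= min_remainder:
        sizes.append(r)
    elif r > 0:
        sizes[-1] += r
    return sizes


def make_pseudobulks(
    m: UmiMatrix,
    labels: pd.Series | None = None,
    cfg: PipelineConfig = PipelineConfig(),
    seed: int | None = None,
) -> PseudobulkTable:
    """Sum raw UMI counts over seeded random cell groups per stratum.

    Cells are partitioned within each (cell_type, condition, sample) stratum;
    strata with fewer than ``cfg.min_cells_per_stratum`` cells are dropped
    with a warning. Total counts are conserved per retained stratum.
    """
    if labels is None:
        labels = m.labels()
    labels = pd.Series(np.asarray(labels, dtype=object), index=m.cell_ids)
    if labels.isna().any():
        raise ValueError("labels must cover all cells")
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    X = sp.csc_matrix(m.counts)

    strata = pd.DataFrame(
        {
            "cell_type": labels.to_numpy(),
            "condition": m.cell_meta["condition"].to_numpy(),
            "sample": m.cell_meta["sample"].to_numpy(),
        },
        index=m.cell_ids,
    )
    cols: list[np.ndarray] = []
    meta_rows: list[tuple] = []
    grouped = strata.groupby(["cell_type", "condition", "sample"], sort=True)
    for (ctype, cond, samp), grp in grouped:
        pos = m.cell_ids.get_indexer(grp.index)
        if pos.size < cfg.min_cells_per_stratum:
            log.warning(
                "stratum (%s, %s, %s) has %d < %d cells; dropped",
                ctype, cond, samp, pos.size, cfg.min_cells_per_stratum,
            )
            continue
        perm = rng.permutation(pos)
        start = 0
        for chunk_index, size in enumerate(
            _chunk_sizes(pos.size, cfg.pseudobulk_group_size, cfg.pseudobulk_min_remainder)
        ):
            members = perm[start:start + size]
            start += size
            cols.append(np.asarray(X[:, members].sum(axis=1)).ravel())
            meta_rows.append((ctype, cond, samp, chunk_index, size))
    if not cols:
        raise ValueError("no stratum large enough to form pseudobulk replicates")
    meta = pd.DataFrame(
        meta_rows,
        columns=["cell_type", "condition", "sample", "chunk_index", "n_cells_summed"],
    )
    return PseudobulkTable(
        counts=np.column_stack(cols).astype(np.int64),
        gene_ids=m.gene_ids,
        replicate_meta=meta,
    )


# ---------------------------------------------------------------------------
# NB GLM machinery (vectorized across genes)
# ---------------------------------------------------------------------------


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Per-gene NB log-likelihood summed over replicates; phi scalar or (G,).

    phi = 0 gives the Poisson limit.
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-10)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    phi_safe = np.maximum(phi, 1e-300)
    out = np.where(
        phi > 0,
        gammaln(y + 1.0 / phi_safe)
        - gammaln(1.0 / phi_safe)
        - gammaln(y + 1.0)
        + y * np.log(phi_safe * mu / (1.0 + phi_safe * mu))
        - np.log1p(phi * mu) / phi_safe,
        y * np.log(mu) - mu - gammaln(y + 1.0),
    )
    return out.sum(axis=-1)


def _fit_nb_glm(Y: np.ndarray, X: np.ndarray, offsets: np.ndarray, phi):
    """Fisher-scoring NB GLM fit per gene with shared design and fixed phi.

    Returns (beta (G,p), loglik (G,), cr_adjust (G,), converged (G,)).
    ``cr_adjust`` is 0.5*logdet(X'WX), the Cox-Reid term.
    """
    Y = np.asarray(Y, dtype=float)
    G, R = Y.shape
    p = X.shape[1]
    phi_col = np.asarray(phi, dtype=float)
    phi_col = phi_col[:, None] if phi_col.ndim == 1 else phi_col

    beta = np.zeros((G, p))
    base = np.log(np.maximum(Y @ np.exp(-offsets) / R, 1e-8))
    beta[:, 0] = base
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    for _ in range(60):
        eta = np.clip(beta @ X.T + offsets, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        W = mu / (1.0 + phi_col * mu)  # Fisher weights, Poisson limit mu
        z = (eta - offsets) + (Y - mu) / mu
        A = np.einsum("rp,gr,rq->gpq", X, W, X)
        A += np.eye(p) * 1e-10
        b = np.einsum("rp,gr->gp", X, W * z)
        new = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        step = new - beta
        beta = np.where(active[:, None], new, beta)
        done = np.max(np.abs(step), axis=1) < 1e-10
        converged |= done & active
        active &= ~done
        if not active.any():
            break
    eta = np.clip(beta @ X.T + offsets, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    W = mu / (1.0 + phi_col * mu)
    A = np.einsum("rp,gr,rq->gpq", X, W, X) + np.eye(p) * 1e-10
    sign, logdet = np.linalg.slogdet(A)
    ll = nb_loglik(Y, mu, phi_col)
    return beta, ll, 0.5 * logdet, converged


@dataclass
class NbFit:
    """Estimated NB model parameters for one pseudobulk table."""

    common_dispersion: float
    dispersion: np.ndarray  # per-gene tagwise phi
    offsets: np.ndarray  # log library sizes per replicate
    design: np.ndarray  # (R, 2) intercept + condition
    gene_ids: pd.Index
    group_means: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if np.any(self.dispersion < 0) or self.common_dispersion < 0:
            raise ValueError("dispersions must be >= 0")
        if not np.all(np.isfinite(self.offsets)):
            raise ValueError("offsets must be finite")


_PHI_GRID = np.concatenate([[1e-6], np.logspace(-4, 1, 46)])


def _refine_argmax(grid: np.ndarray, values: np.ndarray) -> float:
    """Parabolic refinement of an argmax over a log-spaced grid."""
    i = int(np.argmax(values))
    if i == 0 or i == len(grid) - 1:
        return float(grid[i])
    x = np.log(grid[i - 1:i + 2])
    y = values[i - 1:i + 2]
    denom = (y[0] - 2 * y[1] + y[2])
    if denom >= 0:
        return float(grid[i])
    shift = 0.5 * (y[0] - y[2]) / denom
    return float(np.exp(x[1] + shift * (x[1] - x[0])))


def fit_nb_dispersion(
    pb: PseudobulkTable,
    design: np.ndarray | None = None,
    cfg: PipelineConfig = PipelineConfig(),
) -> NbFit:
    """Estimate common and tagwise NB dispersions by Cox-Reid APL.

    The common dispersion maximizes the adjusted profile likelihood summed
    over genes on a log-spaced grid (with parabolic refinement). Tagwise
    dispersions maximize the gene's own APL plus the gene-averaged APL
    weighted to carry the information of ``cfg.dispersion_prior_reps``
    replicates, shrinking noisy per-gene estimates toward the common value.
    Offsets are log column totals.
    """
    Y = pb.counts.astype(float)
    G, R = Y.shape
    cond = pb.condition_indicator() if design is None else np.asarray(design, dtype=float)
    for level in np.unique(cond):
        if (cond == level).sum() < 2:
            raise ValueError("need >= 2 replicates per condition to estimate dispersion")
    X = np.column_stack([np.ones(R), cond])
    col_totals = Y.sum(axis=0)
    if np.any(col_totals <= 0):
        raise ValueError("empty pseudobulk replicate")
    offsets = np.log(col_totals)

    expressed = Y.sum(axis=1) > 0
    Ye = Y[expressed]
    apl = np.empty((Ye.shape[0], _PHI_GRID.size))
    for k, phi in enumerate(_PHI_GRID):
        _, ll, cr, _ = _fit_nb_glm(Ye, X, offsets, phi)
        apl[:, k] = ll - cr
    common = _refine_argmax(_PHI_GRID, apl.sum(axis=0))

    w = cfg.dispersion_prior_reps / R
    weighted = apl + w * apl.mean(axis=0)
    tagwise = np.full(G, common)
    tag_e = np.array([_refine_argmax(_PHI_GRID, weighted[g]) for g in range(Ye.shape[0])])
    tagwise[expressed] = tag_e

    means = pd.DataFrame(
        {
            "control": Y[:, cond == 0].mean(axis=1),
            "pop": Y[:, cond == 1].mean(axis=1),
        },
        index=pb.gene_ids,
    )
    return NbFit(
        common_dispersion=common,
        dispersion=tagwise,
        offsets=offsets,
        design=X,
        gene_ids=pb.gene_ids,
        group_means=means,
    )


def nb_lrt(
    pb: PseudobulkTable,
    fit: NbFit,
    cfg: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Per-gene likelihood-ratio test of the condition effect.

    Full model: intercept + condition; reduced: intercept only; both with
    fixed tagwise dispersion and library-size offsets. Returns a DataFrame
    with gene, log2fc (POP vs control), p_value, significant, converged;
    non-converged genes are flagged and assigned p = 1, never dropped.
    """
    if not fit.gene_ids.equals(pb.gene_ids):
        raise ValueError("fit was computed on a different gene set")
    Y = pb.counts.astype(float)
    phi = fit.dispersion
    beta_full, ll_full, _, conv_full = _fit_nb_glm(Y, fit.design, fit.offsets, phi)
    beta_red, ll_red, _, conv_red = _fit_nb_glm(Y, fit.design[:, :1], fit.offsets, phi)
    lr = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    pvals = stats.chi2.sf(lr, df=1)
    log2fc = beta_full[:, 1] / LN2
    converged = conv_full & conv_red
    zero = Y.sum(axis=1) == 0
    log2fc[zero] = 0.0
    pvals[zero] = 1.0
    converged |= zero
    if not converged.all():
        log.warning("%d genes did not converge; p set to 1", int((~converged).sum()))
        pvals = np.where(converged, pvals, 1.0)
        log2fc = np.where(converged, log2fc, 0.0)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "gene": pb.gene_ids,
            "log2fc": log2fc,
            "p_value": pvals,
            "significant": (np.abs(log2fc) > cfg.de_abs_log2fc) & (pvals < cfg.de_alpha),
            "converged": converged,
        }
    )
    return out.reset_index(drop=True)


def run_de(
    pb: PseudobulkTable,
    cfg: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Dispersion fit + LRT in one call."""
    fit = fit_nb_dispersion(pb, cfg=cfg)
    return nb_lrt(pb, fit, cfg)


def bulk_table_de(
    table: pd.DataFrame,
    cfg: PipelineConfig = PipelineConfig(),
    conditions: np.ndarray | None = None,
) -> pd.DataFrame:
    """NB LRT on a plain gene x replicate counts table.

    Replicate conditions come from ``conditions`` (0 control / 1 POP per
    column) or are parsed from column names prefixed ``control``/``POP``.
    """
    if conditions is None:
        cond = []
        for c in table.columns:
            if str(c).startswith(CONTROL):
                cond.append(0.0)
            elif str(c).startswith(POP):
                cond.append(1.0)
            else:
                raise ValueError(f"cannot infer condition from column {c!r}")
        conditions = np.asarray(cond)
    meta = pd.DataFrame(
        {
            "cell_type": "bulk",
            "condition": np.where(np.asarray(conditions) > 0, POP, CONTROL),
            "sample": list(map(str, table.columns)),
            "chunk_index": 0,
            "n_cells_summed": 1,
        }
    )
    pb = PseudobulkTable(
        counts=table.to_numpy(dtype=np.int64), gene_ids=table.index, replicate_meta=meta
    )
    return run_de(pb, cfg)


def de_per_cell_type(
    m: UmiMatrix,
    labels: pd.Series | None = None,
    cfg: PipelineConfig = PipelineConfig(),
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Pseudobulk + NB LRT separately for every cell type.

    Types lacking enough replicates in either condition are skipped with a
    warning. Returns a mapping cell type -> DE table.
    """
    if labels is None:
        labels = m.labels()
    labels = pd.Series(np.asarray(labels, dtype=object), index=m.cell_ids)
    results: dict[str, pd.DataFrame] = {}
    for ctype in sorted(map(str, labels.dropna().unique())):
        mask = (labels == ctype).to_numpy()
        sub = m.subset_cells(mask)
        conds = set(sub.cell_meta["condition"].unique())
        if conds != set(CONDITIONS):
            log.warning("cell type %r absent in one condition; skipped", ctype)
            continue
        try:
            pb = make_pseudobulks(sub, labels[mask], cfg, seed=seed)
            cond = pb.condition_indicator()
            if min((cond == 0).sum(), (cond == 1).sum()) < 2:
                log.warning("cell type %r has <2 replicates in a condition; skipped", ctype)
                continue
            results[ctype] = run_de(pb, cfg)
        except ValueError as exc:
            log.warning("cell type %r skipped: %s", ctype, exc)
    return results


def de_summary(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Up/down significant-gene counts per cell type."""
    rows = []
    for ctype, df in sorted(results.items()):
        sig = df[df["significant"]]
        rows.append((ctype, int((sig["log2fc"] > 0).sum()), int((sig["log2fc"] < 0).sum())))
    return pd.DataFrame(rows, columns=["cell_type", "n_up", "n_down"])
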