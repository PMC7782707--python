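"""In-memory containers: the sparse UMI count matrix and its normalized form.

Both are oriented genes x cells throughout the package; per-cell metadata
travels with the counts so every downstream stage can stratify by sample,
condition and cell-type label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from popsc.config import CONDITIONS

MITO_PREFIX = "MT-"

REQUIRED_CELL_COLUMNS = ("sample", "condition")


def is_mito_symbol(symbols) -> np.ndarray:
    """Flag mitochondrial genes by the human ``MT-`` symbol prefix (case-insensitive)."""
    return np.array([str(s).upper().startswith(MITO_PREFIX) for s in symbols], dtype=bool)


@dataclass
class UmiMatrix:
    """Sparse gene x cell UMI count matrix with gene and cell annotations.

    ``counts`` holds non-negative integers; ``cell_meta`` is indexed by barcode
    and must carry a ``sample`` and a ``condition`` (control or POP) per cell,
    plus an optional ``cell_type`` label; ``gene_meta`` is indexed by gene
    symbol and carries an ``is_mito`` flag.
    """

    counts: sp.csr_matrix
    gene_ids: pd.Index
    cell_ids: pd.Index
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = pd.Index(self.gene_ids, name="gene")
        self.cell_ids = pd.Index(self.cell_ids, name="cell")
        if self.gene_meta is None:
            self.gene_meta = pd.DataFrame(
                {"is_mito": is_mito_symbol(self.gene_ids)}, index=self.gene_ids
            )
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.gene_ids.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.cell_ids.has_duplicates:
            raise ValueError("duplicate cell barcodes")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise ValueError("negative counts")
            if not np.issubdtype(data.dtype, np.integer) and np.any(data != np.rint(data)):
                raise ValueError("counts must be integral")
        missing = [c for c in REQUIRED_CELL_COLUMNS if c not in self.cell_meta.columns]
        if missing:
            raise ValueError(f"cell_meta missing required columns: {missing}")
        if not self.cell_meta.index.equals(self.cell_ids):
            self.cell_meta = self.cell_meta.reindex(self.cell_ids)
            if self.cell_meta[list(REQUIRED_CELL_COLUMNS)].isna().any().any():
                raise ValueError("cell_meta does not cover all cells")
        bad = set(self.cell_meta["condition"].unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
        if "is_mito" not in self.gene_meta.columns:
            raise ValueError("gene_meta missing is_mito flag")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def detected_genes_per_cell(self) -> np.ndarray:
        """Number of genes with count >= 1 in each cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel().astype(float)

    def mito_fraction_per_cell(self) -> np.ndarray:
        """Mitochondrial count fraction per cell (0 for empty cells)."""
        totals = self.counts_per_cell()
        mito_mask = self.gene_meta["is_mito"].to_numpy(dtype=bool)
        mito = np.asarray(self.counts[mito_mask].sum(axis=0)).ravel().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / np.maximum(totals, 1.0), 0.0)
        return frac

    def subset_cells(self, mask_or_ids) -> "UmiMatrix":
        if isinstance(mask_or_ids, (pd.Index, list)):
            idx = self.cell_ids.get_indexer(mask_or_ids)
            if (idx < 0).any():
                raise KeyError("unknown cell ids in subset")
        else:
            idx = np.flatnonzero(np.asarray(mask_or_ids))
        return UmiMatrix(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[idx],
            cell_meta=self.cell_meta.iloc[idx],
            gene_meta=self.gene_meta,
        )

    def labels(self, column: str = "cell_type") -> pd.Series:
        if column not in self.cell_meta.columns:
            raise KeyError(f"cell_meta has no {column!r} column")
        return self.cell_meta[column]


@dataclass
class NormalizedMatrix:
    """Library-size normalized, log-transformed expression (genes x cells).

    Values are ln(1 + count / cell_total * size_factor); a zero count is
    always a zero value. ``provenance`` records the source matrix and the
    normalization parameters.
    """

    values: sp.csr_matrix
    gene_ids: pd.Index
    cell_ids: pd.Index
    cell_meta: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = pd.Index(self.gene_ids, name="gene")
        self.cell_ids = pd.Index(self.cell_ids, name="cell")
        if self.values.data.size and not np.all(np.isfinite(self.values.data)):
            raise ValueError("normalized values must be finite")
        if self.values.data.size and self.values.data.min() < 0:
            raise ValueError("normalized values must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_vector(self, gene: str) -> np.ndarray:
        """Dense expression vector of one gene across cells."""
        i = self.gene_ids.get_loc(gene)
        return np.asarray(self.values[i].todense()).ravel()

    def labels(self, column: str = "cell_type") -> pd.Series:
        if column not in self.cell_meta.columns:
            raise KeyError(f"cell_meta has no {column!r} column")
        return self.cell_meta[column]
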