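"""Readers and writers for the plain-text formats the pipeline touches.

The on-disk unit for counts is the 10x-style MTX triplet: a MatrixMarket
coordinate file plus feature and barcode tables, with an optional per-cell
metadata table (cell_id, sample, condition, cell_type) alongside.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from popsc.communication import LigandReceptorPair
from popsc.enrichment import GeneSet
from popsc.matrix import UmiMatrix

log = logging.getLogger(__name__)

MATRIX_NAMES = ("matrix.mtx",)
FEATURE_NAMES = ("features.tsv", "genes.tsv")
BARCODE_NAMES = ("barcodes.tsv",)
METADATA_NAME = "metadata.tsv"


def _find_member(dir_path: Path, names: Sequence[str], what: str) -> Path:
    for name in names:
        p = dir_path / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{dir_path}: missing {what} file (looked for {', '.join(names)})")


def read_10x_mtx(dir_path: str | Path) -> UmiMatrix:
    """Read an MTX triplet directory into a validated :class:`UmiMatrix`.

    Orientation on disk is detected from the id-table lengths and normalized
    to genes x cells; a square matrix is taken as rows = genes by convention.
    If a ``metadata.tsv`` (cell_id, sample, condition[, cell_type]) is present
    it supplies the per-cell annotations; otherwise placeholder annotations
    (single sample, control condition) are filled in with a warning.
    """
    dir_path = Path(dir_path)
    mtx_path = _find_member(dir_path, MATRIX_NAMES, "matrix")
    feat_path = _find_member(dir_path, FEATURE_NAMES, "features")
    bc_path = _find_member(dir_path, BARCODE_NAMES, "barcodes")

    def _first_column(path: Path) -> np.ndarray:
        try:
            return pd.read_csv(path, sep="\t", header=None, dtype=str).iloc[:, 0].to_numpy()
        except pd.errors.EmptyDataError:
            return np.array([], dtype=str)

    mat = scipy.io.mmread(mtx_path)
    gene_ids = _first_column(feat_path)
    cell_ids = _first_column(bc_path)

    n_rows, n_cols = mat.shape
    if n_rows == len(gene_ids) and n_cols == len(cell_ids):
        pass
    elif n_rows == len(cell_ids) and n_cols == len(gene_ids) and n_rows != n_cols:
        mat = mat.T
    else:
        raise ValueError(
            f"{mtx_path}: matrix shape {mat.shape} matches neither "
            f"{len(gene_ids)} genes x {len(cell_ids)} cells nor its transpose"
        )

    data = np.asarray(mat.data if sp.issparse(mat) else mat)
    if data.size and not np.issubdtype(data.dtype, np.integer):
        if np.any(data != np.rint(data)):
            raise ValueError(f"{mtx_path}: non-integer count values")
        mat = mat.astype(np.int64)

    meta_path = dir_path / METADATA_NAME
    if meta_path.exists():
        cell_meta = pd.read_csv(meta_path, sep="\t", dtype={"cell_id": str}).set_index("cell_id")
        cell_meta.index.name = "cell"
    else:
        log.warning("%s: no metadata.tsv; filling placeholder sample/condition", dir_path)
        cell_meta = pd.DataFrame(
            {"sample": "S0", "condition": "control"}, index=pd.Index(cell_ids, name="cell")
        )
    return UmiMatrix(
        counts=sp.csr_matrix(mat),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_meta=cell_meta,
    )


def write_mtx(m: UmiMatrix, dir_path: str | Path) -> Path:
    """Write the MTX triplet plus metadata so that :func:`read_10x_mtx` round-trips.

    ``is_mito`` is not stored: it is re-derived from the symbol prefix on read.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        dir_path / "matrix.mtx", sp.coo_matrix(m.counts), field="integer"
    )
    pd.Series(m.gene_ids).to_csv(dir_path / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.cell_ids).to_csv(dir_path / "barcodes.tsv", sep="\t", header=False, index=False)
    meta = m.cell_meta.copy()
    meta.insert(0, "cell_id", m.cell_ids)
    meta.to_csv(dir_path / METADATA_NAME, sep="\t", index=False)
    return dir_path


def read_lr_pairs(path: str | Path) -> list[LigandReceptorPair]:
    """Read a ligand-receptor pair table (TSV with ``ligand``/``receptor`` columns).

    Pairs are deduplicated preserving order; self-pairs are retained.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "ligand" not in cols or "receptor" not in cols:
        raise ValueError(f"{path}: needs 'ligand' and 'receptor' columns, found {list(df.columns)}")
    if df.empty:
        raise ValueError(f"{path}: no ligand-receptor pairs")
    seen: dict[LigandReceptorPair, None] = {}
    for lig, rec in zip(df[cols["ligand"]], df[cols["receptor"]]):
        if not lig or not rec or pd.isna(lig) or pd.isna(rec):
            raise ValueError(f"{path}: empty ligand or receptor symbol")
        seen.setdefault(LigandReceptorPair(str(lig), str(rec)))
    return list(seen)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT gene-set file: one set per line (name, description, members)."""
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: malformed GMT line (<3 fields)")
        name, description, *genes = fields
        members = tuple(dict.fromkeys(g for g in genes if g))
        if not members:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
        sets.append(GeneSet(name=name, description=description, members=members))
    return sets


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a plain gene x replicate counts table (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if values.size and (np.any(values < 0) or np.any(values != np.rint(values))):
        raise ValueError(f"{path}: counts must be non-negative integers")
    return df.astype(np.int64)
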