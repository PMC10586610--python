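"""Readers, writers and the in-memory data model.

Single-cell counts arrive as a CellRanger-style MatrixMarket triplet
(matrix.mtx + genes.tsv + barcodes.tsv) and are held genes x cells in a
sparse CSR wrapper.  Per-cell RNAscope object tables and no-probe-control
tables are plain CSV; all pipeline outputs are TSV ('.' decimal, UTF-8,
no index column), written at full precision so a write/read round trip is
exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

SIGNAL_COLUMNS = [
    "cell_id",
    "section_id",
    "animal_id",
    "condition",
    "channel",
    "integral_intensity",
]
CONTROL_COLUMNS = ["cell_id", "channel", "max_intensity"]


class FormatError(ValueError):
    """A file does not satisfy its declared format contract."""


@dataclass
class CountMatrix:
    """UMI count matrix, genes x cells, non-negative integers (CSR)."""

    values: sparse.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sparse.csr_matrix(self.values)
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("count matrix contains negative entries")
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        folded = [g.casefold() for g in self.gene_ids]
        if len(set(folded)) != len(folded):
            raise FormatError("gene ids are not unique (case-insensitive)")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("cell ids are not unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class GeneSet:
    """A gene list with parental origin (MEG / PEG / unknown)."""

    table: pd.DataFrame  # columns: gene, origin

    def __post_init__(self) -> None:
        missing = {"gene", "origin"} - set(self.table.columns)
        if missing:
            raise FormatError(f"gene set table missing columns: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def __len__(self) -> int:
        return len(self.table)


def _read_lines(path: Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n").rstrip("\r") for line in fh if line.strip()]


def read_count_matrix(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> CountMatrix:
    """Read a MatrixMarket coordinate matrix with gene/barcode side files.

    The triplet body is sparse: entries absent from it are zero.  The gene
    and barcode files carry one record per line; only the first
    (tab-separated) field is used as the identifier.  Dimension mismatches
    between the MTX header and the side files raise :class:`FormatError`;
    negative or fractional matrix entries raise ``ValueError``.
    """
    mat = mmread(str(matrix_path))
    if mat.ndim != 2:
        raise FormatError("matrix file is not a 2-D MatrixMarket matrix")
    coo = sparse.coo_matrix(mat)
    if coo.nnz:
        if np.any(coo.data < 0):
            raise ValueError("matrix contains negative entries")
        if not np.all(np.equal(np.mod(coo.data, 1), 0)):
            raise ValueError("matrix contains non-integer entries")
    genes = [line.split("\t")[0] for line in _read_lines(Path(genes_path))]
    barcodes = [line.split("\t")[0] for line in _read_lines(Path(barcodes_path))]
    n_genes, n_cells = coo.shape
    if len(genes) != n_genes:
        raise FormatError(
            f"gene file has {len(genes)} records but matrix header declares "
            f"{n_genes} rows"
        )
    if len(barcodes) != n_cells:
        raise FormatError(
            f"barcode file has {len(barcodes)} records but matrix header "
            f"declares {n_cells} columns"
        )
    values = sparse.csr_matrix(coo.astype(np.int64))
    return CountMatrix(values=values, gene_ids=genes, cell_ids=barcodes)


def write_count_matrix(
    counts: CountMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write a CountMatrix back out as an MTX triplet (integer field)."""
    mmwrite(str(matrix_path), counts.values, field="integer")
    Path(genes_path).write_text(
        "".join(g + "\n" for g in counts.gene_ids), encoding="utf-8"
    )
    Path(barcodes_path).write_text(
        "".join(b + "\n" for b in counts.cell_ids), encoding="utf-8"
    )


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a cell_id -> identity table (CSV with header)."""
    ann = pd.read_csv(path, dtype=str)
    missing = {"cell_id", "identity"} - set(ann.columns)
    if missing:
        raise FormatError(f"annotation file missing columns: {sorted(missing)}")
    if ann["cell_id"].duplicated().any():
        dupes = ann.loc[ann["cell_id"].duplicated(), "cell_id"].tolist()
        raise FormatError(f"duplicate cell ids in annotation: {dupes[:5]}")
    return ann[["cell_id", "identity"]]


def read_gene_set(path: str | Path) -> GeneSet:
    """Read a gene-set CSV with columns gene[,origin].

    Duplicate symbols are collapsed (first occurrence wins) with a logged
    warning; a missing origin column defaults every gene to "unknown".
    """
    df = pd.read_csv(path, dtype=str)
    if "gene" not in df.columns:
        raise FormatError("gene set file has no 'gene' column")
    if df.empty:
        raise ValueError(f"gene set file {path} is empty")
    if "origin" not in df.columns:
        df["origin"] = "unknown"
    df["origin"] = df["origin"].fillna("unknown")
    bad = set(df["origin"]) - {"MEG", "PEG", "unknown"}
    if bad:
        raise ValueError(f"unknown parental origin labels: {sorted(bad)}")
    dup = df["gene"].str.casefold().duplicated()
    if dup.any():
        logger.warning(
            "gene set contains %d duplicate symbols; keeping first occurrence",
            int(dup.sum()),
        )
        df = df[~dup]
    return GeneSet(table=df[["gene", "origin"]].reset_index(drop=True))


def _read_csv_with(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    return df[list(required)]


def read_signal_table(path: str | Path) -> pd.DataFrame:
    """Read a per-cell fluorescent-object table (one row per object)."""
    df = _read_csv_with(path, SIGNAL_COLUMNS)
    if (df["integral_intensity"] < 0).any():
        raise ValueError(f"{path}: negative integral_intensity")
    return df


def read_control_table(path: str | Path) -> pd.DataFrame:
    """Read a no-probe-control table: one max intensity per (cell, channel)."""
    df = _read_csv_with(path, CONTROL_COLUMNS)
    if (df["max_intensity"] < 0).any():
        raise ValueError(f"{path}: negative max_intensity")
    if df.duplicated(subset=["cell_id", "channel"]).any():
        raise FormatError(f"{path}: duplicate (cell_id, channel) rows")
    return df


def write_table(records: pd.DataFrame, path: str | Path) -> Path:
    """Write a DataFrame as TSV (UTF-8, '.' decimal, no index).

    Floats are serialized with repr precision, so reading the file back
    reproduces the values bit-exactly.
    """
    path = Path(path)
    records.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", encoding="utf-8")


def match_genes(
    query: Sequence[str],
    universe: Sequence[str],
    symbol_map: dict[str, str] | None = None,
) -> tuple[list[str], list[str]]:
    """Case-insensitively match gene symbols against a dataset universe.

    ``symbol_map`` is an optional hook translating set symbols into the
    dataset's identifier space before matching (e.g. symbol -> Ensembl).
    Returns (matched universe identifiers, unmatched query symbols);
    unmatched genes are reported by the caller, not fatal — a probe absent
    from a dataset (e.g. a gene never sequenced) simply drops out.
    """
    lookup = {u.casefold(): u for u in universe}
    matched: list[str] = []
    unmatched: list[str] = []
    for g in query:
        name = symbol_map.get(g, g) if symbol_map else g
        hit = lookup.get(name.casefold())
        if hit is None:
            unmatched.append(g)
        else:
            matched.append(hit)
    return matched, unmatched
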