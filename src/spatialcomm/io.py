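"""Reading, aligning and writing of the standard inputs and outputs.

The three inputs — an expression matrix (MTX triplet or dense CSV/TSV),
per-cell 2-D coordinates and per-cell type labels — are string-keyed by
cell id and joined into a single :class:`SpatialExpressionDataset`. The
canonical cell order is the expression-file order; coordinates and labels
are reordered to match.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .exceptions import FormatError, ValidationError

FLOAT_FMT = "%.6g"


@dataclass
class SpatialExpressionDataset:
    """Expression, coordinates and cell-type labels aligned by cell id.

    Attributes
    ----------
    expression : (Z, W) ndarray
        Nonnegative expression values, cells x genes.
    coordinates : (Z, 2) ndarray
        Spatial coordinates in native units.
    labels : (Z,) ndarray of str
        Cell-type label per cell.
    cell_ids, gene_ids : ndarray of str
        Unique identifiers; row/column order is canonical.
    """

    expression: np.ndarray
    coordinates: np.ndarray
    labels: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    cell_types: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        z = self.expression.shape[0]
        if not (self.coordinates.shape[0] == self.labels.shape[0] == z == self.cell_ids.shape[0]):
            raise ValidationError(
                "expression, coordinates, labels and cell_ids disagree on cell count"
            )
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValidationError("coordinates must be a Z x 2 matrix")
        if self.expression.shape[1] != self.gene_ids.shape[0]:
            raise ValidationError("gene_ids length does not match expression columns")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell_ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene_ids")
        if np.any(self.expression < 0):
            raise ValidationError("expression contains negative entries")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError("coordinates contain non-finite values")
        # unique types in first-appearance order
        seen: dict = {}
        for lab in self.labels:
            if lab not in seen:
                seen[lab] = None
        self.cell_types = np.asarray(list(seen), dtype=object)

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def n_types(self) -> int:
        return len(self.cell_types)


def _read_name_file(path: Path) -> np.ndarray:
    names = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            # 10x-style genes.tsv may carry extra columns; first field is the id
            names.append(line.split("\t")[0])
    return np.asarray(names, dtype=object)


def load_expression(
    path: str | Path,
    format: str | None = None,
    orientation: str | None = None,
    genes_file: str | Path | None = None,
    cells_file: str | Path | None = None,
):
    """Load an expression matrix in cells x genes orientation.

    Parameters
    ----------
    path : file path
        ``.mtx`` triplet, or a dense CSV/TSV with a header row and an index
        column of cell ids (or gene ids, per *orientation*).
    format : {"mtx", "csv", "tsv"}, optional
        Inferred from the suffix when omitted.
    orientation : {"cells_x_genes", "genes_x_cells"}, optional
        On-disk orientation. Defaults to ``genes_x_cells`` for MTX (the
        common single-cell dialect) and ``cells_x_genes`` for CSV/TSV.
    genes_file, cells_file : paths, optional
        Companion name files for MTX; default to ``genes.tsv`` and
        ``barcodes.tsv`` next to the matrix.

    Returns
    -------
    expression : (Z, W) ndarray
    gene_ids, cell_ids : ndarray of str
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"mtx": "mtx", "csv": "csv", "tsv": "tsv", "txt": "tsv"}.get(suffix)
        if format is None:
            raise FormatError(f"cannot infer format from suffix of {path}")
    if format == "mtx":
        orientation = orientation or "genes_x_cells"
        genes_file = Path(genes_file) if genes_file else path.parent / "genes.tsv"
        cells_file = Path(cells_file) if cells_file else path.parent / "barcodes.tsv"
        for p in (genes_file, cells_file):
            if not p.exists():
                raise FileNotFoundError(f"companion name file missing: {p}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        genes = _read_name_file(genes_file)
        cells = _read_name_file(cells_file)
        if orientation == "genes_x_cells":
            row_names, col_names = genes, cells
        else:
            row_names, col_names = cells, genes
        if mat.shape[0] != len(row_names) or mat.shape[1] != len(col_names):
            raise FormatError(
                f"MTX declares shape {mat.shape} but name files provide "
                f"{len(row_names)} x {len(col_names)} names"
            )
        if orientation == "genes_x_cells":
            mat = mat.T
    elif format in ("csv", "tsv"):
        orientation = orientation or "cells_x_genes"
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if orientation == "genes_x_cells":
            df = df.T
        mat = df.to_numpy(dtype=float)
        cells = np.asarray(df.index.astype(str), dtype=object)
        genes = np.asarray(df.columns.astype(str), dtype=object)
    else:
        raise FormatError(f"unknown expression format {format!r}")
    if np.any(mat < 0):
        raise ValidationError("expression contains negative entries")
    return mat, genes, cells


def load_coordinates(path: str | Path) -> pd.DataFrame:
    """Load the (cell_id, x, y) coordinate table.

    Returns a DataFrame indexed by cell_id with float columns x, y.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    for col in ("cell_id", "x", "y"):
        if col not in df.columns:
            raise ValidationError(f"coordinates file missing column {col!r}")
    if df["cell_id"].duplicated().any():
        dups = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()[:10]
        raise ValidationError(f"duplicate cell_id in coordinates: {dups}")
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.loc[vals.isna(), "cell_id"].tolist()
        if bad:
            raise ValidationError(
                f"non-numeric {col} coordinate for cell(s) {bad[:10]}"
            )
        df[col] = vals
    return df.set_index("cell_id")[["x", "y"]]


def load_labels(path: str | Path) -> pd.Series:
    """Load the (cell_id, cell_type) label table as a Series keyed by cell_id."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise ValidationError(f"label file {path} is empty")
    for col in ("cell_id", "cell_type"):
        if col not in df.columns:
            raise ValidationError(f"label file missing column {col!r}")
    if df["cell_id"].duplicated().any():
        dups = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()[:10]
        raise ValidationError(f"duplicate cell_id in labels: {dups}")
    empty = df["cell_type"].isna() | (df["cell_type"].str.strip() == "")
    if empty.any():
        raise ValidationError(
            f"empty cell_type for cell(s) {df.loc[empty, 'cell_id'].tolist()[:10]}"
        )
    return df.set_index("cell_id")["cell_type"]


def assemble_dataset(
    expression: np.ndarray,
    gene_ids: Sequence[str],
    cell_ids: Sequence[str],
    coordinates: pd.DataFrame,
    labels: pd.Series,
) -> SpatialExpressionDataset:
    """Join the three inputs by cell id into one dataset.

    The expression row order is canonical; coordinates and labels are
    reordered to it. The three cell-id sets must be identical.
    """
    cell_ids = np.asarray(list(cell_ids), dtype=object)
    expr_set = set(cell_ids)
    for name, other in (("coordinates", set(coordinates.index)), ("labels", set(labels.index))):
        if other != expr_set:
            diff = sorted(expr_set.symmetric_difference(other))[:10]
            raise ValidationError(
                f"cell_id mismatch between expression and {name}; "
                f"symmetric difference (first 10): {diff}"
            )
    coords = coordinates.loc[cell_ids, ["x", "y"]].to_numpy(dtype=float)
    labs = labels.loc[cell_ids].to_numpy(dtype=object)
    return SpatialExpressionDataset(
        expression=np.asarray(expression, dtype=float),
        coordinates=coords,
        labels=labs,
        cell_ids=cell_ids,
        gene_ids=np.asarray(list(gene_ids), dtype=object),
    )


def load_dataset(
    expression_path: str | Path,
    coordinates_path: str | Path,
    labels_path: str | Path,
    format: str | None = None,
    orientation: str | None = None,
) -> SpatialExpressionDataset:
    """Convenience loader chaining the three readers and :func:`assemble_dataset`."""
    expr, genes, cells = load_expression(expression_path, format=format, orientation=orientation)
    coords = load_coordinates(coordinates_path)
    labels = load_labels(labels_path)
    return assemble_dataset(expr, genes, cells, coords, labels)


# ---------------------------------------------------------------------------
# writers

def write_matrix_tsv(
    matrix: np.ndarray,
    row_names: Sequence,
    col_names: Sequence,
    path: str | Path,
) -> None:
    df = pd.DataFrame(np.asarray(matrix), index=list(row_names), columns=list(col_names))
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="id")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def write_edge_list_csv(edges, path: str | Path) -> None:
    """Write (source, target, weight) rows; header always present."""
    with open(path, "w") as fh:
        fh.write("source,target,weight\n")
        for s, t, w in edges:
            fh.write(f"{s},{t},{FLOAT_FMT % w}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_mtx(
    expression: np.ndarray,
    gene_ids: Sequence[str],
    cell_ids: Sequence[str],
    out_dir: str | Path,
    orientation: str = "genes_x_cells",
) -> Path:
    """Write an MTX triplet (matrix.mtx + genes.tsv + barcodes.tsv)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mat = np.asarray(expression, dtype=float)
    if orientation == "genes_x_cells":
        mat = mat.T
    scipy.io.mmwrite(out_dir / "matrix.mtx", scipy.sparse.coo_matrix(mat))
    (out_dir / "genes.tsv").write_text("\n".join(map(str, gene_ids)) + "\n")
    (out_dir / "barcodes.tsv").write_text("\n".join(map(str, cell_ids)) + "\n")
    return out_dir / "matrix.mtx"
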