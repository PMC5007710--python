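"""Reading and writing of the delimited-text and GCT 1.2 matrix formats.

Internal orientation is fixed (response: lines x compounds; expression:
probes x lines) and readers adapt the file to it.  Missing cells in text
files may be spelled "" / "NA" / "NaN" / "n.s." (case-insensitive); any
other non-numeric cell is a hard error naming its coordinates.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CellLinePanel, DataError, DrugResponseMatrix, ExpressionMatrix

__all__ = [
    "MISSING_TOKENS",
    "read_matrix",
    "read_panel",
    "write_matrix",
    "write_sidecar",
]

MISSING_TOKENS = frozenset({"", "na", "nan", "n.s."})


def _parse_cell(raw: str, row_id: str, col_id: str) -> float:
    token = raw.strip()
    if token.lower() in MISSING_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise DataError(
            f"non-numeric cell {raw!r} at row {row_id!r}, column {col_id!r}"
        ) from None


def _read_delimited(path: Path, sep: str) -> pd.DataFrame:
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, index_col=0)
    data = {}
    for col in raw.columns:
        data[col] = [
            _parse_cell(v, r, col) for r, v in zip(raw.index, raw[col], strict=True)
        ]
    return pd.DataFrame(data, index=raw.index.astype(str))


def _read_gct(path: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse a GCT 1.2 file into (values probes x lines, annotations)."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise DataError(f"not a GCT 1.2 file (version line {version!r})")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise DataError("malformed GCT dimension line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        table = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    if list(table.columns[:2]) != ["Name", "Description"]:
        raise DataError("GCT header must start with Name<TAB>Description")
    if table.shape[0] != n_rows or table.shape[1] - 2 != n_cols:
        raise DataError(
            f"GCT declares {n_rows} x {n_cols} but file holds "
            f"{table.shape[0]} x {table.shape[1] - 2}"
        )
    table = table.set_index(table["Name"].astype(str))
    annotations = pd.DataFrame({"description": table["Description"]})
    annotations.index = table.index
    sample_cols = table.columns[2:]
    data = {
        col: [_parse_cell(v, r, col) for r, v in zip(table.index, table[col])]
        for col in sample_cols
    }
    values = pd.DataFrame(data, index=table.index)
    return values, annotations


def read_matrix(
    path,
    kind: str,
    *,
    sep: str = "\t",
    panel: CellLinePanel | None = None,
) -> DrugResponseMatrix | ExpressionMatrix:
    """Read a response or expression matrix from TSV/CSV (or GCT 1.2).

    Parameters
    ----------
    path
        Delimited text with one header row and a leading ID column; for
        ``kind="expression"`` a ``.gct`` file (GCT 1.2) is also accepted.
    kind
        ``"response"`` (lines x compounds of log10 IC50) or
        ``"expression"`` (probes x lines).
    sep
        Field separator for delimited text; ignored for GCT.
    """
    path = Path(path)
    if kind == "response":
        values = _read_delimited(path, sep)
        return DrugResponseMatrix(values, panel)
    if kind == "expression":
        if path.suffix.lower() == ".gct":
            values, annotations = _read_gct(path)
        else:
            values = _read_delimited(path, sep)
            annotations = pd.DataFrame(index=values.index)
        return ExpressionMatrix(values, annotations, panel)
    raise ValueError(f"kind must be 'response' or 'expression', got {kind!r}")


def read_panel(path, *, sep: str = "\t") -> CellLinePanel:
    """Read a two-column (line_id, panel) annotation table."""
    table = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, index_col=0)
    if table.shape[1] < 1:
        raise DataError("panel table needs a panel column next to the ID column")
    return CellLinePanel(table.iloc[:, 0].astype(str))


def write_matrix(matrix, path, *, sep: str = "\t", missing: str = "NA") -> None:
    """Write a matrix back to delimited text; missing cells become ``NA``.

    A written file read back with :func:`read_matrix` reproduces values,
    IDs and the missing mask exactly (floats are serialised with ``repr``
    precision).
    """
    values = matrix.values
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("id" + sep + sep.join(map(str, values.columns)) + "\n")
        arr = values.to_numpy(dtype=float)
        for row_id, row in zip(values.index, arr):
            cells = [missing if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(str(row_id) + sep + sep.join(cells) + "\n")


def write_gct(matrix: ExpressionMatrix, path) -> None:
    """Write an expression matrix as GCT 1.2 (Description from annotations)."""
    values = matrix.values
    desc = (
        matrix.annotations["description"]
        if "description" in matrix.annotations.columns
        else pd.Series("na", index=values.index)
    )
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{values.shape[0]}\t{values.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, values.columns)) + "\n")
        arr = values.to_numpy(dtype=float)
        for probe, d, row in zip(values.index, desc, arr):
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(f"{probe}\t{d}\t" + "\t".join(cells) + "\n")


def write_panel(panel: CellLinePanel, path, *, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(f"line_id{sep}panel\n")
        for line_id, label in panel.labels.items():
            fh.write(f"{line_id}{sep}{label}\n")


def write_sidecar(path, *, inputs=None, parameters=None, seed=None, extra=None) -> None:
    """Write the JSON run-metadata sidecar next to an output bundle."""
    meta = {
        "inputs": inputs or {},
        "parameters": parameters or {},
        "seed": seed,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        meta.update(extra)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
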