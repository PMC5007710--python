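"""Core domain types for panel-based drug-response / expression analysis.

The package works on two matrices measured over the same panel of tumor
cell lines (an NCI-60-style screen):

* a drug-response matrix of ``log10(IC50 [M])`` values, cell lines x
  compounds — more negative means more potent;
* an expression matrix of continuous mRNA values, probes x cell lines,
  with per-probe annotations (gene symbol, GenBank accession, clone id).

Both are thin dataclass wrappers around :class:`pandas.DataFrame`, with
``NaN`` encoding missing entries, so every downstream stage can rely on a
single validated orientation: response is lines-by-compounds, expression
is probes-by-lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellLinePanel",
    "DrugResponseMatrix",
    "ExpressionMatrix",
    "DataError",
    "AlignmentError",
    "align",
    "summarise_by_panel",
]

#: plausible range of log10 molar IC50 values; values outside trigger a warning
RESPONSE_RANGE = (-10.0, -2.0)


class DataError(ValueError):
    """Raised when an input matrix violates a structural invariant."""


class AlignmentError(ValueError):
    """Raised when two matrices cannot be aligned on their cell lines."""


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dupes = idx[idx.duplicated()].unique().tolist()
        raise DataError(f"duplicate {what}: {dupes}")
    if len(idx) == 0:
        raise DataError(f"empty {what} list")


@dataclass(frozen=True)
class CellLinePanel:
    """Ordered cell-line identifiers with one tumor-type label per line.

    Parameters
    ----------
    labels
        Series mapping line id -> tumor-type panel name (e.g. ``leukemia``,
        ``colon``); the NCI screen uses 9 such panels over 60 lines.
    """

    labels: pd.Series

    def __post_init__(self):
        _check_unique(self.labels.index, "cell-line id")
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()].tolist()
            raise DataError(f"lines without a panel label: {missing}")

    @property
    def line_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def panel_names(self) -> list[str]:
        return sorted(self.labels.unique())

    def subset(self, line_ids) -> "CellLinePanel":
        return CellLinePanel(self.labels.loc[list(line_ids)])

    def __len__(self) -> int:
        return len(self.labels)


def _validate_grid(values: pd.DataFrame, what: str) -> None:
    _check_unique(values.index, f"{what} row id")
    _check_unique(values.columns, f"{what} column id")
    arr = values.to_numpy(dtype=float)
    bad = np.isinf(arr)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataError(
            f"non-finite value at row {values.index[i]!r}, "
            f"column {values.columns[j]!r}"
        )


@dataclass
class DrugResponseMatrix:
    """Cell lines x compounds grid of log10 molar IC50 values.

    ``NaN`` entries are missing measurements; all analyses use
    pairwise-complete semantics over them.
    """

    values: pd.DataFrame  # lines x compounds
    panel: CellLinePanel | None = None

    def __post_init__(self):
        _validate_grid(self.values, "response")
        if self.panel is not None:
            extra = set(self.values.index) - set(self.panel.line_ids)
            if extra:
                raise DataError(f"lines absent from panel annotation: {sorted(extra)}")
        arr = self.values.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        lo, hi = RESPONSE_RANGE
        if finite.size and ((finite < lo).any() or (finite > hi).any()):
            warnings.warn(
                f"log10 IC50 values outside the plausible range [{lo}, {hi}]",
                stacklevel=2,
            )

    @property
    def line_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def profile(self, compound: str) -> pd.Series:
        """The log10 IC50 vector of one compound across the panel."""
        if compound not in self.values.columns:
            raise KeyError(f"unknown compound {compound!r}")
        return self.values[compound]

    def subset_lines(self, line_ids) -> "DrugResponseMatrix":
        panel = self.panel.subset(line_ids) if self.panel is not None else None
        return DrugResponseMatrix(self.values.loc[list(line_ids)], panel)


@dataclass
class ExpressionMatrix:
    """Probes x cell lines grid of continuous expression values.

    ``annotations`` carries pass-through probe metadata (``symbol``,
    ``genebank``, ``description`` ...) indexed like ``values``; the package
    never interprets it.
    """

    values: pd.DataFrame  # probes x lines
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)
    panel: CellLinePanel | None = None

    def __post_init__(self):
        _validate_grid(self.values, "expression")
        if self.annotations.empty:
            self.annotations = pd.DataFrame(index=self.values.index.copy())
        elif not self.annotations.index.equals(self.values.index):
            self.annotations = self.annotations.reindex(self.values.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def line_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def subset_lines(self, line_ids) -> "ExpressionMatrix":
        panel = self.panel.subset(line_ids) if self.panel is not None else None
        return ExpressionMatrix(self.values[list(line_ids)], self.annotations, panel)

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        ids = list(probe_ids)
        return ExpressionMatrix(
            self.values.loc[ids], self.annotations.loc[ids], self.panel
        )


def align(
    response: DrugResponseMatrix, expr: ExpressionMatrix, min_shared: int = 3
) -> tuple[DrugResponseMatrix, ExpressionMatrix, dict]:
    """Restrict both matrices to their shared cell lines, in matching order.

    The shared lines keep the response matrix's ordering.  Returns the two
    restricted matrices and a report of the lines dropped from each side.

    Raises
    ------
    AlignmentError
        If fewer than ``min_shared`` lines are common to both inputs.
    """
    resp_lines = list(response.line_ids)
    expr_lines = set(expr.line_ids)
    shared = [ln for ln in resp_lines if ln in expr_lines]
    if len(shared) < min_shared:
        raise AlignmentError(
            f"only {len(shared)} shared cell line(s); need at least {min_shared}"
        )
    report = {
        "n_shared": len(shared),
        "dropped_from_response": sorted(set(resp_lines) - set(shared)),
        "dropped_from_expression": sorted(expr_lines - set(shared)),
    }
    return response.subset_lines(shared), expr.subset_lines(shared), report


def summarise_by_panel(response: DrugResponseMatrix) -> pd.DataFrame:
    """Mean log10 IC50 per (tumor-type panel, compound).

    Returns a long-format frame with columns ``panel``, ``compound``,
    ``mean_log10_ic50`` and ``n`` (count of non-missing values behind each
    mean).  A panel with no measurements for a compound gets a missing
    mean with ``n = 0`` — never a zero.
    """
    if response.panel is None:
        raise DataError("response matrix carries no panel annotation")
    labels = response.panel.labels.loc[response.line_ids]
    rows = []
    for panel_name, sub in response.values.groupby(labels, sort=True):
        for compound in response.compound_ids:
            col = sub[compound]
            n = int(col.notna().sum())
            mean = float(col.mean()) if n else float("nan")
            rows.append(
                {
                    "panel": panel_name,
                    "compound": compound,
                    "mean_log10_ic50": mean,
                    "n": n,
                }
            )
    return pd.DataFrame(rows, columns=["panel", "compound", "mean_log10_ic50", "n"])
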