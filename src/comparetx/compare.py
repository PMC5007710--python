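"""COMPARE gene ranking: correlate every probe with one compound's potency.

The COMPARE procedure (NCI Developmental Therapeutics Program) ranks
each probe on the array by the Pearson correlation of its expression
profile across the cell-line panel with one compound's log10 IC50
profile.  Probes with positive r — high expression where IC50 is high,
i.e. where the compound is weak — form the *standard* (resistance-
associated) list; probes with negative r form the *reverse*
(sensitivity-associated) list.  Candidate genes are those with
``|r|`` above a symmetric cut-off, conventionally 0.6.

Ties in r are broken lexicographically by probe id so rankings are
reproducible; probes with too few complete pairs or constant expression
are excluded and reported, never scored as r = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import DataError, DrugResponseMatrix, ExpressionMatrix
from .correlation import DEFAULT_MIN_PAIRS, DEFAULT_THRESHOLD, pearson

__all__ = ["CompareResult", "compare", "filter_candidates"]


def _ranked(table: pd.DataFrame) -> pd.DataFrame:
    """Order by descending r, ties by probe id, and assign ranks 1..n."""
    out = table.copy()
    out["_probe"] = out.index
    out = out.sort_values(["r", "_probe"], ascending=[False, True], kind="mergesort")
    out = out.drop(columns="_probe")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass(frozen=True)
class CompareResult:
    """Ranked per-probe correlations against one compound's response.

    Attributes
    ----------
    compound_id : str
        The compound whose log10 IC50 profile was correlated.
    table : pandas.DataFrame
        One row per scored probe (index: probe id), columns ``r``, ``p``,
        ``n_pairs``, ``rank`` plus any pass-through annotation columns,
        ordered by rank.
    threshold : float
        The |r| cut-off used for the candidate lists.
    excluded : pandas.DataFrame
        Probes not scored (index: probe id, column ``reason``).
    """

    compound_id: str
    table: pd.DataFrame
    threshold: float
    excluded: pd.DataFrame

    @property
    def standard_list(self) -> pd.DataFrame:
        """Resistance-associated probes: r > +threshold, descending r."""
        return self.table[self.table["r"] > self.threshold]

    @property
    def reverse_list(self) -> pd.DataFrame:
        """Sensitivity-associated probes: r < -threshold, ascending r."""
        sub = self.table[self.table["r"] < -self.threshold]
        return sub.iloc[::-1]

    @property
    def candidate_ids(self) -> list[str]:
        """Probes past the cut-off, in ranking order (standard then reverse)."""
        return list(self.standard_list.index) + list(self.reverse_list.index[::-1])

    def list_label(self) -> pd.Series:
        """Per-probe membership: ``standard`` / ``reverse`` / ``none``."""
        lab = pd.Series("none", index=self.table.index, dtype=object)
        lab[self.table["r"] > self.threshold] = "standard"
        lab[self.table["r"] < -self.threshold] = "reverse"
        return lab

    @classmethod
    def from_coefficients(
        cls, compound_id: str, coefficients, threshold: float = DEFAULT_THRESHOLD
    ) -> "CompareResult":
        """Build a result from precomputed coefficients (no p-values).

        Useful for re-thresholding a published coefficient table where
        the underlying expression data is not available.
        """
        coeffs = pd.Series(coefficients, dtype=float)
        table = pd.DataFrame(
            {"r": coeffs, "p": np.nan, "n_pairs": 0}, index=coeffs.index
        )
        return cls(compound_id, _ranked(table), threshold, _no_exclusions())


def _no_exclusions() -> pd.DataFrame:
    return pd.DataFrame(columns=["reason"], index=pd.Index([], name="probe_id"))


def compare(
    expr: ExpressionMatrix,
    response: DrugResponseMatrix,
    compound: str,
    threshold: float = DEFAULT_THRESHOLD,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> CompareResult:
    """Rank every probe by correlation with one compound's log10 IC50 profile.

    Expression and response must already be aligned to the same cell
    lines in the same order (see :func:`comparetx.core.align`); each
    probe is correlated with the compound's profile over the pairs where
    both are measured.

    Raises
    ------
    KeyError
        If ``compound`` is not in the response matrix.
    DataError
        If no probe at all can be scored.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    if list(expr.line_ids) != list(response.line_ids):
        raise DataError("expression and response are not aligned; call align() first")
    y = response.profile(compound).to_numpy(dtype=float)
    expr_arr = expr.values.to_numpy(dtype=float)
    records, excluded = {}, {}
    for probe, row in zip(expr.probe_ids, expr_arr):
        res = pearson(row, y, min_pairs)
        if res.valid:
            records[probe] = (res.r, res.p, res.n_pairs)
        else:
            excluded[probe] = res.flag
    if not records:
        raise DataError(f"no probe could be scored against {compound!r}")
    table = pd.DataFrame.from_dict(
        records, orient="index", columns=["r", "p", "n_pairs"]
    )
    table.index.name = "probe_id"
    table["n_pairs"] = table["n_pairs"].astype(int)
    if not expr.annotations.empty:
        table = table.join(expr.annotations, how="left")
    excluded_df = pd.DataFrame(
        {"reason": pd.Series(excluded, dtype=object)},
    )
    excluded_df.index.name = "probe_id"
    return CompareResult(compound, _ranked(table), threshold, excluded_df)


def filter_candidates(result: CompareResult, threshold: float) -> CompareResult:
    """Re-threshold the candidate lists without recomputing correlations.

    Monotone by construction: a larger threshold yields candidate lists
    that are subsets of those from a smaller one.  Threshold 1 is allowed
    here (it empties both lists, since |r| <= 1).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return replace(result, threshold=threshold)
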