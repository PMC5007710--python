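"""Cluster-versus-sensitivity association: dichotomize, tabulate, chi-square.

Cell lines are split at a log10 IC50 cut-off (by default the median over
measured lines) into *sensitive* (strictly below the cut-off, i.e. the
drug is potent there) and *resistant* (at or above); lines without a
measurement are unclassified and excluded.  Membership in the flat
expression clusters is then crossed with the two response classes in a
k x 2 contingency table, tested with the plain chi-square statistic
``sum (O - E)^2 / E`` (no continuity correction) on ``(k - 1)`` degrees
of freedom against the upper tail of the chi-square distribution.

Low expected counts (< 5) are flagged rather than corrected: the
uncorrected statistic is the procedure this pipeline reproduces, and the
flags let a user judge the approximation.

The composed analysis — COMPARE gene selection, candidate clustering,
dichotomization, chi-square — is exposed both as the convenience
function :func:`predict_response` and as the
:class:`ResponseAssociationModel` / :class:`ResponseAssociationResults`
pair, which keeps every intermediate (ranked genes, dendrogram, flat
clusters, partition) on the results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import cluster as _cluster
from .compare import CompareResult, compare, filter_candidates
from .core import DataError, DrugResponseMatrix, ExpressionMatrix, align
from .correlation import DEFAULT_MIN_PAIRS, DEFAULT_THRESHOLD

__all__ = [
    "SensitivityPartition",
    "AssociationResult",
    "dichotomize",
    "contingency",
    "chi_square",
    "predict_response",
    "ResponseAssociationModel",
    "ResponseAssociationResults",
]

DEFAULT_K = 4

SENSITIVE = "sensitive"
RESISTANT = "resistant"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class SensitivityPartition:
    """Dichotomized response: per-line sensitive/resistant/unclassified.

    ``sensitive`` is strict (< cutoff); equality at the cut-off counts
    as resistant.
    """

    compound_id: str
    cutoff: float
    labels: pd.Series

    @property
    def n_classified(self) -> int:
        return int((self.labels != UNCLASSIFIED).sum())

    def classified(self) -> pd.Series:
        return self.labels[self.labels != UNCLASSIFIED]


def dichotomize(
    response: DrugResponseMatrix, compound: str, cutoff: float | None = None
) -> SensitivityPartition:
    """Split lines at a log10 IC50 cut-off for one compound.

    With ``cutoff=None`` the median of the non-missing values is used
    (midpoint convention for even counts).  Lines with a missing
    response are labelled unclassified.
    """
    values = response.profile(compound)
    observed = values.dropna()
    if observed.empty:
        raise DataError(f"all responses missing for compound {compound!r}")
    if cutoff is None:
        cutoff = float(np.median(observed.to_numpy()))
    labels = pd.Series(UNCLASSIFIED, index=values.index, dtype=object)
    labels[values < cutoff] = SENSITIVE
    labels[values >= cutoff] = RESISTANT
    return SensitivityPartition(compound, float(cutoff), labels)


@dataclass(frozen=True)
class AssociationResult:
    """k x 2 contingency table with its chi-square test.

    ``counts`` has one row per cluster and columns sensitive/resistant;
    ``expected`` the margin-derived expected frequencies;
    ``low_expected_cells`` lists (cluster, class) cells with expected
    count below 5; ``dropped_clusters`` any all-zero rows removed before
    testing.
    """

    counts: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    df: int
    p: float
    cutoff: float | None = None
    low_expected_cells: tuple = ()
    dropped_clusters: tuple = ()

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def table_with_margins(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["total"] = out.sum(axis=1)
        out.loc["total"] = out.sum(axis=0)
        return out


def contingency(
    partition: SensitivityPartition, assignment: _cluster.ClusterAssignment
) -> pd.DataFrame:
    """Cross-tabulate cluster membership against sensitive/resistant.

    Only lines present in both inputs and classified by the partition
    are counted; the grand total therefore reports how many lines the
    test actually uses (it may be below the panel size).
    """
    labels = partition.classified()
    shared = [ln for ln in assignment.labels.index if ln in labels.index]
    if not shared:
        raise DataError("no classified cell line shared between partition and clusters")
    clusters = assignment.labels.loc[shared]
    classes = labels.loc[shared]
    counts = pd.crosstab(clusters, classes)
    counts = counts.reindex(
        index=sorted(assignment.labels.unique()),
        columns=[SENSITIVE, RESISTANT],
        fill_value=0,
    )
    counts.index.name = "cluster"
    counts.columns.name = "response"
    return counts


def chi_square(counts: pd.DataFrame, cutoff: float | None = None) -> AssociationResult:
    """Pearson chi-square test of independence on a k x 2 count table.

    Expected counts come from the row/column margins; the statistic is
    ``sum (O - E)^2 / E`` with no continuity correction, referred to the
    chi-square distribution with ``(rows - 1) * (cols - 1)`` degrees of
    freedom.  All-zero rows are dropped with a warning (df adjusts);
    a table degenerate after dropping (a single row, or an all-zero
    column) is an error.
    """
    counts = counts.copy()
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise DataError("contingency counts must be non-negative integers")
    zero_rows = counts.index[arr.sum(axis=1) == 0]
    if len(zero_rows):
        warnings.warn(f"dropping empty cluster row(s): {list(zero_rows)}", stacklevel=2)
        counts = counts.drop(index=zero_rows)
        arr = counts.to_numpy(dtype=float)
    if counts.shape[0] < 2 or (arr.sum(axis=0) == 0).any():
        raise DataError("degenerate contingency table: need >=2 non-empty rows "
                        "and no all-zero response column")
    total = arr.sum()
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / total
    chi2 = float(((arr - expected) ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    low = tuple(
        (counts.index[i], counts.columns[j])
        for i, j in np.argwhere(expected < 5.0)
    )
    return AssociationResult(
        counts=counts.astype(int),
        expected=pd.DataFrame(expected, index=counts.index, columns=counts.columns),
        chi2=chi2,
        df=df,
        p=p,
        cutoff=cutoff,
        low_expected_cells=low,
        dropped_clusters=tuple(zero_rows),
    )


class ResponseAssociationModel:
    """Does the transcriptome predict response to one compound?

    The model couples an expression matrix and a drug-response matrix
    over a shared cell-line panel and, on :meth:`fit`, runs the full
    procedure: COMPARE-rank all probes against the compound's log10 IC50
    profile, keep candidates with ``|r|`` above ``threshold``, cluster
    the lines on the z-standardized candidate submatrix with complete
    linkage, cut ``k`` flat clusters, dichotomize the lines at the
    IC50 ``cutoff`` (median by default), and chi-square test cluster
    membership against sensitivity.

    Parameters
    ----------
    expression, response
        The two matrices; they are aligned on shared lines internally.
    compound
        Compound id in ``response`` to analyse.
    threshold
        COMPARE |r| cut-off for candidate genes (default 0.6).
    k
        Number of flat clusters (default 4).
    cutoff
        log10 molar sensitivity cut-off; ``None`` = median.
    min_pairs
        Minimum complete pairs per correlation.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        response: DrugResponseMatrix,
        compound: str,
        *,
        threshold: float = DEFAULT_THRESHOLD,
        k: int = DEFAULT_K,
        cutoff: float | None = None,
        min_pairs: int = DEFAULT_MIN_PAIRS,
    ):
        self.response, self.expression, self.alignment = align(response, expression)
        if compound not in self.response.values.columns:
            raise KeyError(f"unknown compound {compound!r}")
        self.compound = compound
        self.threshold = threshold
        self.k = k
        self.cutoff = cutoff
        self.min_pairs = min_pairs

    @classmethod
    def from_dataframes(
        cls,
        expression: pd.DataFrame,
        response: pd.DataFrame,
        compound: str,
        *,
        annotations: pd.DataFrame | None = None,
        **kwargs,
    ) -> "ResponseAssociationModel":
        """Build from raw DataFrames (expression probes x lines, response
        lines x compounds)."""
        expr = ExpressionMatrix(
            expression, annotations if annotations is not None else pd.DataFrame()
        )
        resp = DrugResponseMatrix(response)
        return cls(expr, resp, compound, **kwargs)

    def fit(self) -> "ResponseAssociationResults":
        """Run the full pipeline and return the results object."""
        cmp_result = compare(
            self.expression,
            self.response,
            self.compound,
            threshold=self.threshold,
            min_pairs=self.min_pairs,
        )
        candidates = cmp_result.candidate_ids
        if len(candidates) < 2:
            raise DataError(
                f"only {len(candidates)} candidate gene(s) at |r| > "
                f"{self.threshold}; expression profile undefined"
            )
        sub = self.expression.values.loc[candidates]  # probes x lines
        profiles = _cluster.standardize(sub.T)  # lines x genes, z per gene
        dendrogram = _cluster.complete_linkage(profiles)
        assignment = _cluster.cut(dendrogram, self.k)
        partition = dichotomize(self.response, self.compound, self.cutoff)
        counts = contingency(partition, assignment)
        association = chi_square(counts, cutoff=partition.cutoff)
        return ResponseAssociationResults(
            model=self,
            compare_result=cmp_result,
            candidate_ids=tuple(candidates),
            dendrogram=dendrogram,
            assignment=assignment,
            partition=partition,
            association=association,
        )


@dataclass(frozen=True)
class ResponseAssociationResults:
    """Fitted expression-predicts-response analysis with all intermediates."""

    model: ResponseAssociationModel
    compare_result: CompareResult
    candidate_ids: tuple
    dendrogram: _cluster.Dendrogram
    assignment: _cluster.ClusterAssignment
    partition: SensitivityPartition
    association: AssociationResult

    @property
    def chi2(self) -> float:
        return self.association.chi2

    @property
    def df(self) -> int:
        return self.association.df

    @property
    def pvalue(self) -> float:
        return self.association.p

    def summary(self) -> str:
        """Human-readable account of the fitted analysis."""
        m = self.model
        std = self.compare_result.standard_list
        rev = self.compare_result.reverse_list
        lines = [
            "Expression-cluster response association",
            "=" * 44,
            f"compound:            {m.compound}",
            f"cell lines analysed: {len(m.response.line_ids)}",
            f"probes scored:       {len(self.compare_result.table)}",
            f"COMPARE threshold:   |r| > {self.compare_result.threshold:g}",
            f"  standard list (resistance-assoc.): {len(std)}",
            f"  reverse list (sensitivity-assoc.): {len(rev)}",
            f"clusters (complete linkage): k = {self.assignment.k}",
            f"sensitivity cut-off: log10 IC50 = {self.partition.cutoff:g} "
            f"(sensitive < cutoff)",
            "",
            "Contingency (clusters x response):",
            self.association.table_with_margins().to_string(),
            "",
            f"chi2 = {self.chi2:.4f}, df = {self.df}, p = {self.pvalue:.4g}",
        ]
        if self.association.low_expected_cells:
            lines.append(
                f"note: {len(self.association.low_expected_cells)} cell(s) with "
                "expected count < 5; chi-square approximation may be rough"
            )
        return "\n".join(lines)


def predict_response(
    expression: ExpressionMatrix,
    response: DrugResponseMatrix,
    compound: str,
    threshold: float = DEFAULT_THRESHOLD,
    k: int = DEFAULT_K,
    cutoff: float | None = None,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> ResponseAssociationResults:
    """Convenience one-call composition of the full pipeline.

    Equivalent to ``ResponseAssociationModel(...).fit()``; see that class
    for the stages and parameters.
    """
    return ResponseAssociationModel(
        expression,
        response,
        compound,
        threshold=threshold,
        k=k,
        cutoff=cutoff,
        min_pairs=min_pairs,
    ).fit()
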