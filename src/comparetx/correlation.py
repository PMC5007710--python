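"""Pearson correlation kernel and compound cross-resistance matrices.

A single kernel, :func:`pearson`, backs every correlation in the package
(cross-resistance grids and COMPARE gene ranking alike).  It uses
pairwise-complete observations — a pair of values enters only when both
are measured — and reports the number of complete pairs next to every
coefficient, since per-pair n varies across a screen with missing data.

Cross-resistance between two compounds is the Pearson correlation of
their log10 IC50 profiles across the cell-line panel: lines resistant to
one compound tending to resist the other produces a positive r.  The
conventional call is ``|r| > 0.6`` with ``p <= 0.05`` (two-sided, from
the t distribution with n-2 degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DrugResponseMatrix

__all__ = [
    "CorrelationResult",
    "CrossResistanceMatrix",
    "pearson",
    "cross_resistance_matrix",
]

#: significance convention used throughout: p <= ALPHA is "significant"
ALPHA = 0.05
#: default |r| cut-off for calling cross-resistance
DEFAULT_THRESHOLD = 0.6
#: below this many complete pairs a correlation is not reported
DEFAULT_MIN_PAIRS = 3


@dataclass(frozen=True)
class CorrelationResult:
    """One Pearson coefficient with its two-sided p-value.

    ``flag`` is ``"ok"`` for a valid result, ``"insufficient_pairs"`` or
    ``"constant_input"`` for a missing one (``r`` and ``p`` are then NaN,
    never zero — a zero would silently read as "no correlation").
    """

    r: float
    p: float
    n_pairs: int
    flag: str = "ok"

    @property
    def valid(self) -> bool:
        return self.flag == "ok"

    @property
    def significant(self) -> bool:
        return self.valid and self.p <= ALPHA


def pearson(x, y, min_pairs: int = DEFAULT_MIN_PAIRS) -> CorrelationResult:
    """Product-moment correlation over pairwise-complete observations.

    Parameters
    ----------
    x, y
        Equal-length 1-D sequences; NaN marks missing.
    min_pairs
        Minimum number of complete pairs for a result to be reported.

    Returns
    -------
    CorrelationResult
        ``r`` in [-1, 1]; ``p`` two-sided from the t distribution with
        ``n_pairs - 2`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < max(min_pairs, 2):
        return CorrelationResult(np.nan, np.nan, n, "insufficient_pairs")
    xs, ys = x[mask], y[mask]
    dx = xs - xs.mean()
    dy = ys - ys.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        return CorrelationResult(np.nan, np.nan, n, "constant_input")
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r, p, n)


@dataclass
class CrossResistanceMatrix:
    """Grid of pairwise compound correlations over the cell-line panel.

    ``r``, ``p`` and ``n_pairs`` are aligned DataFrames (set_a rows x
    set_b columns); ``cross_resistant`` flags cells with ``|r| >
    threshold`` and ``p <= 0.05``.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n_pairs: pd.DataFrame
    threshold: float

    @property
    def cross_resistant(self) -> pd.DataFrame:
        return (self.r.abs() > self.threshold) & (self.p <= ALPHA)

    def to_long(self) -> pd.DataFrame:
        """Long-format table: compound_a, compound_b, r, p, n_pairs, flag."""
        rows = []
        for a in self.r.index:
            for b in self.r.columns:
                rows.append(
                    {
                        "compound_a": a,
                        "compound_b": b,
                        "r": self.r.at[a, b],
                        "p": self.p.at[a, b],
                        "n_pairs": self.n_pairs.at[a, b],
                        "cross_resistant": bool(self.cross_resistant.at[a, b]),
                    }
                )
        return pd.DataFrame(rows)

    def render(self) -> pd.DataFrame:
        """Wide string render: "r / p", with "n.s." for p > 0.05."""
        out = pd.DataFrame(index=self.r.index, columns=self.r.columns, dtype=object)
        for a in self.r.index:
            for b in self.r.columns:
                r, p = self.r.at[a, b], self.p.at[a, b]
                if np.isnan(r):
                    out.at[a, b] = "NA"
                elif p > ALPHA:
                    out.at[a, b] = f"{r:.3f} / n.s."
                else:
                    out.at[a, b] = f"{r:.3f} / {p:.3g}"
        return out


def cross_resistance_matrix(
    response: DrugResponseMatrix,
    set_a=None,
    set_b=None,
    threshold: float = DEFAULT_THRESHOLD,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> CrossResistanceMatrix:
    """Correlate every compound in ``set_a`` with every compound in ``set_b``.

    Defaults to the full all-versus-all grid, which is symmetric with a
    unit diagonal.  Each cell uses the complete pairs of that particular
    compound pair, so ``n_pairs`` may differ across cells.
    """
    compounds = list(response.compound_ids)
    set_a = compounds if set_a is None else list(set_a)
    set_b = compounds if set_b is None else list(set_b)
    for cid in set_a + set_b:
        if cid not in response.values.columns:
            raise KeyError(f"unknown compound {cid!r}")
    r = pd.DataFrame(np.nan, index=set_a, columns=set_b)
    p = pd.DataFrame(np.nan, index=set_a, columns=set_b)
    n = pd.DataFrame(0, index=set_a, columns=set_b, dtype=int)
    cache: dict[tuple[str, str], CorrelationResult] = {}
    for a in set_a:
        xa = response.values[a].to_numpy(dtype=float)
        for b in set_b:
            key = (a, b) if a <= b else (b, a)
            res = cache.get(key)
            if res is None:
                res = pearson(xa, response.values[b].to_numpy(dtype=float), min_pairs)
                cache[key] = res
            r.at[a, b], p.at[a, b] = res.r, res.p
            n.at[a, b] = res.n_pairs
    return CrossResistanceMatrix(r, p, n, threshold)
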