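"""Synthetic drug-screen data with the structure the analysis assumes.

The generator emulates an NCI-60-style screen: ~60 cell lines over 9
tumor-type panels, log10 IC50 values centred in [-8, -4], and an
expression matrix with a small planted set of response-correlated genes
in a large independent background.

Drug response follows a one-factor cross-resistance model: each line c
has a latent sensitivity factor ``f_c ~ N(0, 1)`` and each compound d in
family F has

    log10IC50(c, d) = mu_d + lambda_F * f_c + eps,   eps ~ N(0, sigma^2)

so any two compounds in the same family share the factor and correlate
with the intraclass correlation ``lambda^2 / (lambda^2 + sigma^2)``,
while compounds from different families are independent.  This is the
simplest mechanism producing the block-correlation pattern a
cross-resistance table shows.

Planted expression follows ``expr(g, c) = s * rho * y_c +
sqrt(1 - rho^2) * e`` with ``y`` the standardized target-compound
response and ``s`` the sign, giving ``corr(expr, y)`` expectation
``s * rho``; background genes are independent standard normals.  All
noise is Gaussian, which keeps the downstream Pearson machinery exact
and closed-form checks available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import CellLinePanel, DrugResponseMatrix, ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "simulate_response",
    "simulate_expression",
    "simulate_dataset",
    "inject_missing",
    "TUMOR_PANELS",
]

#: the nine tumor types of the NCI screen, assigned round-robin to lines
TUMOR_PANELS = (
    "leukemia",
    "melanoma",
    "lung",
    "colon",
    "cns",
    "ovarian",
    "renal",
    "prostate",
    "breast",
)

#: family loading / noise sd giving within-family correlation 0.7 at unit
#: total variance: lambda^2 / (lambda^2 + sigma^2) = 0.7
_LAMBDA_07 = math.sqrt(0.7)
_SIGMA_07 = math.sqrt(0.3)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic screen.

    ``families`` lists (name, n_compounds, factor loading); the default
    mirrors the screen shape this package targets — 8 query compounds in
    one cross-resistant family plus 3 alkylating-agent-style reference
    drugs in another, both at within-family correlation 0.7.
    ``planted_genes`` lists (sign, rho) with sign in {+1, -1} and target
    correlation rho in (0, 1); the default plants 10 positive and 10
    negative genes at rho 0.8 among 2000 background genes.
    """

    seed: int
    n_lines: int = 60
    n_panels: int = 9
    families: tuple = (
        ("withanolide", 8, _LAMBDA_07),
        ("nitrosourea", 3, _LAMBDA_07),
    )
    noise_sd: float = _SIGMA_07
    mu_range: tuple = (-7.0, -5.0)
    n_background_genes: int = 2000
    planted_genes: tuple = tuple([(+1, 0.8)] * 10 + [(-1, 0.8)] * 10)
    panel_effect_sd: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_lines < 1 or self.n_panels < 1 or self.n_background_genes < 0:
            raise ValueError("counts must be positive")
        if not self.families:
            raise ValueError("need at least one compound family")
        for name, n_compounds, lam in self.families:
            if n_compounds < 1:
                raise ValueError(f"family {name!r} needs >= 1 compound")
            if lam == 0.0 and self.noise_sd == 0.0:
                raise ValueError(
                    f"family {name!r}: zero loading and zero noise imply "
                    "a constant response"
                )
        for sign, rho in self.planted_genes:
            if sign not in (+1, -1):
                raise ValueError(f"planted sign must be +1 or -1, got {sign}")
            if not 0.0 < rho < 1.0:
                raise ValueError(f"planted rho must be in (0, 1), got {rho}")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ValueError(f"missing rate must be in [0, 0.5]")

    @property
    def compound_ids(self) -> list[str]:
        return [
            f"{name}_{i + 1}"
            for name, n_compounds, _lam in self.families
            for i in range(n_compounds)
        ]

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load from a flat TOML file mirroring the field names."""
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        if "families" in raw:
            raw["families"] = tuple(tuple(f) for f in raw["families"])
        if "planted_genes" in raw:
            raw["planted_genes"] = tuple(tuple(g) for g in raw["planted_genes"])
        if "mu_range" in raw:
            raw["mu_range"] = tuple(raw["mu_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_lines": self.n_lines,
            "n_panels": self.n_panels,
            "families": [list(f) for f in self.families],
            "noise_sd": self.noise_sd,
            "mu_range": list(self.mu_range),
            "n_background_genes": self.n_background_genes,
            "planted_genes": [list(g) for g in self.planted_genes],
            "panel_effect_sd": self.panel_effect_sd,
            "missing_rate": self.missing_rate,
        }


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def _panel(config: SimulationConfig) -> CellLinePanel:
    width = max(2, len(str(config.n_lines)))
    line_ids = [f"CL{i + 1:0{width}d}" for i in range(config.n_lines)]
    labels = [
        TUMOR_PANELS[i % config.n_panels]
        if config.n_panels <= len(TUMOR_PANELS)
        else f"panel_{i % config.n_panels + 1}"
        for i in range(config.n_lines)
    ]
    return CellLinePanel(pd.Series(labels, index=line_ids, name="panel"))


def simulate_response(config: SimulationConfig) -> DrugResponseMatrix:
    """Draw the lines x compounds log10 IC50 matrix from the factor model."""
    rng = _rng(config, 0)
    panel = _panel(config)
    n = config.n_lines
    columns = {}
    factors = {
        name: rng.standard_normal(n) for name, _nc, _lam in config.families
    }
    panel_names = sorted(set(panel.labels))
    panel_shift = (
        dict(zip(panel_names, rng.normal(0.0, config.panel_effect_sd, len(panel_names))))
        if config.panel_effect_sd > 0
        else {}
    )
    base = (
        np.array([panel_shift[p] for p in panel.labels])
        if panel_shift
        else np.zeros(n)
    )
    for name, n_compounds, lam in config.families:
        f = factors[name]
        for i in range(n_compounds):
            mu = rng.uniform(*config.mu_range)
            eps = rng.normal(0.0, config.noise_sd, n)
            columns[f"{name}_{i + 1}"] = mu + base + lam * f + eps
    values = pd.DataFrame(columns, index=panel.line_ids)
    matrix = DrugResponseMatrix(values, panel)
    if config.missing_rate > 0:
        matrix = inject_missing(matrix, config.missing_rate, config.seed + 101)
    return matrix


def simulate_expression(
    config: SimulationConfig,
    response: DrugResponseMatrix,
    target_compound: str,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw the probes x lines expression matrix with planted correlates.

    Returns the matrix and a truth table (probe_id, sign, rho) of the
    planted genes.  Lines with a missing target response contribute only
    noise to planted genes (their signal term is the mean, 0).
    """
    y_raw = response.profile(target_compound)
    n_missing = int(y_raw.isna().sum())
    if n_missing > 0.5 * len(y_raw):
        raise ValueError(
            f"target compound {target_compound!r} has >50% missing response"
        )
    rng = _rng(config, 1)
    observed = y_raw.dropna()
    y = (y_raw - observed.mean()) / observed.std(ddof=1)
    y = y.fillna(0.0).to_numpy()
    n = len(y)

    n_planted = len(config.planted_genes)
    width = max(2, len(str(max(n_planted, config.n_background_genes))))
    rows, truth = {}, []
    for g, (sign, rho) in enumerate(config.planted_genes):
        probe = f"planted_{g + 1:0{width}d}"
        noise = rng.standard_normal(n)
        rows[probe] = sign * rho * y + math.sqrt(1.0 - rho * rho) * noise
        truth.append({"probe_id": probe, "sign": sign, "rho": rho})
    background = rng.standard_normal((config.n_background_genes, n))
    for g in range(config.n_background_genes):
        rows[f"bg_{g + 1:0{width}d}"] = background[g]

    values = pd.DataFrame.from_dict(rows, orient="index", columns=list(y_raw.index))
    annotations = pd.DataFrame(
        {
            "symbol": [p.upper().replace("_", "") for p in values.index],
            "genebank": [f"SYN{i + 1:06d}" for i in range(len(values))],
        },
        index=values.index,
    )
    matrix = ExpressionMatrix(values, annotations, response.panel)
    if config.missing_rate > 0:
        matrix = inject_missing(matrix, config.missing_rate, config.seed + 202)
    truth_table = pd.DataFrame(truth, columns=["probe_id", "sign", "rho"])
    return matrix, truth_table


def simulate_dataset(
    config: SimulationConfig, target_compound: str | None = None
) -> tuple[DrugResponseMatrix, ExpressionMatrix, pd.DataFrame]:
    """Response + expression + planted-gene truth table in one call.

    ``target_compound`` defaults to the first compound of the first
    family.
    """
    response = simulate_response(config)
    if target_compound is None:
        target_compound = response.compound_ids[0]
    expression, truth = simulate_expression(config, response, target_compound)
    return response, expression, truth


def inject_missing(matrix, rate: float, seed: int):
    """Mask each cell independently with probability ``rate``.

    Accepts either matrix type and returns the same type; reproducible
    by ``seed``.
    """
    if not 0.0 <= rate <= 0.5:
        raise ValueError(f"missing rate must be in [0, 0.5], got {rate}")
    if rate == 0.0:
        return matrix
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    mask = rng.random(values.shape) < rate
    values = values.mask(pd.DataFrame(mask, index=values.index, columns=values.columns))
    return replace(matrix, values=values)
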