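"""End-to-end orchestration: run every stage and write the report bundle.

`run_all` executes, in order, the per-panel potency summary, the
cross-resistance grid, COMPARE ranking, candidate clustering and the
cluster-versus-sensitivity test, writing each stage's table as TSV plus
a JSON sidecar that suffices to re-run the pipeline identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

from . import io as _io
from .association import ResponseAssociationModel
from .compare import compare
from .core import DataError, align, summarise_by_panel
from .correlation import cross_resistance_matrix
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger("comparetx")


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: either file inputs or a simulation, never both."""

    out_dir: str
    response_path: str | None = None
    expression_path: str | None = None
    panel_path: str | None = None
    simulation: SimulationConfig | None = None
    compound: str | None = None
    threshold: float = 0.6
    k: int = 4
    cutoff: float | None = None  # None = median
    seed: int | None = None

    def __post_init__(self):
        have_paths = self.response_path is not None or self.expression_path is not None
        if have_paths and self.simulation is not None:
            raise ValueError("provide input paths or a simulation config, not both")
        if not have_paths and self.simulation is None:
            raise ValueError("provide input paths or a simulation config")
        if have_paths and (self.response_path is None or self.expression_path is None):
            raise ValueError("both response and expression paths are required")

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "response_path": self.response_path,
            "expression_path": self.expression_path,
            "panel_path": self.panel_path,
            "simulation": self.simulation.to_dict() if self.simulation else None,
            "compound": self.compound,
            "threshold": self.threshold,
            "k": self.k,
            "cutoff": self.cutoff,
            "seed": self.seed,
        }


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        response, expression, truth = simulate_dataset(
            config.simulation, config.compound
        )
        return response, expression, truth
    panel = _io.read_panel(config.panel_path) if config.panel_path else None
    response = _io.read_matrix(config.response_path, "response", panel=panel)
    expression = _io.read_matrix(config.expression_path, "expression", panel=panel)
    return response, expression, None


def run_all(config: RunConfig) -> dict:
    """Run the full workflow; returns a bundle of results and output paths.

    On a stage failure the bundle written so far is kept, a ``FAILED``
    marker names the stage, and the error propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"out_dir": str(out)}
    stage = "load_inputs"
    t0 = time.perf_counter()
    try:
        response, expression, truth = _load_inputs(config)
        if truth is not None:
            truth.to_csv(out / "planted_truth.tsv", sep="\t", index=False)
        compound = config.compound or response.compound_ids[0]
        log.info(
            "inputs: %d lines x %d compounds response, %d probes expression",
            len(response.line_ids),
            len(response.compound_ids),
            len(expression.probe_ids),
        )

        stage = "summarise_by_panel"
        if response.panel is not None:
            summary = summarise_by_panel(response)
            summary.to_csv(out / "panel_summary.tsv", sep="\t", index=False)
            bundle["panel_summary"] = summary
            log.info("panel summary: %d (panel, compound) means", len(summary))

        stage = "cross_resistance"
        xres = cross_resistance_matrix(response, threshold=config.threshold)
        xres.to_long().to_csv(out / "cross_resistance.tsv", sep="\t", index=False)
        xres.render().to_csv(out / "cross_resistance_matrix.tsv", sep="\t")
        bundle["cross_resistance"] = xres
        log.info("cross-resistance grid: %d x %d", *xres.r.shape)

        stage = "compare"
        response_a, expression_a, report = align(response, expression)
        cmp_result = compare(
            expression_a, response_a, compound, threshold=config.threshold
        )
        cmp_table = cmp_result.table.copy()
        cmp_table["list"] = cmp_result.list_label()
        cmp_table.to_csv(out / "compare.tsv", sep="\t")
        bundle["compare"] = cmp_result
        log.info(
            "COMPARE vs %s: %d probes scored, %d candidates at |r| > %g",
            compound,
            len(cmp_result.table),
            len(cmp_result.candidate_ids),
            config.threshold,
        )

        stage = "predict_response"
        model = ResponseAssociationModel(
            expression,
            response,
            compound,
            threshold=config.threshold,
            k=config.k,
            cutoff=config.cutoff,
        )
        results = model.fit()
        bundle["results"] = results
        results.dendrogram.to_merge_table().to_csv(
            out / "dendrogram_merges.tsv", sep="\t", index=False
        )
        (out / "dendrogram.nwk").write_text(results.dendrogram.to_newick() + "\n")
        results.assignment.labels.rename_axis("line_id").to_csv(
            out / "clusters.tsv", sep="\t"
        )
        results.partition.labels.rename_axis("line_id").rename("response").to_csv(
            out / "partition.tsv", sep="\t"
        )
        results.association.table_with_margins().to_csv(
            out / "contingency.tsv", sep="\t"
        )
        assoc = {
            "compound": compound,
            "chi2": results.chi2,
            "df": results.df,
            "p": results.pvalue,
            "cutoff": results.partition.cutoff,
            "k": results.assignment.k,
            "n_candidates": len(results.candidate_ids),
            "n_classified": results.partition.n_classified,
            "low_expected_cells": [
                list(map(str, cell))
                for cell in results.association.low_expected_cells
            ],
        }
        with open(out / "association.json", "w") as fh:
            json.dump(assoc, fh, indent=2)
            fh.write("\n")
        bundle["association"] = assoc
        log.info(
            "association: chi2 = %.4f, df = %d, p = %.4g",
            results.chi2,
            results.df,
            results.pvalue,
        )

        stage = "sidecar"
        _io.write_sidecar(
            out / "run_metadata.json",
            inputs={
                "response": config.response_path,
                "expression": config.expression_path,
                "panel": config.panel_path,
            },
            parameters=config.to_dict(),
            seed=config.seed
            if config.seed is not None
            else (config.simulation.seed if config.simulation else None),
        )
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc
    log.info("run complete in %.2f s", time.perf_counter() - t0)
    return bundle
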