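"""End-to-end orchestration: simulate -> summarize -> normalize -> score."""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import pandas as pd

from . import io as mio
from .design import ArrayDesign, build_design, read_design, write_design
from .errors import MemaError
from .normalize import normalize_pipeline, scree_table
from .scoring import ecm_modifier_rank, exclude_conditions, rescue_score, summarize_mep
from .simulate import SimulationParams, simulate_experiment
from .spots import filter_nuclei, gate_edu, summarize_spots

log = logging.getLogger("memascreen")


class StageError(MemaError):
    """Wraps a failure with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def analyze_experiment(
    cells: pd.DataFrame,
    design: ArrayDesign,
    *,
    k: int = 3,
    span: float = 0.5,
    degree: int = 1,
    signals: list[str] | None = None,
    gate_scope: str = "array_id",
    normalize: bool = True,
):
    """Library entry point: per-cell table to normalized spots, MEP summary
    and ligand rescue scores.

    Returns a dict with keys ``spots`` (normalized spot table), ``mep``
    (MEP summary), ``hits`` (ligand rescue table), ``gate_report``, and
    ``models``.  ``normalize=False`` skips RUV/LOESS (ablation mode).
    """
    kept, excluded = filter_nuclei(cells)
    gated, gate_report = gate_edu(kept, scope=gate_scope)
    spots = summarize_spots(gated, design, excluded)
    models = {}
    if normalize:
        spots, models = normalize_pipeline(
            spots, signals=signals, k=k, span=span, degree=degree)
    mep = summarize_mep(spots)
    hits = rescue_score(
        spots, treatment=design.treatments[1], control_treatment=design.vehicle_treatment)
    return {"spots": spots, "mep": mep, "hits": hits,
            "gate_report": gate_report, "models": models}


def run_pipeline(config: mio.PipelineConfig) -> dict[str, Path]:
    """Execute the configured pipeline and write the artifact bundle.

    Stages: design/simulate (or load cells) -> summarize -> normalize ->
    score.  Every table is written as commented CSV; the resolved config and
    a run log accompany the outputs.  Raises :class:`StageError` on failure.
    """
    if not logging.getLogger().handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                            format="%(name)s %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.snapshot(out / "config.yaml")
    artifacts: dict[str, Path] = {"config": out / "config.yaml"}
    meta = {"seed": config.seed}

    stage = "design"
    try:
        if config.design_dir:
            design = read_design(config.design_dir)
        else:
            design = build_design(
                config.n_ecm, config.n_ligand, config.replicate_target,
                config.wells_per_plate, config.seed,
                n_rows=config.n_rows, n_cols=config.n_cols,
                cell_lines=config.cell_lines, treatments=config.treatments,
                dropout_rate=config.dropout_rate)
        write_design(design, out)
        artifacts["design"] = out / "design.csv"
        log.info("[design] %d arrays, %d printed spots/array",
                 len(design.wells), len(design.layout))

        stage = "simulate"
        if config.cells_path:
            cells = mio.read_table(config.cells_path, mio.CELL_SCHEMA, mio.CELL_OPTIONAL)
        elif config.simulate:
            params = SimulationParams(seed=config.seed)
            cells = simulate_experiment(design, params)
            mio.write_table(cells, out / "cells.csv", meta)
            artifacts["cells"] = out / "cells.csv"
        else:
            raise mio.ConfigError("no cells_path given and simulate disabled")
        log.info("[simulate] %d cells", len(cells))

        stage = "summarize"
        kept, excluded = filter_nuclei(cells, config.min_area, config.max_area)
        gated, gate_report = gate_edu(kept, scope=config.gate_scope)
        spots = summarize_spots(gated, design, excluded)
        mio.write_table(spots, out / "spots.csv", meta)
        mio.write_table(gate_report, out / "gate_report.csv", meta)
        artifacts["spots"] = out / "spots.csv"
        artifacts["gate_report"] = out / "gate_report.csv"
        log.info("[summarize] %d spots, %d cells kept, %d excluded",
                 len(spots), len(kept), len(excluded))

        stage = "normalize"
        norm_spots, models = normalize_pipeline(
            spots, signals=config.signals, k=config.k_unwanted,
            span=config.loess_span, degree=config.loess_degree)
        nmeta = {**meta, "k": config.k_unwanted, "span": config.loess_span}
        mio.write_table(norm_spots, out / "spots_normalized.csv", nmeta)
        mio.write_table(scree_table(models), out / "scree.csv", nmeta)
        artifacts["spots_normalized"] = out / "spots_normalized.csv"
        artifacts["scree"] = out / "scree.csv"
        log.info("[normalize] %d signals normalized (k=%d, span=%.2f)",
                 len(models), config.k_unwanted, config.loess_span)

        stage = "score"
        mep = summarize_mep(norm_spots)
        if config.exclusions:
            mep, audit = exclude_conditions(
                mep, [tuple(e) for e in config.exclusions])
            mio.write_table(audit, out / "exclusion_audit.csv", meta)
            artifacts["exclusion_audit"] = out / "exclusion_audit.csv"
        drug = config.drug_treatment or config.treatments[1]
        hits = rescue_score(norm_spots, reference_ligand=config.reference_ligand,
                            treatment=drug, control_treatment=config.treatments[0])
        top_ligand = hits.sort_values(["cell_line", "rank"]).groupby("cell_line").head(1)
        ecm_frames = [
            ecm_modifier_rank(mep, lig, treatment=drug, cell_line=cl)
            .assign(ligand=lig)
            for cl, lig in zip(top_ligand["cell_line"], top_ligand["ligand"])
        ]
        mio.write_table(mep, out / "mep_summary.csv", meta)
        mio.write_table(hits, out / "hit_table.csv", meta)
        mio.write_table(pd.concat(ecm_frames, ignore_index=True),
                        out / "ecm_modifiers.csv", meta)
        artifacts["mep_summary"] = out / "mep_summary.csv"
        artifacts["hit_table"] = out / "hit_table.csv"
        artifacts["ecm_modifiers"] = out / "ecm_modifiers.csv"
        log.info("[score] %d MEPs, top ligand per cell line: %s",
                 len(mep), dict(zip(top_ligand["cell_line"], top_ligand["ligand"])))
    except Exception as e:  # annotate failures with the stage name
        raise StageError(stage, e) from e
    return artifacts
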