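"""End-to-end driver: simulate/load -> segment -> quantify -> stats -> fits.

``run_pipeline`` is deterministic given (config, seed) and writes a stable
artifact set: per-cell CSV, per-well CSV, hit list CSV, plate QC JSON, fit
JSON, the resolved configuration and a run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dose_response, io, screening
from .config import RunConfig
from .core import ImagePair, PlateLayout
from .quantification import WellSummary, analyze_well, summarize_well
from .synthetic import (
    NoiseSpec,
    StateDistributions,
    TranslocationDoseModel,
    WellSpec,
    render_plate,
)

logger = logging.getLogger(__name__)

CELL_COLUMNS = [
    "well", "label", "nuc_mean_gfp", "cyt_mean_gfp", "nc_ratio",
    "nuclear_vertices", "translocated",
]
WELL_COLUMNS = [
    "well", "role", "compound", "conc", "conc_unit", "n_cells",
    "pct_translocated", "mean_vertices", "activity_pct", "qc_flags",
]


@dataclass
class PipelineResult:
    cells: pd.DataFrame
    wells: pd.DataFrame
    hits: pd.DataFrame
    qc: dict
    fits: dict
    summaries: dict[str, WellSummary] = field(default_factory=dict)


def _simulate(config: RunConfig, out_dir: Path) -> tuple[PlateLayout, dict[str, ImagePair]]:
    sim = config.simulate
    series = dose_response.make_dilution_series(
        sim.series.top_conc, sim.series.fold, sim.series.n_points, sim.series.unit
    )
    layout = PlateLayout.dose_response(
        sim.compound,
        series.concentrations,
        conc_unit=series.unit,
        n_negative=sim.n_negative,
        n_positive=sim.n_positive,
        replicates=sim.replicates,
    )
    model = TranslocationDoseModel(
        bottom_fraction=sim.dose_model.bottom_fraction,
        top_fraction=sim.dose_model.top_fraction,
        ec50=sim.dose_model.ec50_uM,
        hill=sim.dose_model.hill,
    )
    spec = WellSpec(
        n_cells=sim.cells_per_well,
        image_shape=tuple(sim.image_shape),
        noise=NoiseSpec(
            background_level=sim.noise.background_level,
            read_noise_sd=sim.noise.read_noise_sd,
            shot_noise=sim.noise.shot_noise,
        ),
    )
    states = StateDistributions(
        median_resting=sim.states.median_resting,
        median_translocated=sim.states.median_translocated,
        sd_log=sim.states.sd_log,
    )
    pairs, truth = render_plate(
        layout, model, spec, seed=config.seed, states=states,
        cyt_thickness=sim.cyt_thickness,
    )
    img_dir = out_dir / "images"
    io.write_well_images(img_dir, pairs)
    layout.to_csv(img_dir / "layout.csv")
    truth.to_frame().to_csv(img_dir / "ground_truth.csv", index=False)
    return layout, pairs


def analyze_plate(
    pairs: dict[str, ImagePair],
    layout: PlateLayout,
    config: RunConfig,
    flags: dict[str, str] | None = None,
) -> PipelineResult:
    """Analyze one plate's images; pure computation, no file output."""
    seg = config.segmentation
    cell_rows: list[dict] = []
    summaries: dict[str, WellSummary] = {}
    excluded_total = 0
    for entry in layout.entries():
        if entry.role == "empty" or entry.well not in pairs:
            continue
        records, excluded = analyze_well(
            pairs[entry.well],
            entry.well,
            threshold=config.nc_threshold,
            block_size=seg.block_size,
            offset_frac=seg.offset_frac,
            min_area=seg.min_area,
            max_area=seg.max_area,
            ring_gap=seg.ring_gap,
            ring_width=seg.ring_width,
            mode=config.intensity_mode,
        )
        excluded_total += len(excluded)
        summaries[entry.well] = summarize_well(entry.well, records, config.min_cells)
        cell_rows.extend(dataclasses.asdict(r) for r in records)

    cells = pd.DataFrame(cell_rows, columns=CELL_COLUMNS)

    neg = [summaries[w].pct_translocated for w in layout.wells("negative") if w in summaries]
    pos = [summaries[w].pct_translocated for w in layout.wells("positive") if w in summaries]
    controls = screening.ControlStats.from_values(pos, neg, plate_id=layout.plate_id)
    zp = screening.zprime(controls)

    activities: dict[str, tuple[str, float]] = {}
    well_rows: list[dict] = []
    for entry in layout.entries():
        if entry.role == "empty":
            continue
        s = summaries.get(entry.well)
        row = {
            "well": entry.well, "role": entry.role, "compound": entry.compound,
            "conc": entry.conc, "conc_unit": entry.conc_unit,
            "n_cells": s.n_cells if s else 0,
            "pct_translocated": s.pct_translocated if s else float("nan"),
            "mean_vertices": s.mean_vertices if s else float("nan"),
            "activity_pct": float("nan"),
            "qc_flags": ";".join(s.qc_flags) if s else (flags or {}).get(entry.well, "missing"),
        }
        if s is not None and np.isfinite(s.pct_translocated):
            act = screening.normalize_activity(s.pct_translocated, controls)
            row["activity_pct"] = act
            if entry.role == "compound":
                activities[entry.well] = (entry.compound, act)
        well_rows.append(row)
    wells = pd.DataFrame(well_rows, columns=WELL_COLUMNS)

    hit_calls = screening.call_hits(activities, hit_threshold=config.hit_threshold)
    hits = pd.DataFrame(
        [dataclasses.asdict(h) for h in hit_calls],
        columns=["well", "compound", "activity_pct", "is_hit"],
    )

    qc = {
        "plate_id": layout.plate_id,
        "zprime": zp,
        "controls": dataclasses.asdict(controls),
        "n_wells_analyzed": len(summaries),
        "n_cells_total": int(cells.shape[0]),
        "n_cells_excluded": excluded_total,
        "well_flags": flags or {},
    }

    fits: dict[str, dict] = {}
    by_compound = wells[wells["role"] == "compound"].groupby("compound")["conc"].nunique()
    fittable = by_compound[by_compound >= 5].index
    if len(fittable) > 0:
        fit_results = dose_response.ec50_from_plate(
            {w: s for w, s in summaries.items()},
            layout,
            controls,
            direction=config.fit.direction,
            min_span=config.fit.min_span,
        )
        for compound, f in fit_results.items():
            if compound not in fittable:
                continue
            d = dataclasses.asdict(f)
            d["ec50"] = f.midpoint if f.converged else None
            d["status"] = "converged" if f.converged else "inactive-or-not-converged"
            fits[compound] = d

    return PipelineResult(cells=cells, wells=wells, hits=hits, qc=qc, fits=fits,
                          summaries=summaries)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _sanitize(obj):
    """Replace non-finite floats with None so artifact JSON stays strict."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (float, np.floating)) and not np.isfinite(obj):
        return None
    return obj


def run_pipeline(config: RunConfig, out_dir: str | Path) -> PipelineResult:
    """Run the full pipeline and write all artifacts under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("foxscreen")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    try:
        config.write_resolved(out_dir / "config_resolved.json")
        if config.simulate is not None:
            layout, pairs = _simulate(config, out_dir)
            flags: dict[str, str] = {}
        else:
            layout = PlateLayout.from_csv(Path(config.input_dir) / "layout.csv")
            pairs, flags = io.read_well_images(config.input_dir, layout)

        result = analyze_plate(pairs, layout, config, flags)

        result.cells.to_csv(out_dir / "cells.csv", index=False)
        result.wells.to_csv(out_dir / "wells.csv", index=False)
        result.hits.to_csv(out_dir / "hits.csv", index=False)
        with open(out_dir / "qc.json", "w") as fh:
            json.dump(_sanitize(result.qc), fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
        with open(out_dir / "fits.json", "w") as fh:
            json.dump(_sanitize(result.fits), fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
        logger.info(
            "plate %s: %d wells, %d cells, Z'=%.3f",
            layout.plate_id, result.qc["n_wells_analyzed"],
            result.qc["n_cells_total"], result.qc["zprime"],
        )
        return result
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
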