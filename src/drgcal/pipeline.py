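"""Top-level pipeline: simulate -> extract -> classify -> maps -> report.

``run_pipeline`` executes the full analysis on a simulated session and
writes a deterministic report bundle: per-cell classification CSV, pooled
proportion summary CSV, SD activity maps (TIFF), heatmap layout CSV and PNG,
ground-truth and schedule JSON, and a run manifest (config hash, package
versions, seed, per-stage cell counts).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classify import (
    Category,
    call_responders,
    classify_cells,
    flag_exclusions,
    responder_proportions,
)
from .config import PipelineConfig
from .io import write_movie_tiff
from .maps import render_heatmap, save_sd_map, sd_map, sort_heatmap
from .protocol import EpisodeSchedule, Site, generate_schedule
from .synthetic import MovieStack, simulate_session, write_ground_truth
from .traces import RoiSet, annulus_correct, compute_dff

log = logging.getLogger("drgcal")


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    movie: MovieStack, rois: RoiSet, schedule: EpisodeSchedule
) -> ValidationReport:
    """Check shape agreement between movie, ROIs and schedule.

    Fatal: frame-shape mismatch, frame-count mismatch, no ROIs.  Warnings:
    non-contiguous labels.
    """
    rep = ValidationReport()
    if rois.label_image.shape != movie.frame_shape:
        rep.errors.append(
            f"label image {rois.label_image.shape} vs movie frame "
            f"{movie.frame_shape}"
        )
    if movie.n_frames != schedule.total_frames:
        rep.errors.append(
            f"movie has {movie.n_frames} frames but schedule covers "
            f"{schedule.total_frames}"
        )
    labels = rois.labels
    if not labels:
        rep.errors.append("no ROIs: label image contains no label > 0")
    elif list(labels) != list(range(1, len(labels) + 1)):
        rep.warnings.append(
            f"labels are not contiguous 1..{len(labels)}: {labels[:10]}..."
        )
    return rep


def analyse_session(config: PipelineConfig) -> dict:
    """Simulate a session under ``config`` and run the full analysis in
    memory: extraction, annulus correction, dF/F, responder calling,
    exclusions, classification and pooled proportions."""
    schedule = generate_schedule(
        frame_rate_hz=config.frame_rate_hz,
        episode_s=config.episode_s,
        baseline_s=config.baseline_s,
    )
    cells, schedule, movie = simulate_session(
        seed=config.seed,
        schedule=schedule,
        n_per_class=config.cell_counts(),
        image_shape=tuple(config.image_shape),
        footprint_radius=config.footprint_radius,
        amplitude_pct=config.amplitude_pct,
        background_level=config.background_level,
        background_drift_amplitude=config.background_drift_amplitude,
        noise_sd=config.noise_sd,
        tau_s=config.tau_s,
        plant_overlap_pair=config.plant_overlap_pair,
    )
    rois = RoiSet.from_cells(
        cells,
        image_shape=tuple(config.image_shape),
        annulus_gap_px=config.annulus_gap_px,
        annulus_width_px=config.annulus_width_px,
    )
    log.info("simulate: %d cells, %d frames", len(cells), movie.n_frames)

    rep = validate_inputs(movie, rois, schedule)
    if not rep.ok:
        raise RuntimeError(f"stage validate: {rep.errors}")

    corrected = annulus_correct(movie, rois, neuropil_scale=config.neuropil_scale)
    dff = compute_dff(corrected, schedule)
    responders = call_responders(dff, schedule, config.threshold_pct)
    flags = flag_exclusions(
        dff,
        responders,
        rois,
        schedule,
        spontaneous_consecutive_frames=config.spontaneous_consecutive_frames,
        persistent_fraction=config.persistent_fraction,
    )
    classifications = classify_cells(responders, flags, schedule)
    summary = responder_proportions(classifications, group=f"seed{config.seed}")
    n_excluded = sum(
        1 for c in classifications if c.category.value.startswith("excluded")
    )
    log.info(
        "classify: %d cells -> %d excluded, %d pooled responders",
        len(classifications), n_excluded, summary.n_responders,
    )
    return {
        "cells": cells,
        "schedule": schedule,
        "movie": movie,
        "rois": rois,
        "dff": dff,
        "responders": responders,
        "flags": flags,
        "classifications": classifications,
        "summary": summary,
        "n_excluded": n_excluded,
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full simulated-session analysis and write the report bundle.

    Deterministic given ``config.seed``: two runs with the same config
    produce bit-identical bundles.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = analyse_session(config)
    cells, schedule, movie = res["cells"], res["schedule"], res["movie"]
    dff, responders = res["dff"], res["responders"]
    classifications, summary = res["classifications"], res["summary"]
    n_excluded = res["n_excluded"]

    # -- write the bundle --------------------------------------------------
    schedule.to_json(out / "schedule.json")
    write_ground_truth(cells, out / "ground_truth.json")
    cls_df = (
        responders.to_frame()
        .merge(
            _classification_frame(classifications),
            on="cell_id",
            how="left",
        )
        .sort_values(["cell_id", "episode"])
    )
    cls_df.to_csv(out / "classification.csv", index=False, float_format="%.6f")
    summary.to_frame().to_csv(out / "proportions.csv", index=False, float_format="%.6f")

    for site in (Site.EXTERNAL, Site.INTERNAL):
        amap = sd_map(movie, schedule, site)
        save_sd_map(amap, out / f"sd_map_{site.value}.tif")
    layout = sort_heatmap(dff, classifications)
    layout.to_frame().to_csv(out / "heatmap_layout.csv", index=False)
    render_heatmap(dff, layout, out / "heatmap.png")
    if config.save_movie:
        write_movie_tiff(movie, out / "movie.tif")

    config_yaml = config.to_yaml()
    (out / "config.yaml").write_text(config_yaml)
    manifest = {
        "drgcal_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "n_cells": len(cells),
        "n_excluded": n_excluded,
        "n_pooled_responders": summary.n_responders,
        "category_counts": {
            c.value: summary.counts.get(c, 0) for c in Category
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    res["layout"] = layout
    res["out_dir"] = out
    return res


def _classification_frame(classifications) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in classifications],
            "category": [c.category.value for c in classifications],
            "session_peak_dff": [c.peak_dff for c in classifications],
        }
    )
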