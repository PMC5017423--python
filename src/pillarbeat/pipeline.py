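"""End-to-end pipeline: detect -> track -> beat analysis (-> group stats).

Each stage exchanges tidy CSV tables so it can be run, inspected and
tested on its own; a run manifest records library versions, the seed, the
config hash and per-stage outcomes so reruns are reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .beat import (Beats, alignment_summary, beat_frequency,
                   beats_to_dataframe, segment_beats)
from .config import AnalysisConfig
from .detect import InsufficientDataError, detect_pillars, fit_lattice, \
    select_reference_frame
from .stackio import ImageStack, read_stack
from .track import (build_tracks_table, estimate_reference, to_displacement,
                    track_pillars)

logger = logging.getLogger("pillarbeat")

__all__ = ["PipelineResult", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    """Everything one run produced, in memory plus the written paths."""

    pillars: "pd.DataFrame"
    tracks: pd.DataFrame | None
    beats: pd.DataFrame | None
    summary: dict | None
    manifest: dict
    outdir: Path


def run_pipeline(
    stack: ImageStack | str | Path,
    config: AnalysisConfig | None = None,
    outdir=None,
    *,
    seed: int | None = None,
    stop_after: str | None = None,
) -> PipelineResult:
    """Run the full analysis on a stack (object or TIFF path).

    Stages: ``detect`` (pillar set + lattice QC), ``track`` (sub-pixel
    trajectories -> calibrated deflections and forces), ``analyze`` (beat
    segmentation, frequency, direction and alignment statistics).
    ``stop_after`` halts after the named stage.  When ``outdir`` is given,
    every stage's CSV/JSON artifact plus the effective config and a run
    manifest are written there.
    """
    config = config or AnalysisConfig()
    if not isinstance(stack, ImageStack):
        stack = read_stack(stack, config.pixel_size_um, config.frame_rate_fps)

    stages_run: list[str] = []
    manifest: dict = {
        "pillarbeat_version": __version__,
        "numpy_version": np.__version__,
        "seed": seed,
        "config_hash": config.content_hash(),
        "n_frames": int(stack.n_frames),
        "frame_rate_fps": stack.frame_rate_fps,
        "pixel_size_um": stack.pixel_size_um,
    }

    # ---- detect ------------------------------------------------------
    try:
        ref_idx = select_reference_frame(stack.data)
        pillars = detect_pillars(
            stack.data[ref_idx],
            config.expected_radius_px,
            config.effective_min_separation_px(),
            invert=config.invert,
        )
        try:
            lattice = fit_lattice(pillars.centers_px)
            manifest["lattice_pitch_px"] = lattice.pitch_px
            manifest["lattice_orientation_deg"] = lattice.orientation_deg
        except InsufficientDataError:
            lattice = None
        pillars.lattice = lattice
    except Exception as exc:
        logger.error("[detect] %s", exc)
        raise StageError("detect", exc) from exc
    stages_run.append("detect")
    manifest["reference_frame"] = ref_idx
    manifest["n_pillars"] = len(pillars)
    logger.info("[detect] %d pillars, reference frame %d", len(pillars), ref_idx)

    tracks_df = beats_df = None
    summary = None
    if stop_after != "detect":
        # ---- track ---------------------------------------------------
        try:
            trajectories = track_pillars(
                stack, pillars, config.search_window_px,
                reference_frame=ref_idx,
                quality_threshold=config.quality_threshold,
            )
            k = config.spring_constant()
            series = []
            for traj in trajectories:
                ref = estimate_reference(traj, config.reference_method,
                                         frame_index=ref_idx)
                series.append(to_displacement(
                    traj, ref, stack.pixel_size_um, stack.frame_rate_fps,
                    reference_method=config.reference_method,
                ))
            tracks_df = build_tracks_table(trajectories, series, k)
        except Exception as exc:
            logger.error("[track] %s", exc)
            raise StageError("track", exc) from exc
        stages_run.append("track")
        manifest["spring_constant_n_per_m"] = k.n_per_m
        manifest["n_lost_frames"] = int(tracks_df["lost"].sum())
        logger.info("[track] %d trajectories", len(trajectories))

    if stop_after not in ("detect", "track") and tracks_df is not None:
        # ---- analyze -------------------------------------------------
        try:
            all_beats: list[Beats] = [
                segment_beats(s, config.min_beat_amplitude_um,
                              config.min_beat_separation_s, k=k)
                for s in series
            ]
            beats_df = beats_to_dataframe(all_beats, stack.frame_rate_fps)
            angles = beats_df["angle_deg"].dropna().to_numpy()
            align = (alignment_summary(angles, config.histogram_bins)
                     if angles.size else None)
            freqs = [beat_frequency(b, stack.duration_s) for b in all_beats]
            defined = [f.hz for f in freqs if f.defined]
            summary = {
                "n_pillars": len(pillars),
                "n_beats_total": int(len(beats_df)),
                "n_quiescent_pillars": sum(b.quiescent for b in all_beats),
                "median_beat_frequency_hz": (float(np.median(defined))
                                             if defined else None),
                "mean_beat_amplitude_um": (float(beats_df["amp_um"].mean())
                                           if len(beats_df) else None),
                "mean_peak_force_un": (float(beats_df["peak_force_un"].mean())
                                       if len(beats_df) else None),
                "alignment": align.to_dict() if align else None,
            }
        except Exception as exc:
            logger.error("[analyze] %s", exc)
            raise StageError("analyze", exc) from exc
        stages_run.append("analyze")
        logger.info("[analyze] %d beats across %d pillars",
                    len(beats_df), len(pillars))

    manifest["stages"] = stages_run

    result = PipelineResult(
        pillars=pillars.to_dataframe(), tracks=tracks_df, beats=beats_df,
        summary=summary, manifest=manifest,
        outdir=Path(outdir) if outdir else Path("."),
    )
    if outdir is not None:
        _write_outputs(result, config, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, config: AnalysisConfig,
                   outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.content_hash()
    result.pillars.assign(config_hash=h).to_csv(outdir / "pillars.csv",
                                                index=False)
    if result.tracks is not None:
        result.tracks.assign(config_hash=h).to_csv(outdir / "tracks.csv",
                                                   index=False)
    if result.beats is not None:
        result.beats.assign(config_hash=h).to_csv(outdir / "beats.csv",
                                                  index=False)
    if result.summary is not None:
        (outdir / "summary.json").write_text(
            json.dumps({"config_hash": h, **result.summary}, indent=2))
    (outdir / "config.json").write_text(config.to_json())
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
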