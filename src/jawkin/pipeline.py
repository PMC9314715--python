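"""End-to-end batch pipeline: marker CSVs -> poses -> angles -> events -> summary.

For each trial the pipeline fits per-frame rigid poses for every
configured body, decomposes each configured JCS into z-y-x Euler angle
series, computes the gape series, detects feeding events and channel
extrema, and finally summarises event quantities across trials as
mean ± s.e.m.  Trials that cannot be analysed (missing markers, no pose at
the reference frame) are skipped with a logged reason; if every trial
fails a :class:`~jawkin.errors.PipelineError` is raised.

All numeric outputs use fixed float formatting, so re-running on identical
inputs produces byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import JawkinError, PipelineError
from .events import (
    EventTable,
    GapeSeries,
    compute_gape,
    expansive_onset_10pct,
    find_angle_extrema,
    find_initial_depression,
    find_peak_gape,
    summarize_across_trials,
)
from .io import MarkerTrajectorySet, StudyConfig, read_marker_csv
from .jcs import AngleSeries, JCSDefinition, acs_from_spec, jcs_angle_series
from .rigid import PoseSeries, RigidBodyDefinition, track_body
from .smoothing import lowpass

__all__ = ["TrialResult", "analyze_trial", "run_pipeline"]

logger = logging.getLogger(__name__)

OUT_FLOAT_FORMAT = "%.6f"


@dataclass
class TrialResult:
    trial_id: str
    poses: dict[str, PoseSeries]
    angles: dict[str, AngleSeries]
    gape: GapeSeries
    events: EventTable


def _jcs_definitions(config: StudyConfig) -> list[JCSDefinition]:
    defs = []
    for j in config.jcs:
        defs.append(
            JCSDefinition(
                name=j.name,
                proximal=j.proximal,
                distal=j.distal,
                proximal_acs=acs_from_spec(j.proximal_acs, j.proximal),
                distal_acs=acs_from_spec(config.body(j.distal).acs, j.distal),
                body_kind=j.body_kind,
                reference_frame=j.reference_frame,
            )
        )
    return defs


def _maybe_smooth(x: np.ndarray, config: StudyConfig) -> np.ndarray:
    if not config.smoothing.enabled:
        return x
    return lowpass(x, config.sample_rate_hz, config.smoothing.cutoff_hz, config.smoothing.order)


def analyze_trial(config: StudyConfig, traj: MarkerTrajectorySet) -> TrialResult:
    """Run the full single-trial analysis on one trajectory set."""
    bodies = {b.name: RigidBodyDefinition.from_config(b) for b in config.bodies}
    poses = {name: track_body(traj, body) for name, body in bodies.items()}
    for name, ps in poses.items():
        n_valid = int(ps.valid.sum())
        logger.info(
            "trial %s body %s: %d/%d frames tracked, median residual %.4f mm",
            traj.trial_id, name, n_valid, ps.frames,
            float(np.nanmedian(ps.residuals_mm)) if n_valid else float("nan"),
        )

    angles: dict[str, AngleSeries] = {}
    by_kind: dict[str, AngleSeries] = {}
    for jdef in _jcs_definitions(config):
        series = jcs_angle_series(poses[jdef.proximal], poses[jdef.distal], jdef)
        # event detection runs on (optionally) smoothed channels
        smoothed = AngleSeries(
            name=series.name,
            body_kind=series.body_kind,
            raw_deg=_maybe_smooth(series.raw_deg, config),
            semantic_deg=_maybe_smooth(series.semantic_deg, config),
            reference_frame=series.reference_frame,
            sample_rate_hz=series.sample_rate_hz,
            gimbal=series.gimbal,
        )
        angles[jdef.name] = series
        by_kind[jdef.body_kind] = smoothed

    if "lower_jaw" not in by_kind or "upper_jaw" not in by_kind:
        raise PipelineError("config must define one lower_jaw and one upper_jaw JCS")

    gape = compute_gape(
        poses[config.gape_upper.body], poses[config.gape_lower.body],
        config.gape_upper, config.gape_lower,
    )
    gape_s = GapeSeries(_maybe_smooth(gape.gape_mm, config), gape.sample_rate_hz)

    peak_frame, max_gape = find_peak_gape(gape_s)
    init, never = find_initial_depression(
        gape_s, peak_frame, config.events.closure_threshold_fraction * max_gape
    )
    onset = expansive_onset_10pct(gape_s, peak_frame, init, config.events.expansive_onset_fraction)
    channels = find_angle_extrema(
        by_kind["lower_jaw"], by_kind["upper_jaw"], peak_frame, (init, gape_s.frames)
    )
    events = EventTable(
        trial_id=traj.trial_id,
        peak_gape_frame=peak_frame,
        max_gape_mm=max_gape,
        initial_depression_frame=init,
        never_closed=never,
        expansive_onset_frame=onset,
        channels=channels,
        sample_rate_hz=traj.sample_rate_hz,
    )
    logger.info(
        "trial %s: peak gape %.2f mm at frame %d, initial depression frame %d%s",
        traj.trial_id, max_gape, peak_frame, init, " (never closed)" if never else "",
    )
    return TrialResult(trial_id=traj.trial_id, poses=poses, angles=angles, gape=gape, events=events)


def run_pipeline(
    config: StudyConfig,
    trial_paths: list[str | Path],
    out_dir: str | Path,
) -> pd.DataFrame:
    """Analyse a list of trial CSVs and write per-trial and summary tables.

    Writes, per trial: pose series CSV per body, angle series CSV per JCS,
    and an event table CSV; plus a study-level ``summary.csv`` with
    mean ± s.e.m. per quantity.  Returns the summary DataFrame.
    """
    if not trial_paths:
        raise PipelineError("no trial files given")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tables: list[EventTable] = []
    for path in trial_paths:
        path = Path(path)
        try:
            traj = read_marker_csv(path, sample_rate_hz=config.sample_rate_hz)
            result = analyze_trial(config, traj)
        except JawkinError as exc:
            logger.warning("trial %s skipped: %s", path.name, exc)
            continue
        except ValueError as exc:
            logger.warning("trial %s skipped: %s", path.name, exc)
            continue
        tid = result.trial_id
        for name, ps in result.poses.items():
            ps.to_frame().to_csv(out / f"pose_{tid}_{name}.csv", index=False, float_format=OUT_FLOAT_FORMAT)
        for name, series in result.angles.items():
            df = series.to_frame()
            df["time_ms_rel_peak_gape"] = (
                (df["frame"] - result.events.peak_gape_frame) / series.sample_rate_hz * 1000.0
            )
            df.to_csv(out / f"angles_{tid}_{name}.csv", index=False, float_format=OUT_FLOAT_FORMAT)
        result.events.to_frame().to_csv(out / f"events_{tid}.csv", index=False, float_format=OUT_FLOAT_FORMAT)
        tables.append(result.events)

    if not tables:
        raise PipelineError("all trials failed; nothing to summarize")
    summary = summarize_across_trials(tables)
    summary.to_csv(out / "summary.csv", index=False, float_format=OUT_FLOAT_FORMAT)
    logger.info("wrote summary for %d trials to %s", len(tables), out / "summary.csv")
    return summary
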