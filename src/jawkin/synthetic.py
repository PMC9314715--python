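"""Forward-kinematics generator for synthetic suction-feeding trials.

This module is the validation counterpart of the analysis pipeline: it
composes known joint-angle profiles into rigid-body poses and marker
trajectories using *exactly* the same axis, order and sign conventions the
analysis decomposes with, so a noise-free round trip must reproduce every
channel to numerical precision.  With calibrated Gaussian marker noise it
emulates a bamboo-shark suction-feeding study: a static cranium (4
markers), and upper and lower jaws (3 markers each) that depress, evert
and invert with raised-cosine pulses whose magnitudes and timings are
drawn per trial from study-level tables.

Design notes
------------
* Angle pulses are raised cosines, ``p(t) = A/2 (1 - cos(2 pi (t - t0 +
  d/2)/d))`` on ``|t - t0| <= d/2``: smooth, compactly supported, with the
  drawn amplitude as the exact channel extremum.
* Pulse peak times are expressed in ms relative to the trial's peak gape.
  Depression (hinge) channels are drawn first; because the gape landmarks
  lie on each jaw's long axis, gape is exactly independent of the
  long-axis-rotation channels, so the realized peak-gape frame can be
  computed from the hinge channels alone and the LAR pulse times drawn
  relative to it.
* The upper-jaw depression pulse duration is calibrated (once per study,
  deterministically) so that at the nominal table values the noise-free
  gape peaks exactly at the pulse time origin: the mouth stops opening
  when upper-jaw protrusion catches up with slowing lower-jaw depression.
* A broad half-amplitude "sustain" pulse keeps the lower jaw depressed
  after the strike so the mouth is closed by upper-jaw protrusion, as in
  recorded feeding sequences; it starts just after the strike peak so the
  drawn depression magnitude remains the exact extremum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigError
from .events import (
    EventTable,
    GapeSeries,
    compute_gape,
    expansive_onset_10pct,
    find_angle_extrema,
    find_initial_depression,
    find_peak_gape,
)
from .io import (
    AcsSpec,
    BodyConfig,
    EventParams,
    GapeLandmark,
    JcsConfig,
    MarkerTrajectorySet,
    SmoothingParams,
    StudyConfig,
    write_marker_csv,
)
from .jcs import SEMANTIC_CHANNELS, SIGN_MAPS, AngleSeries, acs_from_spec
from .rigid import PoseSeries
from .transforms import euler_zyx_matrix, rot_z

__all__ = [
    "Pulse",
    "ChannelProfile",
    "MotionProfile",
    "SyntheticTrial",
    "pulse_profile",
    "forward_kinematics",
    "add_marker_noise",
    "generate_study",
    "static_trial",
    "default_skeleton",
    "default_magnitudes",
    "default_timings",
    "GRAND_MEAN_PRECISION_MM",
]

logger = logging.getLogger(__name__)

# --- study-level constants (the emulated experimental conditions) ----------

#: marker-tracking precision the noise level is calibrated against (mm):
#: per-coordinate sigma = GRAND_MEAN_PRECISION_MM / sqrt(2) reproduces this
#: grand mean pair-distance s.d.
GRAND_MEAN_PRECISION_MM = 0.12

#: default per-coordinate marker noise (mm)
DEFAULT_SIGMA_MM = 0.1

#: lower-jaw depression strike pulse duration (ms) — fast expansive phase
STRIKE_DURATION_MS = 110.0
#: sustain pulse keeping the lower jaw depressed after the strike
SUSTAIN_DELAY_MS = 124.0
SUSTAIN_DURATION_MS = 240.0
SUSTAIN_FRACTION = 0.5
#: LAR pulse durations (ms)
EVERSION_DURATION_MS = 120.0
INVERSION_DURATION_MS = 130.0
UPPER_EVERSION_DURATION_MS = 140.0
#: medio-lateral (y) motion of the jaw joints: small medial pulse at peak gape
Y_PULSE_DEG = -2.0
Y_PULSE_DURATION_MS = 160.0
#: pre-strike ventilation: small rhythmic depression bumps of the lower jaw
VENT_AMPLITUDE_DEG = -1.5
VENT_DURATION_MS = 175.0
VENT_TIMES_MS = (-1000.0, -650.0, -300.0)
#: fraction of the trial elapsed at the nominal peak-gape time
PEAK_POSITION_FRACTION = 0.7


def default_magnitudes() -> pd.DataFrame:
    """Across-trial rotation-magnitude table (deg): mean and trial s.d.

    Means are the in-vivo across-trial values the generator emulates;
    eversion and depression are negative by the package sign conventions.
    """
    rows = {
        "lower_eversion": (-8.0, 1.1),
        "lower_inversion": (11.2, 1.5),
        "upper_eversion": (-12.3, 0.9),
        "lower_depression": (-22.7, 0.6),
        "upper_depression": (-15.7, 1.8),
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=["mean_deg", "sd_deg"])


def default_timings() -> pd.DataFrame:
    """Pulse-peak timing table (ms relative to peak gape): mean and s.d."""
    rows = {
        "lower_eversion": (-19.0, 7.0),
        "lower_inversion": (87.0, 6.0),
        "upper_eversion": (0.0, 1.6),
        "lower_depression": (6.0, 2.0),
        "upper_depression": (55.0, 5.0),
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=["mean_ms", "sd_ms"])


def default_skeleton(sample_rate_hz: float = 320.0) -> StudyConfig:
    """Default three-body shark skeleton at the ~6.5 cm cranium scale.

    Four cranium markers on a ~20 mm tetrahedron, three markers per jaw on
    ~15 mm triangles near the jaw tips (~40 mm from the joint).  Both jaw
    ACSs sit at the jaw joint (the world origin at rest) with the hinge
    along world z; the lower-jaw long axis points cranially (+x world), the
    upper-jaw long axis caudally (-x world) so that equal raw long-axis
    angles mean the same inversion/eversion sense for both jaws.  Gape
    landmarks are the jaw tips, on each jaw's long axis.  Smoothing is
    enabled at 20 Hz for event detection on noisy trials.
    """
    z_hint = (0.0, 0.0, 1.0)
    bodies = [
        BodyConfig(
            name="cranium",
            markers={
                "cr1": (2.0, 10.0, -8.0),
                "cr2": (22.0, 12.0, -6.0),
                "cr3": (10.0, 26.0, 0.0),
                "cr4": (12.0, 12.0, 10.0),
            },
            acs=AcsSpec((0.0, 0.0, 0.0), (1.0, 0.0, 0.0), z_hint),
        ),
        BodyConfig(
            name="upper_jaw",
            markers={
                "uj1": (25.0, 3.0, -7.0),
                "uj2": (38.0, 6.0, 0.0),
                "uj3": (25.0, 3.0, 8.0),
            },
            acs=AcsSpec((0.0, 0.0, 0.0), (-1.0, 0.0, 0.0), z_hint),
        ),
        BodyConfig(
            name="lower_jaw",
            markers={
                "lj1": (25.0, -2.0, -7.0),
                "lj2": (38.0, -5.0, 0.0),
                "lj3": (25.0, -2.0, 8.0),
            },
            acs=AcsSpec((0.0, 0.0, 0.0), (1.0, 0.0, 0.0), z_hint),
        ),
    ]
    jcs = [
        JcsConfig(
            name="upper_jaw_jcs",
            proximal="cranium",
            distal="upper_jaw",
            proximal_acs=AcsSpec((0.0, 0.0, 0.0), (-1.0, 0.0, 0.0), z_hint),
            body_kind="upper_jaw",
        ),
        JcsConfig(
            name="lower_jaw_jcs",
            proximal="cranium",
            distal="lower_jaw",
            proximal_acs=AcsSpec((0.0, 0.0, 0.0), (1.0, 0.0, 0.0), z_hint),
            body_kind="lower_jaw",
        ),
    ]
    return StudyConfig(
        bodies=bodies,
        jcs=jcs,
        gape_upper=GapeLandmark("upper_jaw", (40.0, 0.0, 0.0)),
        gape_lower=GapeLandmark("lower_jaw", (40.0, 0.0, 0.0)),
        sample_rate_hz=sample_rate_hz,
        events=EventParams(),
        smoothing=SmoothingParams(enabled=True, cutoff_hz=20.0, order=4),
    )


# --- motion profiles -------------------------------------------------------


@dataclass(frozen=True)
class Pulse:
    """One raised-cosine angle pulse: peak value (deg), peak time and
    duration (ms)."""

    peak_deg: float
    peak_time_ms: float
    duration_ms: float

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("pulse duration must be positive")


@dataclass(frozen=True)
class ChannelProfile:
    baseline_deg: float = 0.0
    pulses: tuple[Pulse, ...] = ()


@dataclass(frozen=True)
class MotionProfile:
    """Per-jaw semantic channel profiles (elevation, lateral, inversion)."""

    elevation: ChannelProfile = field(default_factory=ChannelProfile)
    lateral: ChannelProfile = field(default_factory=ChannelProfile)
    inversion: ChannelProfile = field(default_factory=ChannelProfile)

    def channel(self, name: str) -> ChannelProfile:
        return getattr(self, name)


def pulse_profile(pulses: Sequence[Pulse], baseline_deg: float, t_ms: np.ndarray) -> np.ndarray:
    """Evaluate baseline + sum of raised-cosine pulses at times ``t_ms``."""
    t = np.asarray(t_ms, dtype=float)
    out = np.full(t.shape, float(baseline_deg))
    for p in pulses:
        s = t - p.peak_time_ms
        inside = np.abs(s) <= p.duration_ms / 2
        out[inside] += (
            p.peak_deg
            / 2.0
            * (1.0 - np.cos(2.0 * np.pi * (s[inside] + p.duration_ms / 2) / p.duration_ms))
        )
    return out


def _semantic_angles(profile: MotionProfile, t_ms: np.ndarray) -> np.ndarray:
    """(frames, 3) semantic channels (elevation, lateral, inversion) in deg."""
    return np.column_stack(
        [
            pulse_profile(profile.channel(ch).pulses, profile.channel(ch).baseline_deg, t_ms)
            for ch in SEMANTIC_CHANNELS
        ]
    )


# --- forward kinematics ----------------------------------------------------


def _cranium_pose(config: StudyConfig, t_ms: np.ndarray, drift_deg: float, drift_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Cranium pose: static by default, optional slow sinusoidal drift."""
    F = t_ms.shape[0]
    if drift_deg == 0.0 and drift_mm == 0.0:
        return np.broadcast_to(np.eye(3), (F, 3, 3)).copy(), np.zeros((F, 3))
    phase = 2.0 * np.pi * t_ms / 2000.0
    rot = rot_z(drift_deg * np.sin(phase))
    trans = np.column_stack([drift_mm * np.sin(phase), np.zeros(F), np.zeros(F)])
    return rot, trans


def _jaw_pose(
    config: StudyConfig,
    jcs: JcsConfig,
    semantic: np.ndarray,
    cran_rot: np.ndarray,
    cran_trans: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Compose jaw poses from semantic channels through the JCS definition.

    The distal pose places the distal ACS at the proximal ACS rotated by
    ``Rz Ry Rx`` of the raw angles, i.e. the exact inverse of the
    analysis-side decomposition.
    """
    sign = SIGN_MAPS[jcs.body_kind]
    raw = semantic * sign  # (F, 3) as (z, y, x)
    rot_rel = euler_zyx_matrix(raw[:, 0], raw[:, 1], raw[:, 2])
    a_p = acs_from_spec(jcs.proximal_acs, jcs.proximal).axes
    o_p = np.asarray(jcs.proximal_acs.origin, dtype=float)
    dist_acs = acs_from_spec(config.body(jcs.distal).acs, jcs.distal)
    a_d, o_d = dist_acs.axes, dist_acs.origin

    core = a_p @ rot_rel @ a_d.T  # (F, 3, 3)
    rotations = cran_rot @ core
    t_local = np.einsum("fij,j->fi", a_p @ rot_rel, -(a_d.T @ o_d)) + o_p
    translations = np.einsum("fij,fj->fi", cran_rot, t_local) + cran_trans
    return rotations, translations


def forward_kinematics(
    config: StudyConfig,
    profiles: Mapping[str, MotionProfile],
    t_ms: np.ndarray,
    *,
    cranium_drift_deg: float = 0.0,
    cranium_drift_mm: float = 0.0,
) -> tuple[MarkerTrajectorySet, dict[str, PoseSeries], dict[str, np.ndarray]]:
    """Generate noise-free marker trajectories from joint-angle profiles.

    ``profiles`` maps distal body names (e.g. ``lower_jaw``) to their
    semantic :class:`MotionProfile`; bodies without a profile (and no JCS)
    follow the cranium.  Returns the trajectory set, the true pose series
    per body, and the true semantic angle arrays per profiled body.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    F = t_ms.shape[0]
    cran_rot, cran_trans = _cranium_pose(config, t_ms, cranium_drift_deg, cranium_drift_mm)
    jcs_by_distal = {j.distal: j for j in config.jcs}

    poses: dict[str, PoseSeries] = {}
    angles: dict[str, np.ndarray] = {}
    markers: list[str] = []
    columns: list[np.ndarray] = []
    for body in config.bodies:
        if body.name in jcs_by_distal:
            jcs = jcs_by_distal[body.name]
            profile = profiles.get(body.name, MotionProfile())
            semantic = _semantic_angles(profile, t_ms)
            rot, trans = _jaw_pose(config, jcs, semantic, cran_rot, cran_trans)
            angles[body.name] = semantic
        else:
            rot, trans = cran_rot, cran_trans
        poses[body.name] = PoseSeries(
            body=body.name,
            rotations=rot,
            translations=trans,
            residuals_mm=np.zeros(F),
            sample_rate_hz=config.sample_rate_hz,
        )
        ref = np.array(list(body.markers.values()), dtype=float)  # (n, 3)
        world = np.einsum("fij,nj->fni", rot, ref) + trans[:, None, :]
        markers.extend(body.markers)
        columns.append(world)

    traj = MarkerTrajectorySet(
        trial_id="synthetic",
        sample_rate_hz=config.sample_rate_hz,
        markers=markers,
        positions=np.concatenate(columns, axis=1),
    )
    return traj, poses, angles


def add_marker_noise(
    traj: MarkerTrajectorySet,
    sigma_mm: float,
    dropout_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> MarkerTrajectorySet:
    """Add i.i.d. per-coordinate Gaussian noise and Bernoulli marker dropout."""
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = traj.positions.copy()
    if sigma_mm > 0:
        pos = pos + rng.normal(0.0, sigma_mm, size=pos.shape)
    if dropout_rate > 0:
        drop = rng.random(pos.shape[:2]) < dropout_rate
        pos[drop] = np.nan
    return MarkerTrajectorySet(
        trial_id=traj.trial_id,
        sample_rate_hz=traj.sample_rate_hz,
        markers=list(traj.markers),
        positions=pos,
    )


# --- study generation ------------------------------------------------------


@dataclass
class GroundTruth:
    """Generator-side truth for one trial: drawn parameters, true per-frame
    semantic angles and gape, and the event table computed from them."""

    trial_id: str
    drawn: dict[str, float]
    angles: dict[str, np.ndarray]
    gape: GapeSeries
    events: EventTable


@dataclass
class SyntheticTrial:
    trial_id: str
    seed: int
    trajectories: MarkerTrajectorySet
    noise_free: MarkerTrajectorySet
    truth: GroundTruth


def _times_ms(n_frames: int, sample_rate_hz: float) -> np.ndarray:
    """Frame times in ms with t = 0 at the nominal peak-gape position."""
    offset = PEAK_POSITION_FRACTION * n_frames / sample_rate_hz * 1000.0
    return np.arange(n_frames) / sample_rate_hz * 1000.0 - offset


def _hinge_profiles(
    dep_low: float, t_low: float, dep_up: float, t_up: float, d_up: float, *, ventilation: bool = True
) -> dict[str, MotionProfile]:
    """Depression (z) and medio-lateral (y) profiles for both jaws."""
    low_pulses = [
        Pulse(dep_low, t_low, STRIKE_DURATION_MS),
        Pulse(SUSTAIN_FRACTION * dep_low, t_low + SUSTAIN_DELAY_MS, SUSTAIN_DURATION_MS),
    ]
    if ventilation:
        low_pulses += [Pulse(VENT_AMPLITUDE_DEG, tv, VENT_DURATION_MS) for tv in VENT_TIMES_MS]
    y = ChannelProfile(pulses=(Pulse(Y_PULSE_DEG, 0.0, Y_PULSE_DURATION_MS),))
    return {
        "lower_jaw": MotionProfile(elevation=ChannelProfile(pulses=tuple(low_pulses)), lateral=y),
        "upper_jaw": MotionProfile(
            elevation=ChannelProfile(pulses=(Pulse(dep_up, t_up, d_up),)), lateral=y
        ),
    }


def _gape_curve(config: StudyConfig, profiles: Mapping[str, MotionProfile], t_ms: np.ndarray) -> np.ndarray:
    """Noise-free gape at arbitrary times (landmarks only; no markers)."""
    jcs_by_distal = {j.distal: j for j in config.jcs}
    cran_rot, cran_trans = _cranium_pose(config, t_ms, 0.0, 0.0)
    pts = {}
    for lm in (config.gape_upper, config.gape_lower):
        jcs = jcs_by_distal[lm.body]
        semantic = _semantic_angles(profiles.get(lm.body, MotionProfile()), t_ms)
        rot, trans = _jaw_pose(config, jcs, semantic, cran_rot, cran_trans)
        pts[lm.body] = np.einsum("fij,j->fi", rot, np.asarray(lm.point, float)) + trans
    return np.linalg.norm(pts[config.gape_upper.body] - pts[config.gape_lower.body], axis=1)


def calibrate_upper_depression_duration(
    config: StudyConfig,
    magnitudes: pd.DataFrame,
    timings: pd.DataFrame,
    *,
    bounds: tuple[float, float] = (100.0, 400.0),
) -> float:
    """Upper-jaw depression duration placing the nominal gape peak at t = 0.

    Solves (deterministically, on the nominal noise-free study) for the
    pulse duration at which the gape derivative vanishes at the pulse time
    origin, i.e. upper-jaw protrusion starts closing the mouth exactly when
    lower-jaw depression stops opening it.  Among the (at most two) roots
    the faster one is chosen: with a rapidly accelerating protrusion the
    gape maximum is sharp and unambiguous, whereas the slow root balances
    opening and closing over tens of milliseconds and leaves a flat-topped,
    ill-defined peak.
    """

    def slope(d_up: float) -> float:
        profiles = _hinge_profiles(
            magnitudes.loc["lower_depression", "mean_deg"],
            timings.loc["lower_depression", "mean_ms"],
            magnitudes.loc["upper_depression", "mean_deg"],
            timings.loc["upper_depression", "mean_ms"],
            d_up,
            ventilation=False,
        )
        h = 0.5
        g = _gape_curve(config, profiles, np.array([-h, h]))
        return float(g[1] - g[0]) / (2 * h)

    grid = np.linspace(bounds[0], bounds[1], 25)
    vals = [slope(d) for d in grid]
    bracket = None
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            bracket = (a, a)
            break
        elif fa * fb < 0:
            bracket = (a, b)  # first (fastest) sign change
            break
    if bracket is None:
        d = float(grid[int(np.argmin(np.abs(vals)))])
        logger.warning(
            "gape-peak calibration found no zero crossing in %s; using d=%.1f ms "
            "(nominal peak gape will not sit exactly at the pulse time origin)",
            bounds, d,
        )
        return d
    if bracket[0] == bracket[1]:
        return float(bracket[0])
    return float(brentq(slope, *bracket, xtol=1e-6))


def _truth_events(
    config: StudyConfig,
    gape: GapeSeries,
    angles: dict[str, np.ndarray],
    trial_id: str,
) -> EventTable:
    """Apply the event definitions to the true (noise-free) curves."""
    peak_frame, max_gape = find_peak_gape(gape)
    init, never = find_initial_depression(
        gape, peak_frame, config.events.closure_threshold_fraction * max_gape
    )
    onset = expansive_onset_10pct(gape, peak_frame, init, config.events.expansive_onset_fraction)
    series = {}
    for body, sem in angles.items():
        kind = {"lower_jaw": "lower_jaw", "upper_jaw": "upper_jaw"}[body]
        series[body] = AngleSeries(
            name=body,
            body_kind=kind,
            raw_deg=sem * SIGN_MAPS[kind],
            semantic_deg=sem,
            reference_frame=0,
            sample_rate_hz=gape.sample_rate_hz,
        )
    channels = find_angle_extrema(series["lower_jaw"], series["upper_jaw"], peak_frame, (init, gape.frames))
    return EventTable(
        trial_id=trial_id,
        peak_gape_frame=peak_frame,
        max_gape_mm=max_gape,
        initial_depression_frame=init,
        never_closed=never,
        expansive_onset_frame=onset,
        channels=channels,
        sample_rate_hz=gape.sample_rate_hz,
    )


def generate_trial(
    config: StudyConfig,
    seed: int,
    *,
    magnitudes: pd.DataFrame,
    timings: pd.DataFrame,
    d_up: float,
    sigma_mm: float = DEFAULT_SIGMA_MM,
    dropout_rate: float = 0.0,
    duration_s: float = 2.0,
    trial_id: str = "synthetic",
) -> SyntheticTrial:
    """Generate one trial: draw parameters, compose motion, add noise."""
    rng = np.random.default_rng(seed)
    t_ms = _times_ms(int(round(duration_s * config.sample_rate_hz)), config.sample_rate_hz)

    def draw(table: pd.DataFrame, key: str, cols: tuple[str, str]) -> float:
        return float(rng.normal(table.loc[key, cols[0]], table.loc[key, cols[1]]))

    drawn = {
        "lower_depression_deg": draw(magnitudes, "lower_depression", ("mean_deg", "sd_deg")),
        "upper_depression_deg": draw(magnitudes, "upper_depression", ("mean_deg", "sd_deg")),
        "lower_eversion_deg": draw(magnitudes, "lower_eversion", ("mean_deg", "sd_deg")),
        "lower_inversion_deg": draw(magnitudes, "lower_inversion", ("mean_deg", "sd_deg")),
        "upper_eversion_deg": draw(magnitudes, "upper_eversion", ("mean_deg", "sd_deg")),
        "lower_depression_time_ms": draw(timings, "lower_depression", ("mean_ms", "sd_ms")),
        "upper_depression_time_ms": draw(timings, "upper_depression", ("mean_ms", "sd_ms")),
    }

    # stage 1: hinge channels fix the realized peak-gape frame
    profiles = _hinge_profiles(
        drawn["lower_depression_deg"],
        drawn["lower_depression_time_ms"],
        drawn["upper_depression_deg"],
        drawn["upper_depression_time_ms"],
        d_up,
    )
    gape0 = _gape_curve(config, profiles, t_ms)
    t_star = float(t_ms[int(np.argmax(gape0))])

    # stage 2: LAR pulse times are relative to the realized peak gape
    for key in ("lower_eversion", "lower_inversion", "upper_eversion"):
        drawn[f"{key}_time_ms"] = t_star + draw(timings, key, ("mean_ms", "sd_ms"))
    profiles["lower_jaw"] = MotionProfile(
        elevation=profiles["lower_jaw"].elevation,
        lateral=profiles["lower_jaw"].lateral,
        inversion=ChannelProfile(
            pulses=(
                Pulse(drawn["lower_eversion_deg"], drawn["lower_eversion_time_ms"], EVERSION_DURATION_MS),
                Pulse(drawn["lower_inversion_deg"], drawn["lower_inversion_time_ms"], INVERSION_DURATION_MS),
            )
        ),
    )
    profiles["upper_jaw"] = MotionProfile(
        elevation=profiles["upper_jaw"].elevation,
        lateral=profiles["upper_jaw"].lateral,
        inversion=ChannelProfile(
            pulses=(
                Pulse(drawn["upper_eversion_deg"], drawn["upper_eversion_time_ms"], UPPER_EVERSION_DURATION_MS),
            )
        ),
    )

    noise_free, _poses, angles = forward_kinematics(config, profiles, t_ms)
    noise_free.trial_id = trial_id
    noisy = add_marker_noise(noise_free, sigma_mm, dropout_rate, rng)
    gape = GapeSeries(_gape_curve(config, profiles, t_ms), config.sample_rate_hz)
    truth = GroundTruth(
        trial_id=trial_id,
        drawn=drawn,
        angles=angles,
        gape=gape,
        events=_truth_events(config, gape, angles, trial_id),
    )
    return SyntheticTrial(trial_id=trial_id, seed=seed, trajectories=noisy, noise_free=noise_free, truth=truth)


def generate_study(
    n_individuals: int = 3,
    trials_per_individual: int = 4,
    *,
    magnitudes: pd.DataFrame | None = None,
    timings: pd.DataFrame | None = None,
    sigma_mm: float = DEFAULT_SIGMA_MM,
    dropout_rate: float = 0.0,
    base_seed: int = 1,
    sample_rate_hz: float = 320.0,
    duration_s: float = 2.0,
    out_dir: str | Path | None = None,
) -> tuple[StudyConfig, list[SyntheticTrial]]:
    """Generate a full synthetic study (default 3 individuals x 4 trials).

    Per-trial magnitude and timing parameters are drawn from the study
    tables (defaults: :func:`default_magnitudes` / :func:`default_timings`);
    per-trial seeds are ``base_seed + trial_index``.  If ``out_dir`` is
    given, writes trial CSVs, the study config YAML and a ground-truth
    manifest CSV there.
    """
    if n_individuals < 1 or trials_per_individual < 1:
        raise ValueError("need at least one individual and one trial")
    magnitudes = default_magnitudes() if magnitudes is None else magnitudes
    timings = default_timings() if timings is None else timings
    config = default_skeleton(sample_rate_hz)
    d_up = calibrate_upper_depression_duration(config, magnitudes, timings)
    logger.info("calibrated upper-jaw depression duration: %.2f ms", d_up)

    trials: list[SyntheticTrial] = []
    idx = 0
    for ind in range(n_individuals):
        for rep in range(trials_per_individual):
            trial_id = f"ind{ind + 1}_trial{rep + 1}"
            trials.append(
                generate_trial(
                    config,
                    base_seed + idx,
                    magnitudes=magnitudes,
                    timings=timings,
                    d_up=d_up,
                    sigma_mm=sigma_mm,
                    dropout_rate=dropout_rate,
                    duration_s=duration_s,
                    trial_id=trial_id,
                )
            )
            idx += 1

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.save(out / "study_config.yaml")
        manifest = []
        for trial in trials:
            write_marker_csv(trial.trajectories, out / f"{trial.trial_id}.csv")
            row = {"trial_id": trial.trial_id, "seed": trial.seed}
            row.update({f"drawn_{k}": v for k, v in trial.truth.drawn.items()})
            row.update({f"true_{k}": v for k, v in trial.truth.events.quantities().items()})
            manifest.append(row)
        pd.DataFrame(manifest).to_csv(out / "ground_truth.csv", index=False, float_format="%.6f")
    return config, trials


def static_trial(
    config: StudyConfig,
    n_frames: int,
    *,
    sigma_mm: float = 0.0,
    dropout_rate: float = 0.0,
    seed: int = 0,
    trial_id: str = "static",
) -> MarkerTrajectorySet:
    """A motionless trial (all profiles zero), e.g. for precision studies."""
    t_ms = _times_ms(n_frames, config.sample_rate_hz)
    traj, _, _ = forward_kinematics(config, {}, t_ms)
    traj.trial_id = trial_id
    return add_marker_noise(traj, sigma_mm, dropout_rate, seed)
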