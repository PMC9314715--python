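"""Marker trajectory CSV and study configuration input/output.

The marker dialect is the plain 3D-points CSV commonly exported from
XMALab-style trackers: a header row of ``<label>_X, <label>_Y, <label>_Z``
triples, one row per video frame, world coordinates in millimetres, empty
cells (or ``NaN``) for untracked marker/frame combinations.

The study configuration is a YAML document declaring rigid bodies (member
markers, reference coordinates, anatomical coordinate system placement),
joint coordinate systems, gape landmarks, event parameters and smoothing
settings.  See :func:`StudyConfig.from_dict` for the schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError

__all__ = [
    "MarkerTrajectorySet",
    "read_marker_csv",
    "write_marker_csv",
    "AcsSpec",
    "BodyConfig",
    "JcsConfig",
    "GapeLandmark",
    "EventParams",
    "SmoothingParams",
    "StudyConfig",
]

_SUFFIXES = ("_X", "_Y", "_Z")
#: fixed float format so that re-running on identical inputs is byte-identical
FLOAT_FORMAT = "%.17g"


@dataclass
class MarkerTrajectorySet:
    """Per-trial time series of labelled 3D marker positions.

    ``positions`` is a ``(frames, n_markers, 3)`` float array in mm with NaN
    marking missing marker/frame combinations.
    """

    trial_id: str
    sample_rate_hz: float
    markers: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker labels must be unique")
        if self.positions.ndim != 3 or self.positions.shape[1:] != (len(self.markers), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} inconsistent with "
                f"{len(self.markers)} markers"
            )

    @property
    def frames(self) -> int:
        return self.positions.shape[0]

    def marker_index(self, label: str) -> int:
        try:
            return self.markers.index(label)
        except ValueError:
            raise KeyError(f"marker {label!r} not present in trial {self.trial_id!r}") from None

    def get(self, label: str) -> np.ndarray:
        """Return the (frames, 3) trajectory of one marker."""
        return self.positions[:, self.marker_index(label), :]

    def subset(self, labels: Sequence[str]) -> np.ndarray:
        """Return a (frames, len(labels), 3) view-copy in the given order."""
        idx = [self.marker_index(m) for m in labels]
        return self.positions[:, idx, :]


def read_marker_csv(path: str | Path, *, sample_rate_hz: float = 320.0, trial_id: str | None = None) -> MarkerTrajectorySet:
    """Read a marker trajectory CSV in the ``<label>_X/_Y/_Z`` dialect.

    Empty cells and the literal ``NaN`` become missing values.  The sample
    rate is not stored in the file format and must be supplied (default
    320 Hz).  Raises :class:`FormatError` naming the offending column for a
    malformed header and a parse error with line number for ragged rows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=float, skip_blank_lines=False, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: could not parse CSV: {exc}") from exc
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric data: {exc}") from exc

    labels: list[str] = []
    for col in df.columns:
        if not col.endswith(_SUFFIXES):
            raise FormatError(
                f"{path}: column {col!r} does not end in _X/_Y/_Z"
            )
        label, suffix = col[:-2], col[-2:]
        if suffix == "_X":
            labels.append(label)

    for label in labels:
        for sfx in _SUFFIXES:
            if f"{label}{sfx}" not in df.columns:
                raise FormatError(
                    f"{path}: marker {label!r} is missing column {label}{sfx}"
                )
    expected = {f"{label}{sfx}" for label in labels for sfx in _SUFFIXES}
    extra = [c for c in df.columns if c not in expected]
    if extra:
        raise FormatError(f"{path}: column {extra[0]!r} has no matching _X column")

    n = len(df)
    positions = np.empty((n, len(labels), 3))
    for j, label in enumerate(labels):
        for k, sfx in enumerate(_SUFFIXES):
            positions[:, j, k] = df[f"{label}{sfx}"].to_numpy()
    # a marker is either fully present or fully missing at a frame
    partial = np.isnan(positions).any(axis=2) & ~np.isnan(positions).all(axis=2)
    positions[partial] = np.nan

    return MarkerTrajectorySet(
        trial_id=trial_id if trial_id is not None else path.stem,
        sample_rate_hz=sample_rate_hz,
        markers=labels,
        positions=positions,
    )


def write_marker_csv(trajectories: MarkerTrajectorySet, path: str | Path) -> None:
    """Write a trajectory set in the dialect read by :func:`read_marker_csv`.

    Missing values are written as empty cells; floats use a 17-significant-
    digit format so the read/write pair is the identity on values.
    """
    path = Path(path)
    cols: dict[str, np.ndarray] = {}
    for j, label in enumerate(trajectories.markers):
        for k, sfx in enumerate(_SUFFIXES):
            cols[f"{label}{sfx}"] = trajectories.positions[:, j, k]
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, na_rep="")


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcsSpec:
    """Anatomical coordinate system placement in body reference coordinates."""

    origin: tuple[float, float, float]
    x_axis: tuple[float, float, float]
    z_axis: tuple[float, float, float]


@dataclass(frozen=True)
class BodyConfig:
    name: str
    markers: dict[str, tuple[float, float, float]]  # label -> reference coords (mm)
    acs: AcsSpec


@dataclass(frozen=True)
class JcsConfig:
    name: str
    proximal: str
    distal: str
    proximal_acs: AcsSpec
    body_kind: str  # "lower_jaw" or "upper_jaw"
    reference_frame: int = 0


@dataclass(frozen=True)
class GapeLandmark:
    body: str
    point: tuple[float, float, float]


@dataclass(frozen=True)
class EventParams:
    expansive_onset_fraction: float = 0.10
    closure_threshold_fraction: float = 0.02


@dataclass(frozen=True)
class SmoothingParams:
    enabled: bool = False
    cutoff_hz: float = 20.0
    order: int = 4


@dataclass
class StudyConfig:
    """Declarative description of one analysis: bodies, JCSs, gape, events."""

    bodies: list[BodyConfig]
    jcs: list[JcsConfig]
    gape_upper: GapeLandmark
    gape_lower: GapeLandmark
    sample_rate_hz: float = 320.0
    events: EventParams = field(default_factory=EventParams)
    smoothing: SmoothingParams = field(default_factory=SmoothingParams)

    def __post_init__(self) -> None:
        names = [b.name for b in self.bodies]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate body names in config")
        for j in self.jcs:
            if j.proximal == j.distal:
                raise ConfigError(f"JCS {j.name!r}: proximal and distal must differ")
            for b in (j.proximal, j.distal):
                if b not in names:
                    raise ConfigError(f"JCS {j.name!r} references unknown body {b!r}")
        if self.gape_upper.body == self.gape_lower.body:
            raise ConfigError("gape landmarks must attach to two distinct bodies")
        for lm in (self.gape_upper, self.gape_lower):
            if lm.body not in names:
                raise ConfigError(f"gape landmark references unknown body {lm.body!r}")

    def body(self, name: str) -> BodyConfig:
        for b in self.bodies:
            if b.name == name:
                return b
        raise ConfigError(f"unknown body {name!r}")

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        def acs(a: Mapping) -> AcsSpec:
            return AcsSpec(tuple(a["origin"]), tuple(a["x_axis"]), tuple(a["z_axis"]))

        try:
            bodies = [
                BodyConfig(
                    name=b["name"],
                    markers={m: tuple(xyz) for m, xyz in b["markers"].items()},
                    acs=acs(b["acs"]),
                )
                for b in d["bodies"]
            ]
            jcs = [
                JcsConfig(
                    name=j["name"],
                    proximal=j["proximal"],
                    distal=j["distal"],
                    proximal_acs=acs(j["proximal_acs"]),
                    body_kind=j["body_kind"],
                    reference_frame=int(j.get("reference_frame", 0)),
                )
                for j in d["jcs"]
            ]
            gape = d["gape"]
            ev = d.get("events", {})
            sm = d.get("smoothing", {})
            return cls(
                bodies=bodies,
                jcs=jcs,
                gape_upper=GapeLandmark(gape["upper"]["body"], tuple(gape["upper"]["point"])),
                gape_lower=GapeLandmark(gape["lower"]["body"], tuple(gape["lower"]["point"])),
                sample_rate_hz=float(d.get("sample_rate_hz", 320.0)),
                events=EventParams(
                    expansive_onset_fraction=float(ev.get("expansive_onset_fraction", 0.10)),
                    closure_threshold_fraction=float(ev.get("closure_threshold_fraction", 0.02)),
                ),
                smoothing=SmoothingParams(
                    enabled=bool(sm.get("enabled", False)),
                    cutoff_hz=float(sm.get("cutoff_hz", 20.0)),
                    order=int(sm.get("order", 4)),
                ),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"invalid study config: {exc}") from exc

    def to_dict(self) -> dict:
        def acs(a: AcsSpec) -> dict:
            return {
                "origin": [float(v) for v in a.origin],
                "x_axis": [float(v) for v in a.x_axis],
                "z_axis": [float(v) for v in a.z_axis],
            }

        return {
            "sample_rate_hz": float(self.sample_rate_hz),
            "bodies": [
                {
                    "name": b.name,
                    "markers": {m: [float(v) for v in xyz] for m, xyz in b.markers.items()},
                    "acs": acs(b.acs),
                }
                for b in self.bodies
            ],
            "jcs": [
                {
                    "name": j.name,
                    "proximal": j.proximal,
                    "distal": j.distal,
                    "proximal_acs": acs(j.proximal_acs),
                    "body_kind": j.body_kind,
                    "reference_frame": j.reference_frame,
                }
                for j in self.jcs
            ],
            "gape": {
                "upper": {"body": self.gape_upper.body, "point": [float(v) for v in self.gape_upper.point]},
                "lower": {"body": self.gape_lower.body, "point": [float(v) for v in self.gape_lower.point]},
            },
            "events": {
                "expansive_onset_fraction": self.events.expansive_onset_fraction,
                "closure_threshold_fraction": self.events.closure_threshold_fraction,
            },
            "smoothing": {
                "enabled": self.smoothing.enabled,
                "cutoff_hz": self.smoothing.cutoff_hz,
                "order": self.smoothing.order,
            },
        }

    @classmethod
    def load(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
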