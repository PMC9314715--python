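"""Rigid-body pose fitting and marker-tracking precision statistics.

Per-frame poses are estimated from tracked marker positions by least squares
over proper rigid transforms (Kabsch/Procrustes without scaling): given
reference coordinates :math:`p_i` and observations :math:`q_i`, find
:math:`R, t` minimising :math:`\\sum_i \\|R p_i + t - q_i\\|^2`, with a
reflection excluded by a sign correction on the smallest singular direction.
This is the maximum-likelihood estimate under isotropic Gaussian marker
noise.

Tracking precision is summarised the standard XROMM way: the standard
deviation over frames of each within-body inter-marker distance.  On a
truly rigid body these distances are constant, so any spread measures
tracking noise; for small isotropic per-coordinate noise of s.d. sigma the
expected pair-distance s.d. is sigma * sqrt(2).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import AcsSpec, BodyConfig, MarkerTrajectorySet
from .transforms import RigidTransform

__all__ = [
    "RigidBodyDefinition",
    "PoseSeries",
    "PrecisionReport",
    "fit_rigid_pose",
    "track_body",
    "marker_pair_distance_sd",
    "precision_report",
]

logger = logging.getLogger(__name__)

#: relative tolerance on the 2nd singular value of centered reference
#: coordinates below which a marker set is treated as collinear
COLLINEAR_RTOL = 1e-8


@dataclass(frozen=True)
class RigidBodyDefinition:
    """A named rigid body: member markers, reference coordinates and ACS.

    ``reference_coords`` is (n_markers, 3) in mm, in the body's reference
    configuration; at least three non-collinear markers are required.
    """

    name: str
    marker_labels: tuple[str, ...]
    reference_coords: np.ndarray
    acs: AcsSpec | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_labels", tuple(self.marker_labels))
        coords = np.asarray(self.reference_coords, dtype=float)
        object.__setattr__(self, "reference_coords", coords)
        if len(self.marker_labels) < 3:
            raise ConfigError(f"body {self.name!r} needs >= 3 markers")
        if coords.shape != (len(self.marker_labels), 3):
            raise ConfigError(
                f"body {self.name!r}: reference_coords shape {coords.shape} does not "
                f"match {len(self.marker_labels)} markers"
            )
        if _is_collinear(coords):
            raise ConfigError(f"body {self.name!r}: reference markers are collinear")

    @classmethod
    def from_config(cls, body: BodyConfig) -> "RigidBodyDefinition":
        labels = tuple(body.markers)
        coords = np.array([body.markers[m] for m in labels], dtype=float)
        return cls(name=body.name, marker_labels=labels, reference_coords=coords, acs=body.acs)


def _is_collinear(coords: np.ndarray) -> bool:
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[1] <= COLLINEAR_RTOL * max(s[0], 1.0)


@dataclass
class PoseSeries:
    """Per-frame rigid transform of one body in world coordinates.

    ``rotations`` is (frames, 3, 3) and ``translations`` (frames, 3); frames
    where the body was untrackable (fewer than three visible markers, or a
    collinear visible subset) are NaN-filled, with NaN residuals.
    """

    body: str
    rotations: np.ndarray
    translations: np.ndarray
    residuals_mm: np.ndarray
    sample_rate_hz: float

    @property
    def frames(self) -> int:
        return self.rotations.shape[0]

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of frames with a pose."""
        return np.isfinite(self.rotations).all(axis=(1, 2))

    def transform(self, frame: int) -> RigidTransform:
        return RigidTransform(self.rotations[frame], self.translations[frame])

    def apply_to_point(self, point_body: Sequence[float]) -> np.ndarray:
        """World trajectory (frames, 3) of a body-attached point."""
        p = np.asarray(point_body, dtype=float)
        return np.einsum("fij,j->fi", self.rotations, p) + self.translations

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: frame, time_s, row-major rotation, translation, residual."""
        f = np.arange(self.frames)
        data = {"frame": f, "time_s": f / self.sample_rate_hz}
        for i in range(3):
            for j in range(3):
                data[f"r{i}{j}"] = self.rotations[:, i, j]
        for k, ax in enumerate("xyz"):
            data[f"t{ax}_mm"] = self.translations[:, k]
        data["residual_mm"] = self.residuals_mm
        return pd.DataFrame(data)


def fit_rigid_pose(
    reference_coords: np.ndarray, observed_coords: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid registration of observed onto reference markers.

    Returns the proper rigid transform (det = +1 enforced by a sign
    correction on the smallest singular direction) minimising the sum of
    squared marker distances, and the residual RMSD in mm.

    Raises :class:`ValueError` for fewer than three correspondences or a
    collinear reference; batch tracking (:func:`track_body`) treats those
    frames as untrackable instead of raising.
    """
    p = np.asarray(reference_coords, dtype=float)
    q = np.asarray(observed_coords, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError(f"shape mismatch: reference {p.shape} vs observed {q.shape}")
    if p.shape[0] < 3:
        raise ValueError("need at least 3 marker correspondences")
    if _is_collinear(p):
        raise ValueError("reference markers are collinear")

    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    H = pc.T @ qc  # cross-covariance; R maximises trace(R H)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = q.mean(axis=0) - R @ p.mean(axis=0)
    resid = float(np.sqrt(np.mean(np.sum((p @ R.T + t - q) ** 2, axis=1))))
    return RigidTransform(R, t), resid


def track_body(trajectories: MarkerTrajectorySet, body: RigidBodyDefinition) -> PoseSeries:
    """Fit a pose at every frame from the body's visible markers.

    Every frame uses all markers of the body that are non-missing at that
    frame; frames with fewer than three visible markers (or a collinear
    visible subset) yield a missing pose.  Raises :class:`ConfigError` if
    the body references a marker label absent from the trajectory set.
    """
    for label in body.marker_labels:
        if label not in trajectories.markers:
            raise ConfigError(
                f"body {body.name!r} references marker {label!r} absent from "
                f"trial {trajectories.trial_id!r}"
            )
    obs = trajectories.subset(body.marker_labels)  # (F, n, 3)
    F = obs.shape[0]
    rotations = np.full((F, 3, 3), np.nan)
    translations = np.full((F, 3), np.nan)
    residuals = np.full(F, np.nan)
    present = np.isfinite(obs).all(axis=2)  # (F, n)

    for f in range(F):
        mask = present[f]
        if mask.sum() < 3:
            continue
        ref = body.reference_coords[mask]
        if _is_collinear(ref):
            continue
        tf, resid = fit_rigid_pose(ref, obs[f, mask])
        rotations[f] = tf.rotation
        translations[f] = tf.translation
        residuals[f] = resid

    return PoseSeries(
        body=body.name,
        rotations=rotations,
        translations=translations,
        residuals_mm=residuals,
        sample_rate_hz=trajectories.sample_rate_hz,
    )


def marker_pair_distance_sd(
    trajectories: MarkerTrajectorySet, body: RigidBodyDefinition
) -> list[tuple[tuple[str, str], float]]:
    """Sample s.d. (n-1 denominator) of each within-body pair distance.

    For each unordered marker pair the per-frame Euclidean distance is
    computed over frames where both markers are present; pairs with fewer
    than two usable frames are omitted with a warning.
    """
    if len(body.marker_labels) < 2:
        raise ConfigError(f"body {body.name!r} needs >= 2 markers for pair distances")
    out: list[tuple[tuple[str, str], float]] = []
    for a, b in itertools.combinations(body.marker_labels, 2):
        pa, pb = trajectories.get(a), trajectories.get(b)
        both = np.isfinite(pa).all(axis=1) & np.isfinite(pb).all(axis=1)
        if both.sum() < 2:
            logger.warning(
                "body %s pair (%s, %s): only %d usable frames, omitted",
                body.name, a, b, int(both.sum()),
            )
            continue
        dist = np.linalg.norm(pa[both] - pb[both], axis=1)
        out.append(((a, b), float(np.std(dist, ddof=1))))
    return out


@dataclass
class PrecisionReport:
    """Pooled marker-pair distance s.d. summary across trials and bodies.

    The headline number is ``grand_mean_mm``, the arithmetic
    mean of all pooled pair s.d. values; its spread is reported both as the
    s.d. and the s.e.m. of the pooled values since "mean ± x" conventions
    vary between studies.
    """

    pairs: pd.DataFrame  # columns: trial_id, body, marker_a, marker_b, sd_mm
    body_means_mm: dict[str, float]
    grand_mean_mm: float
    sd_mm: float
    sem_mm: float
    n_pairs: int

    def to_frame(self) -> pd.DataFrame:
        summary = pd.DataFrame(
            {
                "trial_id": ["<all>"] * 3,
                "body": ["<all>"] * 3,
                "marker_a": ["grand_mean_mm", "sd_mm", "sem_mm"],
                "marker_b": [""] * 3,
                "sd_mm": [self.grand_mean_mm, self.sd_mm, self.sem_mm],
            }
        )
        return pd.concat([self.pairs, summary], ignore_index=True)


def precision_report(
    trial_body_pairs: Iterable[tuple[MarkerTrajectorySet, RigidBodyDefinition]],
) -> PrecisionReport:
    """Pool pair-distance s.d. values across (trial, body) combinations."""
    rows = []
    for traj, body in trial_body_pairs:
        for (a, b), sd in marker_pair_distance_sd(traj, body):
            rows.append(
                {"trial_id": traj.trial_id, "body": body.name, "marker_a": a, "marker_b": b, "sd_mm": sd}
            )
    if not rows:
        raise ValueError("no valid marker pairs anywhere: empty precision report")
    pairs = pd.DataFrame(rows)
    vals = pairs["sd_mm"].to_numpy()
    n = len(vals)
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return PrecisionReport(
        pairs=pairs,
        body_means_mm={b: float(g["sd_mm"].mean()) for b, g in pairs.groupby("body")},
        grand_mean_mm=float(vals.mean()),
        sd_mm=sd,
        sem_mm=sd / np.sqrt(n) if n > 1 else 0.0,
        n_pairs=n,
    )
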