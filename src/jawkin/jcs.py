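"""Joint coordinate systems and anatomical Euler-angle semantics.

A joint coordinate system (JCS) here pairs an anatomical coordinate system
(ACS) on a proximal body (the cranium) with one on a distal body (upper or
lower jaw).  The per-frame relative rotation of the distal ACS expressed in
the proximal ACS,

    R_rel(t) = (R_prox(t) A_prox)^T (R_dist(t) A_dist),

is decomposed as z-y-x Euler angles (``R_rel = Rz Ry Rx``), unwrapped along
time and zeroed at a reference frame, giving rotation "from starting
position" in degrees.

Axis semantics follow shark jaw anatomy: the z axis is the hinge
(depression negative, elevation positive); the x axis runs along the
element's long axis — cranially for the lower jaw and caudally for the
upper jaw, so that positive long-axis rotation means inversion (tooth row
rotates medially) and negative means eversion (tooth row rotates
laterally) for *both* jaws; the y axis captures medio-lateral motion of
the jaw joint, whose raw sign differs between jaws and is mapped to a
common "lateral positive" semantic channel per body kind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError
from .io import AcsSpec
from .rigid import PoseSeries
from .transforms import RigidTransform, euler_zyx

__all__ = [
    "AnatomicalCoordinateSystem",
    "JCSDefinition",
    "AngleSeries",
    "build_acs",
    "relative_rotation",
    "jcs_angle_series",
    "apply_sign_conventions",
    "SEMANTIC_CHANNELS",
]

#: semantic channel names in z, y, x order after sign mapping
SEMANTIC_CHANNELS = ("elevation", "lateral", "inversion")

#: raw-Euler -> semantic sign maps per body kind, in (z, y, x) order.
#: z: elevation positive / depression negative for both jaws (the ACS is
#: built that way); x: inversion positive / eversion negative for both jaws
#: (the caudally flipped upper-jaw x axis preserves the meaning); y: the
#: raw lateral sense differs between jaws, so the upper jaw flips.
SIGN_MAPS = {
    "lower_jaw": np.array([1.0, 1.0, 1.0]),
    "upper_jaw": np.array([1.0, -1.0, 1.0]),
}


@dataclass(frozen=True)
class AnatomicalCoordinateSystem:
    """Body-fixed anatomical frame: origin plus orthonormal axes.

    ``axes`` columns are the X, Y, Z unit axes expressed in body reference
    coordinates; the transform maps ACS coordinates to body coordinates.
    """

    body: str
    origin: np.ndarray
    axes: np.ndarray  # (3, 3), columns X, Y, Z

    def as_transform(self) -> RigidTransform:
        return RigidTransform(self.axes, self.origin)


def build_acs(
    origin,
    x_hint,
    z_hint,
    *,
    body: str = "",
) -> AnatomicalCoordinateSystem:
    """Orthonormalise hint directions into a right-handed anatomical frame.

    ``X = normalize(x_hint)``, ``Y = normalize(z_hint × X)``, ``Z = X × Y``;
    the z hint therefore only needs to indicate the hinge direction, not be
    exactly orthogonal to the long axis.  Raises :class:`ConfigError` for
    (near-)parallel hints.
    """
    x = np.asarray(x_hint, dtype=float)
    z = np.asarray(z_hint, dtype=float)
    nx = np.linalg.norm(x)
    nz = np.linalg.norm(z)
    if nx == 0 or nz == 0:
        raise ConfigError(f"ACS for {body!r}: zero-length axis hint")
    x = x / nx
    y = np.cross(z / nz, x)
    ny = np.linalg.norm(y)
    if ny < 1e-6:
        raise ConfigError(f"ACS for {body!r}: x and z hints are parallel")
    y = y / ny
    zc = np.cross(x, y)
    axes = np.column_stack([x, y, zc])
    return AnatomicalCoordinateSystem(body=body, origin=np.asarray(origin, dtype=float), axes=axes)


def acs_from_spec(spec: AcsSpec, body: str = "") -> AnatomicalCoordinateSystem:
    return build_acs(spec.origin, spec.x_axis, spec.z_axis, body=body)


@dataclass(frozen=True)
class JCSDefinition:
    """One joint coordinate system: proximal/distal bodies and their ACSs.

    The rotation order is fixed z-y-x; ``reference_frame`` is the frame at
    which the angle series is zeroed; ``body_kind`` selects the semantic
    sign map (``lower_jaw`` or ``upper_jaw``).
    """

    name: str
    proximal: str
    distal: str
    proximal_acs: AnatomicalCoordinateSystem
    distal_acs: AnatomicalCoordinateSystem
    body_kind: str
    reference_frame: int = 0

    def __post_init__(self) -> None:
        if self.proximal == self.distal:
            raise ConfigError(f"JCS {self.name!r}: proximal and distal must differ")
        if self.body_kind not in SIGN_MAPS:
            raise ConfigError(
                f"JCS {self.name!r}: unknown body_kind {self.body_kind!r} "
                f"(expected one of {sorted(SIGN_MAPS)})"
            )


@dataclass
class AngleSeries:
    """Per-frame JCS Euler angles in degrees, zeroed at a reference frame.

    ``raw_deg`` holds the (frames, 3) unwrapped, zeroed (thz, thy, thx)
    channels; ``semantic_deg`` the same channels after the body-kind sign
    map, ordered as :data:`SEMANTIC_CHANNELS` (elevation, lateral,
    inversion).  ``gimbal`` flags frames decomposed at gimbal lock.
    """

    name: str
    body_kind: str
    raw_deg: np.ndarray
    semantic_deg: np.ndarray
    reference_frame: int
    sample_rate_hz: float
    gimbal: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    @property
    def frames(self) -> int:
        return self.raw_deg.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.semantic_deg[:, SEMANTIC_CHANNELS.index(name)]

    def to_frame(self) -> pd.DataFrame:
        f = np.arange(self.frames)
        df = pd.DataFrame(
            {
                "frame": f,
                "theta_z_deg": self.raw_deg[:, 0],
                "theta_y_deg": self.raw_deg[:, 1],
                "theta_x_deg": self.raw_deg[:, 2],
            }
        )
        for k, ch in enumerate(SEMANTIC_CHANNELS):
            df[f"{ch}_deg"] = self.semantic_deg[:, k]
        return df


def relative_rotation(
    prox: PoseSeries, dist: PoseSeries, definition: JCSDefinition
) -> np.ndarray:
    """Per-frame rotation of the distal ACS expressed in the proximal ACS.

    Returns (frames, 3, 3); frames where either pose is missing are NaN.
    Raises :class:`AlignmentError` on mismatched frame counts.
    """
    if prox.frames != dist.frames:
        raise AlignmentError(
            f"JCS {definition.name!r}: proximal has {prox.frames} frames, "
            f"distal {dist.frames}"
        )
    a_prox = definition.proximal_acs.axes
    a_dist = definition.distal_acs.axes
    # (R_prox A_prox)^T (R_dist A_dist); NaN poses propagate to NaN output
    world_prox = prox.rotations @ a_prox
    world_dist = dist.rotations @ a_dist
    return np.swapaxes(world_prox, 1, 2) @ world_dist


def _unwrap_deg(angles: np.ndarray) -> np.ndarray:
    """Unwrap each channel along time, tolerating NaN runs."""
    out = angles.copy()
    for k in range(angles.shape[1]):
        col = out[:, k]
        ok = np.isfinite(col)
        if ok.sum() > 1:
            col[ok] = np.unwrap(col[ok], period=360.0)
    return out


def jcs_angle_series(
    prox: PoseSeries, dist: PoseSeries, definition: JCSDefinition
) -> AngleSeries:
    """Full JCS decomposition: relative rotation, z-y-x Euler, unwrap, zero.

    The reference frame must have both poses; otherwise a ValueError names
    the frame.
    """
    rel = relative_rotation(prox, dist, definition)
    ref = definition.reference_frame
    if not (0 <= ref < rel.shape[0]) or not np.isfinite(rel[ref]).all():
        raise ValueError(
            f"JCS {definition.name!r}: no pose at reference frame {ref}; "
            "cannot zero the angle series"
        )
    angles, gimbal = euler_zyx(rel, return_flags=True)
    angles = _unwrap_deg(angles)
    angles = angles - angles[ref]
    raw = AngleSeries(
        name=definition.name,
        body_kind=definition.body_kind,
        raw_deg=angles,
        semantic_deg=np.empty_like(angles),
        reference_frame=ref,
        sample_rate_hz=prox.sample_rate_hz,
        gimbal=gimbal,
    )
    return apply_sign_conventions(raw, definition.body_kind)


def apply_sign_conventions(raw: AngleSeries, body_kind: str) -> AngleSeries:
    """Populate semantic channels from raw Euler channels for a body kind.

    Semantics shared by both jaws after mapping: elevation positive /
    depression negative; inversion positive / eversion negative; joint
    moving laterally positive / medially negative.
    """
    if body_kind not in SIGN_MAPS:
        raise ConfigError(f"unknown body_kind {body_kind!r}")
    raw.semantic_deg = raw.raw_deg * SIGN_MAPS[body_kind]
    raw.body_kind = body_kind
    return raw
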