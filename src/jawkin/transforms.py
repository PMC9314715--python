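"""Rigid transforms and z-y-x Euler angle conversions.

Conventions used throughout the package:

* rotations are *active*, act on column vectors, and are right-handed;
* a :class:`RigidTransform` maps body reference coordinates to world
  coordinates, ``x_world = R @ x_body + t``;
* the Euler decomposition is ``R = Rz(thz) @ Ry(thy) @ Rx(thx)`` ("z-y-x"
  order), angles in degrees, with ``thy`` restricted to [-90, 90].

Sign and order conventions are the main interoperability hazard when
exchanging joint angles between motion-analysis tools, so they are fixed
here once and every other module composes or decomposes through these
helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "rot_x",
    "rot_y",
    "rot_z",
    "euler_zyx_matrix",
    "euler_zyx",
]

#: |cos(thy)| below which the decomposition is treated as gimbal locked.
GIMBAL_TOL = 1e-7

#: allowed deviation from orthogonality for rotation matrices fed to euler_zyx.
ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform (rotation + translation), millimetres.

    Maps body reference coordinates to world coordinates using the
    column-vector convention: ``x_world = rotation @ x_body + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(3))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (..., 3) array of points into world coordinates."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def is_proper(self, tol: float = 1e-9) -> bool:
        """Check orthogonality and det=+1 within ``tol``."""
        r = self.rotation
        return (
            np.allclose(r.T @ r, np.eye(3), atol=tol)
            and abs(np.linalg.det(r) - 1.0) <= tol
        )


def _rot(axis: int, angle_deg: float | np.ndarray) -> np.ndarray:
    a = np.deg2rad(np.asarray(angle_deg, dtype=float))
    c, s = np.cos(a), np.sin(a)
    one = np.ones_like(c)
    zero = np.zeros_like(c)
    if axis == 0:  # x
        rows = [[one, zero, zero], [zero, c, -s], [zero, s, c]]
    elif axis == 1:  # y
        rows = [[c, zero, s], [zero, one, zero], [-s, zero, c]]
    else:  # z
        rows = [[c, -s, zero], [s, c, zero], [zero, zero, one]]
    out = np.stack([np.stack(r, axis=-1) for r in rows], axis=-2)
    return out


def rot_x(angle_deg: float | np.ndarray) -> np.ndarray:
    """Active rotation about +x by ``angle_deg`` degrees; (..., 3, 3)."""
    return _rot(0, angle_deg)


def rot_y(angle_deg: float | np.ndarray) -> np.ndarray:
    return _rot(1, angle_deg)


def rot_z(angle_deg: float | np.ndarray) -> np.ndarray:
    return _rot(2, angle_deg)


def euler_zyx_matrix(thz: float | np.ndarray, thy: float | np.ndarray, thx: float | np.ndarray) -> np.ndarray:
    """Compose ``Rz(thz) @ Ry(thy) @ Rx(thx)`` (degrees); broadcasts."""
    return rot_z(thz) @ rot_y(thy) @ rot_x(thx)


def euler_zyx(
    R: np.ndarray,
    *,
    validate: bool = True,
    return_flags: bool = False,
):
    """Decompose rotation matrices as z-y-x Euler angles in degrees.

    Parameters
    ----------
    R:
        (..., 3, 3) proper rotation matrices.
    validate:
        If true, raise :class:`ValueError` when a finite input matrix is not
        orthogonal within ``ORTHO_TOL``.
    return_flags:
        Also return a boolean array marking frames within ``GIMBAL_TOL`` of
        gimbal lock (|cos thy| ~ 0). At lock the convention is ``thx = 0``
        with ``thz`` absorbing the remaining rotation about the world z axis.

    Returns
    -------
    angles:
        (..., 3) array of ``(thz, thy, thx)`` in degrees, ``thy`` in
        [-90, 90]. NaN-filled for non-finite (missing) input matrices.
    """
    R = np.asarray(R, dtype=float)
    if R.shape[-2:] != (3, 3):
        raise ValueError(f"expected (...,3,3) rotation matrices, got shape {R.shape}")
    flat = R.reshape(-1, 3, 3)
    finite = np.isfinite(flat).all(axis=(1, 2))
    if validate and finite.any():
        good = flat[finite]
        err = np.abs(np.swapaxes(good, 1, 2) @ good - np.eye(3)).max()
        if err > ORTHO_TOL:
            raise ValueError(
                f"input is not orthogonal within {ORTHO_TOL:g} (max deviation {err:.3g})"
            )

    angles = np.full((flat.shape[0], 3), np.nan)
    locked = np.zeros(flat.shape[0], dtype=bool)

    sy = np.clip(-flat[:, 2, 0], -1.0, 1.0)  # R[2,0] = -sin(thy)
    thy = np.arcsin(sy)
    cy = np.cos(thy)
    lock = finite & (np.abs(cy) < GIMBAL_TOL)
    ok = finite & ~lock

    angles[ok, 0] = np.arctan2(flat[ok, 1, 0], flat[ok, 0, 0])
    angles[ok, 1] = thy[ok]
    angles[ok, 2] = np.arctan2(flat[ok, 2, 1], flat[ok, 2, 2])

    # Gimbal lock: thy = ±90°, only thz ± thx is determined.  Convention:
    # thx = 0 and thz takes the whole sum, flagged for the caller.
    angles[lock, 0] = np.arctan2(-flat[lock, 0, 1], flat[lock, 1, 1])
    angles[lock, 1] = thy[lock]
    angles[lock, 2] = 0.0
    locked[lock] = True

    angles = np.rad2deg(angles).reshape(R.shape[:-2] + (3,))
    if return_flags:
        return angles, locked.reshape(R.shape[:-2])
    return angles
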