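"""Coordinate frames, sign conventions, and rigid-transform helpers.

This module is the single source of truth for every sign convention in the
package.

Tibial (global) frame
---------------------
* ``x``: anterior positive, posterior negative.
* ``y``: superior (up) positive; ``y = 0`` at the underside of the insert.
* ``z``: mediolateral, ``z = 0`` at the insert midline.  For a right knee
  the medial side is ``z > 0``; a left knee mirrors ``z``.

Femoral frame
-------------
Origin at the centre of the distal sagittal arc, axes parallel to the
tibial frame at zero flexion.  The femoral bearing surface hangs below the
origin; the posterior arc centre sits posterior-inferior to it.

Input channels
--------------
* Flexion ``phi`` (deg): rotation of the femur by ``+phi`` about the ``+z``
  axis through the selected centre of rotation.  ``+phi`` brings the
  posterior femoral surface into articulation (flexion).
* AP channel ``v`` (mm): position of the tibia along its AP axis using the
  simulator convention that *anterior tibial shift is negative*.  In the
  tibial frame the femur is therefore displaced by ``+v`` along ``x``
  (``v = -10`` puts the femur 10 mm posterior on the insert, i.e. femoral
  rollback).
* IE channel ``psi`` (deg): internal tibial rotation positive.  Relative to
  the tibia the femur rotates by ``-psi`` about the vertical axis through
  the offset rotation centre (the axis is offset medially from the joint
  centre by a fraction of the insert width).

All transforms are 4x4 homogeneous matrices mapping femoral-frame points
into the tibial frame.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rotation",
    "translation",
    "apply_transform",
    "invert",
    "ie_axis_z",
]


def translation(vec) -> np.ndarray:
    """Homogeneous translation by ``vec`` (length-3)."""
    T = np.eye(4)
    T[:3, 3] = np.asarray(vec, dtype=float)
    return T


def rotation(axis, angle_deg: float, point=None) -> np.ndarray:
    """Homogeneous rotation of ``angle_deg`` about ``axis`` through ``point``.

    ``axis`` need not be normalised.  If ``point`` is None the axis passes
    through the origin.  Right-handed positive rotation.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    x, y, z = axis
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    R = np.eye(3) + s * K + (1.0 - c) * (K @ K)
    T = np.eye(4)
    T[:3, :3] = R
    if point is not None:
        p = np.asarray(point, dtype=float)
        T[:3, 3] = p - R @ p
    return T


def apply_transform(T: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 4x4 homogeneous transform to an (N, 3) array (or single point)."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    out = pts @ T[:3, :3].T + T[:3, 3]
    return out[0] if single else out


def invert(T: np.ndarray) -> np.ndarray:
    """Invert a rigid 4x4 transform (rotation transpose, not np.linalg.inv)."""
    R = T[:3, :3]
    out = np.eye(4)
    out[:3, :3] = R.T
    out[:3, 3] = -R.T @ T[:3, 3]
    return out


def ie_axis_z(width_mm: float, side: str = "right", offset_frac: float = 0.07) -> float:
    """z-coordinate of the load / tibial-rotation axis.

    The axis is offset medially from the joint centre by ``offset_frac`` of
    the implant width (7% by default, the simulator mounting convention).
    Medial is ``+z`` for a right knee, ``-z`` for a left knee.
    """
    if side not in ("right", "left"):
        raise ValueError(f"side must be 'right' or 'left', got {side!r}")
    sign = 1.0 if side == "right" else -1.0
    return sign * offset_frac * width_mm
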