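"""Rotation helpers and the clinical Cardan angle convention.

Joint angles are the intrinsic Cardan decomposition of the distal segment's
orientation relative to the proximal segment, sequence mediolateral ->
anteroposterior -> longitudinal (lab Y -> X -> Z in the neutral pose), i.e.
flexion/extension first, ab/adduction second, axial rotation third — the
field-standard clinical sequence.  Output angles are mapped to clinical
positive directions (flexion +, adduction +, internal rotation +,
dorsiflexion +, inversion +) via per-joint, per-side sign multipliers.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "rot_axis_angle",
    "compose_joint",
    "decompose_joint",
    "joint_signs",
    "SEQUENCE",
]

SEQUENCE = "YXZ"  # intrinsic: flexion axis, then frontal, then longitudinal

# sign of the raw Y-rotation that corresponds to clinically positive
# flexion (hip), flexion (knee), dorsiflexion (ankle)
_FLEX_SIGN = {"hip": -1.0, "knee": 1.0, "ankle": -1.0}


def joint_signs(joint: str, side: str) -> np.ndarray:
    """(3,) multipliers clinical -> raw (Y, X, Z) intrinsic angles."""
    if joint not in _FLEX_SIGN:
        raise ValueError(f"unknown joint {joint!r}")
    if side not in ("l", "r"):
        raise ValueError(f"side must be 'l' or 'r', got {side!r}")
    lateral = 1.0 if side == "r" else -1.0  # adduction/int-rotation flip on the left
    return np.array([_FLEX_SIGN[joint], lateral, lateral])


def rot_axis_angle(axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Batched Rodrigues rotation matrices.

    axis: (..., 3) unit vectors; angle: (...) radians -> (..., 3, 3).
    """
    axis = np.asarray(axis, dtype=float)
    angle = np.asarray(angle, dtype=float)
    u = axis / np.linalg.norm(axis, axis=-1, keepdims=True)
    c = np.cos(angle)[..., None, None]
    s = np.sin(angle)[..., None, None]
    ux, uy, uz = u[..., 0], u[..., 1], u[..., 2]
    zero = np.zeros_like(ux)
    k = np.stack(
        [
            np.stack([zero, -uz, uy], axis=-1),
            np.stack([uz, zero, -ux], axis=-1),
            np.stack([-uy, ux, zero], axis=-1),
        ],
        axis=-2,
    )
    eye = np.broadcast_to(np.eye(3), k.shape)
    return eye * c + k * s + (1 - c) * (u[..., :, None] @ u[..., None, :])


def compose_joint(joint: str, side: str, angles_deg: np.ndarray) -> np.ndarray:
    """Clinical (flexion, adduction, internal-rotation) degrees -> (n, 3, 3)."""
    angles_deg = np.atleast_2d(np.asarray(angles_deg, dtype=float))
    raw = angles_deg * joint_signs(joint, side)
    return Rotation.from_euler(SEQUENCE, raw, degrees=True).as_matrix()

def decompose_joint(joint: str, side: str, matrices: np.ndarray, unwrap: bool = True) -> np.ndarray:
    """(n, 3, 3) relative rotations -> clinical angles, degrees, (n, 3).

    Angles are unwrapped along the time axis so curves stay continuous
    through +-180 deg.
    """
    matrices = np.asarray(matrices, dtype=float)
    single = matrices.ndim == 2
    if single:
        matrices = matrices[None]
    raw = Rotation.from_matrix(matrices).as_euler(SEQUENCE, degrees=True)
    if unwrap and len(raw) > 1:
        raw = np.degrees(np.unwrap(np.radians(raw), axis=0))
    out = raw / joint_signs(joint, side)
    return out[0] if single else out


def gimbal_flags(matrices: np.ndarray, margin_deg: float = 1.0) -> np.ndarray:
    """True where the middle Cardan angle is within ``margin_deg`` of +-90."""
    raw = Rotation.from_matrix(np.atleast_3d(matrices)).as_euler(SEQUENCE, degrees=True)
    return np.abs(np.abs(raw[..., 1]) - 90.0) < margin_deg


def orthonormalize(matrices: np.ndarray) -> np.ndarray:
    """Project near-rotation matrices onto SO(3) (batched, via SVD)."""
    u, _, vt = np.linalg.svd(np.asarray(matrices, dtype=float))
    r = u @ vt
    det = np.linalg.det(r)
    # flip the last singular direction where a reflection slipped in
    flip = det < 0
    if np.any(flip):
        u2 = u.copy()
        u2[flip, :, -1] *= -1
        r = u2 @ vt
    return r
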