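"""Segment frames from marker clusters and clinical joint angles.

Anatomical axes are constructed once per subject from the static
(neutral-standing) trial: the pelvis from the ASIS pair and sacrum, thigh
and shank from the estimated hip center, knee- and ankle-joint-line
midpoints, and the foot from its long axis with the static vertical.
During movement each segment is tracked by a least-squares rigid-body
(Kabsch) fit of all its available cluster markers to the static cluster —
robust to single-marker noise — and the anatomical frame rides on that fit.

Joint angles are the Cardan decomposition (flexion -> ab/adduction ->
axial rotation) of the distal anatomical frame relative to the proximal
one, zeroed at the static pose: the neutral standing posture defines 0 deg
on every axis, so marker-placement differences between laboratories enter
the angles only through the anatomical-axis tilt they induce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rotations import decompose_joint, gimbal_flags
from .markers import MarkerSet, default_marker_set
from .skeleton import HIP_REGRESSION_FRACTIONS
from .trial import Trial

__all__ = [
    "estimate_hip_centers",
    "calibrate",
    "build_segment_frames",
    "joint_angles_euler",
    "compute_joint_angles",
    "JOINTS",
]

# joint -> (proximal segment, distal segment template)
JOINTS = {"hip": ("pelvis", "thigh_{s}"), "knee": ("thigh_{s}", "shank_{s}"), "ankle": ("shank_{s}", "foot_{s}")}

_TRACKED_SEGMENTS = ("pelvis", "trunk", "thigh_l", "thigh_r", "shank_l", "shank_r", "foot_l", "foot_r")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _static_positions(static_trial: Trial) -> dict[str, np.ndarray]:
    """Mean lab position (mm) of every marker over the static trial."""
    out = {}
    for j, label in enumerate(static_trial.labels):
        ok = static_trial.valid[:, j]
        if not ok.any():
            continue
        out[label] = static_trial.markers[ok, j, :].mean(axis=0)
    return out


def estimate_hip_centers(
    static_trial: Trial, fractions: tuple[float, float, float] = HIP_REGRESSION_FRACTIONS
) -> dict[str, np.ndarray]:
    """Hip joint centers (lab, mm, static pose) from the pelvic regression.

    The hip center sits at fractions of the inter-ASIS breadth d posterior,
    lateral and distal of the mid-ASIS point, expressed along the pelvis
    anatomical axes.  The regression fractions are configurable so an
    alternative published regression can be swapped in.
    """
    pos = _static_positions(static_trial)
    for lm in ("LASIS", "RASIS", "SACR"):
        if lm not in pos:
            raise ValueError(f"missing pelvis landmark {lm!r} in static trial")
    d = float(np.linalg.norm(pos["LASIS"] - pos["RASIS"]))
    if d <= 1e-9:
        raise ValueError("degenerate pelvis: inter-ASIS width is zero")
    axes, origin = _pelvis_axes(pos)
    post, lat, dist = fractions
    x_a, y_a, z_a = axes[:, 0], axes[:, 1], axes[:, 2]
    return {
        "l": origin + d * (-post * x_a + lat * y_a - dist * z_a),
        "r": origin + d * (-post * x_a - lat * y_a - dist * z_a),
    }


def _pelvis_axes(pos: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    mid_asis = 0.5 * (pos["LASIS"] + pos["RASIS"])
    y = _unit(pos["LASIS"] - pos["RASIS"])
    x0 = mid_asis - pos["SACR"]
    z = _unit(np.cross(x0, y))
    x = np.cross(y, z)
    return np.stack([x, y, z], axis=-1), mid_asis


def _long_ml_axes(z0: np.ndarray, ml: np.ndarray) -> np.ndarray:
    """Frame with exact long axis z and approximate mediolateral axis."""
    z = _unit(z0)
    x = _unit(np.cross(ml, z))
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=-1)


@dataclass
class SegmentCalibration:
    segment: str
    cluster: list[str]
    static_points: np.ndarray  # (k, 3) mm
    A_static: np.ndarray  # (3, 3) anatomical axes, columns, local->lab
    origin_static: np.ndarray  # (3,) mm, proximal joint center


@dataclass
class AnatomicalCalibration:
    segments: dict[str, SegmentCalibration]
    hip_centers: dict[str, np.ndarray]
    r_rel_static: dict[str, np.ndarray] = field(default_factory=dict)  # "hip_l" -> (3,3)


def calibrate(
    static_trial: Trial,
    marker_set: MarkerSet | None = None,
    hip_fractions: tuple[float, float, float] = HIP_REGRESSION_FRACTIONS,
) -> AnatomicalCalibration:
    """Anatomical calibration from a neutral-standing static trial."""
    marker_set = marker_set or default_marker_set()
    pos = _static_positions(static_trial)
    by_seg = marker_set.segments()
    hips = estimate_hip_centers(static_trial, hip_fractions)

    segs: dict[str, SegmentCalibration] = {}

    def _add(segment: str, A: np.ndarray, origin: np.ndarray) -> None:
        cluster = [m for m in by_seg.get(segment, []) if m in pos]
        if len(cluster) < 3:
            raise ValueError(f"segment {segment!r}: fewer than 3 markers in static trial")
        pts = np.stack([pos[m] for m in cluster])
        segs[segment] = SegmentCalibration(segment, cluster, pts, A, origin)

    A_p, origin_p = _pelvis_axes(pos)
    _add("pelvis", A_p, origin_p)
    _add("trunk", np.eye(3), pos["C7"])

    for side in ("l", "r"):
        P = side.upper()
        knee_c = 0.5 * (pos[f"{P}KNEM"] + pos[f"{P}KNEL"])
        ankle_c = 0.5 * (pos[f"{P}ANKM"] + pos[f"{P}ANKL"])
        ml_sign = 1.0 if side == "l" else -1.0  # mediolateral axis points left
        ml_thigh = ml_sign * (pos[f"{P}KNEL"] - pos[f"{P}KNEM"])
        ml_shank = ml_sign * (pos[f"{P}ANKL"] - pos[f"{P}ANKM"])
        _add(f"thigh_{side}", _long_ml_axes(hips[side] - knee_c, ml_thigh), hips[side])
        _add(f"shank_{side}", _long_ml_axes(knee_c - ankle_c, ml_shank), knee_c)
        x_f = _unit(pos[f"{P}TOE"] - pos[f"{P}HEE"])
        y_f = _unit(np.cross(np.array([0.0, 0.0, 1.0]), x_f))
        z_f = np.cross(x_f, y_f)
        segs[f"foot_{side}"] = SegmentCalibration(
            f"foot_{side}",
            [m for m in by_seg[f"foot_{side}"] if m in pos],
            np.stack([pos[m] for m in by_seg[f"foot_{side}"] if m in pos]),
            np.stack([x_f, y_f, z_f], axis=-1),
            ankle_c,
        )

    cal = AnatomicalCalibration(segments=segs, hip_centers=hips)
    for joint, (prox_t, dist_t) in JOINTS.items():
        for side in ("l", "r"):
            prox = segs[prox_t.format(s=side) if "{s}" in prox_t else prox_t]
            dist = segs[dist_t.format(s=side)]
            cal.r_rel_static[f"{joint}_{side}"] = prox.A_static.T @ dist.A_static
    return cal


def _kabsch_batch(
    x_static: np.ndarray, x_dyn: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid fit static cluster -> each dynamic frame.

    x_static: (k, 3); x_dyn: (n, k, 3).  Returns R (n,3,3), t (n,3) such
    that R @ x_static + t ~= x_dyn, and per-frame RMS residual (n,).
    """
    cs = x_static.mean(axis=0)
    cd = x_dyn.mean(axis=1)
    xs = x_static - cs
    xd = x_dyn - cd[:, None, :]
    h = np.einsum("ki,nkj->nij", xs, xd)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("nij,nkj->nik", vt, u).transpose(0, 2, 1))
    # R = V diag(1,1,det) U^T  (mapping static -> dynamic)
    v = vt.transpose(0, 2, 1)
    v_adj = v.copy()
    v_adj[:, :, 2] *= np.sign(det)[:, None]
    r = np.einsum("nij,nkj->nik", v_adj, u)
    t = cd - np.einsum("nij,j->ni", r, cs)
    fit = np.einsum("nij,kj->nki", r, xs) + cd[:, None, :] - cd[:, None, :]
    resid = fit - xd
    rms = np.sqrt(np.mean(np.sum(resid**2, axis=2), axis=1))
    return r, t, rms


@dataclass
class SegmentFrames:
    """Tracked anatomical frame series for one segment.

    ``A`` columns are the anatomical axes in the lab (orthonormal,
    right-handed); ``origin`` is the proximal joint center in mm.
    """

    segment: str
    A: np.ndarray  # (n, 3, 3)
    origin: np.ndarray  # (n, 3) mm
    residual_rms: np.ndarray  # (n,) mm


def build_segment_frames(
    trial: Trial,
    static_trial: Trial | AnatomicalCalibration,
    marker_set: MarkerSet | None = None,
    segments: tuple[str, ...] = _TRACKED_SEGMENTS,
) -> dict[str, SegmentFrames]:
    """Track every segment's anatomical frame through a movement trial."""
    cal = (
        static_trial
        if isinstance(static_trial, AnatomicalCalibration)
        else calibrate(static_trial, marker_set)
    )
    n = trial.n_frames
    out: dict[str, SegmentFrames] = {}
    for seg_name in segments:
        sc = cal.segments[seg_name]
        idx = [trial.index(m) for m in sc.cluster]
        valid = trial.valid[:, idx]
        R = np.empty((n, 3, 3))
        t = np.empty((n, 3))
        rms = np.empty(n)
        patterns, inverse = np.unique(valid, axis=0, return_inverse=True)
        for p, pat in enumerate(patterns):
            rows = np.flatnonzero(inverse == p)
            if pat.sum() < 3:
                raise ValueError(
                    f"segment {seg_name!r}: fewer than 3 valid markers at frame {rows[0]}"
                )
            sub = np.flatnonzero(pat)
            Rp, tp, rp = _kabsch_batch(sc.static_points[sub], trial.markers[np.ix_(rows, np.array(idx)[sub])])
            R[rows], t[rows], rms[rows] = Rp, tp, rp
        A = R @ sc.A_static
        origin = t + np.einsum("nij,j->ni", R, sc.origin_static)
        out[seg_name] = SegmentFrames(segment=seg_name, A=A, origin=origin, residual_rms=rms)
    return out


def joint_angles_euler(
    prox: SegmentFrames | np.ndarray,
    dist: SegmentFrames | np.ndarray,
    joint: str,
    side: str,
    r_rel_static: np.ndarray | None = None,
    gimbal_margin_deg: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Clinical joint angles (deg) of distal relative to proximal.

    The relative rotation is zeroed at the static pose when
    ``r_rel_static`` is given (angles are then deviations from neutral).
    Returns (angles (n, 3), gimbal warning flags (n,)).
    """
    A_p = prox.A if isinstance(prox, SegmentFrames) else np.asarray(prox)
    A_d = dist.A if isinstance(dist, SegmentFrames) else np.asarray(dist)
    r_rel = np.einsum("nji,njk->nik", A_p, A_d)
    if r_rel_static is not None:
        r_rel = np.einsum("ji,njk->nik", r_rel_static, r_rel)
    angles = decompose_joint(joint, side, r_rel)
    flags = gimbal_flags(r_rel, gimbal_margin_deg)
    return angles, flags


def compute_joint_angles(
    trial: Trial,
    static_trial: Trial | AnatomicalCalibration,
    marker_set: MarkerSet | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, SegmentFrames], AnatomicalCalibration]:
    """Hip/knee/ankle angle series for both sides, plus the tracked frames.

    Returns (angles, frames, calibration) with angles keyed ``"hip_l"`` etc.,
    each (n_frames, 3) degrees in (flexion, adduction, internal-rotation)
    order (ankle: dorsiflexion, inversion, internal rotation).
    """
    cal = (
        static_trial
        if isinstance(static_trial, AnatomicalCalibration)
        else calibrate(static_trial, marker_set)
    )
    frames = build_segment_frames(trial, cal, marker_set)
    angles: dict[str, np.ndarray] = {}
    for joint, (prox_t, dist_t) in JOINTS.items():
        for side in ("l", "r"):
            prox = frames[prox_t.format(s=side) if "{s}" in prox_t else prox_t]
            dist = frames[dist_t.format(s=side)]
            ang, _ = joint_angles_euler(
                prox, dist, joint, side, cal.r_rel_static[f"{joint}_{side}"]
            )
            angles[f"{joint}_{side}"] = ang
    return angles, frames, cal
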