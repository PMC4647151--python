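"""Inverse-dynamics joint moments (Newton-Euler, bottom-up).

The recursion runs foot -> shank -> thigh per side, using segment poses
tracked by the kinematics module, segment inertial parameters from the
anthropometry table, and measured ground-reaction forces.  Reported
moments are *internal* (the moment the proximal segment's musculature
exerts on the distal segment), expressed in the proximal segment's
anatomical frame and normalized by body mass (N*m/kg).

Force handling follows the capture protocol: the plate's center of
pressure is computed from the raw force/moment channels (masked where the
vertical force is below the stance threshold, to avoid divide-by-small-
force artifacts), then COP, force and free moment are low-pass filtered at
the same cutoff as the markers and decimated onto the marker clock.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rotations import joint_signs
from .anthropometry import LENGTH_FRACTIONS, SegmentInertia, segment_inertia
from .kinematics import AnatomicalCalibration, SegmentFrames
from .preprocess import butterworth_lowpass
from .trial import GRAVITY, Trial

__all__ = [
    "segment_kinematics",
    "newton_euler_side",
    "inverse_dynamics",
    "assign_plates",
    "prepare_grf",
    "GrfInput",
]

_G_VEC = np.array([0.0, 0.0, -GRAVITY])


def _grad(x: np.ndarray, dt: float) -> np.ndarray:
    """Central differences along axis 0 (one-sided at the ends)."""
    return np.gradient(x, dt, axis=0)


def segment_kinematics(
    R: np.ndarray, origin: np.ndarray, rate: float, com_local: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """Linear/angular velocity and acceleration of one segment.

    ``R`` (n,3,3) local->lab, ``origin`` (n,3) meters.  Angular velocity is
    extracted from the skew part of dR/dt R^T; all derivatives are central
    differences with one-sided endpoints.
    """
    R = np.asarray(R, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if len(R) < 3:
        raise ValueError("need at least 3 frames to differentiate")
    dt = 1.0 / rate
    com = origin if com_local is None else origin + np.einsum("nij,j->ni", R, com_local)
    vel = _grad(com, dt)
    acc = _grad(vel, dt)
    rdot = _grad(R, dt)
    w_skew = np.einsum("nij,nkj->nik", rdot, R)
    w_skew = 0.5 * (w_skew - w_skew.transpose(0, 2, 1))
    omega = np.stack([w_skew[:, 2, 1], w_skew[:, 0, 2], w_skew[:, 1, 0]], axis=1)
    alpha = _grad(omega, dt)
    return {"com": com, "vel": vel, "acc": acc, "omega": omega, "alpha": alpha}


@dataclass
class GrfInput:
    """External load on one foot, marker clock, SI units (N, m, N*m)."""

    force: np.ndarray  # (n, 3)
    cop: np.ndarray  # (n, 3) m
    tz: np.ndarray  # (n,) vertical free moment


def newton_euler_side(
    poses: dict[str, tuple[np.ndarray, np.ndarray]],
    inertias: dict[str, SegmentInertia],
    grf: GrfInput,
    rate: float,
    gravity: float = GRAVITY,
) -> dict[str, dict[str, np.ndarray]]:
    """Bottom-up recursion for one leg.

    ``poses[kind] = (R (n,3,3), origin_m (n,3))`` for kind in foot/shank/
    thigh, origins at the distal joint of the parent (ankle, knee, hip).
    Returns per joint the internal joint force and moment (lab frame, N and
    N*m, acting on the distal segment at its proximal joint).
    """
    g_vec = np.array([0.0, 0.0, -gravity])
    out: dict[str, dict[str, np.ndarray]] = {}
    # external load on the foot acts at the COP
    n = len(grf.force)
    f_child = grf.force.copy()  # force applied to segment by whatever is below it
    p_child = grf.cop.copy()
    m_child = np.zeros((n, 3))
    m_child[:, 2] = grf.tz
    joints = {"foot": "ankle", "shank": "knee", "thigh": "hip"}
    for kind in ("foot", "shank", "thigh"):
        R, origin = poses[kind]
        inert = inertias[kind]
        kin = segment_kinematics(R, origin, rate, inert.com_local)
        c = kin["com"]
        # linear balance: m a = F_prox + m g + F_child
        f_prox = inert.mass * (kin["acc"] - g_vec) - f_child
        # angular balance about the segment CoM
        i_lab = np.einsum("nij,j,nkj->nik", R, inert.inertia, R)
        h_dot = np.einsum("nij,nj->ni", i_lab, kin["alpha"]) + np.cross(
            kin["omega"], np.einsum("nij,nj->ni", i_lab, kin["omega"])
        )
        m_prox = (
            h_dot
            - np.cross(origin - c, f_prox)
            - np.cross(p_child - c, f_child)
            - m_child
        )
        out[joints[kind]] = {"force": f_prox, "moment": m_prox, "position": origin}
        # reaction on the next segment up
        f_child = -f_prox
        p_child = origin
        m_child = -m_prox
    return out


def assign_plates(trial: Trial, stance_slice: slice, threshold: float = 10.0) -> dict[str, int]:
    """Match each foot to the plate whose stance COP is nearest its ankle.

    Raises if both feet resolve to the same plate (ambiguous assignment).
    """
    cops = []
    for p, plate in enumerate(trial.plates):
        cop = plate.cop(threshold)[stance_slice]
        if np.isfinite(cop[:, 1]).any():
            cops.append((p, np.nanmean(cop[:, :2], axis=0)))
    assignment: dict[str, int] = {}
    for side in ("l", "r"):
        ank = np.nanmean(trial.marker(f"{side.upper()}ANKL")[:, :2], axis=0) / 1000.0
        if not cops:
            raise ValueError("no loaded force plate found during stance")
        dists = [(np.linalg.norm(xy / 1000.0 - ank), p) for p, xy in cops]
        assignment[side] = min(dists)[1]
    if len(trial.plates) > 1 and assignment["l"] == assignment["r"]:
        raise ValueError("plate assignment ambiguous: both feet map to one plate")
    return assignment


def prepare_grf(
    trial: Trial,
    plate_index: int,
    cutoff_hz: float = 12.0,
    order: int = 4,
    threshold: float = 10.0,
) -> GrfInput:
    """Filtered, marker-clock external load for one plate (SI units)."""
    plate = trial.plates[plate_index]
    cop_mm = plate.cop(threshold)
    tz = plate.free_moment_z(threshold)
    # fill COP/free moment outside stance by edge-hold interpolation so the
    # filter sees a finite series; the flight-phase values are irrelevant
    # because the force there is ~0
    n = len(cop_mm)
    t = np.arange(n)
    cop_filled = np.empty_like(cop_mm)
    ok = np.isfinite(cop_mm[:, 0])
    if not ok.any():
        cop_filled[:] = 0.0
        tz_filled = np.zeros(n)
    else:
        for c in range(3):
            cop_filled[:, c] = np.interp(t, t[ok], cop_mm[ok, c])
        tz_filled = np.interp(t, t[ok], tz[ok])
    force_f = butterworth_lowpass(plate.force, trial.force_rate, cutoff_hz, order)
    cop_f = butterworth_lowpass(cop_filled, trial.force_rate, cutoff_hz, order)
    tz_f = butterworth_lowpass(tz_filled, trial.force_rate, cutoff_hz, order)
    step = trial.rate_ratio
    m = trial.n_frames
    sel = np.arange(m) * step
    return GrfInput(force=force_f[sel], cop=cop_f[sel] / 1000.0, tz=tz_f[sel])


def _inertias_for(subject_mass: float, height_cm: float) -> dict[str, SegmentInertia]:
    h = height_cm / 100.0
    return {
        "foot": segment_inertia("foot", subject_mass, LENGTH_FRACTIONS["foot_length"] * h),
        "shank": segment_inertia("shank", subject_mass, LENGTH_FRACTIONS["shank_length"] * h),
        "thigh": segment_inertia("thigh", subject_mass, LENGTH_FRACTIONS["thigh_length"] * h),
    }


def inverse_dynamics(
    trial: Trial,
    frames: dict[str, SegmentFrames],
    cal: AnatomicalCalibration | None = None,
    cutoff_hz: float = 12.0,
    order: int = 4,
    threshold: float = 10.0,
    grf_by_side: dict[str, GrfInput] | None = None,
) -> dict[str, np.ndarray]:
    """Mass-normalized internal joint moments for both sides.

    Returns ``{"ankle_l": (n, 3), ...}`` in N*m/kg, components ordered
    (flexion axis, frontal axis, longitudinal axis) of the *proximal*
    anatomical frame, mapped to clinical positive directions with the same
    per-side sign convention as the joint angles.
    """
    mass = trial.subject.mass
    inertias = _inertias_for(mass, trial.subject.height)
    if grf_by_side is None:
        grf_total = trial.total_grf()
        loaded = np.flatnonzero(grf_total[:, 2] > threshold)
        stance_slice = slice(int(loaded[0]), int(loaded[-1]) + 1) if loaded.size else slice(0, 1)
        assignment = assign_plates(trial, stance_slice, threshold)
        grf_by_side = {
            side: prepare_grf(trial, plate, cutoff_hz, order, threshold)
            for side, plate in assignment.items()
        }
    out: dict[str, np.ndarray] = {}
    prox_of = {"ankle": "shank_{s}", "knee": "thigh_{s}", "hip": "pelvis"}
    for side in ("l", "r"):
        poses = {
            kind: (frames[f"{kind}_{side}"].A, frames[f"{kind}_{side}"].origin / 1000.0)
            for kind in ("foot", "shank", "thigh")
        }
        res = newton_euler_side(poses, inertias, grf_by_side[side], trial.marker_rate)
        for joint in ("ankle", "knee", "hip"):
            prox_seg = prox_of[joint].format(s=side)
            A_p = frames[prox_seg].A
            m_local = np.einsum("nji,nj->ni", A_p, res[joint]["moment"])
            raw = m_local[:, [1, 0, 2]]  # (flexion axis Y, frontal X, longitudinal Z)
            clinical = raw / joint_signs(joint, side)
            out[f"{joint}_{side}"] = clinical / mass
    return out
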