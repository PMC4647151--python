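"""Rigid-segment skeleton model used by the synthetic DVJ generator.

Segments: pelvis, trunk (with head and arms rigidly attached), and per side
thigh, shank, foot, arm.  Each segment frame has its origin at the proximal
joint center (pelvis: mid-ASIS; trunk: a fixed point above the pelvis
origin), is lab-aligned in the neutral standing pose, and carries fixed
local marker positions, so all markers within a segment stay rigid by
construction.  Hip joint centers are placed from inter-ASIS breadth using
the standard pelvic regression fractions (posterior 0.19 d, lateral 0.36 d,
distal 0.30 d), the same regression the kinematics module uses by default —
which closes the loop between generated and reconstructed geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anthropometry import LENGTH_FRACTIONS, SEGMENT_TABLE
from .trial import Subject

__all__ = ["SkeletonModel", "build_skeleton", "HIP_REGRESSION_FRACTIONS", "markers_from_poses"]

# hip center offset from mid-ASIS as fractions of inter-ASIS breadth:
# (posterior, lateral, distal)
HIP_REGRESSION_FRACTIONS = (0.19, 0.36, 0.30)


@dataclass
class SegmentPose:
    """Batched rigid pose: origin (n, 3) meters, R (n, 3, 3) local->lab."""

    origin: np.ndarray
    R: np.ndarray


@dataclass
class SkeletonModel:
    subject: Subject
    lengths: dict[str, float]  # m, keys of LENGTH_FRACTIONS
    marker_locals: dict[str, tuple[str, np.ndarray]]  # label -> (segment, local m)
    hip_local: dict[str, np.ndarray]  # side 'l'/'r' -> hip center in pelvis frame
    trunk_offset: np.ndarray  # trunk origin relative to pelvis origin (neutral)
    mass_fractions: dict[str, float] = field(
        default_factory=lambda: {k: v["mass_frac"] for k, v in SEGMENT_TABLE.items()}
    )

    @property
    def hip_width(self) -> float:
        return float(self.hip_local["l"][1] - self.hip_local["r"][1])

    def segment_markers(self, segment: str) -> list[str]:
        return [m for m, (seg, _) in self.marker_locals.items() if seg == segment]

    def com_local(self, segment_kind: str) -> np.ndarray:
        entry = SEGMENT_TABLE[segment_kind]
        return np.asarray(entry["com"], dtype=float) * self.lengths[entry["ref"]]


def _lat(side: str) -> float:
    """Sign of the lateral direction on lab Y (left limb: +Y, right: -Y)."""
    return 1.0 if side == "l" else -1.0


def build_skeleton(subject: Subject, table: dict | None = None) -> SkeletonModel:
    """Construct a subject-scaled skeleton with plausible marker placements."""
    h = subject.height / 100.0  # m
    fr = dict(LENGTH_FRACTIONS)
    lengths = {k: v * h for k, v in fr.items()}
    d = lengths["asis_breadth"]
    lt, ls = lengths["thigh_length"], lengths["shank_length"]
    ha, lf = lengths["ankle_height"], lengths["foot_length"]

    post, latf, dist = HIP_REGRESSION_FRACTIONS
    hip_local = {
        "l": np.array([-post * d, +latf * d, -dist * d]),
        "r": np.array([-post * d, -latf * d, -dist * d]),
    }

    locals_: dict[str, tuple[str, np.ndarray]] = {
        # pelvis (origin mid-ASIS)
        "LASIS": ("pelvis", np.array([0.0, d / 2, 0.0])),
        "RASIS": ("pelvis", np.array([0.0, -d / 2, 0.0])),
        "SACR": ("pelvis", np.array([-0.50 * d, 0.0, 0.0])),
        "LPSIS": ("pelvis", np.array([-0.45 * d, 0.21 * d, 0.06 * d])),
        # trunk (origin above pelvis origin; arms and head ride on it)
        "C7": ("trunk", np.array([-0.06, 0.0, 0.46])),
        "STRN": ("trunk", np.array([0.09, 0.0, 0.33])),
        "BPK1": ("trunk", np.array([-0.13, 0.0, 0.32])),
        "BPK2": ("trunk", np.array([-0.13, 0.055, 0.22])),
        "BPK3": ("trunk", np.array([-0.13, -0.045, 0.13])),
    }
    for side in ("l", "r"):
        s = _lat(side)
        P = side.upper()
        locals_[f"{P}SHO"] = ("trunk", np.array([-0.01, s * 0.19, 0.44]))
        # arm segment, origin at the shoulder, rigid w.r.t. the trunk
        locals_[f"{P}UPARM"] = (f"arm_{side}", np.array([0.01, s * 0.04, -0.12]))
        locals_[f"{P}ELB"] = (f"arm_{side}", np.array([0.03, s * 0.05, -0.30]))
        locals_[f"{P}WRI"] = (f"arm_{side}", np.array([0.22, s * 0.03, -0.38]))
        # thigh, origin at hip center
        locals_[f"{P}TROC"] = (f"thigh_{side}", np.array([0.0, s * 0.07, -0.03]))
        locals_[f"{P}THI"] = (f"thigh_{side}", np.array([0.04, s * 0.05, -0.55 * lt]))
        locals_[f"{P}KNEL"] = (f"thigh_{side}", np.array([0.0, s * 0.055, -lt]))
        locals_[f"{P}KNEM"] = (f"thigh_{side}", np.array([0.0, -s * 0.055, -lt]))
        # shank, origin at knee center
        locals_[f"{P}TTUB"] = (f"shank_{side}", np.array([0.045, 0.0, -0.12 * ls]))
        locals_[f"{P}SHNL"] = (f"shank_{side}", np.array([0.0, s * 0.05, -0.50 * ls]))
        locals_[f"{P}SHNK"] = (f"shank_{side}", np.array([0.01, s * 0.045, -0.82 * ls]))
        locals_[f"{P}ANKM"] = (f"shank_{side}", np.array([0.0, -s * 0.045, -ls]))
        locals_[f"{P}ANKL"] = (f"shank_{side}", np.array([0.0, s * 0.045, -ls]))
        # foot, origin at ankle center, sole at z = -ankle_height
        # heel and toe share local height and the midline so the foot's
        # anatomical long axis is exactly anterior in the neutral pose
        locals_[f"{P}HEE"] = (f"foot_{side}", np.array([-0.06, 0.0, -ha + 0.02]))
        locals_[f"{P}MFT"] = (f"foot_{side}", np.array([0.05, 0.0, -ha + 0.045]))
        locals_[f"{P}MT5"] = (f"foot_{side}", np.array([0.09, s * 0.045, -ha + 0.015]))
        locals_[f"{P}TOE"] = (f"foot_{side}", np.array([lf - 0.06, 0.0, -ha + 0.02]))

    return SkeletonModel(
        subject=subject,
        lengths=lengths,
        marker_locals=locals_,
        hip_local=hip_local,
        trunk_offset=np.array([-0.01, 0.0, 0.10]),
    )


def markers_from_poses(
    model: SkeletonModel, poses: dict[str, SegmentPose], labels: list[str]
) -> np.ndarray:
    """Forward kinematics: (n_frames, n_markers, 3) marker positions in meters."""
    n = next(iter(poses.values())).origin.shape[0]
    out = np.empty((n, len(labels), 3))
    for j, label in enumerate(labels):
        seg, local = model.marker_locals[label]
        pose = poses[seg]
        out[:, j, :] = pose.origin + np.einsum("nij,j->ni", pose.R, local)
    return out
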