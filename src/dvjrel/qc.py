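"""Data-quality verification: skeleton tracking check and outlier curves.

Two automated verification steps guard a batch pipeline against
mistracked markers:

1. ``skeleton_check`` fits a simplified rigid skeleton — per-segment
   least-squares cluster fits plus inter-marker distance drift against the
   static capture.  Swapped or mistracked marker labels make the rigid fit
   impossible and the residual jumps, flagging the trial for human
   re-tracking.
2. ``outlier_curves`` screens groups of time-normalized waveforms with a
   pointwise confidence band; curves that spend too long outside the band
   are flagged for re-examination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .kinematics import AnatomicalCalibration, build_segment_frames, calibrate
from .markers import MarkerSet, default_marker_set
from .trial import Trial

__all__ = ["skeleton_check", "outlier_curves", "SkeletonCheckResult", "QCReport"]


@dataclass
class SkeletonCheckResult:
    trial_id: str
    residual_rms: float  # mm, worst segment mean
    residual_max: float  # mm, worst single frame
    distance_drift_max: float  # mm, worst inter-marker distance deviation vs static
    frac_frames_over: float  # fraction of frames with any segment residual > threshold
    per_segment_rms: dict[str, float]
    passed: bool


def skeleton_check(
    trial: Trial,
    static_trial: Trial | AnatomicalCalibration,
    marker_set: MarkerSet | None = None,
    residual_threshold_mm: float = 15.0,
    max_frac_over: float = 0.01,
) -> SkeletonCheckResult:
    """Rigid-skeleton tracking sanity check for one (gap-filled) trial.

    The trial fails when any segment's cluster-fit residual exceeds
    ``residual_threshold_mm`` in more than ``max_frac_over`` of frames.
    """
    marker_set = marker_set or default_marker_set()
    cal = (
        static_trial
        if isinstance(static_trial, AnatomicalCalibration)
        else calibrate(static_trial, marker_set)
    )
    frames = build_segment_frames(trial, cal, marker_set)
    per_seg = {name: float(sf.residual_rms.mean()) for name, sf in frames.items()}
    res_stack = np.stack([sf.residual_rms for sf in frames.values()])
    over = (res_stack > residual_threshold_mm).any(axis=0)

    drift_max = 0.0
    for name, sf in frames.items():
        sc = cal.segments[name]
        idx = [trial.index(m) for m in sc.cluster]
        pts = trial.markers[:, idx, :]
        for (i, a), (j, b) in combinations(enumerate(sc.cluster), 2):
            d_static = np.linalg.norm(sc.static_points[i] - sc.static_points[j])
            d_dyn = np.linalg.norm(pts[:, i] - pts[:, j], axis=1)
            ok = trial.valid[:, idx[i]] & trial.valid[:, idx[j]]
            if ok.any():
                drift_max = max(drift_max, float(np.nanmax(np.abs(d_dyn[ok] - d_static))))

    frac_over = float(over.mean())
    trial_id = f"{trial.site}/{trial.subject.id}/t{trial.trial_index}"
    return SkeletonCheckResult(
        trial_id=trial_id,
        residual_rms=max(per_seg.values()),
        residual_max=float(res_stack.max()),
        distance_drift_max=drift_max,
        frac_frames_over=frac_over,
        per_segment_rms=per_seg,
        passed=frac_over <= max_frac_over,
    )


def outlier_curves(
    curves: np.ndarray, confidence: float = 0.95, max_frac_outside: float = 0.20
) -> np.ndarray:
    """Flag outlying curves against the group's pointwise confidence band.

    ``curves`` is (n_curves, T).  The band is mean +- z * SD at each time
    point (z from the two-sided normal ``confidence``); a curve is flagged
    when more than ``max_frac_outside`` of its points fall outside the
    band computed from the *other* curves (leave-one-out, so a gross
    outlier cannot mask itself).  Needs at least 5 curves.
    """
    from scipy.stats import norm

    y = np.asarray(curves, dtype=float)
    if y.ndim != 2 or y.shape[0] < 5:
        raise ValueError("insufficient curves: need at least 5")
    n, t = y.shape
    z = norm.ppf(0.5 + confidence / 2.0)
    flags = np.zeros(n, dtype=bool)
    idx = np.arange(n)
    for i in range(n):
        rest = y[idx != i]
        mu = rest.mean(axis=0)
        sd = rest.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, np.inf)  # a zero-variance point never flags
        outside = np.abs(y[i] - mu) > z * sd
        flags[i] = outside.mean() > max_frac_outside
    return flags


@dataclass
class QCReport:
    skeleton: list[SkeletonCheckResult] = field(default_factory=list)
    outlier_flags: dict[str, list[str]] = field(default_factory=dict)  # variable -> trial ids

    @property
    def n_failed(self) -> int:
        return sum(not r.passed for r in self.skeleton)

    @property
    def passed(self) -> bool:
        return self.n_failed == 0 and not any(self.outlier_flags.values())

    def to_dict(self) -> dict:
        return {
            "n_trials": len(self.skeleton),
            "n_failed_skeleton": self.n_failed,
            "failed_trials": [r.trial_id for r in self.skeleton if not r.passed],
            "outlier_flags": self.outlier_flags,
            "worst_residual_mm": max((r.residual_max for r in self.skeleton), default=0.0),
        }
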