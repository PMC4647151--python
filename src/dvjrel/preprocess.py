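"""Gap filling, filtering, stance detection and time normalization.

Processing order for a trial is fixed: gap fill -> low-pass filter ->
stance windowing -> kinematics/kinetics -> time normalization.  Two
deliberate choices are documented in docs/methods.md: the 12 Hz figure is
interpreted as the low-pass *cutoff* (sampling at 12 Hz would contradict
the capture rates), and the 10 N stance threshold is applied to the
unfiltered vertical ground-reaction force, since zero-phase filtering
smears the landing onset across tens of milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .markers import _runs_of_missing
from .trial import SiteConfig, Trial

__all__ = [
    "StanceInterval",
    "detect_stance",
    "fill_gaps_spline",
    "fill_gap_virtual_asis",
    "fill_trial_gaps",
    "butterworth_lowpass",
    "time_normalize",
]


class StanceDetectionError(RuntimeError):
    pass


@dataclass
class StanceInterval:
    """Half-open stance interval [initial_contact, take_off).

    Detected on the force-plate clock by the 10 N rule; marker-clock indices
    are obtained by integer division of the rate ratio.
    """

    ic_force: int
    to_force: int
    force_rate: float
    rate_ratio: int

    def __post_init__(self) -> None:
        if self.ic_force >= self.to_force:
            raise ValueError("initial contact must precede take-off")

    @property
    def initial_contact(self) -> int:  # marker clock
        return self.ic_force // self.rate_ratio

    @property
    def take_off(self) -> int:  # marker clock
        return -(-self.to_force // self.rate_ratio)  # ceil, keeps interval covering

    @property
    def duration(self) -> float:
        return (self.to_force - self.ic_force) / self.force_rate


def detect_stance(
    vertical_grf: np.ndarray,
    force_rate: float,
    rate_ratio: int = 1,
    threshold: float = 10.0,
    debounce_s: float = 0.0,
) -> StanceInterval:
    """Stance by the 10 N rule: first sample with GRF > threshold, to the
    first subsequent sample with GRF < threshold.

    With chatter around the threshold the earliest qualifying crossing wins;
    an optional debounce window (seconds above/below threshold required to
    qualify, default off) is exposed for noisy plates.
    """
    grf = np.asarray(vertical_grf, dtype=float)
    if not np.isfinite(grf).all():
        raise ValueError("vertical GRF must be finite")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    above = grf > threshold
    win = max(1, int(round(debounce_s * force_rate))) if debounce_s > 0 else 1

    def _first_run(mask: np.ndarray, start: int) -> int | None:
        idx = start
        while idx < len(mask):
            if mask[idx]:
                end = idx + win
                if end <= len(mask) and mask[idx:end].all():
                    return idx
                idx += 1
            else:
                idx += 1
        return None

    ic = _first_run(above, 0)
    if ic is None:
        raise StanceDetectionError("no stance detected (GRF never exceeded threshold)")
    to = _first_run(~above, ic + 1)
    if to is None:
        raise StanceDetectionError("no take-off detected (GRF never fell below threshold)")
    return StanceInterval(ic_force=ic, to_force=to, force_rate=force_rate, rate_ratio=rate_ratio)


# ------------------------------------------------------------------ gap fill


@dataclass
class GapFillRecord:
    marker: str
    start: int
    length: int
    method: str  # 'spline' | 'virtual_asis' | 'unfilled'
    reason: str = ""
    rms_vs_spline: float | None = None


@dataclass
class GapFillReport:
    records: list[GapFillRecord] = field(default_factory=list)

    def filled(self) -> list[GapFillRecord]:
        return [r for r in self.records if r.method != "unfilled"]

    def unfilled(self) -> list[GapFillRecord]:
        return [r for r in self.records if r.method == "unfilled"]


def fill_gaps_spline(
    series: np.ndarray, valid: np.ndarray, max_gap_frames: int
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, bool, str]]]:
    """Cubic-spline fill of gaps up to ``max_gap_frames``.

    ``series`` is (n,) or (n, d); returns (filled, new_valid, records) with
    records (start, length, filled?, reason).  Gaps touching the trial
    boundary are never filled.  The spline interpolates through all valid
    samples, so polynomial trajectories up to cubic are recovered exactly.
    """
    series = np.asarray(series, dtype=float)
    flat = series.ndim == 1
    data = series[:, None] if flat else series.copy()
    valid = np.asarray(valid, dtype=bool).copy()
    n = len(data)
    records: list[tuple[int, int, bool, str]] = []
    runs = _runs_of_missing(valid)
    if runs:
        t_valid = np.flatnonzero(valid)
        spline = CubicSpline(t_valid, data[t_valid]) if len(t_valid) >= 4 else None
        for s, e in runs:
            length = e - s
            if s == 0 or e == n:
                records.append((s, length, False, "gap touches trial boundary"))
            elif length > max_gap_frames:
                records.append((s, length, False, f"gap longer than limit {max_gap_frames}"))
            elif spline is None:
                records.append((s, length, False, "too few valid samples for a cubic spline"))
            else:
                idx = np.arange(s, e)
                data[idx] = spline(idx)
                valid[idx] = True
                records.append((s, length, True, ""))
    out = data[:, 0] if flat else data
    return out, valid, records


_PELVIS_REFS = {"l": ("RASIS", "SACR", "LPSIS"), "r": ("LASIS", "SACR", "LPSIS")}


def _pelvis_ref_frame(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray):
    """Orthonormal frame from three pelvis landmarks; (n,3,3) columns, (n,3) origin."""
    e1 = p2 - p1
    e1 = e1 / np.linalg.norm(e1, axis=-1, keepdims=True)
    v = p3 - p1
    e3 = np.cross(e1, v)
    e3 = e3 / np.linalg.norm(e3, axis=-1, keepdims=True)
    e2 = np.cross(e3, e1)
    return np.stack([e1, e2, e3], axis=-1), p1


def fill_gap_virtual_asis(
    trial: Trial, side: str, gap: tuple[int, int] | None = None
) -> tuple[np.ndarray, dict]:
    """Reconstruct a missing ASIS from a pelvis frame built on the
    contralateral ASIS, the sacrum and the left PSIS.

    The missing ASIS is a fixed point of the (rigid) pelvis: its local
    position in the three-landmark frame is estimated from a calibration
    window where all four landmarks are valid, then applied across the gap.
    Returns the filled (n, 3) series and a report including the RMS
    deviation from a plain cubic-spline fill over the gap frames.
    """
    side = side.lower()
    target = ("LASIS" if side == "l" else "RASIS")
    refs = _PELVIS_REFS[side]
    ref_valid = np.logical_and.reduce([trial.marker_valid(m) for m in refs])
    tgt = trial.marker(target).copy()
    tgt_valid = trial.marker_valid(target).copy()
    if gap is None:
        missing = np.flatnonzero(~tgt_valid)
        if missing.size == 0:
            return tgt, {"gap": None, "n_filled": 0, "rms_vs_spline": None}
        gap = (int(missing[0]), int(missing[-1]) + 1)
    s, e = gap
    if e <= s:
        return tgt, {"gap": gap, "n_filled": 0, "rms_vs_spline": None}
    calib = ref_valid & tgt_valid
    if calib.sum() < 5:
        raise RuntimeError(
            "cannot build pelvis frame: no calibration window with all four "
            "pelvis landmarks valid"
        )
    if not ref_valid[s:e].all():
        raise RuntimeError("cannot build pelvis frame: reference landmarks invalid in gap")
    p = {m: trial.marker(m) for m in refs}
    R, origin = _pelvis_ref_frame(p[refs[0]], p[refs[1]], p[refs[2]])
    ci = np.flatnonzero(calib)
    local = np.einsum("nji,nj->ni", R[ci], tgt[ci] - origin[ci])
    local_mean = local.mean(axis=0)
    gi = np.arange(s, e)
    recon = origin[gi] + np.einsum("nij,j->ni", R[gi], local_mean)
    # comparison fill by plain spline over the same gap (diagnostic only)
    rms = None
    spl, _, recs = fill_gaps_spline(tgt, tgt_valid, max_gap_frames=len(tgt))
    if any(r[2] for r in recs):
        rms = float(np.sqrt(np.mean(np.sum((spl[gi] - recon) ** 2, axis=1))))
    out = tgt
    out[gi] = recon
    report = {
        "gap": (s, e),
        "n_filled": int(e - s),
        "rms_vs_spline": rms,
        "local_sd": float(local.std(axis=0).max()),
    }
    return out, report


def fill_trial_gaps(trial: Trial, site: SiteConfig | None = None) -> tuple[Trial, GapFillReport]:
    """Apply the study's gap-filling rules to every marker of a trial.

    Gaps shorter than 10% of the marker sampling frequency are cubic-spline
    filled.  ASIS gaps between 10% and 25% are reconstructed with the
    virtual pelvis-fixed fill.  Longer gaps are left masked and reported
    (such trials are candidates for exclusion).
    """
    if site is None:
        site = SiteConfig(trial.site, trial.marker_rate, trial.force_rate)
    limit = site.max_spline_gap_frames
    vlimit = site.max_virtual_gap_frames
    out = trial.copy()
    report = GapFillReport()
    # pass 1: spline-fill every marker, collecting the leftovers
    pending: list[tuple[str, int, int, str]] = []
    for j, label in enumerate(trial.labels):
        valid = out.valid[:, j]
        if valid.all():
            continue
        filled, new_valid, recs = fill_gaps_spline(out.markers[:, j, :], valid, limit)
        out.markers[:, j, :] = filled
        out.valid[:, j] = new_valid
        for s, length, ok, reason in recs:
            if ok:
                report.records.append(GapFillRecord(label, s, length, "spline"))
            else:
                pending.append((label, s, length, reason))
    # pass 2: virtual pelvis-fixed fill for the remaining ASIS gaps; running
    # after the spline pass lets the fill use an already-repaired
    # contralateral ASIS as a reference landmark.  Sweeps repeat while any
    # fill succeeds, so one repaired ASIS can unblock the other side.
    progress = True
    while pending and progress:
        progress = False
        deferred: list[tuple[str, int, int, str, str]] = []
        for label, s, length, reason in pending:
            is_asis = label in ("LASIS", "RASIS")
            if is_asis and limit < length <= vlimit and 0 < s and s + length < trial.n_frames:
                side = "l" if label == "LASIS" else "r"
                j = out.index(label)
                try:
                    series2, info = fill_gap_virtual_asis(out, side, (s, s + length))
                except RuntimeError as exc:
                    deferred.append((label, s, length, reason, str(exc)))
                    continue
                out.markers[:, j, :] = series2
                out.valid[s : s + length, j] = True
                report.records.append(
                    GapFillRecord(label, s, length, "virtual_asis", rms_vs_spline=info["rms_vs_spline"])
                )
                progress = True
            else:
                if is_asis and length > vlimit:
                    reason = (
                        f"ASIS gap longer than the 25% limit ({vlimit} frames); "
                        "trial flagged for exclusion"
                    )
                deferred.append((label, s, length, reason, reason))
        pending = [(lab, s, ln, rsn) for lab, s, ln, rsn, _ in deferred] if progress else []
        if not progress:
            for label, s, length, _reason, final in deferred:
                report.records.append(GapFillRecord(label, s, length, "unfilled", reason=final))
    return out, report


# ----------------------------------------------------------------- filtering


def butterworth_lowpass(
    series: np.ndarray, rate: float, cutoff_hz: float = 12.0, order: int = 4
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass along axis 0.

    A single pass of the ``order``-th Butterworth is applied in each
    direction, so the effective magnitude response is |H(f)|^2 of the
    analog prototype.  Masked (NaN) samples must be gap-filled first.
    """
    series = np.asarray(series, dtype=float)
    if np.isnan(series).any():
        raise ValueError("series contains masked samples; run gap filling before filtering")
    if rate <= 2 * cutoff_hz:
        raise ValueError(f"sampling rate {rate} too low for a {cutoff_hz} Hz cutoff")
    b, a = butter(order, cutoff_hz, fs=rate)
    return filtfilt(b, a, series, axis=0)


def filter_trial(trial: Trial, cutoff_hz: float = 12.0, order: int = 4) -> Trial:
    """Filter all marker and force channels of a trial at the same cutoff.

    Markers must be fully gap-filled (no invalid samples) beforehand.
    """
    out = trial.copy()
    if not out.valid.all():
        raise ValueError("trial has unfilled gaps; run fill_trial_gaps first")
    n, m, _ = out.markers.shape
    out.markers = butterworth_lowpass(out.markers.reshape(n, -1), trial.marker_rate, cutoff_hz, order).reshape(n, m, 3)
    for plate in out.plates:
        plate.force = butterworth_lowpass(plate.force, trial.force_rate, cutoff_hz, order)
        plate.moment = butterworth_lowpass(plate.moment, trial.force_rate, cutoff_hz, order)
    out.meta["filtered"] = {"cutoff_hz": cutoff_hz, "order": order}
    return out


# ---------------------------------------------------------- time normalizing


def time_normalize(series: np.ndarray, n_points: int = 101) -> np.ndarray:
    """Linear resampling of a stance-phase series onto 0-100% (101 points).

    Endpoints are preserved exactly.  ``series`` is (n,) or (n, d).
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    if n < 4:
        raise ValueError(f"degenerate stance: {n} samples (need >= 4)")
    x_old = np.linspace(0.0, 1.0, n)
    x_new = np.linspace(0.0, 1.0, n_points)
    if series.ndim == 1:
        return np.interp(x_new, x_old, series)
    return np.stack([np.interp(x_new, x_old, series[:, j]) for j in range(series.shape[1])], axis=1)
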