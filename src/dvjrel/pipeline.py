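"""End-to-end processing: trials -> waveforms -> peaks -> QC -> reliability.

``process_trial`` applies the fixed processing order (gap fill, low-pass
filter, stance windowing, kinematics/kinetics, 101-point time
normalization); ``process_cohort`` maps it over a generated or loaded
cohort and assembles long-form peak and waveform tables;
``run_pipeline`` orchestrates simulate -> process -> qc -> reliability
and writes every stage's outputs plus a manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .kinematics import calibrate, compute_joint_angles
from .kinetics import inverse_dynamics
from .preprocess import (
    StanceInterval,
    detect_stance,
    fill_trial_gaps,
    filter_trial,
    time_normalize,
)
from .qc import QCReport, outlier_curves, skeleton_check
from .reliability import (
    ANGLE_DIRECTIONS,
    MOMENT_DIRECTIONS,
    extract_peaks,
    reliability_report,
)
from .simulate import Cohort, DVJSpec, NoiseSpec, generate_cohort
from .trial import Trial

__all__ = ["PipelineConfig", "process_trial", "process_cohort", "run_pipeline"]


@dataclass
class PipelineConfig:
    cutoff_hz: float | None = 12.0  # None disables filtering
    filter_order: int = 4
    stance_threshold_n: float = 10.0
    n_points: int = 101
    qc_residual_mm: float = 15.0
    qc_max_frac_over: float = 0.01
    qc_outlier_confidence: float = 0.95
    qc_gate: bool = False  # drop QC-failed trials before reliability
    sides: tuple[str, ...] = ("l", "r")
    seed: int = 0
    plots: bool = False

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TrialResult:
    subject: str
    site: str
    trial_index: int
    stance: StanceInterval
    angles: dict[str, np.ndarray]  # joint_side -> (T, 3), time-normalized
    moments: dict[str, np.ndarray]
    gap_report: object
    skeleton: object


def process_trial(
    trial: Trial,
    static_trial,
    config: PipelineConfig | None = None,
) -> TrialResult:
    """One trial through the full processing chain."""
    config = config or PipelineConfig()
    cal = static_trial if not isinstance(static_trial, Trial) else calibrate(static_trial)
    filled, gap_report = fill_trial_gaps(trial)
    if not filled.valid.all():
        bad = [r for r in gap_report.unfilled()]
        raise RuntimeError(
            f"trial {trial.site}/{trial.subject.id}/t{trial.trial_index} has "
            f"unfillable gaps ({bad[0].marker}: {bad[0].reason}); excluded"
        )
    smoothed = (
        filter_trial(filled, config.cutoff_hz, config.filter_order)
        if config.cutoff_hz
        else filled
    )
    # stance from the unfiltered force signal
    stance = detect_stance(
        filled.total_grf()[:, 2],
        filled.force_rate,
        filled.rate_ratio,
        config.stance_threshold_n,
    )
    angles, frames, _ = compute_joint_angles(smoothed, cal)
    # kinetics: raw force channels (filtered once inside), filtered marker frames
    raw_for_forces = filled.copy()
    moments = inverse_dynamics(
        raw_for_forces,
        frames,
        cal,
        cutoff_hz=config.cutoff_hz or 12.0,
        order=config.filter_order,
        threshold=config.stance_threshold_n,
    )
    sk = skeleton_check(
        filled, cal, residual_threshold_mm=config.qc_residual_mm, max_frac_over=config.qc_max_frac_over
    )
    ic, to = stance.initial_contact, stance.take_off
    ang_tn = {k: time_normalize(v[ic:to], config.n_points) for k, v in angles.items()}
    mom_tn = {k: time_normalize(v[ic:to], config.n_points) for k, v in moments.items()}
    return TrialResult(
        subject=trial.subject.id,
        site=trial.site,
        trial_index=trial.trial_index,
        stance=stance,
        angles=ang_tn,
        moments=mom_tn,
        gap_report=gap_report,
        skeleton=sk,
    )


def _waveform_rows(res: TrialResult, sides) -> list[dict]:
    rows = []
    for side in sides:
        for dirs, series in ((ANGLE_DIRECTIONS, res.angles), (MOMENT_DIRECTIONS, res.moments)):
            for var, (joint, axis, sign) in dirs.items():
                rows.append(
                    {
                        "subject": res.subject,
                        "site": res.site,
                        "trial": res.trial_index,
                        "side": side,
                        "variable": var,
                        "curve": sign * series[f"{joint}_{side}"][:, axis],
                    }
                )
    return rows


def process_cohort(
    cohort: Cohort, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, QCReport, list[TrialResult], list[str]]:
    """Process every trial of a cohort.

    Returns (peaks, waveforms, qc_report, per-trial results, exclusions).
    """
    config = config or PipelineConfig()
    cals = {key: calibrate(st) for key, st in cohort.statics.items()}
    peak_frames, wf_rows, results, excluded = [], [], [], []
    qc = QCReport()
    for trial, _truth in cohort.items:
        try:
            res = process_trial(trial, cals[(trial.site, trial.subject.id)], config)
        except RuntimeError as exc:
            excluded.append(str(exc))
            continue
        qc.skeleton.append(res.skeleton)
        if config.qc_gate and not res.skeleton.passed:
            excluded.append(f"QC gate: {res.skeleton.trial_id}")
            continue
        results.append(res)
        for side in config.sides:
            peak_frames.append(
                extract_peaks(
                    res.angles, "angle",
                    subject=res.subject, site=res.site, trial=res.trial_index, side=side,
                )
            )
            peak_frames.append(
                extract_peaks(
                    res.moments, "moment",
                    subject=res.subject, site=res.site, trial=res.trial_index, side=side,
                )
            )
        wf_rows.extend(_waveform_rows(res, config.sides))
    peaks = pd.concat(peak_frames, ignore_index=True) if peak_frames else pd.DataFrame()
    waveforms = pd.DataFrame(wf_rows)
    # outlier-curve screening per variable per site (pooled subjects/trials)
    if len(waveforms):
        for (var, site), grp in waveforms.groupby(["variable", "site"], sort=True):
            if len(grp) < 5:
                continue
            flags = outlier_curves(
                np.stack(list(grp["curve"])), config.qc_outlier_confidence
            )
            if flags.any():
                ids = [
                    f"{r.site}/{r.subject}/t{r.trial}-{r.side}"
                    for r, fl in zip(grp.itertuples(), flags)
                    if fl
                ]
                qc.outlier_flags.setdefault(f"{var}@{site}", []).extend(ids)
    return peaks, waveforms, qc, results, excluded


def run_pipeline(
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    spec: DVJSpec | None = None,
    noise: NoiseSpec | None = None,
    cohort: Cohort | None = None,
) -> dict:
    """Simulate (unless a cohort is given), process, QC and report.

    Writes per-stage outputs under ``out_dir`` and returns the manifest.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = generate_cohort(spec, noise, seed=config.seed)
    peaks, waveforms, qc, results, excluded = process_cohort(cohort, config)

    outputs: list[str] = []

    def _write(name: str, writer) -> None:
        path = out / name
        writer(path)
        outputs.append(name)

    _write("peaks.tsv", lambda p: peaks.to_csv(p, sep="\t", index=False))
    wf_flat = waveforms.copy()
    if len(wf_flat):
        curves = np.stack(list(wf_flat.pop("curve")))
        cols = pd.DataFrame(curves, columns=[f"t{i:03d}" for i in range(curves.shape[1])])
        wf_flat = pd.concat([wf_flat.reset_index(drop=True), cols], axis=1)
    _write("waveforms.tsv", lambda p: wf_flat.to_csv(p, sep="\t", index=False))
    _write("qc_report.json", lambda p: p.write_text(json.dumps(qc.to_dict(), indent=2)))

    reports = {}
    designs = ("within", "between", "among") if len(cohort.spec.sites) >= 3 else ("within", "between")
    for side in config.sides:
        rep = reliability_report(peaks, waveforms, side=side, designs=designs)
        reports[side] = rep
        _write(
            f"reliability_{side}.tsv",
            lambda p, rep=rep: rep.to_frame().to_csv(p, sep="\t", index=False, float_format="%.6g"),
        )
    if config.plots and len(waveforms):
        _plot_waveforms(waveforms, out, outputs)

    stances = [r.stance.duration for r in results]
    manifest = {
        "version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_trials_processed": len(results),
        "n_excluded": len(excluded),
        "excluded": excluded,
        "mean_stance_s": float(np.mean(stances)) if stances else None,
        "qc_failed": qc.n_failed,
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _plot_waveforms(waveforms: pd.DataFrame, out: Path, outputs: list[str]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir = out / "plots"
    plot_dir.mkdir(exist_ok=True)
    for var, grp in waveforms.groupby("variable", sort=True):
        try:
            fig, ax = plt.subplots(figsize=(5, 3.2))
            curves = np.stack(list(grp["curve"]))
            x = np.linspace(0, 100, curves.shape[1])
            mu, sd = curves.mean(axis=0), curves.std(axis=0)
            ax.plot(x, curves.T, color="0.8", lw=0.3)
            ax.plot(x, mu, color="C0", lw=1.5)
            ax.fill_between(x, mu - 1.96 * sd, mu + 1.96 * sd, alpha=0.2)
            ax.set_xlabel("% stance")
            ax.set_ylabel(var)
            fig.tight_layout()
            fig.savefig(plot_dir / f"{var}.png", dpi=100)
            plt.close(fig)
            outputs.append(f"plots/{var}.png")
        except Exception:  # plotting is best-effort QC, never fatal
            continue
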