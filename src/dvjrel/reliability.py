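"""Peak extraction, trial averaging, and reliability statistics.

The reliability suite mirrors a three-laboratory screening study design:

* within-site, trial-to-trial: each subject's 3 trials act as raters,
  ICC(3,k) with k = 3, plus SEM and the CMC over the subject's 3 curves;
* between site pairs: trial-averaged subject values, the 2 sites act as
  raters, ICC(3,1), SEM, CMC over the 2 per-site mean curves;
* among all sites: 3 sites as raters, ICC(3,k), CMC over the 3 per-site
  mean curves.

ICC forms follow the Shrout-Fleiss two-way mixed model: with BMS/JMS/EMS
the between-subject, between-rater and residual mean squares,

    ICC(3,1) = (BMS - EMS) / (BMS + (k - 1) EMS)
    ICC(3,k) = (BMS - EMS) / BMS

classified excellent (> 0.75), good (0.4-0.75) or poor (< 0.4).
SEM = SD * sqrt(1 - ICC) in the variable's units.  The CMC is Kadaba's
waveform coefficient of multiple correlation over time-normalized stance
curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "VARIABLES",
    "classify_icc",
    "extract_peaks",
    "average_trials",
    "icc_two_way",
    "sem",
    "cmc_kadaba",
    "reliability_report",
    "ICCResult",
    "CMCResult",
    "ReliabilityReport",
]

# The 16 outcome variables: 8 peak angles (deg) and 8 peak moments (N*m/kg).
# Each maps to (waveform key template, axis index, sign): the peak is the
# maximum of sign * curve over stance, so e.g. knee abduction (internally
# adduction-positive) and ankle eversion (inversion-positive) flip sign, and
# sagittal-plane moments are taken in the internal extensor/plantarflexor
# direction that dominates a landing.
ANGLE_DIRECTIONS: dict[str, tuple[str, int, float]] = {
    "hip_flexion_angle": ("hip", 0, +1.0),
    "hip_adduction_angle": ("hip", 1, +1.0),
    "hip_internal_rotation_angle": ("hip", 2, +1.0),
    "knee_flexion_angle": ("knee", 0, +1.0),
    "knee_abduction_angle": ("knee", 1, -1.0),
    "knee_internal_rotation_angle": ("knee", 2, +1.0),
    "ankle_dorsiflexion_angle": ("ankle", 0, +1.0),
    "ankle_eversion_angle": ("ankle", 1, -1.0),
}
MOMENT_DIRECTIONS: dict[str, tuple[str, int, float]] = {
    "hip_flexion_moment": ("hip", 0, -1.0),
    "hip_adduction_moment": ("hip", 1, +1.0),
    "hip_internal_rotation_moment": ("hip", 2, +1.0),
    "knee_flexion_moment": ("knee", 0, -1.0),
    "knee_abduction_moment": ("knee", 1, -1.0),
    "knee_internal_rotation_moment": ("knee", 2, +1.0),
    "ankle_dorsiflexion_moment": ("ankle", 0, -1.0),
    "ankle_eversion_moment": ("ankle", 1, -1.0),
}
VARIABLES: list[str] = list(ANGLE_DIRECTIONS) + list(MOMENT_DIRECTIONS)


def classify_icc(icc: float) -> str:
    """excellent if ICC > 0.75, good if 0.4 <= ICC <= 0.75, poor if < 0.4."""
    if icc > 0.75:
        return "excellent"
    if icc >= 0.4:
        return "good"
    return "poor"


def extract_peaks(
    waveforms: dict[str, np.ndarray],
    kind: str,
    *,
    subject: str,
    site: str,
    trial: int,
    side: str,
    directions: dict[str, tuple[str, int, float]] | None = None,
) -> pd.DataFrame:
    """Peak values from one trial's stance-phase waveforms.

    ``waveforms`` maps "hip_l" etc. to (T, 3) arrays; ``kind`` is 'angle'
    or 'moment'.  The peak of each variable is the signed extremum in its
    configured direction.  Returns long-form records.
    """
    if directions is None:
        directions = ANGLE_DIRECTIONS if kind == "angle" else MOMENT_DIRECTIONS
    rows = []
    for var, (joint, axis, sign) in directions.items():
        curve = waveforms[f"{joint}_{side}"]
        if curve.shape[0] == 0:
            raise ValueError("empty stance window")
        rows.append(
            {
                "subject": subject,
                "site": site,
                "trial": trial,
                "side": side,
                "variable": var,
                "peak": float(sign * np.max(sign * curve[:, axis])),
            }
        )
    return pd.DataFrame(rows)


def average_trials(peaks: pd.DataFrame) -> pd.DataFrame:
    """Mean peak over available trials per subject x site x side x variable."""
    g = (
        peaks.groupby(["subject", "site", "side", "variable"], sort=True)["peak"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "peak", "count": "n_trials"})
    )
    return g


@dataclass
class ICCResult:
    form: str  # '3,1' or '3,k'
    estimate: float
    k: int
    n: int
    bms: float
    jms: float
    ems: float
    classification: str = field(init=False)

    def __post_init__(self) -> None:
        if self.estimate > 1 + 1e-12:
            raise ValueError("ICC cannot exceed 1")
        self.classification = classify_icc(self.estimate)


def icc_two_way(matrix: np.ndarray, form: str = "single") -> ICCResult:
    """Shrout-Fleiss two-way ICC from an n-subject x k-rater matrix.

    ``form`` 'single' -> ICC(3,1); 'average' -> ICC(3,k).  The matrix must
    be complete (apply casewise deletion first); negative estimates are
    returned as computed.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x raters)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 raters, got {n} x {k}")
    if np.isnan(x).any():
        raise ValueError("missing cells: delete incomplete subjects before calling")
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("degenerate matrix: zero total variance")
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    jms = ss_cols / (k - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    if form == "single":
        est = (bms - ems) / (bms + (k - 1) * ems)
        label = "3,1"
    elif form == "average":
        est = (bms - ems) / bms if bms != 0 else float("-inf")
        label = "3,k"
    else:
        raise ValueError("form must be 'single' or 'average'")
    return ICCResult(form=label, estimate=float(est), k=k, n=n, bms=float(bms), jms=float(jms), ems=float(ems))


def sem(values: np.ndarray, icc: float) -> tuple[float, bool]:
    """Standard error of measurement: SD * sqrt(1 - ICC).

    SD is the between-subject standard deviation of the design's cell
    values (all cells, ddof = 1).  Negative ICC is floored at 0 inside the
    formula; the second return flags that flooring happened.
    """
    x = np.asarray(values, dtype=float).ravel()
    sd = float(np.std(x, ddof=1))
    floored = icc < 0
    icc_eff = max(icc, 0.0)
    return sd * float(np.sqrt(1.0 - icc_eff)), floored


@dataclass
class CMCResult:
    values: np.ndarray  # per-subject CMC, NaN where undefined
    n_undefined: int

    @property
    def mean(self) -> float:
        ok = np.isfinite(self.values)
        return float(np.mean(self.values[ok])) if ok.any() else float("nan")

    @property
    def sd(self) -> float:
        ok = np.isfinite(self.values)
        return float(np.std(self.values[ok], ddof=1)) if ok.sum() > 1 else float("nan")


def cmc_kadaba(curves: np.ndarray) -> float:
    """Kadaba's coefficient of multiple correlation for M curves x T points.

        CMC = sqrt(1 - [sum_i sum_t (Y_it - Ybar_t)^2 / (T (M-1))]
                     / [sum_i sum_t (Y_it - Ybar)^2 / (M T - 1)])

    Returns NaN (undefined) when the within-time dispersion exceeds the
    total dispersion (no common shape) or when the curves carry no
    variance at all; undefined values are never clipped into [0, 1].
    """
    y = np.asarray(curves, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2:
        raise ValueError("need an (M >= 2) x T array of curves")
    m, t = y.shape
    ybar_t = y.mean(axis=0)
    ybar = y.mean()
    num = np.sum((y - ybar_t) ** 2) / (t * (m - 1))
    den = np.sum((y - ybar) ** 2) / (m * t - 1)
    if den == 0.0:
        return float("nan")
    ratio = num / den
    if ratio > 1.0:
        return float("nan")
    return float(np.sqrt(1.0 - ratio))


# ----------------------------------------------------------------- reporting


@dataclass
class DesignResult:
    design: str  # 'within' / 'between' / 'among'
    unit: str  # site id or 'A-B' pair label or 'all'
    variable: str
    icc: ICCResult
    sem: float | None
    sem_floored: bool
    cmc: CMCResult
    n_subjects: int


@dataclass
class ReliabilityReport:
    side: str
    results: list[DesignResult]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "design": r.design,
                    "unit": r.unit,
                    "variable": r.variable,
                    "icc_form": r.icc.form,
                    "icc": r.icc.estimate,
                    "classification": r.icc.classification,
                    "sem": r.sem,
                    "cmc_mean": r.cmc.mean,
                    "cmc_sd": r.cmc.sd,
                    "cmc_undefined": r.cmc.n_undefined,
                    "n_subjects": r.n_subjects,
                }
            )
        return pd.DataFrame(rows)


def _pivot_complete(df: pd.DataFrame, index: str, columns: str) -> pd.DataFrame:
    """Pivot to index x columns and casewise-delete incomplete rows."""
    wide = df.pivot_table(index=index, columns=columns, values="peak", aggfunc="mean")
    return wide.dropna(axis=0)


def _cmc_over(curve_sets: list[np.ndarray]) -> CMCResult:
    vals = np.array([cmc_kadaba(c) for c in curve_sets])
    return CMCResult(values=vals, n_undefined=int(np.sum(~np.isfinite(vals))))


def reliability_report(
    peaks: pd.DataFrame,
    waveforms: pd.DataFrame | None = None,
    side: str = "r",
    designs: tuple[str, ...] = ("within", "between", "among"),
) -> ReliabilityReport:
    """Full reliability report for one side.

    ``peaks``: long-form records (subject, site, trial, side, variable,
    peak).  ``waveforms``: optional long-form time-normalized curves with
    columns (subject, site, trial, side, variable, and t000..t100 or a
    'curve' object column); when omitted CMC entries are NaN.

    Subjects missing a whole site are casewise deleted per analysis.
    """
    pk = peaks[peaks["side"] == side]
    sites = sorted(pk["site"].unique())
    results: list[DesignResult] = []

    wf = None
    if waveforms is not None:
        wf = waveforms[waveforms["side"] == side]

    def _curves(var: str, site_sel: list[str], per: str) -> list[np.ndarray] | None:
        """Per-subject curve stacks: trials within one site, or per-site means."""
        if wf is None:
            return None
        sel = wf[(wf["variable"] == var) & (wf["site"].isin(site_sel))]
        out = []
        for _, grp in sel.groupby("subject", sort=True):
            if per == "trials":
                stack = np.stack(list(grp["curve"]))
            else:  # per-site mean curves
                if grp["site"].nunique() < len(site_sel):
                    continue
                stack = np.stack(
                    [np.mean(np.stack(list(g["curve"])), axis=0) for _, g in grp.groupby("site", sort=True)]
                )
            if stack.shape[0] >= 2:
                out.append(stack)
        return out

    for var in sorted(pk["variable"].unique()):
        dfv = pk[pk["variable"] == var]
        if "within" in designs:
            for site in sites:
                wide = _pivot_complete(dfv[dfv["site"] == site], "subject", "trial")
                if wide.shape[1] < 2 or wide.shape[0] < 2:
                    continue
                icc = icc_two_way(wide.to_numpy(), form="average")
                s, fl = sem(wide.to_numpy(), icc.estimate)
                curves = _curves(var, [site], per="trials")
                cmc = _cmc_over(curves) if curves else CMCResult(np.array([np.nan]), 1)
                results.append(
                    DesignResult("within", site, var, icc, s, fl, cmc, wide.shape[0])
                )
        means = average_trials(dfv)
        if "between" in designs and len(sites) >= 2:
            for s1, s2 in combinations(sites, 2):
                sub = means[means["site"].isin([s1, s2])]
                wide = _pivot_complete(sub, "subject", "site")
                if wide.shape[1] < 2 or wide.shape[0] < 2:
                    continue
                icc = icc_two_way(wide.to_numpy(), form="single")
                s, fl = sem(wide.to_numpy(), icc.estimate)
                curves = _curves(var, [s1, s2], per="site_means")
                cmc = _cmc_over(curves) if curves else CMCResult(np.array([np.nan]), 1)
                results.append(
                    DesignResult("between", f"{s1}-{s2}", var, icc, s, fl, cmc, wide.shape[0])
                )
        if "among" in designs and len(sites) >= 3:
            wide = _pivot_complete(means, "subject", "site")
            if wide.shape[1] >= 3 and wide.shape[0] >= 2:
                icc = icc_two_way(wide.to_numpy(), form="average")
                curves = _curves(var, sites, per="site_means")
                cmc = _cmc_over(curves) if curves else CMCResult(np.array([np.nan]), 1)
                results.append(
                    DesignResult("among", "all", var, icc, None, False, cmc, wide.shape[0])
                )
    return ReliabilityReport(side=side, results=results)
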