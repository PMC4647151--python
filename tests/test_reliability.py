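"""ICC, SEM, CMC and the report layout.

Oracles: a from-scratch two-way ANOVA coded with explicit Python loops
(no shared code with the vectorized implementation), the published ICC
routine in pingouin as an independent library cross-check, and a direct
triple-summation implementation of the CMC formula.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dvjrel.reliability import (
    VARIABLES,
    average_trials,
    classify_icc,
    cmc_kadaba,
    extract_peaks,
    icc_two_way,
    reliability_report,
    sem,
)


def icc_oracle(mat, form):
    """Shrout-Fleiss two-way ICC via explicit loops (independent oracle)."""
    n, k = mat.shape
    grand = sum(mat[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(mat[i][j] for j in range(k)) / k for i in range(n)]
    col = [sum(mat[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((r - grand) ** 2 for r in row)
    ss_cols = n * sum((c - grand) ** 2 for c in col)
    ss_tot = sum((mat[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    bms = ss_rows / (n - 1)
    ems = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    if form == "single":
        return (bms - ems) / (bms + (k - 1) * ems)
    return (bms - ems) / bms


def cmc_oracle(curves):
    """Direct triple-summation of the Kadaba CMC formula."""
    m = len(curves)
    t = len(curves[0])
    ybar_t = [sum(curves[i][j] for i in range(m)) / m for j in range(t)]
    ybar = sum(ybar_t) / t
    num = sum((curves[i][j] - ybar_t[j]) ** 2 for i in range(m) for j in range(t))
    den = sum((curves[i][j] - ybar) ** 2 for i in range(m) for j in range(t))
    ratio = (num / (t * (m - 1))) / (den / (m * t - 1))
    return float("nan") if ratio > 1 else np.sqrt(1 - ratio)


class TestICC:
    def test_identical_raters_give_one_for_both_forms(self):
        mat = np.tile(np.array([[1.0], [2.0], [5.0], [9.0]]), (1, 3))
        assert icc_two_way(mat, "single").estimate == pytest.approx(1.0)
        assert icc_two_way(mat, "average").estimate == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "value,expected",
        [(0.373, "poor"), (0.451, "good"), (0.789, "excellent"), (0.4, "good"), (0.75, "good"), (-0.112, "poor")],
    )
    def test_classification_thresholds(self, value, expected):
        assert classify_icc(value) == expected

    @given(st.integers(0, 999))
    @settings(max_examples=150)
    def test_matches_loop_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n, k = rng.integers(4, 31), rng.integers(2, 6)
        mat = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * 2
        for form in ("single", "average"):
            assert icc_two_way(mat, form).estimate == pytest.approx(
                icc_oracle(mat, form), abs=1e-12
            )

    def test_matches_pingouin_published_routine(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        mat = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)) * 2
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 3),
                "raters": np.tile(np.arange(3), 12),
                "ratings": mat.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, "targets", "raters", "ratings").set_index("Type")
        # the two-way consistency model: pingouin's ICC(C,1) / ICC(C,k)
        assert icc_two_way(mat, "single").estimate == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-9)
        assert icc_two_way(mat, "average").estimate == pytest.approx(ref.loc["ICC(C,k)", "ICC"], abs=1e-9)

    def test_mean_squares_retained_for_audit(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(6, 3))
        res = icc_two_way(mat, "single")
        assert res.bms > 0 and res.ems > 0 and res.n == 6 and res.k == 3

    def test_negative_estimates_reported_not_floored(self):
        # rater disagreement larger than subject variance drives ICC < 0
        mat = np.array([[1.0, 9.0], [9.2, 1.1], [1.2, 8.8], [9.1, 0.9]])
        assert icc_two_way(mat, "single").estimate < 0

    def test_error_paths(self):
        with pytest.raises(ValueError, match="degenerate"):
            icc_two_way(np.ones((4, 3)))
        with pytest.raises(ValueError, match="missing cells"):
            icc_two_way(np.array([[1.0, np.nan], [2.0, 3.0]]))
        with pytest.raises(ValueError, match=">= 2"):
            icc_two_way(np.ones((1, 3)))


class TestSEM:
    def test_perfect_reliability_gives_zero(self):
        assert sem(np.array([1.0, 2.0, 3.0]), icc=1.0)[0] == 0.0

    def test_closed_form_value(self):
        values = np.array([0.0, 20.0])  # SD = sqrt(200) ... use explicit SD
        x = np.array([10.0, 20.0, 30.0])  # sd = 10
        s, floored = sem(x, icc=0.75)
        assert s == pytest.approx(10.0 * np.sqrt(0.25))
        assert not floored

    def test_negative_icc_floored_and_flagged(self):
        x = np.array([10.0, 20.0, 30.0])
        s, floored = sem(x, icc=-0.25)
        assert floored
        assert s == pytest.approx(np.std(x, ddof=1))

    def test_synthetic_within_subject_sd_recovered(self):
        # cells = subject effect + N(0, 2): SEM should estimate ~2
        rng = np.random.default_rng(4)
        subj = rng.normal(0, 10, size=(25, 1))
        mat = subj + rng.normal(0, 2.0, size=(25, 3))
        icc = icc_two_way(mat, "single").estimate
        s, _ = sem(mat, icc)
        assert s == pytest.approx(2.0, rel=0.25)


class TestCMC:
    def test_identical_nonconstant_curves_give_one(self):
        c = np.tile(np.sin(np.linspace(0, np.pi, 50)), (4, 1))
        assert cmc_kadaba(c) == pytest.approx(1.0)

    def test_uncorrelated_noise_is_undefined(self):
        rng = np.random.default_rng(0)
        c = rng.standard_normal((6, 101))
        assert np.isnan(cmc_kadaba(c))

    def test_constant_identical_curves_flagged_undefined(self):
        assert np.isnan(cmc_kadaba(np.ones((3, 20))))

    def test_small_integer_example_matches_direct_oracle(self):
        curves = np.array(
            [[1, 2, 3, 4, 5], [2, 3, 4, 5, 6], [1, 3, 3, 5, 5]], dtype=float
        )
        assert cmc_kadaba(curves) == pytest.approx(cmc_oracle(curves.tolist()), abs=1e-12)

    @given(st.integers(0, 199))
    @settings(max_examples=80)
    def test_matches_oracle_on_random_curve_sets(self, seed):
        rng = np.random.default_rng(seed)
        m, t = rng.integers(2, 6), rng.integers(3, 12)
        shape = np.sin(np.linspace(0, 3, t))
        curves = shape + 0.3 * rng.standard_normal((m, t))
        ours, ref = cmc_kadaba(curves), cmc_oracle(curves.tolist())
        if np.isnan(ref):
            assert np.isnan(ours)
        else:
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_values_never_exceed_one(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            c = np.sin(np.linspace(0, 3, 20)) + 0.1 * rng.standard_normal((3, 20))
            v = cmc_kadaba(c)
            assert np.isnan(v) or 0.0 <= v <= 1.0


class TestPeaksAndAveraging:
    def _waveforms(self, curve):
        z = np.zeros_like(curve)
        arr = np.stack([curve, z, z], axis=1)
        return {f"{j}_r": arr.copy() for j in ("hip", "knee", "ankle")}

    def test_sinusoid_peak_is_amplitude(self):
        t = np.linspace(0, 1, 101)
        wf = self._waveforms(30.0 * np.sin(np.pi * t))
        df = extract_peaks(wf, "angle", subject="s", site="A", trial=1, side="r")
        knee = df[df["variable"] == "knee_flexion_angle"]["peak"].iloc[0]
        assert knee == pytest.approx(30.0, abs=1e-9)

    def test_constant_zero_peak_is_zero(self):
        wf = self._waveforms(np.zeros(101))
        df = extract_peaks(wf, "angle", subject="s", site="A", trial=1, side="r")
        assert (df["peak"] == 0).all()

    def test_signed_direction_for_abduction_variables(self):
        t = np.linspace(0, 1, 101)
        curve = -8.0 * np.sin(np.pi * t)  # adduction-negative = abduction
        wf = self._waveforms(np.zeros(101))
        wf["knee_r"][:, 1] = curve
        df = extract_peaks(wf, "angle", subject="s", site="A", trial=1, side="r")
        ab = df[df["variable"] == "knee_abduction_angle"]["peak"].iloc[0]
        assert ab == pytest.approx(-8.0, abs=1e-9)  # reported in adduction scale

    def test_average_of_three_trials(self):
        df = pd.DataFrame(
            {
                "subject": ["s"] * 3,
                "site": ["A"] * 3,
                "side": ["r"] * 3,
                "trial": [1, 2, 3],
                "variable": ["knee_flexion_angle"] * 3,
                "peak": [10.0, 12.0, 14.0],
            }
        )
        out = average_trials(df)
        assert out["peak"].iloc[0] == pytest.approx(12.0)
        assert out["n_trials"].iloc[0] == 3

    def test_missing_trial_still_averaged_with_count(self):
        df = pd.DataFrame(
            {
                "subject": ["s"] * 2,
                "site": ["A"] * 2,
                "side": ["r"] * 2,
                "trial": [1, 3],
                "variable": ["v"] * 2,
                "peak": [10.0, 14.0],
            }
        )
        out = average_trials(df)
        assert out["peak"].iloc[0] == pytest.approx(12.0)
        assert out["n_trials"].iloc[0] == 2

    def test_matches_brute_force_group_by(self):
        rng = np.random.default_rng(2)
        rows = []
        for s in range(4):
            for site in "AB":
                for tr in (1, 2, 3):
                    rows.append(
                        {
                            "subject": f"s{s}",
                            "site": site,
                            "side": "r",
                            "trial": tr,
                            "variable": "v",
                            "peak": rng.normal(),
                        }
                    )
        df = pd.DataFrame(rows)
        out = average_trials(df)
        for _, r in out.iterrows():
            manual = np.mean(
                [
                    x["peak"]
                    for x in rows
                    if x["subject"] == r["subject"] and x["site"] == r["site"]
                ]
            )
            assert r["peak"] == pytest.approx(manual)


def _synthetic_peak_table(n_subjects=8, sites=("A", "B", "C"), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for var in VARIABLES:
        subj_eff = rng.normal(0, 5, n_subjects)
        site_eff = {s: rng.normal(0, 1) for s in sites}
        for i in range(n_subjects):
            for s in sites:
                for tr in (1, 2, 3):
                    rows.append(
                        {
                            "subject": f"s{i:02d}",
                            "site": s,
                            "side": "r",
                            "trial": tr,
                            "variable": var,
                            "peak": 20 + subj_eff[i] + site_eff[s] + rng.normal(0, 1),
                        }
                    )
    return pd.DataFrame(rows)


class TestReport:
    def test_layout_covers_16_variables_and_all_designs(self):
        peaks = _synthetic_peak_table()
        rep = reliability_report(peaks, None, side="r").to_frame()
        assert set(rep["variable"]) == set(VARIABLES)
        assert len(rep[rep["design"] == "among"]) == 16
        assert len(rep[rep["design"] == "between"]) == 16 * 3
        assert len(rep[rep["design"] == "within"]) == 16 * 3
        assert set(rep[rep["design"] == "between"]["unit"]) == {"A-B", "B-C", "A-C"}
        # forms follow the study design
        assert (rep[rep["design"] == "between"]["icc_form"] == "3,1").all()
        assert (rep[rep["design"] != "between"]["icc_form"] == "3,k").all()

    def test_subject_missing_a_site_is_casewise_deleted(self):
        peaks = _synthetic_peak_table(n_subjects=6)
        peaks = peaks[~((peaks["subject"] == "s00") & (peaks["site"] == "C"))]
        rep = reliability_report(peaks, None, side="r").to_frame()
        among = rep[rep["design"] == "among"]
        assert (among["n_subjects"] == 5).all()
        ab = rep[(rep["design"] == "between") & (rep["unit"] == "A-B")]
        assert (ab["n_subjects"] == 6).all()

    def test_cmc_computed_from_waveforms(self):
        rng = np.random.default_rng(1)
        peaks = _synthetic_peak_table(n_subjects=6, seed=1)
        shape = np.sin(np.linspace(0, np.pi, 101))
        wf_rows = []
        for _, r in peaks[peaks["trial"] == 1].iterrows():
            for tr in (1, 2, 3):
                wf_rows.append(
                    {
                        "subject": r["subject"],
                        "site": r["site"],
                        "side": "r",
                        "trial": tr,
                        "variable": r["variable"],
                        "curve": 20 * shape + 0.5 * rng.standard_normal(101),
                    }
                )
        wf = pd.DataFrame(wf_rows)
        rep = reliability_report(peaks, wf, side="r").to_frame()
        within = rep[rep["design"] == "within"]
        assert (within["cmc_mean"].dropna() > 0.9).all()
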