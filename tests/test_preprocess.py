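"""Stance detection, gap filling, filtering and time normalization."""

import numpy as np
import pytest
from scipy.signal import butter, filtfilt

from dvjrel.preprocess import (
    StanceDetectionError,
    butterworth_lowpass,
    detect_stance,
    fill_gap_virtual_asis,
    fill_gaps_spline,
    fill_trial_gaps,
    time_normalize,
)


class TestStanceDetection:
    def test_flat_zero_grf_raises(self):
        with pytest.raises(StanceDetectionError, match="no stance"):
            detect_stance(np.zeros(100), 1200.0)

    def test_never_unloading_raises(self):
        grf = np.concatenate([np.zeros(10), np.full(90, 500.0)])
        with pytest.raises(StanceDetectionError, match="take-off"):
            detect_stance(grf, 1200.0)

    def test_known_contact_and_takeoff_at_1200hz(self):
        # loaded exactly over t in [0.5, 0.9) s
        t = np.arange(2400) / 1200.0
        grf = np.where((t >= 0.5) & (t < 0.9), 800.0, 0.0)
        st = detect_stance(grf, 1200.0, rate_ratio=5)
        assert (st.ic_force, st.to_force) == (600, 1080)
        assert st.duration == pytest.approx(0.400)
        assert st.initial_contact == 120
        assert st.take_off == 216

    def test_chatter_uses_earliest_crossing(self):
        grf = np.array([0.0, 9.9, 10.1, 9.8, 10.2, 9.7, 0.0])
        st = detect_stance(grf, 100.0)
        assert st.ic_force == 2  # first sample above threshold
        assert st.to_force == 3  # first subsequent sample below

    def test_debounce_skips_chatter(self):
        grf = np.concatenate([[0, 11, 5], np.full(50, 300.0), np.zeros(10)])
        st = detect_stance(grf, 1000.0, debounce_s=0.003)
        assert st.ic_force == 3
        assert st.to_force == 53

    def test_generator_truth_recovered_within_one_sample(self, clean_trial):
        trial, truth = clean_trial
        st = detect_stance(trial.total_grf()[:, 2], trial.force_rate, trial.rate_ratio)
        assert abs(st.ic_force - truth.ic_force) <= 1
        assert abs(st.to_force - truth.to_force) <= 1


class TestSplineFill:
    def test_cubic_trajectory_recovered_exactly(self):
        t = np.arange(100, dtype=float)
        series = 0.001 * t**3 - 0.2 * t**2 + 3 * t - 7
        valid = np.ones(100, dtype=bool)
        valid[40:50] = True
        valid[40:50] = False
        filled, new_valid, recs = fill_gaps_spline(series.copy(), valid, max_gap_frames=24)
        assert new_valid.all()
        np.testing.assert_allclose(filled, series, atol=1e-9)
        assert recs == [(40, 10, True, "")]

    def test_gap_over_limit_left_unfilled(self):
        series = np.sin(np.arange(200) / 10.0)
        valid = np.ones(200, dtype=bool)
        valid[50:75] = False  # 25 frames > limit 24
        _, new_valid, recs = fill_gaps_spline(series, valid, max_gap_frames=24)
        assert not new_valid[50:75].any()
        assert recs[0][2] is False and "limit" in recs[0][3]

    def test_boundary_gap_never_filled(self):
        series = np.arange(50, dtype=float)
        valid = np.ones(50, dtype=bool)
        valid[:5] = False
        _, new_valid, recs = fill_gaps_spline(series, valid, max_gap_frames=24)
        assert not new_valid[:5].any()
        assert "boundary" in recs[0][3]

    def test_smooth_signal_fill_error_below_noise_floor(self):
        # 2 Hz sinusoid at 240 Hz, 20-frame gap: fill error well under 0.5 mm
        t = np.arange(480) / 240.0
        series = 30.0 * np.sin(2 * np.pi * 2.0 * t)
        valid = np.ones(len(t), dtype=bool)
        valid[200:220] = False
        filled, new_valid, _ = fill_gaps_spline(series.copy(), valid, max_gap_frames=24)
        assert new_valid.all()
        assert np.max(np.abs(filled[200:220] - series[200:220])) < 0.5


class TestVirtualAsisFill:
    def test_zero_length_gap_is_identity(self, clean_trial):
        trial, _ = clean_trial
        filled, info = fill_gap_virtual_asis(trial, "l", gap=(50, 50))
        np.testing.assert_array_equal(filled, trial.marker("LASIS"))
        assert info["n_filled"] == 0

    def test_rigid_pelvis_reconstruction_is_exact(self, clean_trial):
        trial, _ = clean_trial
        sub = trial.copy()
        j = sub.index("LASIS")
        true_series = sub.markers[:, j, :].copy()
        sub.valid[100:140, j] = False
        sub.markers[100:140, j] = np.nan
        filled, info = fill_gap_virtual_asis(sub, "l", gap=(100, 140))
        np.testing.assert_allclose(filled[100:140], true_series[100:140], atol=1e-6)
        assert info["n_filled"] == 40

    def test_noisy_pelvis_keeps_peak_hip_angle_within_one_degree(self, model):
        """2 mm pelvis marker noise: the reconstructed ASIS changes the peak
        hip angles by under a degree (no clinically relevant difference)."""
        from dvjrel.kinematics import compute_joint_angles
        from dvjrel.preprocess import detect_stance
        from dvjrel.simulate import DVJSpec, NoiseSpec, generate_static_trial, generate_trial

        from dvjrel.preprocess import filter_trial

        noise = NoiseSpec(marker_noise_sd=2.0, soft_tissue_amplitude=0.0, site_placement_offset_sd=0.0, gap_spec=None)
        trial, truth = generate_trial(model, DVJSpec(), noise, seed=11)
        static = generate_static_trial(model, noise, seed=12)
        st = detect_stance(trial.total_grf()[:, 2], trial.force_rate, trial.rate_ratio)
        ic, to = st.initial_contact, st.take_off

        ref_angles, _, _ = compute_joint_angles(filter_trial(trial), static)
        gapped = trial.copy()
        j = gapped.index("LASIS")
        gapped.valid[ic : ic + 40, j] = False
        gapped.markers[ic : ic + 40, j] = np.nan
        filled, _ = fill_gap_virtual_asis(gapped, "l", gap=(ic, ic + 40))
        gapped.markers[:, j, :] = filled
        gapped.valid[:, j] = True
        fill_angles, _, _ = compute_joint_angles(filter_trial(gapped), static)
        peak_ref = ref_angles["hip_l"][ic:to].max(axis=0)
        peak_fill = fill_angles["hip_l"][ic:to].max(axis=0)
        assert np.all(np.abs(peak_ref - peak_fill) <= 1.0)

    def test_missing_calibration_window_raises(self, clean_trial):
        trial, _ = clean_trial
        sub = trial.copy()
        j = sub.index("LASIS")
        sub.valid[:, j] = False
        sub.markers[:, j] = np.nan
        with pytest.raises(RuntimeError, match="pelvis frame"):
            fill_gap_virtual_asis(sub, "l", gap=(10, 20))


class TestGapRouting:
    @pytest.mark.parametrize(
        "rate,gap_len,expected_method",
        [
            (240.0, 24, "spline"),  # exactly 10% -> spline
            (240.0, 25, "virtual_asis"),  # just over 10% -> virtual (ASIS)
            (240.0, 61, "unfilled"),  # over 25% (60) -> excluded
            (200.0, 20, "spline"),
            (200.0, 21, "virtual_asis"),
            (200.0, 51, "unfilled"),
        ],
    )
    def test_asis_gap_routing_by_site_rate(self, model, rate, gap_len, expected_method):
        from dvjrel.simulate import DVJSpec, NoiseSpec, generate_trial
        from dvjrel.trial import SiteConfig

        site = SiteConfig("A" if rate == 240 else "C", rate, rate * 5)
        trial, _ = generate_trial(model, DVJSpec(), NoiseSpec.zero(), seed=4, site=site)
        j = trial.index("RASIS")
        trial.valid[60 : 60 + gap_len, j] = False
        trial.markers[60 : 60 + gap_len, j] = np.nan
        _, report = fill_trial_gaps(trial)
        rec = [r for r in report.records if r.marker == "RASIS"][0]
        assert rec.method == expected_method

    def test_fill_report_lengths_account_for_every_injected_sample(self, noisy_trial):
        trial, truth = noisy_trial
        filled, report = fill_trial_gaps(trial)
        assert sum(r.length for r in report.records) == sum(
            g.length for g in truth.gap_ledger
        )


class TestButterworth:
    def test_constant_series_unchanged(self):
        out = butterworth_lowpass(np.full(500, 3.7), rate=240.0)
        np.testing.assert_allclose(out, 3.7, atol=1e-9)

    def test_stopband_attenuation_matches_squared_analog_response(self):
        # 50 Hz sinusoid, sampled fast enough that bilinear warping is
        # negligible: the dual pass squares the analog-prototype magnitude
        rate = 2400.0
        t = np.arange(48000) / rate
        x = np.sin(2 * np.pi * 50.0 * t)
        y = butterworth_lowpass(x, rate=rate, cutoff_hz=12.0, order=4)
        measured = np.abs(y[12000:36000]).max()
        expected = (1.0 / np.sqrt(1.0 + (50.0 / 12.0) ** (2 * 4))) ** 2
        assert measured == pytest.approx(expected, rel=0.05)

    def test_stopband_attenuation_matches_squared_digital_response(self):
        # at the capture rate itself the oracle is the designed digital
        # filter's |H|^2 (bilinear warping shifts the analog curve at 50 Hz)
        from scipy.signal import freqz

        t = np.arange(4800) / 240.0
        x = np.sin(2 * np.pi * 50.0 * t)
        y = butterworth_lowpass(x, rate=240.0, cutoff_hz=12.0, order=4)
        measured = np.abs(y[1200:3600]).max()
        b, a = butter(4, 12.0, fs=240.0)
        _, h = freqz(b, a, worN=[50.0], fs=240.0)
        assert measured == pytest.approx(np.abs(h[0]) ** 2, rel=0.05)

    def test_passband_preserved(self):
        t = np.arange(4800) / 240.0
        x = np.sin(2 * np.pi * 1.0 * t)
        y = butterworth_lowpass(x, rate=240.0)
        assert np.abs(y[1200:3600]).max() >= 0.99

    def test_idempotent_in_passband(self):
        t = np.arange(4800) / 240.0
        x = np.sin(2 * np.pi * 1.0 * t)
        y1 = butterworth_lowpass(x, rate=240.0)
        y2 = butterworth_lowpass(y1, rate=240.0)
        assert np.abs(y2 - y1)[1200:3600].max() < 0.01

    def test_masked_samples_rejected(self):
        x = np.ones(100)
        x[3] = np.nan
        with pytest.raises(ValueError, match="gap filling"):
            butterworth_lowpass(x, rate=240.0)

    def test_matches_scipy_reference_pipeline(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)
        b, a = butter(4, 12.0, fs=240.0)
        np.testing.assert_allclose(
            butterworth_lowpass(x, 240.0), filtfilt(b, a, x), atol=1e-12
        )


class TestTimeNormalize:
    def test_constant_stays_constant(self):
        out = time_normalize(np.full(77, 5.0))
        assert out.shape == (101,)
        np.testing.assert_allclose(out, 5.0)

    def test_linear_ramp_maps_to_percent_grid(self):
        out = time_normalize(np.linspace(0, 1, 301))
        np.testing.assert_allclose(out, np.arange(101) / 100.0, atol=1e-12)

    def test_endpoints_preserved_exactly(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(96, 3))
        out = time_normalize(x)
        np.testing.assert_array_equal(out[0], x[0])
        np.testing.assert_array_equal(out[-1], x[-1])

    def test_sinusoid_matches_analytic_resample(self):
        # one full cycle over 96 stance frames; linear-interpolation error
        # bound h^2 |f''| / 8 keeps the deviation under 1e-3 of amplitude
        n = 96
        t = np.linspace(0, 1, n)
        x = np.sin(2 * np.pi * t)
        out = time_normalize(x)
        analytic = np.sin(2 * np.pi * np.linspace(0, 1, 101))
        assert np.abs(out - analytic).max() <= 1e-3

    def test_degenerate_stance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            time_normalize(np.ones(3))
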