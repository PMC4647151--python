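"""Segment derivatives and Newton-Euler inverse dynamics.

The dynamic oracle here is an independently coded d'Alembert balance: the
net internal moment at a joint equals the rate of change of angular
momentum of everything distal to it, minus the moments of gravity and the
ground reaction about the joint — a direct (non-recursive) summation that
shares no code with the bottom-up recursion it checks.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dvjrel.anthropometry import SEGMENT_TABLE, segment_inertia
from dvjrel.kinematics import calibrate, compute_joint_angles
from dvjrel.kinetics import (
    GrfInput,
    _inertias_for,
    assign_plates,
    inverse_dynamics,
    newton_euler_side,
    prepare_grf,
    segment_kinematics,
)
from dvjrel.preprocess import detect_stance
from dvjrel.trial import GRAVITY


def _static_pose(n, origin):
    return (
        np.broadcast_to(np.eye(3), (n, 3, 3)).copy(),
        np.tile(np.asarray(origin, dtype=float), (n, 1)),
    )


class TestSegmentKinematics:
    def test_stationary_segment_has_zero_derivatives(self):
        R, o = _static_pose(50, [0.1, 0.2, 0.9])
        kin = segment_kinematics(R, o, rate=240.0)
        for key in ("vel", "acc", "omega", "alpha"):
            np.testing.assert_allclose(kin[key], 0.0, atol=1e-12)

    def test_constant_velocity_translation(self):
        t = np.arange(100) / 240.0
        v = np.array([0.3, -0.1, 0.2])
        o = t[:, None] * v
        R = np.broadcast_to(np.eye(3), (100, 3, 3)).copy()
        kin = segment_kinematics(R, o, rate=240.0)
        np.testing.assert_allclose(kin["vel"], np.tile(v, (100, 1)), atol=1e-9)
        np.testing.assert_allclose(kin["acc"], 0.0, atol=1e-6)

    def test_sinusoidal_rotation_matches_analytic_rates(self):
        rate, f, amp = 240.0, 2.0, 0.4
        t = np.arange(480) / rate
        theta = amp * np.sin(2 * np.pi * f * t)
        R = Rotation.from_rotvec(np.outer(theta, [0.0, 0.0, 1.0])).as_matrix()
        kin = segment_kinematics(R, np.zeros((480, 3)), rate=rate)
        omega_true = amp * 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        alpha_true = -amp * (2 * np.pi * f) ** 2 * np.sin(2 * np.pi * f * t)
        sl = slice(5, -5)
        assert np.abs(kin["omega"][sl, 2] - omega_true[sl]).max() <= 0.01 * np.abs(omega_true).max()
        assert np.abs(kin["alpha"][sl, 2] - alpha_true[sl]).max() <= 0.01 * np.abs(alpha_true).max()

    def test_too_few_frames_rejected(self):
        R, o = _static_pose(2, [0, 0, 0])
        with pytest.raises(ValueError, match="3 frames"):
            segment_kinematics(R, o, rate=240.0)


class TestStaticNewtonEuler:
    def _standing_chain(self, n=50, mass=62.3, height=170.0):
        inertias = _inertias_for(mass, height)
        poses = {
            "foot": _rt(_static_pose(n, [0.0, 0.0, 0.066])),
            "shank": _rt(_static_pose(n, [0.0, 0.0, 0.48])),
            "thigh": _rt(_static_pose(n, [0.0, 0.0, 0.90])),
        }
        return poses, inertias

    def test_grf_through_ankle_gives_zero_ankle_moment(self):
        n = 50
        poses, inertias = self._standing_chain(n)
        leg_mass = sum(i.mass for i in inertias.values())
        # supported load (half body) through a COP directly below the ankle,
        # but the foot CoM is anterior: include its gravity moment
        fz = 0.5 * 62.3 * GRAVITY
        cop = np.tile([0.0, 0.0, 0.0], (n, 1))
        grf = GrfInput(force=np.tile([0, 0, fz], (n, 1)).astype(float), cop=cop, tz=np.zeros(n))
        res = newton_euler_side(poses, inertias, grf, rate=240.0)
        # frontal (y) ankle moment: gravity of the foot's own CoM offset only
        foot_com_x = inertias["foot"].com_local[0]
        expected = -inertias["foot"].mass * GRAVITY * foot_com_x
        np.testing.assert_allclose(res["ankle"]["moment"][5:-5, 1], expected, atol=1e-9)

    def test_displaced_cop_adds_closed_form_lever_arm(self):
        n = 50
        poses, inertias = self._standing_chain(n)
        fz = 0.5 * 62.3 * GRAVITY
        d = 0.08  # anterior COP displacement, m
        grf0 = GrfInput(np.tile([0, 0, fz], (n, 1)).astype(float), np.zeros((n, 3)), np.zeros(n))
        grfd = GrfInput(
            np.tile([0, 0, fz], (n, 1)).astype(float),
            np.tile([d, 0.0, 0.0], (n, 1)),
            np.zeros(n),
        )
        m0 = newton_euler_side(poses, inertias, grf0, 240.0)["ankle"]["moment"]
        md = newton_euler_side(poses, inertias, grfd, 240.0)["ankle"]["moment"]
        # sagittal moment difference = Fz * d: a pure internal plantar-
        # flexor lever arm, exact to machine precision
        np.testing.assert_allclose((md - m0)[5:-5, 1], fz * d, rtol=1e-12)

    def test_zero_gravity_zero_motion_zero_grf_gives_zero_moments(self):
        n = 50
        poses, inertias = self._standing_chain(n)
        grf = GrfInput(np.zeros((n, 3)), np.zeros((n, 3)), np.zeros(n))
        res = newton_euler_side(poses, inertias, grf, 240.0, gravity=0.0)
        for joint in ("ankle", "knee", "hip"):
            np.testing.assert_allclose(res[joint]["moment"], 0.0, atol=1e-12)
            np.testing.assert_allclose(res[joint]["force"], 0.0, atol=1e-12)

    def test_static_hip_force_supports_weight_above(self):
        n = 50
        poses, inertias = self._standing_chain(n)
        mass = 62.3
        fz = 0.5 * mass * GRAVITY
        grf = GrfInput(np.tile([0, 0, fz], (n, 1)).astype(float), np.zeros((n, 3)), np.zeros(n))
        res = newton_euler_side(poses, inertias, grf, 240.0)
        leg_mass = sum(i.mass for i in inertias.values())
        # the reaction the pelvis receives from both legs carries the HAT weight
        reaction_up = -2 * res["hip"]["force"][10, 2]
        expected = (mass - 2 * leg_mass) * GRAVITY
        assert reaction_up == pytest.approx(expected, rel=1e-9)

    def test_homogeneity_in_mass_and_load(self):
        """Scaling body mass and external load together leaves
        mass-normalized moments unchanged."""
        n = 50
        rng = np.random.default_rng(0)
        poses, inertias1 = self._standing_chain(n, mass=60.0)
        _, inertias2 = self._standing_chain(n, mass=120.0)
        f = rng.normal(size=(n, 3)) * 100
        cop = rng.normal(size=(n, 3)) * 0.05
        grf1 = GrfInput(f, cop, np.zeros(n))
        grf2 = GrfInput(2 * f, cop, np.zeros(n))
        r1 = newton_euler_side(poses, inertias1, grf1, 240.0)
        r2 = newton_euler_side(poses, inertias2, grf2, 240.0)
        np.testing.assert_allclose(
            r2["knee"]["moment"] / 120.0, r1["knee"]["moment"] / 60.0, atol=1e-12
        )


def _rt(pair):
    return pair


def dalembert_knee_moment(poses, inertias, grf, rate):
    """Independent oracle: direct angular-momentum balance of foot+shank
    about the knee (no recursion)."""
    R_k, p_knee = poses["shank"]
    total = np.zeros_like(p_knee)
    for kind in ("foot", "shank"):
        R, origin = poses[kind]
        inert = inertias[kind]
        kin = segment_kinematics(R, origin, rate, inert.com_local)
        i_lab = np.einsum("nij,j,nkj->nik", R, inert.inertia, R)
        h_dot = np.einsum("nij,nj->ni", i_lab, kin["alpha"]) + np.cross(
            kin["omega"], np.einsum("nij,nj->ni", i_lab, kin["omega"])
        )
        g_term = np.cross(kin["com"] - p_knee, inert.mass * np.array([0, 0, -GRAVITY]))
        # rate of change of angular momentum about the knee, minus gravity
        total += h_dot + np.cross(kin["com"] - p_knee, inert.mass * kin["acc"]) - g_term
    tz = np.zeros((len(p_knee), 3))
    tz[:, 2] = grf.tz
    total -= np.cross(grf.cop - p_knee, grf.force) + tz
    return total


class TestDynamicOracle:
    def test_dvj_knee_sagittal_moment_matches_dalembert_oracle(self, clean_trial, clean_static):
        trial, truth = clean_trial
        st = detect_stance(trial.total_grf()[:, 2], trial.force_rate, trial.rate_ratio)
        _, frames, cal = (lambda a: a)(compute_joint_angles(trial, clean_static))
        assignment = assign_plates(trial, slice(st.ic_force, st.to_force))
        inertias = _inertias_for(trial.subject.mass, trial.subject.height)
        side = "r"
        grf = prepare_grf(trial, assignment[side])
        poses = {
            kind: (frames[f"{kind}_{side}"].A, frames[f"{kind}_{side}"].origin / 1000.0)
            for kind in ("foot", "shank", "thigh")
        }
        res = newton_euler_side(poses, inertias, grf, trial.marker_rate)
        oracle = dalembert_knee_moment(poses, inertias, grf, trial.marker_rate)
        ic, to = st.initial_contact, st.take_off
        sl = slice(ic + 3, to - 3)
        peak = np.abs(oracle[sl, 1]).max()
        err = np.abs(res["knee"]["moment"][sl, 1] - oracle[sl, 1]).max()
        assert err <= 0.02 * peak

    def test_zero_noise_moments_match_generator_truth(self, clean_trial, clean_static):
        """Closed loop through the kinetics wrapper: with the same raw
        (unfiltered) force inputs the generator truth uses, marker-level
        reconstruction reproduces the true moment curves."""
        trial, truth = clean_trial
        st = detect_stance(trial.total_grf()[:, 2], trial.force_rate, trial.rate_ratio)
        _, frames, cal = (lambda a: a)(compute_joint_angles(trial, clean_static))
        sel = np.arange(trial.n_frames) * trial.rate_ratio
        grf_by_side = {}
        for side, p in assign_plates(trial, slice(st.ic_force, st.to_force)).items():
            plate = trial.plates[p]
            cop = plate.cop(10.0)
            ok = np.isfinite(cop[:, 0])
            t = np.arange(len(cop))
            copf = np.stack([np.interp(t, t[ok], cop[ok, c]) for c in range(3)], axis=1)
            grf_by_side[side] = GrfInput(
                force=plate.force[sel], cop=copf[sel] / 1000.0, tz=np.zeros(trial.n_frames)
            )
        moments = inverse_dynamics(trial, frames, cal, grf_by_side=grf_by_side)
        ic, to = st.initial_contact + 3, st.take_off - 3
        for key in ("knee_r", "knee_l", "hip_r", "ankle_r"):
            peak_true = np.abs(truth.moments[key][ic:to, 0]).max()
            err = np.abs(moments[key][ic:to, 0] - truth.moments[key][ic:to, 0]).max()
            assert err <= 0.02 * peak_true, key

    def test_plate_assignment_matches_feet(self, clean_trial):
        trial, _ = clean_trial
        st = detect_stance(trial.total_grf()[:, 2], trial.force_rate, trial.rate_ratio)
        assignment = assign_plates(trial, slice(st.ic_force, st.to_force))
        assert assignment == {"l": 0, "r": 1}

    def test_single_plate_for_both_feet_is_ambiguous(self, clean_trial):
        trial, _ = clean_trial
        sub = trial.copy()
        sub.plates = [sub.plates[0], sub.plates[0]]
        # move right foot markers onto the left so both resolve to plate 0
        for m in ("RANKL",):
            sub.markers[:, sub.index(m), 1] = sub.markers[:, sub.index("LANKL"), 1]
        st = detect_stance(sub.total_grf()[:, 2], sub.force_rate, sub.rate_ratio)
        with pytest.raises(ValueError, match="ambiguous"):
            assign_plates(sub, slice(st.ic_force, st.to_force))


class TestInertiaTable:
    def test_mass_fractions_sum_to_one_over_whole_body(self):
        total = (
            2 * SEGMENT_TABLE["foot"]["mass_frac"]
            + 2 * SEGMENT_TABLE["shank"]["mass_frac"]
            + 2 * SEGMENT_TABLE["thigh"]["mass_frac"]
            + SEGMENT_TABLE["pelvis"]["mass_frac"]
            + SEGMENT_TABLE["trunk"]["mass_frac"]
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_inertia_scales_with_mass_and_length_squared(self):
        a = segment_inertia("shank", 60.0, 0.4)
        b = segment_inertia("shank", 120.0, 0.8)
        np.testing.assert_allclose(b.inertia, a.inertia * 2 * 4)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            segment_inertia("shank", -1.0, 0.4)
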