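"""Synthetic multi-site drop-vertical-jump cohort generator.

The generator produces marker and force-plate data with known ground truth
so every downstream stage (gap fill, filtering, stance detection,
kinematics, kinetics, reliability statistics) can be tested without study
capture data.  Study conditions emulated by default: 25 subjects tested at
3 laboratories, 3 trials each; drop from a 31 cm box with feet initially
35 cm apart; stance time ~400 ms; capture at 240/1200 Hz (sites A, B) or
200/1000 Hz (site C).

Construction
------------
Joint motion is driven by a hip-height spline through (contact, deepest
point, take-off) knots with ballistic boundary velocities; a closed-form
two-link inverse kinematics keeps each foot planted during stance, and
smooth half-sine "bumps" add frontal/transverse motion (pelvis tilt/
obliquity/rotation, trunk lean, knee valgus and rotation, hip rotation,
ankle inversion).  Bump and flexion amplitudes are drawn once per subject
(between-subject variance) with small per-trial jitter (trial-to-trial
variance); marker-placement offsets are drawn per site x subject and held
fixed within a site (between-site variance), exactly the two-level
structure the reliability analysis assumes.

The vertical ground-reaction force is derived from the realized whole-body
center-of-mass acceleration, so GRF is zero in flight and the impulse-
momentum balance holds by construction; joint moments therefore have a
self-consistent inverse-dynamics ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from ._rotations import decompose_joint, joint_signs, rot_axis_angle
from .kinetics import GrfInput, _inertias_for, newton_euler_side
from .markers import GapCensusEntry, default_marker_set
from .skeleton import SegmentPose, SkeletonModel, build_skeleton, markers_from_poses
from .trial import GRAVITY, ForcePlate, SiteConfig, Subject, Trial

__all__ = [
    "DVJSpec",
    "NoiseSpec",
    "GapSpec",
    "SyntheticGroundTruth",
    "Cohort",
    "generate_trial",
    "generate_static_trial",
    "generate_cohort",
    "inject_gaps",
    "draw_subject_params",
    "DEFAULT_SITES",
]

DEFAULT_SITES = (
    SiteConfig("A", 240.0, 1200.0),
    SiteConfig("B", 240.0, 1200.0),
    SiteConfig("C", 200.0, 1000.0),
)


@dataclass
class GapSpec:
    """Marker-dropout injection: mainly the ASIS markers, as in real captures."""

    n_gaps: int = 2
    min_length: int = 5
    max_length: int = 30
    targets: tuple[str, ...] = ("LASIS", "RASIS")


@dataclass
class NoiseSpec:
    marker_noise_sd: float = 0.5  # mm, white, per axis
    soft_tissue_amplitude: float = 2.0  # mm, thigh/shank markers
    soft_tissue_freq: float = 8.0  # Hz
    site_placement_offset_sd: float = 7.0  # mm, constant per site x subject x marker
    gap_spec: GapSpec | None = field(default_factory=GapSpec)

    def __post_init__(self) -> None:
        if min(self.marker_noise_sd, self.soft_tissue_amplitude, self.site_placement_offset_sd) < 0:
            raise ValueError("noise magnitudes must be non-negative")

    @classmethod
    def zero(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 8.0, 0.0, None)


# population means and SDs of the subject-level motion parameters
# (degrees unless noted); drawn once per subject, shared across sites
_SUBJECT_PARAMS = {
    "knee_peak": (95.0, 8.0),  # peak knee flexion
    "knee_contact": (25.0, 3.0),  # knee flexion at initial contact
    "knee_takeoff": (20.0, 3.0),
    "t_peak_frac": (0.45, 0.02),  # timing of deepest point, fraction of stance
    "jump_height": (0.25, 0.03),  # m
    "stance_duration": (None, 0.0),  # mean comes from DVJSpec
    "pelvis_tilt": (8.0, 3.0),
    "pelvis_obliquity": (3.0, 1.0),
    "pelvis_rotation": (4.0, 1.5),
    "pelvis_sway": (0.0, 0.03),  # m, lateral weight-shift amplitude
    "stance_width_offset": (0.0, 0.02),  # m, foot-placement variability
    "trunk_lean": (18.0, 5.0),
    "asym": (0.0, 0.03),  # left/right load share offset
}
_SIDE_PARAMS = {
    "hip_rot": (8.0, 3.0),
    "knee_valgus": (8.0, 3.0),
    "knee_rot": (7.0, 3.0),
    "ankle_inv": (-4.0, 2.0),
    "foot_rot": (3.0, 1.5),
}
# trial-to-trial jitter SDs (same units as the parameter)
_TRIAL_JITTER = {
    "knee_peak": 2.5,
    "knee_contact": 1.5,
    "knee_takeoff": 1.5,
    "t_peak_frac": 0.01,
    "jump_height": 0.02,
    "stance_duration": 0.012,
    "pelvis_tilt": 1.0,
    "pelvis_obliquity": 0.8,
    "pelvis_rotation": 0.8,
    "pelvis_sway": 0.01,
    "stance_width_offset": 0.008,
    "trunk_lean": 2.0,
    "asym": 0.01,
    "hip_rot": 1.5,
    "knee_valgus": 1.5,
    "knee_rot": 1.5,
    "ankle_inv": 1.0,
    "foot_rot": 1.0,
}


@dataclass
class DVJSpec:
    drop_height: float = 0.31  # m
    initial_stance_width: float = 0.35  # m
    stance_duration: float = 0.4  # s
    contact_time: float = 0.35  # s from trial start to initial contact
    post_flight: float = 0.25  # s captured after take-off
    pelvis_setback: float = 0.25  # hips travel backward by this fraction of the dip
    # time constant of foot deceleration at contact / heel-rise before
    # take-off (shoe + ankle compliance); keeps the whole-body CoM velocity
    # continuous so the GRF has no single-sample impact deltas
    landing_compliance_tau: float = 0.012  # s
    n_subjects: int = 25
    trials_per_subject: int = 3
    sites: tuple[SiteConfig, ...] = DEFAULT_SITES
    trial_jitter_scale: float = 1.0  # scales all trial-to-trial parameter jitter

    def __post_init__(self) -> None:
        if self.stance_duration <= 0:
            raise ValueError("stance_duration must be positive")
        if self.drop_height < 0 or self.initial_stance_width <= 0:
            raise ValueError("infeasible DVJ geometry (negative drop or stance width)")


def draw_subject_params(spec: DVJSpec, rng: np.random.Generator) -> dict[str, float]:
    """One subject's motion-amplitude random effects."""
    p: dict[str, float] = {}
    for key, (mean, sd) in _SUBJECT_PARAMS.items():
        mu = spec.stance_duration if key == "stance_duration" else mean
        p[key] = mu + sd * rng.standard_normal()
    for key, (mean, sd) in _SIDE_PARAMS.items():
        for side in ("l", "r"):
            p[f"{key}_{side}"] = mean + sd * rng.standard_normal()
    return p


def jitter_params(
    params: dict[str, float], rng: np.random.Generator, scale: float = 1.0
) -> dict[str, float]:
    """Per-trial copy of subject parameters with trial-to-trial jitter."""
    out = dict(params)
    for key, sd in _TRIAL_JITTER.items():
        if key in _SIDE_PARAMS:
            for side in ("l", "r"):
                out[f"{key}_{side}"] = out[f"{key}_{side}"] + scale * sd * rng.standard_normal()
        else:
            out[key] = out[key] + scale * sd * rng.standard_normal()
    out["t_peak_frac"] = float(np.clip(out["t_peak_frac"], 0.25, 0.7))
    out["stance_duration"] = float(max(out["stance_duration"], 0.15))
    return out


@dataclass
class SyntheticGroundTruth:
    """Noise-free reference quantities for one generated trial."""

    angles: dict[str, np.ndarray]  # "hip_l" -> (n_frames, 3) deg, clinical axes
    moments: dict[str, np.ndarray]  # N*m/kg, proximal-frame clinical axes
    contact_time: float  # s
    stance_duration: float  # s
    ic_force: int  # first force sample of stance
    to_force: int  # first force sample after stance
    com: np.ndarray  # (n_force_frames, 3) m
    grf: np.ndarray  # (n_force_frames, 3) N, total
    gap_ledger: list[GapCensusEntry]
    site_offsets: dict[str, np.ndarray]  # mm, per marker (empty if none)
    params: dict[str, float]


class _Motion:
    """Closed-form DVJ motion model for one trial's parameters."""

    def __init__(self, model: SkeletonModel, spec: DVJSpec, p: dict[str, float]):
        self.model, self.spec, self.p = model, spec, p
        L = model.lengths
        self.lt, self.ls, self.ha = (
            L["thigh_length"],
            L["shank_length"],
            L["ankle_height"],
        )
        self.d = L["asis_breadth"]
        self.hip_y = abs(model.hip_local["l"][1])
        self.sw = spec.initial_stance_width + p.get("stance_width_offset", 0.0)
        self.dy = abs(self.sw / 2 - self.hip_y)
        self.tc = spec.contact_time
        self.T = p["stance_duration"]
        self.te = self.tc + self.T
        self.tau = spec.landing_compliance_tau
        self.v_imp = np.sqrt(2 * GRAVITY * spec.drop_height)
        self.v_to = np.sqrt(2 * GRAVITY * max(p["jump_height"], 0.02))
        z_c = self._z_of_knee(p["knee_contact"], setback_from=None)
        z_pk = self._z_of_knee(p["knee_peak"], setback_from=z_c)
        z_to = self._z_of_knee(p["knee_takeoff"], setback_from=z_c)
        self.z_c = z_c
        t_pk = self.tc + p["t_peak_frac"] * self.T
        self.spline = CubicSpline(
            [self.tc, t_pk, self.te],
            [z_c, z_pk, z_to],
            bc_type=((1, -self.v_imp), (1, self.v_to)),
        )

    def _z_of_knee(self, k_deg: float, setback_from: float | None) -> float:
        k = np.radians(k_deg)
        d2 = self.lt**2 + self.ls**2 + 2 * self.lt * self.ls * np.cos(k)
        z = self.ha + np.sqrt(max(d2 - self.dy**2, 1e-4))
        if setback_from is not None:
            for _ in range(6):
                dx = self.spec.pelvis_setback * (setback_from - z)
                z = self.ha + np.sqrt(max(d2 - self.dy**2 - dx**2, 1e-4))
        return float(z)

    def pelvis_origin(self, t: np.ndarray) -> np.ndarray:
        """Piecewise ballistic / spline pelvis origin (n, 3), meters."""
        t = np.asarray(t, dtype=float)
        tcl = np.clip(t, self.tc, self.te)
        z_h = self.spline(tcl)
        x_p = -self.spec.pelvis_setback * (self.z_c - z_h)
        # lateral weight-shift sway: zero (with zero slope) at the stance
        # boundaries so flight continuation stays velocity-continuous
        s = np.clip((tcl - self.tc) / self.T, 0.0, 1.0)
        y_p = self.p.get("pelvis_sway", 0.0) * np.sin(np.pi * s) ** 2
        o = np.stack([x_p, y_p, z_h + 0.30 * self.d], axis=1)
        # flight extension: rigid ballistic continuation of the boundary state
        for mask, t0, v in (
            (t < self.tc, self.tc, np.array([-self.spec.pelvis_setback * self.v_imp, 0, -self.v_imp])),
            (t >= self.te, self.te, np.array([self.spec.pelvis_setback * self.v_to, 0, self.v_to])),
        ):
            if mask.any():
                dt = (t[mask] - t0)[:, None]
                o[mask] = o[mask] + v * dt + np.array([0, 0, -GRAVITY / 2]) * dt**2
        return o

    def poses(self, t: np.ndarray) -> dict[str, SegmentPose]:
        p, model = self.p, self.model
        t = np.asarray(t, dtype=float)
        n = len(t)
        s = np.clip((t - self.tc) / self.T, 0.0, 1.0)
        b = np.sin(np.pi * s) ** 2
        o_full = self.pelvis_origin(t)
        o_stance = self.pelvis_origin(np.clip(t, self.tc, self.te))
        shift = o_full - o_stance  # rigid flight translation

        # foot-compliance vertical offset: the planted foot decelerates from
        # the impact velocity over ~tau at contact and accelerates into
        # take-off, keeping segment velocities continuous at the boundaries
        tcl = np.clip(t, self.tc, self.te)
        sink = -self.v_imp * self.tau * (1.0 - np.exp(-(tcl - self.tc) / self.tau))
        rise = self.v_to * self.tau * np.exp(-(self.te - tcl) / self.tau)
        anchor_dz = sink + rise

        rad = np.radians
        ey = np.array([0.0, 1.0, 0.0])
        ex = np.array([1.0, 0.0, 0.0])
        ez = np.array([0.0, 0.0, 1.0])
        r_p = (
            rot_axis_angle(ey, -rad(p["pelvis_tilt"]) * b)
            @ rot_axis_angle(ex, rad(p["pelvis_obliquity"]) * b)
            @ rot_axis_angle(ez, rad(p["pelvis_rotation"]) * b)
        )
        poses: dict[str, SegmentPose] = {}
        poses["pelvis"] = SegmentPose(o_stance + shift, r_p)
        r_t = r_p @ rot_axis_angle(ey, -rad(p["trunk_lean"]) * b)
        trunk_o = o_stance + np.einsum("nij,j->ni", r_p, model.trunk_offset)
        poses["trunk"] = SegmentPose(trunk_o + shift, r_t)
        for side in ("l", "r"):
            sho_local = model.marker_locals[f"{side.upper()}SHO"][1]
            arm_o = trunk_o + np.einsum("nij,j->ni", r_t, sho_local)
            poses[f"arm_{side}"] = SegmentPose(arm_o + shift, r_t)

        for side in ("l", "r"):
            lat = 1.0 if side == "l" else -1.0
            sig = joint_signs("hip", side)  # (flex, frontal, axial) multipliers
            hip = o_stance + np.einsum("nij,j->ni", r_p, model.hip_local[side])
            anchor = np.zeros((n, 3))
            anchor[:, 1] = lat * self.sw / 2
            anchor[:, 2] = self.ha + anchor_dz
            u = anchor - hip
            dist = np.linalg.norm(u, axis=1)
            dmax = 0.999 * (self.lt + self.ls)
            dc = np.minimum(dist, dmax)
            uhat = u / dist[:, None]
            cos_int = (self.lt**2 + self.ls**2 - dc**2) / (2 * self.lt * self.ls)
            interior = np.arccos(np.clip(cos_int, -1.0, 1.0))
            phi_t = np.arcsin(np.clip(self.ls * np.sin(interior) / dc, -1.0, 1.0))
            n0 = np.cross(ex, uhat)
            n0 /= np.linalg.norm(n0, axis=1, keepdims=True)
            rho_h = rad(p[f"hip_rot_{side}"]) * b * sig[2]
            nvec = np.einsum("nij,nj->ni", rot_axis_angle(uhat, rho_h), n0)
            thigh_dir = np.einsum("nij,nj->ni", rot_axis_angle(nvec, -phi_t), uhat)
            knee = hip + self.lt * thigh_dir
            valg = rad(p[f"knee_valgus_{side}"]) * b
            eoff = np.sin(valg) * (self.lt * self.ls / (self.lt + self.ls))
            knee = knee - lat * eoff[:, None] * nvec  # medial shift = valgus collapse
            z_t = hip - knee
            z_t /= np.linalg.norm(z_t, axis=1, keepdims=True)
            y_t = nvec - np.sum(nvec * z_t, axis=1, keepdims=True) * z_t
            y_t /= np.linalg.norm(y_t, axis=1, keepdims=True)
            x_t = np.cross(y_t, z_t)
            r_thigh = np.stack([x_t, y_t, z_t], axis=-1)
            poses[f"thigh_{side}"] = SegmentPose(hip + shift, r_thigh)

            z_s = knee - anchor
            z_s /= np.linalg.norm(z_s, axis=1, keepdims=True)
            y_s0 = nvec - np.sum(nvec * z_s, axis=1, keepdims=True) * z_s
            y_s0 /= np.linalg.norm(y_s0, axis=1, keepdims=True)
            rho_k = rad(p[f"knee_rot_{side}"]) * b * sig[2]
            y_s = np.einsum("nij,nj->ni", rot_axis_angle(z_s, rho_k), y_s0)
            x_s = np.cross(y_s, z_s)
            r_shank = np.stack([x_s, y_s, z_s], axis=-1)
            poses[f"shank_{side}"] = SegmentPose(knee + shift, r_shank)

            ankle = knee + np.einsum("nij,j->ni", r_shank, np.array([0, 0, -self.ls]))
            sig_a = joint_signs("ankle", side)
            r_f = rot_axis_angle(ez, rad(p[f"foot_rot_{side}"]) * b * sig_a[2]) @ rot_axis_angle(
                ex, rad(p[f"ankle_inv_{side}"]) * b * sig_a[1]
            )
            poses[f"foot_{side}"] = SegmentPose(ankle + shift, r_f)
        return poses

    def stance_bump(self, t: np.ndarray) -> np.ndarray:
        s = np.clip((np.asarray(t) - self.tc) / self.T, 0.0, 1.0)
        return np.sin(np.pi * s) ** 2


def _true_angles(poses: dict[str, SegmentPose]) -> dict[str, np.ndarray]:
    chains = {"hip": ("pelvis", "thigh"), "knee": ("thigh", "shank"), "ankle": ("shank", "foot")}
    out = {}
    for joint, (prox, dist) in chains.items():
        for side in ("l", "r"):
            rp = poses[prox if prox == "pelvis" else f"{prox}_{side}"].R
            rd = poses[f"{dist}_{side}"].R
            rel = np.einsum("nji,njk->nik", rp, rd)
            out[f"{joint}_{side}"] = decompose_joint(joint, side, rel)
    return out


def _body_com(model: SkeletonModel, poses: dict[str, SegmentPose]) -> np.ndarray:
    total = 0.0
    acc = 0.0
    for seg, frac in (
        ("pelvis", model.mass_fractions["pelvis"]),
        ("trunk", model.mass_fractions["trunk"]),
    ):
        acc = acc + frac * (poses[seg].origin + np.einsum("nij,j->ni", poses[seg].R, model.com_local(seg)))
        total += frac
    for side in ("l", "r"):
        for kind in ("thigh", "shank", "foot"):
            frac = model.mass_fractions[kind]
            pose = poses[f"{kind}_{side}"]
            acc = acc + frac * (pose.origin + np.einsum("nij,j->ni", pose.R, model.com_local(kind)))
            total += frac
    return acc / total


def _cop_local(motion: _Motion, t: np.ndarray) -> np.ndarray:
    """Heel-to-toe COP progression in the foot frame (meters)."""
    s = np.clip((np.asarray(t) - motion.tc) / motion.T, 0.0, 1.0)
    prog = 3 * s**2 - 2 * s**3
    x = -0.04 + 0.16 * prog
    return np.stack([x, np.zeros_like(x), np.full_like(x, -motion.ha)], axis=1)


def generate_trial(
    model: SkeletonModel,
    spec: DVJSpec,
    noise: NoiseSpec,
    seed: int | np.random.Generator | None = None,
    *,
    site: SiteConfig | None = None,
    params: dict[str, float] | None = None,
    trial_index: int = 1,
    site_offsets: dict[str, np.ndarray] | None = None,
) -> tuple[Trial, SyntheticGroundTruth]:
    """Generate one DVJ trial and its ground truth.

    ``site_offsets`` (mm, per marker, segment-frame) emulate marker
    placement differences between laboratories; they displace both static
    and dynamic marker positions consistently.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    site = site or DEFAULT_SITES[0]
    if params is None:
        params = jitter_params(draw_subject_params(spec, rng), rng, spec.trial_jitter_scale)
    work_model = _offset_model(model, site_offsets) if site_offsets else model
    motion = _Motion(work_model, spec, params)

    total_t = motion.te + spec.post_flight
    n_m = int(round(total_t * site.marker_rate))
    ratio = site.rate_ratio
    n_f = n_m * ratio
    t_m = np.arange(n_m) / site.marker_rate
    t_f = np.arange(n_f) / site.force_rate

    poses_m = motion.poses(t_m)
    poses_f = motion.poses(t_f)

    labels = default_marker_set().names
    markers = markers_from_poses(work_model, poses_m, labels)  # m

    # --- forces from whole-body CoM dynamics (force clock) ---
    com = _body_com(work_model, poses_f)
    dt_f = 1.0 / site.force_rate
    acc = np.gradient(np.gradient(com, dt_f, axis=0), dt_f, axis=0)
    in_stance = (t_f >= motion.tc) & (t_f < motion.te)
    mass = model.subject.mass
    grf = mass * (acc - np.array([0.0, 0.0, -GRAVITY]))
    grf[~in_stance] = 0.0
    grf[:, 2] = np.maximum(grf[:, 2], 0.0)

    w_l = float(np.clip(0.5 + params["asym"], 0.05, 0.95))
    plates = []
    for side, w in (("l", w_l), ("r", 1.0 - w_l)):
        f_side = grf * w
        pose = poses_f[f"foot_{side}"]
        cop = pose.origin + np.einsum("nij,nj->ni", pose.R, _cop_local(motion, t_f))
        cop[:, 2] = 0.0
        cop_mm = cop * 1000.0
        moment = np.cross(cop_mm, f_side)
        plates.append(ForcePlate(force=f_side, moment=moment))

    # --- measurement noise (marker clock) ---
    noisy = markers.copy()
    soft_targets = [
        i
        for i, lab in enumerate(labels)
        if work_model.marker_locals[lab][0].startswith(("thigh", "shank"))
    ]
    # draw soft-tissue phases/directions deterministically even at zero amplitude
    phases = rng.uniform(0, 2 * np.pi, size=len(soft_targets))
    dirs = rng.standard_normal((len(soft_targets), 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    if noise.soft_tissue_amplitude > 0:
        bump = motion.stance_bump(t_m)
        for k, j in enumerate(soft_targets):
            wobble = np.sin(2 * np.pi * noise.soft_tissue_freq * t_m + phases[k]) * bump
            noisy[:, j, :] += (noise.soft_tissue_amplitude / 1000.0) * wobble[:, None] * dirs[k]
    white = rng.standard_normal(noisy.shape)
    if noise.marker_noise_sd > 0:
        noisy += (noise.marker_noise_sd / 1000.0) * white

    trial = Trial(
        markers=noisy * 1000.0,
        valid=np.ones((n_m, len(labels)), dtype=bool),
        labels=list(labels),
        marker_rate=site.marker_rate,
        plates=plates,
        force_rate=site.force_rate,
        subject=model.subject,
        site=site.site_id,
        trial_index=trial_index,
        static=False,
    )

    # --- ground truth ---
    angles = _true_angles(poses_m)
    moments = _true_moments(work_model, poses_m, motion, t_m, grf, w_l, site.marker_rate, ratio)
    truth = SyntheticGroundTruth(
        angles=angles,
        moments=moments,
        contact_time=motion.tc,
        stance_duration=motion.T,
        ic_force=int(np.ceil(motion.tc * site.force_rate - 1e-9)),
        to_force=int(np.ceil(motion.te * site.force_rate - 1e-9)),
        com=com,
        grf=grf,
        gap_ledger=[],
        site_offsets=dict(site_offsets or {}),
        params=dict(params),
    )

    if noise.gap_spec is not None:
        trial, ledger = inject_gaps(trial, noise.gap_spec, rng)
        truth.gap_ledger = ledger
    return trial, truth


def _true_moments(model, poses_m, motion, t_m, grf_f, w_l, marker_rate, ratio):
    """Internal joint moments from true poses and the generated GRF."""
    mass = model.subject.mass
    inertias = _inertias_for(mass, model.subject.height)
    sel = np.arange(len(t_m)) * ratio
    out: dict[str, np.ndarray] = {}
    prox_of = {"ankle": "shank", "knee": "thigh", "hip": "pelvis"}
    for side, w in (("l", w_l), ("r", 1.0 - w_l)):
        pose_f = poses_m[f"foot_{side}"]
        cop = pose_f.origin + np.einsum("nij,nj->ni", pose_f.R, _cop_local(motion, t_m))
        cop[:, 2] = 0.0
        grf = GrfInput(force=grf_f[sel] * w, cop=cop, tz=np.zeros(len(t_m)))
        chain = {
            kind: (poses_m[f"{kind}_{side}"].R, poses_m[f"{kind}_{side}"].origin)
            for kind in ("foot", "shank", "thigh")
        }
        res = newton_euler_side(chain, inertias, grf, marker_rate)
        for joint in ("ankle", "knee", "hip"):
            prox = prox_of[joint]
            a_p = poses_m[prox if prox == "pelvis" else f"{prox}_{side}"].R
            m_local = np.einsum("nji,nj->ni", a_p, res[joint]["moment"])
            raw = m_local[:, [1, 0, 2]]
            out[f"{joint}_{side}"] = raw / joint_signs(joint, side) / mass
    return out


def _offset_model(model: SkeletonModel, offsets_mm: dict[str, np.ndarray]) -> SkeletonModel:
    locals_ = {
        lab: (seg, local + np.asarray(offsets_mm.get(lab, np.zeros(3))) / 1000.0)
        for lab, (seg, local) in model.marker_locals.items()
    }
    return replace(model, marker_locals=locals_)


def generate_static_trial(
    model: SkeletonModel,
    noise: NoiseSpec,
    seed: int | np.random.Generator | None = None,
    *,
    site: SiteConfig | None = None,
    site_offsets: dict[str, np.ndarray] | None = None,
    duration: float = 0.5,
) -> Trial:
    """Neutral-standing static calibration capture (feet under the hips)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    site = site or DEFAULT_SITES[0]
    work_model = _offset_model(model, site_offsets) if site_offsets else model
    n_m = int(round(duration * site.marker_rate))
    n_f = n_m * site.rate_ratio
    L = work_model.lengths
    z_hip = L["ankle_height"] + L["thigh_length"] + L["shank_length"]
    origin = np.array([0.0, 0.0, z_hip + 0.30 * L["asis_breadth"]])
    eye = np.broadcast_to(np.eye(3), (n_m, 3, 3)).copy()
    poses: dict[str, SegmentPose] = {}
    poses["pelvis"] = SegmentPose(np.tile(origin, (n_m, 1)), eye)
    trunk_o = origin + work_model.trunk_offset
    poses["trunk"] = SegmentPose(np.tile(trunk_o, (n_m, 1)), eye)
    for side in ("l", "r"):
        sho = work_model.marker_locals[f"{side.upper()}SHO"][1]
        poses[f"arm_{side}"] = SegmentPose(np.tile(trunk_o + sho, (n_m, 1)), eye)
        hip = origin + work_model.hip_local[side]
        poses[f"thigh_{side}"] = SegmentPose(np.tile(hip, (n_m, 1)), eye)
        knee = hip + np.array([0, 0, -L["thigh_length"]])
        poses[f"shank_{side}"] = SegmentPose(np.tile(knee, (n_m, 1)), eye)
        ankle = knee + np.array([0, 0, -L["shank_length"]])
        poses[f"foot_{side}"] = SegmentPose(np.tile(ankle, (n_m, 1)), eye)
    labels = default_marker_set().names
    markers = markers_from_poses(work_model, poses, labels)
    if noise.marker_noise_sd > 0:
        markers = markers + (noise.marker_noise_sd / 1000.0) * rng.standard_normal(markers.shape)
    mass = model.subject.mass
    plates = []
    for side, w in (("l", 0.5), ("r", 0.5)):
        f = np.zeros((n_f, 3))
        f[:, 2] = w * mass * GRAVITY
        ankle = poses[f"foot_{side}"].origin[0] * 1000.0
        cop = np.array([ankle[0] + 20.0, ankle[1], 0.0])
        moment = np.cross(np.tile(cop, (n_f, 1)), f)
        plates.append(ForcePlate(force=f, moment=moment))
    return Trial(
        markers=markers * 1000.0,
        valid=np.ones((n_m, len(labels)), dtype=bool),
        labels=list(labels),
        marker_rate=site.marker_rate,
        plates=plates,
        force_rate=site.force_rate,
        subject=model.subject,
        site=site.site_id,
        trial_index=0,
        static=True,
    )


def inject_gaps(
    trial: Trial, gap_spec: GapSpec, seed: int | np.random.Generator | None = None
) -> tuple[Trial, list[GapCensusEntry]]:
    """Mask random marker runs; the returned ledger matches the mask exactly.

    Overlapping requested gaps on one marker are merged (the ledger then
    holds the merged run).  Gaps avoid the first/last frame so they remain
    spline-fillable in principle.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = trial.copy()
    n = trial.n_frames
    requested: dict[str, list[tuple[int, int]]] = {}
    for _ in range(gap_spec.n_gaps):
        label = gap_spec.targets[rng.integers(len(gap_spec.targets))]
        length = int(rng.integers(gap_spec.min_length, gap_spec.max_length + 1))
        length = min(length, n - 2)
        start = int(rng.integers(1, n - length))
        requested.setdefault(label, []).append((start, start + length))
    ledger: list[GapCensusEntry] = []
    for label, intervals in requested.items():
        intervals.sort()
        merged: list[list[int]] = []
        for s, e in intervals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        j = out.index(label)
        for s, e in merged:
            out.valid[s:e, j] = False
            out.markers[s:e, j, :] = np.nan
            ledger.append(GapCensusEntry(marker=label, start=s, length=e - s))
    return out, ledger


@dataclass
class Cohort:
    """A generated multi-site study: trials, statics, and ground truth."""

    spec: DVJSpec
    noise: NoiseSpec
    subjects: list[Subject]
    models: dict[str, SkeletonModel]  # subject id -> skeleton
    statics: dict[tuple[str, str], Trial]  # (site, subject) -> static trial
    items: list[tuple[Trial, SyntheticGroundTruth]]

    @property
    def trials(self) -> list[Trial]:
        return [t for t, _ in self.items]


def generate_cohort(
    spec: DVJSpec | None = None, noise: NoiseSpec | None = None, seed: int | None = 0
) -> Cohort:
    """Generate the default 25-subject x 3-site x 3-trial cohort.

    Per-subject amplitude parameters are drawn once and shared across sites
    (between-subject variance); marker-placement offsets are drawn per
    site x subject and held constant within a site (between-site variance);
    per-trial jitter supplies the trial-to-trial variance.
    """
    spec = spec or DVJSpec()
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    labels = default_marker_set().names
    subjects, models, sub_params = [], {}, {}
    for i in range(spec.n_subjects):
        sid = f"S{i + 1:02d}"
        subj = Subject(
            id=sid,
            mass=float(np.clip(62.3 + 6.8 * rng.standard_normal(), 40, 95)),
            height=float(np.clip(169.3 + 4.5 * rng.standard_normal(), 150, 190)),
        )
        subjects.append(subj)
        models[sid] = build_skeleton(subj)
        sub_params[sid] = draw_subject_params(spec, rng)
    statics: dict[tuple[str, str], Trial] = {}
    items: list[tuple[Trial, SyntheticGroundTruth]] = []
    for site in spec.sites:
        for subj in subjects:
            offsets = {
                lab: noise.site_placement_offset_sd * rng.standard_normal(3) for lab in labels
            }
            statics[(site.site_id, subj.id)] = generate_static_trial(
                models[subj.id], noise, rng, site=site, site_offsets=offsets
            )
            for k in range(spec.trials_per_subject):
                p = jitter_params(sub_params[subj.id], rng, spec.trial_jitter_scale)
                items.append(
                    generate_trial(
                        models[subj.id],
                        spec,
                        noise,
                        rng,
                        site=site,
                        params=p,
                        trial_index=k + 1,
                        site_offsets=offsets,
                    )
                )
    return Cohort(spec=spec, noise=noise, subjects=subjects, models=models, statics=statics, items=items)
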