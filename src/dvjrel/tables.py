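"""Packaged copy of the study's printed reliability tables.

The multicenter screening study reports, for 16 peak variables (8 joint
angles in degrees, 8 mass-normalized joint moments), the between-site
reliability (CMC mean+-SD, ICC(3,k) among all three laboratories and
CMC/ICC(3,1)/SEM per site pair) and the within-site trial-to-trial
reliability (CMC mean+-SD, ICC(3,k), SEM per site).  These printed values
are shipped so reports can be rendered side-by-side against them and so
the published summary statements (classification counts, ranges) can be
recomputed from the tables with the package's own classification rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .reliability import classify_icc

__all__ = [
    "between_site_table",
    "within_site_table",
    "results_summary",
    "ANGLE_VARS",
    "MOMENT_VARS",
]

ANGLE_VARS = [
    "hip_flexion_angle",
    "hip_adduction_angle",
    "hip_internal_rotation_angle",
    "knee_flexion_angle",
    "knee_abduction_angle",
    "knee_internal_rotation_angle",
    "ankle_dorsiflexion_angle",
    "ankle_eversion_angle",
]
MOMENT_VARS = [v.replace("_angle", "_moment") for v in ANGLE_VARS]

# columns: among (cmc_mean, cmc_sd, icc3k), then per pair A-B, B-C, A-C:
# (cmc_mean, cmc_sd, icc31, sem)
_BETWEEN = {
    # angles (deg)
    "hip_flexion_angle": (0.932, 0.09, 0.860, 0.934, 0.07, 0.536, 5.0, 0.974, 0.02, 0.765, 3.4, 0.955, 0.04, 0.719, 4.2),
    "hip_adduction_angle": (0.456, 0.31, 0.855, 0.644, 0.28, 0.724, 2.3, 0.709, 0.25, 0.700, 2.1, 0.638, 0.28, 0.573, 2.8),
    "hip_internal_rotation_angle": (0.693, 0.13, 0.843, 0.823, 0.14, 0.620, 4.0, 0.847, 0.09, 0.673, 4.1, 0.813, 0.11, 0.629, 4.7),
    "knee_flexion_angle": (0.945, 0.10, 0.832, 0.944, 0.10, 0.550, 4.7, 0.981, 0.02, 0.525, 4.5, 0.962, 0.07, 0.762, 3.7),
    "knee_abduction_angle": (0.578, 0.24, 0.893, 0.811, 0.11, 0.715, 2.2, 0.795, 0.23, 0.758, 2.2, 0.810, 0.17, 0.728, 2.3),
    "knee_internal_rotation_angle": (0.523, 0.20, 0.860, 0.827, 0.15, 0.735, 2.9, 0.806, 0.16, 0.547, 4.0, 0.830, 0.13, 0.741, 2.9),
    "ankle_dorsiflexion_angle": (0.954, 0.05, 0.762, 0.948, 0.09, 0.789, 2.0, 0.960, 0.08, 0.373, 3.4, 0.969, 0.03, 0.451, 3.5),
    "ankle_eversion_angle": (0.608, 0.21, 0.777, 0.756, 0.23, 0.470, 2.7, 0.804, 0.16, 0.655, 1.9, 0.786, 0.21, 0.711, 1.7),
    # moments (N*m/kg)
    "hip_flexion_moment": (0.862, 0.14, 0.830, 0.851, 0.14, 0.660, 0.18, 0.917, 0.04, 0.550, 0.22, 0.886, 0.09, 0.673, 0.15),
    "hip_adduction_moment": (0.643, 0.13, 0.626, 0.722, 0.16, 0.553, 0.10, 0.780, 0.12, 0.140, 0.13, 0.697, 0.12, 0.384, 0.10),
    "hip_internal_rotation_moment": (0.700, 0.14, 0.545, 0.775, 0.15, 0.605, 0.07, 0.775, 0.12, 0.293, 0.12, 0.712, 0.16, 0.140, 0.14),
    "knee_flexion_moment": (0.818, 0.22, 0.789, 0.860, 0.13, 0.385, 0.22, 0.936, 0.04, 0.734, 0.16, 0.872, 0.12, 0.504, 0.18),
    "knee_abduction_moment": (0.615, 0.09, 0.620, 0.729, 0.14, 0.216, 0.11, 0.847, 0.12, 0.431, 0.13, 0.765, 0.12, 0.342, 0.13),
    "knee_internal_rotation_moment": (0.493, 0.13, 0.692, 0.738, 0.14, 0.344, 0.06, 0.690, 0.19, 0.370, 0.07, 0.729, 0.18, 0.612, 0.04),
    "ankle_dorsiflexion_moment": (0.743, 0.22, 0.705, 0.799, 0.15, 0.526, 0.13, 0.916, 0.04, 0.639, 0.09, 0.819, 0.13, 0.223, 0.16),
    "ankle_eversion_moment": (0.540, 0.21, -0.112, 0.706, 0.19, 0.798, 0.05, 0.673, 0.22, -0.288, 0.15, 0.592, 0.21, -0.250, 0.15),
}

# per site A, B, C: (cmc_mean, cmc_sd, icc3k, sem)
_WITHIN = {
    "hip_flexion_angle": (0.974, 0.02, 0.908, 2.6, 0.979, 0.01, 0.900, 1.9, 0.982, 0.02, 0.947, 1.7),
    "hip_adduction_angle": (0.610, 0.30, 0.950, 0.9, 0.672, 0.25, 0.916, 1.3, 0.526, 0.35, 0.896, 1.5),
    "hip_internal_rotation_angle": (0.813, 0.19, 0.963, 0.7, 0.830, 0.13, 0.920, 1.2, 0.818, 0.17, 0.946, 0.7),
    "knee_flexion_angle": (0.987, 0.10, 0.932, 2.3, 0.991, 0.01, 0.910, 2.0, 0.991, 0.01, 0.925, 2.3),
    "knee_abduction_angle": (0.816, 0.15, 0.989, 0.5, 0.828, 0.10, 0.973, 0.7, 0.896, 0.08, 0.987, 0.5),
    "knee_internal_rotation_angle": (0.721, 0.18, 0.983, 0.9, 0.825, 0.07, 0.983, 0.8, 0.725, 0.14, 0.977, 1.3),
    "ankle_dorsiflexion_angle": (0.987, 0.01, 0.947, 1.2, 0.942, 0.22, 0.942, 1.4, 0.989, 0.01, 0.928, 1.7),
    "ankle_eversion_angle": (0.801, 0.18, 0.971, 0.8, 0.684, 0.26, 0.883, 1.4, 0.766, 0.15, 0.923, 1.1),
    "hip_flexion_moment": (0.851, 0.26, 0.806, 0.07, 0.933, 0.05, 0.784, 0.09, 0.935, 0.04, 0.896, 0.05),
    "hip_adduction_moment": (0.773, 0.09, 0.766, 0.04, 0.776, 0.15, 0.628, 0.06, 0.785, 0.12, 0.675, 0.07),
    "hip_internal_rotation_moment": (0.811, 0.16, 0.833, 0.03, 0.896, 0.07, 0.827, 0.03, 0.852, 0.19, 0.856, 0.04),
    "knee_flexion_moment": (0.889, 0.16, 0.741, 0.09, 0.932, 0.06, 0.900, 0.08, 0.917, 0.05, 0.882, 0.07),
    "knee_abduction_moment": (0.667, 0.23, 0.849, 0.04, 0.747, 0.24, 0.910, 0.04, 0.770, 0.19, 0.881, 0.03),
    "knee_internal_rotation_moment": (0.579, 0.24, 0.827, 0.03, 0.593, 0.20, 0.603, 0.05, 0.542, 0.27, 0.793, 0.03),
    "ankle_dorsiflexion_moment": (0.774, 0.16, 0.897, 0.02, 0.884, 0.08, 0.803, 0.03, 0.893, 0.06, 0.820, 0.02),
    "ankle_eversion_moment": (0.658, 0.29, 0.899, 0.05, 0.847, 0.10, 0.951, 0.03, 0.825, 0.08, 0.496, 0.08),
}

_PAIRS = ("A-B", "B-C", "A-C")


def between_site_table() -> pd.DataFrame:
    """Long-form between-site reference values (among + site pairs)."""
    rows = []
    for var, vals in _BETWEEN.items():
        kind = "moment" if var.endswith("moment") else "angle"
        rows.append(
            {
                "variable": var,
                "kind": kind,
                "unit": "all",
                "design": "among",
                "cmc_mean": vals[0],
                "cmc_sd": vals[1],
                "icc": vals[2],
                "icc_form": "3,k",
                "sem": np.nan,
            }
        )
        for i, pair in enumerate(_PAIRS):
            o = 3 + 4 * i
            rows.append(
                {
                    "variable": var,
                    "kind": kind,
                    "unit": pair,
                    "design": "between",
                    "cmc_mean": vals[o],
                    "cmc_sd": vals[o + 1],
                    "icc": vals[o + 2],
                    "icc_form": "3,1",
                    "sem": vals[o + 3],
                }
            )
    df = pd.DataFrame(rows)
    df["classification"] = df["icc"].map(classify_icc)
    return df


def within_site_table() -> pd.DataFrame:
    """Long-form within-site trial-to-trial reference values."""
    rows = []
    for var, vals in _WITHIN.items():
        kind = "moment" if var.endswith("moment") else "angle"
        for i, site in enumerate("ABC"):
            o = 4 * i
            rows.append(
                {
                    "variable": var,
                    "kind": kind,
                    "unit": site,
                    "design": "within",
                    "cmc_mean": vals[o],
                    "cmc_sd": vals[o + 1],
                    "icc": vals[o + 2],
                    "icc_form": "3,k",
                    "sem": vals[o + 3],
                }
            )
    df = pd.DataFrame(rows)
    df["classification"] = df["icc"].map(classify_icc)
    return df


def results_summary() -> dict[str, float]:
    """Recompute the published summary sentences from the packaged tables.

    Applies the classification rule and min/max summaries to the printed
    values: classification counts for between-site peak reliability, ICC
    and CMC ranges among sites and within sites, for kinematic and kinetic
    variables separately.
    """
    bt = between_site_table()
    wt = within_site_table()
    among = bt[bt["design"] == "among"]
    pairs = bt[bt["design"] == "between"]
    out: dict[str, float] = {}
    for kind, tag in (("angle", "kinematic"), ("moment", "kinetic")):
        a = among[among["kind"] == kind]
        p = pairs[pairs["kind"] == kind]
        w = wt[wt["kind"] == kind]
        out[f"among_sites_{tag}_icc_min"] = float(a["icc"].min())
        out[f"among_sites_{tag}_icc_max"] = float(a["icc"].max())
        out[f"among_sites_{tag}_cmc_min"] = float(a["cmc_mean"].min())
        out[f"among_sites_{tag}_cmc_max"] = float(a["cmc_mean"].max())
        out[f"between_sites_{tag}_excellent_count"] = int((p["classification"] == "excellent").sum())
        out[f"between_sites_{tag}_poor_count"] = int((p["classification"] == "poor").sum())
        out[f"within_site_{tag}_excellent_count"] = int((w["classification"] == "excellent").sum())
        out[f"within_site_{tag}_good_count"] = int((w["classification"] == "good").sum())
        out[f"within_site_{tag}_cmc_min"] = float(w["cmc_mean"].min())
        out[f"within_site_{tag}_cmc_max"] = float(w["cmc_mean"].max())
    # sagittal vs non-sagittal among-site kinematic waveform similarity
    sagittal = {"hip_flexion_angle", "knee_flexion_angle", "ankle_dorsiflexion_angle"}
    a = among[among["kind"] == "angle"]
    out["among_sites_sagittal_cmc_min"] = float(a[a["variable"].isin(sagittal)]["cmc_mean"].min())
    out["among_sites_nonsagittal_cmc_max"] = float(a[~a["variable"].isin(sagittal)]["cmc_mean"].max())
    return out
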