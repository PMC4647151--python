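"""Segment anthropometry: mass, center-of-mass and radius-of-gyration fractions.

Default fractions follow the standard cadaver-derived tables used throughout
gait analysis (Dempster/Winter-style), with the arms and head folded into the
trunk segment (the screening task keeps the arms in a reach posture, and arm
markers ride rigidly on the trunk in the synthetic model).  The table is an
editable mapping so an alternative anthropometric model can be swapped in via
configuration without touching code.

Conventions: segment frames have Z up along the segment long axis (X forward
along the foot), origin at the proximal joint center.  ``com`` entries are
local CoM offsets as fractions of the reference length; ``rog`` entries are
radius-of-gyration fractions of the reference length about the (x, y, z)
segment axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SEGMENT_TABLE", "LENGTH_FRACTIONS", "SegmentInertia", "segment_inertia"]

# mass fractions sum to 1.000 over: 2 feet, 2 shanks, 2 thighs, pelvis, trunk
SEGMENT_TABLE: dict[str, dict] = {
    "foot": {
        "mass_frac": 0.0145,
        "ref": "foot_length",
        "com": (0.25, 0.0, -0.20),  # forward of the ankle, toward the sole
        "rog": (0.225, 0.475, 0.475),
    },
    "shank": {
        "mass_frac": 0.0465,
        "ref": "shank_length",
        "com": (0.0, 0.0, -0.433),
        "rog": (0.302, 0.302, 0.11),
    },
    "thigh": {
        "mass_frac": 0.100,
        "ref": "thigh_length",
        "com": (0.0, 0.0, -0.433),
        "rog": (0.323, 0.323, 0.13),
    },
    "pelvis": {
        "mass_frac": 0.142,
        "ref": "pelvis_depth",
        "com": (-0.25, 0.0, -0.25),
        "rog": (0.55, 0.55, 0.55),
    },
    "trunk": {  # trunk + head + both arms
        "mass_frac": 0.536,
        "ref": "trunk_length",
        "com": (0.0, 0.0, 0.55),
        "rog": (0.45, 0.45, 0.25),
    },
}

# segment reference lengths as fractions of standing height (m)
LENGTH_FRACTIONS = {
    "ankle_height": 0.039,
    "shank_length": 0.246,  # knee 0.285H - ankle 0.039H
    "thigh_length": 0.245,  # hip 0.530H - knee 0.285H
    "foot_length": 0.152,
    "pelvis_depth": 0.12,
    "trunk_length": 0.35,
    "asis_breadth": 0.142,  # inter-ASIS distance
}


@dataclass
class SegmentInertia:
    """Mass (kg), local CoM (m, segment frame) and principal inertia (kg m^2)."""

    mass: float
    com_local: np.ndarray  # (3,)
    inertia: np.ndarray  # (3,) principal moments about the CoM, segment axes

    def __post_init__(self) -> None:
        if self.mass <= 0 or np.any(np.asarray(self.inertia) <= 0):
            raise ValueError("segment mass and inertia must be positive")


def segment_inertia(
    segment: str, body_mass: float, ref_length: float, table: dict | None = None
) -> SegmentInertia:
    """Inertial parameters for one segment from the fraction table.

    I_axis = mass * (rog_frac * ref_length)^2 about each segment axis.
    """
    entry = (table or SEGMENT_TABLE)[segment]
    mass = entry["mass_frac"] * body_mass
    com = np.asarray(entry["com"], dtype=float) * ref_length
    inertia = mass * (np.asarray(entry["rog"], dtype=float) * ref_length) ** 2
    return SegmentInertia(mass=mass, com_local=com, inertia=inertia)
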