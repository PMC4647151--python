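"""In-memory containers for one motion-capture trial.

Canonical internal units: marker positions in mm, forces in N, moments in
N*mm, body mass in kg, rates in Hz.  Lab frame: X anterior (direction the
subject faces), Y to the subject's left, Z up (right-handed).  Force-plate
moments are expressed about the lab origin, on the floor plane (Z = 0).
Missing marker samples are flagged by an explicit validity mask; masked
coordinates are stored as NaN, never as zeros.  Frames are 0-based and
intervals half-open [start, end).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Subject", "ForcePlate", "Trial", "SiteConfig"]

GRAVITY = 9.81  # m/s^2


@dataclass
class Subject:
    id: str
    mass: float  # kg
    height: float  # cm


@dataclass
class ForcePlate:
    """One plate: force (N) and moment about the lab origin (N*mm), lab frame."""

    force: np.ndarray  # (n, 3)
    moment: np.ndarray  # (n, 3)

    def cop(self, fz_threshold: float = 10.0) -> np.ndarray:
        """Center of pressure (mm) on the Z=0 plane; NaN where Fz < threshold.

        With moments about the lab origin and the contact point on the floor,
        x_cop = -My/Fz and y_cop = Mx/Fz.
        """
        fz = self.force[:, 2]
        out = np.full((len(fz), 3), np.nan)
        ok = fz >= fz_threshold
        out[ok, 0] = -self.moment[ok, 1] / fz[ok]
        out[ok, 1] = self.moment[ok, 0] / fz[ok]
        out[ok, 2] = 0.0
        return out

    def free_moment_z(self, fz_threshold: float = 10.0) -> np.ndarray:
        """Vertical free moment (N*mm) about the COP; NaN where Fz < threshold."""
        cop = self.cop(fz_threshold)
        tz = self.moment[:, 2] - (cop[:, 0] * self.force[:, 1] - cop[:, 1] * self.force[:, 0])
        return tz


@dataclass
class SiteConfig:
    """Per-site capture configuration.

    ``max_spline_gap_frames`` is the spline-fill limit: gaps of less than 10%
    of the marker sampling frequency may be spline-filled (24 frames at
    240 Hz, 20 at 200 Hz).
    """

    site_id: str
    marker_rate: float
    force_rate: float

    def __post_init__(self) -> None:
        ratio = self.force_rate / self.marker_rate
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
            raise ValueError(
                f"force_rate must be an integer multiple of marker_rate "
                f"(got {self.force_rate}/{self.marker_rate})"
            )

    @property
    def rate_ratio(self) -> int:
        return int(round(self.force_rate / self.marker_rate))

    @property
    def max_spline_gap_frames(self) -> int:
        return int(np.floor(0.10 * self.marker_rate))

    @property
    def max_virtual_gap_frames(self) -> int:
        """Upper limit for the virtual ASIS fill (25% of the marker rate)."""
        return int(np.floor(0.25 * self.marker_rate))


@dataclass
class Trial:
    """One DVJ repetition (or a static calibration capture)."""

    markers: np.ndarray  # (n_frames, n_markers, 3) mm; NaN where invalid
    valid: np.ndarray  # (n_frames, n_markers) bool
    labels: list[str]
    marker_rate: float
    plates: list[ForcePlate]
    force_rate: float
    subject: Subject
    site: str = "A"
    trial_index: int = 1
    static: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.markers = np.asarray(self.markers, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.markers.ndim != 3 or self.markers.shape[2] != 3:
            raise ValueError("markers must have shape (frames, markers, 3)")
        if self.markers.shape[0] == 0:
            raise ValueError("empty trial")
        if self.valid.shape != self.markers.shape[:2]:
            raise ValueError("valid mask shape must match markers")
        if len(self.labels) != self.markers.shape[1]:
            raise ValueError("labels length must match marker count")
        ratio = self.force_rate / self.marker_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("force_rate must be an integer multiple of marker_rate")
        if not np.isfinite(self.markers[self.valid]).all():
            raise ValueError("non-finite coordinates at samples flagged valid")

    @property
    def n_frames(self) -> int:
        return self.markers.shape[0]

    @property
    def n_force_frames(self) -> int:
        return self.plates[0].force.shape[0] if self.plates else 0

    @property
    def rate_ratio(self) -> int:
        return int(round(self.force_rate / self.marker_rate))

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no marker labeled {label!r} in trial") from None

    def marker(self, label: str) -> np.ndarray:
        """(n_frames, 3) trajectory of one marker (NaN where invalid)."""
        return self.markers[:, self.index(label), :]

    def marker_valid(self, label: str) -> np.ndarray:
        return self.valid[:, self.index(label)]

    def total_grf(self) -> np.ndarray:
        """(n_force_frames, 3) sum of plate forces, N."""
        return np.sum([p.force for p in self.plates], axis=0)

    def copy(self) -> "Trial":
        return replace(
            self,
            markers=self.markers.copy(),
            valid=self.valid.copy(),
            labels=list(self.labels),
            plates=[ForcePlate(p.force.copy(), p.moment.copy()) for p in self.plates],
            meta=dict(self.meta),
        )
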