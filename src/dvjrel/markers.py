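"""Canonical drop-vertical-jump marker set and validation.

The screening protocol instruments each subject with 43 retroreflective
markers: 32 on the body (C7, sternum midpoint, L5-S1 junction, left PSIS,
and 14 bilateral pairs), 4 on each shoe (heel, dorsal midfoot, fifth
metatarsal, toe) and 3 non-collinear markers on a small backpack worn over
the trunk.  Labels follow common mocap shorthand with an L/R side prefix
for bilateral markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = ["MarkerSet", "default_marker_set", "validate_marker_set", "GapCensusEntry"]

# singles: label -> segment
_SINGLES = {
    "C7": "trunk",
    "STRN": "trunk",  # midpoint suprasternal notch / 2nd costal notch
    "SACR": "pelvis",  # L5-S1 spinal junction
    "LPSIS": "pelvis",
}

# bilateral body markers: suffix -> segment template ({s} = side l/r)
_BILATERAL = {
    "SHO": "trunk",  # shoulder
    "UPARM": "arm_{s}",
    "ELB": "arm_{s}",
    "WRI": "arm_{s}",
    "ASIS": "pelvis",
    "TROC": "thigh_{s}",  # greater trochanter
    "THI": "thigh_{s}",  # mid thigh
    "KNEM": "thigh_{s}",  # medial knee joint line
    "KNEL": "thigh_{s}",  # lateral knee joint line
    "TTUB": "shank_{s}",  # tibial tubercle
    "SHNK": "shank_{s}",  # distal shank
    "SHNL": "shank_{s}",  # lateral shank
    "ANKM": "shank_{s}",  # medial ankle
    "ANKL": "shank_{s}",  # lateral ankle
}

_SHOE = {"HEE": "foot_{s}", "MFT": "foot_{s}", "MT5": "foot_{s}", "TOE": "foot_{s}"}

_BACKPACK = {"BPK1": "trunk", "BPK2": "trunk", "BPK3": "trunk"}


@dataclass
class MarkerSet:
    """A named marker protocol: labels, marker->segment map, required subset."""

    names: list[str]
    segment_map: dict[str, str]
    required: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate marker labels: {dupes}")
        unmapped = [n for n in self.names if n not in self.segment_map]
        if unmapped:
            raise ValueError(f"markers without segment assignment: {unmapped}")
        if not self.required:
            self.required = set(self.names)

    def segments(self) -> dict[str, list[str]]:
        """Group marker labels by segment, preserving label order."""
        out: dict[str, list[str]] = {}
        for name in self.names:
            out.setdefault(self.segment_map[name], []).append(name)
        return out

    def to_yaml(self, path) -> None:
        data = {
            "names": list(self.names),
            "segment_map": dict(self.segment_map),
            "required": sorted(self.required),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MarkerSet":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            names=list(data["names"]),
            segment_map=dict(data["segment_map"]),
            required=set(data.get("required", [])),
        )


def default_marker_set() -> MarkerSet:
    """The 43-marker DVJ screening set (32 body + 8 shoe + 3 backpack)."""
    names: list[str] = []
    segmap: dict[str, str] = {}
    for label, seg in _SINGLES.items():
        names.append(label)
        segmap[label] = seg
    for side in ("L", "R"):
        s = side.lower()
        for suffix, seg in _BILATERAL.items():
            label = side + suffix
            names.append(label)
            segmap[label] = seg.format(s=s)
    for side in ("L", "R"):
        s = side.lower()
        for suffix, seg in _SHOE.items():
            label = side + suffix
            names.append(label)
            segmap[label] = seg.format(s=s)
    for label, seg in _BACKPACK.items():
        names.append(label)
        segmap[label] = seg
    assert len(names) == 43
    return MarkerSet(names=names, segment_map=segmap)


@dataclass
class GapCensusEntry:
    marker: str
    start: int  # frame index, half-open [start, start+length)
    length: int


@dataclass
class MarkerValidationReport:
    missing_required: list[str]
    unexpected: list[str]
    gap_census: list[GapCensusEntry]
    over_limit: list[GapCensusEntry]

    @property
    def ok(self) -> bool:
        return not self.missing_required and not self.unexpected


def _runs_of_missing(valid_col) -> list[tuple[int, int]]:
    """Half-open [start, end) runs where valid_col is False."""
    import numpy as np

    v = ~valid_col.astype(bool)
    if not v.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], v.view("i1"), [0]))))
    return [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]


def validate_marker_set(trial, marker_set: MarkerSet, max_gap_frames: int | None = None):
    """Report-only check of a trial against a marker protocol.

    Lists missing required markers, unexpected labels, and a per-marker gap
    census.  Gaps longer than ``max_gap_frames`` (default: the spline limit
    floor(0.10 * marker_rate)) are additionally listed in ``over_limit``.
    """
    if max_gap_frames is None:
        max_gap_frames = int(0.10 * trial.marker_rate)
    present = set(trial.labels)
    missing = sorted(marker_set.required - present)
    unexpected = sorted(present - set(marker_set.names))
    census: list[GapCensusEntry] = []
    over: list[GapCensusEntry] = []
    for j, label in enumerate(trial.labels):
        for s, e in _runs_of_missing(trial.valid[:, j]):
            entry = GapCensusEntry(marker=label, start=s, length=e - s)
            census.append(entry)
            if entry.length > max_gap_frames:
                over.append(entry)
    return MarkerValidationReport(
        missing_required=missing, unexpected=unexpected, gap_census=census, over_limit=over
    )
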