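"""Reading and writing motion-capture trials.

Two dialects:

* ``tsv`` — a plain-text tab-separated dialect (documented in
  ``docs/format.md``) that round-trips a :class:`~dvjrel.trial.Trial`
  exactly, including gap masks.  This is the canonical on-disk form for
  the pipeline and for tests.
* ``c3d`` — the standard binary motion-capture container, supported for
  interoperability through the optional ``ezc3d`` dependency.
"""

from __future__ import annotations

import importlib.util

import numpy as np

from .trial import ForcePlate, Subject, Trial

__all__ = ["read_trial", "write_trial", "FormatError"]

_MAGIC = "#DVJTRIAL"
_VERSION = "1"


class FormatError(ValueError):
    """Raised when a trial file cannot be parsed under the named dialect."""


def _fmt(x: float) -> str:
    # repr() of a Python float is the shortest string that round-trips exactly
    return repr(float(x))


def write_trial(trial: Trial, path, dialect: str = "tsv") -> None:
    """Write a trial to ``path`` in the given dialect.

    The tsv dialect round-trips losslessly with :func:`read_trial`;
    c3d round-trips marker positions to <= 1e-3 mm.
    """
    if dialect == "tsv":
        _write_tsv(trial, path)
    elif dialect == "c3d":
        _write_c3d(trial, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'c3d')")


def read_trial(path, dialect: str = "tsv") -> Trial:
    """Read a trial from ``path``; gaps are preserved as mask flags, not zeros."""
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "c3d":
        return _read_c3d(path)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'c3d')")


# ---------------------------------------------------------------- tsv dialect


def _write_tsv(trial: Trial, path) -> None:
    lines: list[str] = []
    add = lines.append
    add(f"{_MAGIC}\t{_VERSION}")
    add(f"#site\t{trial.site}")
    add(f"#trial_index\t{trial.trial_index}")
    add(f"#static\t{int(trial.static)}")
    add(f"#marker_rate\t{_fmt(trial.marker_rate)}")
    add(f"#force_rate\t{_fmt(trial.force_rate)}")
    add(f"#subject_id\t{trial.subject.id}")
    add(f"#subject_mass_kg\t{_fmt(trial.subject.mass)}")
    add(f"#subject_height_cm\t{_fmt(trial.subject.height)}")
    add("#axes\tX-anterior Y-left Z-up")
    add("#units\tmarkers=mm forces=N moments=N.mm")
    add("#moment_reference\tlab-origin-floor")
    add(f"#n_plates\t{len(trial.plates)}")
    header = ["frame"]
    for lab in trial.labels:
        header += [f"{lab}_x", f"{lab}_y", f"{lab}_z", f"{lab}_v"]
    add("#MARKERS\t" + "\t".join(header))
    for i in range(trial.n_frames):
        row = [str(i)]
        for j in range(len(trial.labels)):
            if trial.valid[i, j]:
                row += [_fmt(c) for c in trial.markers[i, j]] + ["1"]
            else:
                row += ["nan", "nan", "nan", "0"]
        add("\t".join(row))
    fheader = ["frame"]
    for p in range(len(trial.plates)):
        fheader += [f"p{p + 1}_{c}" for c in ("Fx", "Fy", "Fz", "Mx", "My", "Mz")]
    add("#FORCES\t" + "\t".join(fheader))
    for i in range(trial.n_force_frames):
        row = [str(i)]
        for plate in trial.plates:
            row += [_fmt(c) for c in plate.force[i]]
            row += [_fmt(c) for c in plate.moment[i]]
        add("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_tsv(path) -> Trial:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith(_MAGIC):
        raise FormatError(f"{path}: not a DVJTRIAL tsv file (missing {_MAGIC} header)")
    meta: dict[str, str] = {}
    i = 1
    while i < len(lines) and lines[i].startswith("#") and not lines[i].startswith("#MARKERS"):
        key, _, value = lines[i][1:].partition("\t")
        meta[key] = value
        i += 1
    if i >= len(lines) or not lines[i].startswith("#MARKERS"):
        raise FormatError(f"{path}: missing #MARKERS block")
    try:
        header = lines[i].split("\t")[2:]  # drop '#MARKERS', 'frame'
        labels = [header[k][:-2] for k in range(0, len(header), 4)]
        n_plates = int(meta["n_plates"])
        marker_rate = float(meta["marker_rate"])
        force_rate = float(meta["force_rate"])
        subject = Subject(
            id=meta["subject_id"],
            mass=float(meta["subject_mass_kg"]),
            height=float(meta["subject_height_cm"]),
        )
    except (KeyError, ValueError, IndexError) as exc:
        raise FormatError(f"{path}: bad or missing header record ({exc})") from exc
    i += 1
    mrows: list[list[str]] = []
    while i < len(lines) and not lines[i].startswith("#FORCES"):
        if lines[i].strip():
            mrows.append(lines[i].split("\t"))
        i += 1
    if i >= len(lines):
        raise FormatError(f"{path}: missing #FORCES block")
    i += 1
    frows = [lines[k].split("\t") for k in range(i, len(lines)) if lines[k].strip()]

    if not mrows:
        raise FormatError(f"{path}: empty trial (no marker frames)")
    n, m = len(mrows), len(labels)
    markers = np.empty((n, m, 3))
    valid = np.empty((n, m), dtype=bool)
    try:
        for r, row in enumerate(mrows):
            vals = row[1:]
            for j in range(m):
                x, y, z, v = vals[4 * j : 4 * j + 4]
                markers[r, j] = (float(x), float(y), float(z))
                valid[r, j] = v == "1"
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: malformed marker row {r} ({exc})") from exc
    plates = []
    if n_plates:
        nf = len(frows)
        data = np.empty((nf, 6 * n_plates))
        try:
            for r, row in enumerate(frows):
                data[r] = [float(v) for v in row[1 : 1 + 6 * n_plates]]
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: malformed force row {r} ({exc})") from exc
        for p in range(n_plates):
            plates.append(ForcePlate(force=data[:, 6 * p : 6 * p + 3], moment=data[:, 6 * p + 3 : 6 * p + 6]))
    return Trial(
        markers=markers,
        valid=valid,
        labels=labels,
        marker_rate=marker_rate,
        plates=plates,
        force_rate=force_rate,
        subject=subject,
        site=meta.get("site", "A"),
        trial_index=int(meta.get("trial_index", 1)),
        static=bool(int(meta.get("static", 0))),
    )


# ---------------------------------------------------------------- c3d dialect


def _require_ezc3d():
    if importlib.util.find_spec("ezc3d") is None:
        raise ImportError(
            "c3d support requires the optional 'ezc3d' dependency "
            "(pip install dvjrel[c3d]); the tsv dialect needs no extras"
        )
    import ezc3d

    return ezc3d


def _write_c3d(trial: Trial, path) -> None:
    ezc3d = _require_ezc3d()
    c3d = ezc3d.c3d()
    c3d["parameters"]["POINT"]["RATE"]["value"] = [float(trial.marker_rate)]
    c3d["parameters"]["POINT"]["LABELS"]["value"] = list(trial.labels)
    c3d["parameters"]["POINT"]["UNITS"]["value"] = ["mm"]
    pts = np.zeros((4, len(trial.labels), trial.n_frames))
    xyz = np.where(trial.valid[:, :, None], trial.markers, np.nan)
    pts[:3] = np.transpose(xyz, (2, 1, 0))
    pts[3] = 1.0
    c3d["data"]["points"] = pts
    if trial.plates:
        c3d["parameters"]["ANALOG"]["RATE"]["value"] = [float(trial.force_rate)]
        labels = []
        for p in range(len(trial.plates)):
            labels += [f"P{p + 1}_{c}" for c in ("Fx", "Fy", "Fz", "Mx", "My", "Mz")]
        c3d["parameters"]["ANALOG"]["LABELS"]["value"] = labels
        analog = np.concatenate(
            [np.concatenate([p.force, p.moment], axis=1) for p in trial.plates], axis=1
        )
        c3d["data"]["analogs"] = analog.T[None, :, :]
    c3d.write(str(path))


def _read_c3d(path) -> Trial:
    ezc3d = _require_ezc3d()
    try:
        c3d = ezc3d.c3d(str(path))
    except Exception as exc:  # ezc3d raises bare RuntimeError on bad files
        raise FormatError(f"{path}: unreadable c3d file ({exc})") from exc
    pts = c3d["data"]["points"]  # (4, n_markers, n_frames)
    labels = [str(s).strip() for s in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    markers = np.transpose(pts[:3], (2, 1, 0)).astype(float)
    valid = np.isfinite(markers).all(axis=2)
    markers = np.where(valid[:, :, None], markers, np.nan)
    marker_rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    plates: list[ForcePlate] = []
    force_rate = marker_rate
    analogs = c3d["data"].get("analogs")
    if analogs is not None and analogs.size:
        force_rate = float(c3d["parameters"]["ANALOG"]["RATE"]["value"][0])
        chan = analogs[0].T  # (n_frames, n_channels)
        for p in range(chan.shape[1] // 6):
            block = chan[:, 6 * p : 6 * p + 6]
            plates.append(ForcePlate(force=block[:, :3].copy(), moment=block[:, 3:].copy()))
    return Trial(
        markers=markers,
        valid=valid,
        labels=labels,
        marker_rate=marker_rate,
        plates=plates,
        force_rate=force_rate,
        subject=Subject(id="unknown", mass=float("nan"), height=float("nan")),
    )
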