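"""Open on-disk interchange format for EIT recordings.

A *bundle* is a directory:

``meta.json``
    rows, cols, frame_rate, orientation, subject_id, recording_label,
    pressure sample_rate and alignment.
``frames.csv``
    One row per frame; rows*cols columns, row-major flattened pixels.
``pressure.csv``
    Columns ``time_s, pressure_cmH2O``.

Plain RFC-4180 CSV with "." decimal separator is the conformance
surface; values are written with 12 significant digits so a round trip
is lossless to well below 1e-9.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import ROW0_VENTRAL, FrameSequence, PressureTrace, ValidationError

_META_REQUIRED = ("rows", "cols", "frame_rate", "orientation", "sample_rate", "alignment")


def write_bundle(seq: FrameSequence, trace: PressureTrace, path: str | Path) -> Path:
    """Write a recording to ``path`` (created if needed). Returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows, cols = seq.shape
    meta = {
        "rows": rows,
        "cols": cols,
        "frame_rate": seq.frame_rate,
        "orientation": seq.orientation,
        "subject_id": seq.subject_id,
        "recording_label": seq.recording_label,
        "sample_rate": trace.sample_rate,
        "alignment": trace.alignment,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    np.savetxt(
        path / "frames.csv",
        seq.frames.reshape(seq.n_frames, rows * cols),
        fmt="%.12g",
        delimiter=",",
    )
    np.savetxt(
        path / "pressure.csv",
        np.column_stack([trace.times(), trace.samples]),
        fmt="%.12g",
        delimiter=",",
        header="time_s,pressure_cmH2O",
        comments="",
    )
    return path


def read_bundle(path: str | Path) -> tuple[FrameSequence, PressureTrace]:
    """Read a bundle directory back into its in-memory containers."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise ValidationError(f"not a bundle: missing {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"corrupt meta.json in {path}: {exc}") from exc
    for key in _META_REQUIRED:
        if key not in meta:
            raise ValidationError(f"meta.json is missing required field {key!r}")
    if meta["orientation"] != ROW0_VENTRAL:
        raise ValidationError(
            f"bundle orientation {meta['orientation']!r} is not {ROW0_VENTRAL!r}"
        )

    rows, cols = int(meta["rows"]), int(meta["cols"])
    frames_path = path / "frames.csv"
    if not frames_path.exists():
        raise ValidationError(f"missing frames.csv in {path}")
    flat = np.loadtxt(frames_path, delimiter=",", ndmin=2)
    if flat.shape[1] != rows * cols:
        raise ValidationError(
            f"frames.csv has {flat.shape[1]} pixels per frame, expected rows*cols = {rows * cols}"
        )
    seq = FrameSequence(
        frames=flat.reshape(-1, rows, cols),
        frame_rate=float(meta["frame_rate"]),
        orientation=meta["orientation"],
        subject_id=meta.get("subject_id", ""),
        recording_label=meta.get("recording_label", ""),
    )

    pressure_path = path / "pressure.csv"
    if not pressure_path.exists():
        raise ValidationError(f"missing pressure.csv in {path}")
    table = np.loadtxt(pressure_path, delimiter=",", skiprows=1, ndmin=2)
    if table.shape[1] != 2:
        raise ValidationError("pressure.csv must have exactly two columns")
    trace = PressureTrace(
        samples=table[:, 1],
        sample_rate=float(meta["sample_rate"]),
        alignment=int(meta["alignment"]),
    )
    return seq, trace
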