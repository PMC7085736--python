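"""File formats and core containers for depth-camera breathing recordings.

The canonical on-disk layout for a recording is deliberately minimal and
byte-auditable:

* ``<name>.bin``  — raw little-endian unsigned-16-bit depth frames (millimetres),
  row-major, frames concatenated in time order;
* ``<name>.json`` — sidecar ``{"rows": R, "cols": S, "n_frames": N}``;
* a timestamps CSV with columns ``frame_index,t_s``;
* an annotations CSV with columns ``start_s,end_s,type``;
* a signal CSV with columns ``t_s,value``.

All CSVs are comma-separated with a dot decimal point and a mandatory header
row.  Vendor SDK formats (.bag, Kinect Studio files) are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "APNEA_TYPES",
    "ApneaAnnotation",
    "AnnotationTrack",
    "DepthSequence",
    "write_depth_stack",
    "read_depth_stack",
    "write_annotations",
    "read_annotations",
    "write_signal_csv",
    "read_signal_csv",
]

#: Closed set of apnea event categories used by sleep specialists.
APNEA_TYPES = ("central", "obstructive", "mixed")


@dataclass(frozen=True)
class ApneaAnnotation:
    """One annotated apnea event: ``[start, end)`` in seconds from record start."""

    start: float
    end: float
    type: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"event start {self.start} must precede end {self.end}")
        if self.type not in APNEA_TYPES:
            raise ValueError(
                f"unknown apnea type {self.type!r}; allowed types: {', '.join(APNEA_TYPES)}"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class AnnotationTrack:
    """Ordered collection of apnea annotations for one recording."""

    events: list[ApneaAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.start, e.end))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[ApneaAnnotation]:
        return iter(self.events)

    def __getitem__(self, i: int) -> ApneaAnnotation:
        return self.events[i]


def _validate_roi(roi: Sequence[int], rows: int, cols: int) -> tuple[int, int, int, int]:
    r0, r1, c0, c1 = (int(v) for v in roi)
    if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
        raise ValueError(
            f"ROI {(r0, r1, c0, c1)} is empty or outside the {rows}x{cols} frame"
        )
    return r0, r1, c0, c1


@dataclass
class DepthSequence:
    """Ordered depth frames with per-frame timestamps and a chest ROI.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)``, unsigned 16-bit depth in mm.
    timestamps
        Strictly increasing acquisition times in seconds, one per frame.
    roi
        Half-open, 0-based rectangle ``(row_start, row_stop, col_start, col_stop)``
        covering the chest area.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    roi: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) array")
        if self.frames.dtype != np.uint16:
            self.frames = self.frames.astype(np.uint16)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.ndim != 1 or len(self.timestamps) != len(self.frames):
            raise ValueError(
                f"{len(self.timestamps)} timestamps for {len(self.frames)} frames"
            )
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        self.roi = _validate_roi(self.roi, self.frames.shape[1], self.frames.shape[2])

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def roi_view(self) -> np.ndarray:
        """View of shape ``(n_frames, R, S)`` restricted to the ROI."""
        r0, r1, c0, c1 = self.roi
        return self.frames[:, r0:r1, c0:c1]


# ---------------------------------------------------------------------------
# frame stacks


def write_depth_stack(
    seq: DepthSequence,
    stack_path: str | Path,
    sidecar_path: str | Path,
    timestamps_path: str | Path,
) -> None:
    """Write frames as raw little-endian uint16 plus JSON sidecar and timestamps CSV."""
    arr = np.ascontiguousarray(seq.frames.astype("<u2"))
    Path(stack_path).write_bytes(arr.tobytes())
    n, rows, cols = seq.frames.shape
    Path(sidecar_path).write_text(
        json.dumps({"rows": rows, "cols": cols, "n_frames": n}) + "\n"
    )
    pd.DataFrame(
        {"frame_index": np.arange(n), "t_s": seq.timestamps}
    ).to_csv(timestamps_path, index=False)


def read_depth_stack(
    stack_path: str | Path,
    sidecar_path: str | Path,
    timestamps_path: str | Path,
    roi: Sequence[int],
) -> DepthSequence:
    """Read a raw uint16 frame stack; validates size against the sidecar."""
    meta = json.loads(Path(sidecar_path).read_text())
    rows, cols, n = int(meta["rows"]), int(meta["cols"]), int(meta["n_frames"])
    raw = Path(stack_path).read_bytes()
    expected = rows * cols * n * 2
    if len(raw) != expected:
        raise ValueError(
            f"depth stack {stack_path}: expected {expected} bytes "
            f"({n} frames of {rows}x{cols} uint16), found {len(raw)}"
        )
    frames = np.frombuffer(raw, dtype="<u2").reshape(n, rows, cols).astype(np.uint16)
    ts = pd.read_csv(timestamps_path)
    if len(ts) != n:
        raise ValueError(f"{len(ts)} timestamps for {n} frames in {timestamps_path}")
    return DepthSequence(frames=frames, timestamps=ts["t_s"].to_numpy(float), roi=tuple(roi))


# ---------------------------------------------------------------------------
# annotations and signals


def write_annotations(track: AnnotationTrack, path: str | Path) -> None:
    pd.DataFrame(
        {
            "start_s": [e.start for e in track],
            "end_s": [e.end for e in track],
            "type": [e.type for e in track],
        }
    ).to_csv(path, index=False)


def read_annotations(path: str | Path) -> AnnotationTrack:
    """Read ``start_s,end_s,type`` rows; returns events sorted by start time."""
    df = pd.read_csv(path)
    for col in ("start_s", "end_s", "type"):
        if col not in df.columns:
            raise ValueError(f"annotations {path}: missing column {col!r}")
    events = [
        ApneaAnnotation(float(r.start_s), float(r.end_s), str(r.type))
        for r in df.itertuples()
    ]
    return AnnotationTrack(events)


def write_signal_csv(timestamps: np.ndarray, values: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"t_s": np.asarray(timestamps, float), "value": np.asarray(values, float)}).to_csv(
        path, index=False
    )


def read_signal_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a ``t_s,value`` motion-signal CSV; returns (timestamps, values)."""
    df = pd.read_csv(path)
    for col in ("t_s", "value"):
        if col not in df.columns:
            raise ValueError(f"signal CSV {path}: missing column {col!r}")
    t = df["t_s"].to_numpy(float)
    v = df["value"].to_numpy(float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError(f"signal CSV {path}: timestamps must be strictly increasing")
    return t, v
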