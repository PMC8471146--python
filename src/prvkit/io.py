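"""Readers and writers for the pipeline's plain-text interchange formats.

BVP traces travel as two-column CSV (``t_ms,value``); interval series as
``peak_time_ms,interval_ms``; reports as versioned JSON.  Video input is a
directory of numbered PNG/JPEG frames (read in lexicographic order).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import FormatError
from .ppi import NNISeries, PPISeries
from .signal import BVPSignal, FrameSequence

_FRAME_SUFFIXES = {".png", ".jpg", ".jpeg"}


def read_bvp_csv(path: str | Path) -> BVPSignal:
    """Read a ``t_ms,value`` CSV; the sampling rate is the median spacing.

    Rejects non-monotone or duplicated timestamps (naming the offending
    line) and gaps larger than twice the nominal spacing.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    if list(frame.columns[:2]) != ["t_ms", "value"]:
        raise FormatError(f"{path}: expected header 't_ms,value'")
    t = frame["t_ms"].to_numpy(dtype=float)
    v = frame["value"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        line = bad[0] + 3  # 1-based, after the header line
        raise FormatError(f"{path}: non-increasing t_ms at line {line}")
    nominal = float(np.median(dt))
    gaps = np.flatnonzero(dt > 2 * nominal)
    if gaps.size:
        raise FormatError(
            f"{path}: gap of {dt[gaps[0]]:.3f} ms at line {gaps[0] + 3} "
            f"(nominal spacing {nominal:.3f} ms)"
        )
    fs = 1000.0 / nominal
    if abs(fs - round(fs)) < 1e-6:
        fs = float(round(fs))
    return BVPSignal(v, fs=fs, t0=t[0] / 1000.0)


def write_bvp_csv(bvp: BVPSignal, path: str | Path) -> None:
    """Write a BVP trace as ``t_ms,value`` with full float precision."""
    frame = pd.DataFrame({"t_ms": bvp.times_ms, "value": bvp.samples})
    # %.17g guarantees bit-exact float round-trips through the CSV
    frame.to_csv(path, index=False, float_format="%.17g")


def write_interval_csv(
    ppi: PPISeries, nni: NNISeries | None, path: str | Path
) -> None:
    """Write beat times and intervals (raw and, if given, normalized)."""
    data = {
        "peak_time_ms": ppi.peak_times_ms[1:],
        "interval_ms": ppi.intervals_ms,
    }
    if nni is not None:
        data["nni_ms"] = nni.intervals_ms
        replaced = np.zeros(len(nni.intervals_ms), dtype=int)
        replaced[nni.replaced_indices] = 1
        data["replaced"] = replaced
    pd.DataFrame(data).to_csv(path, index=False)


def read_frames(path_or_dir: str | Path, fps: float | None = None) -> FrameSequence:
    """Load a frame directory (PNG/JPEG, lexicographic order) as a sequence.

    ``fps`` is required for directories (image files carry no timing).
    Video container files are not supported by this build; decode them to
    frames first.
    """
    path = Path(path_or_dir)
    if path.is_dir():
        if fps is None:
            raise FormatError("fps is required when reading a frame directory")
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
        )
        if not files:
            raise FormatError(f"{path}: no PNG/JPEG frames found")
        frames = [np.asarray(Image.open(p).convert("RGB")) for p in files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise FormatError(f"{path}: mixed frame sizes {sorted(shapes)}")
        return FrameSequence(np.stack(frames), fps=fps)
    raise FormatError(
        f"{path}: video container input is not supported; provide a directory "
        "of numbered PNG/JPEG frames and --fps"
    )


def write_frames(frames: FrameSequence, out_dir: str | Path) -> None:
    """Write a frame sequence as numbered PNGs (frame_000001.png, ...)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i in range(len(frames)):
        Image.fromarray(frames.frames[i]).save(out / f"frame_{i + 1:06d}.png")


def write_json(payload: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
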