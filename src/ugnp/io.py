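"""CSV/PNG plumbing with provenance headers.

Every table the pipeline writes starts with ``# key: value`` comment lines
(package version, config hash, seed, column-bearing metadata such as the
constant [OH-] of a trace) followed by a fixed CSV header.  Frame series
are a directory of PNGs plus a ``manifest.csv`` with timestamps.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from ugnp.colorimetry import FrameSeries, ProgressCurve
from ugnp.kinetics import KineticTrace

TRACE_COLUMNS = [
    "t_s",
    "c_precursor_M",
    "c_passivated_M",
    "c_reduced_M",
    "c_ta_M",
    "c_cit_reactive_M",
]
CURVE_COLUMNS = ["t_s", "red_fraction", "normalized_progress"]


def _write_with_header(df: pd.DataFrame, path: str | Path, meta: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_metadata(path: str | Path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    return meta


def write_trace(trace: KineticTrace, path: str | Path, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        {
            "t_s": trace.t,
            "c_precursor_M": trace.c_precursor,
            "c_passivated_M": trace.c_passivated,
            "c_reduced_M": trace.c_reduced,
            "c_ta_M": trace.c_ta,
            "c_cit_reactive_M": trace.c_cit_reactive,
        }
    )
    full_meta = {"c_oh_M": repr(float(trace.c_oh)), "provenance": trace.provenance}
    full_meta.update(meta or {})
    _write_with_header(df, path, full_meta)


def read_trace(path: str | Path) -> KineticTrace:
    meta = read_metadata(path)
    df = pd.read_csv(path, comment="#")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace file {path} missing columns {sorted(missing)}")
    return KineticTrace(
        t=df["t_s"].to_numpy(),
        c_precursor=df["c_precursor_M"].to_numpy(),
        c_passivated=df["c_passivated_M"].to_numpy(),
        c_reduced=df["c_reduced_M"].to_numpy(),
        c_ta=df["c_ta_M"].to_numpy(),
        c_cit_reactive=df["c_cit_reactive_M"].to_numpy(),
        c_oh=float(meta.get("c_oh_M", "0") or 0),
        provenance=meta.get("provenance", "unknown"),
    )


def write_progress_curve(
    curve: ProgressCurve, path: str | Path, meta: dict | None = None
) -> None:
    df = pd.DataFrame(
        {
            "t_s": curve.t,
            "red_fraction": curve.red_fraction,
            "normalized_progress": curve.normalized_progress,
        }
    )
    _write_with_header(df, path, meta or {})


def read_progress_curve(path: str | Path) -> ProgressCurve:
    df = pd.read_csv(path, comment="#")
    return ProgressCurve(
        t=df["t_s"].to_numpy(),
        red_fraction=df["red_fraction"].to_numpy(),
        normalized_progress=df["normalized_progress"].to_numpy(),
    )


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Generic provenance-headed CSV writer for report tables."""
    _write_with_header(df, path, meta or {})


def write_frames(series: FrameSeries, directory: str | Path) -> None:
    """Write a frame series as numbered PNGs plus a timestamp manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, frame in enumerate(series.frames):
        name = f"frame_{i:05d}.png"
        Image.fromarray(np.asarray(frame, dtype=np.uint8)).save(directory / name)
        names.append(name)
    pd.DataFrame({"filename": names, "t_s": series.timestamps}).to_csv(
        directory / "manifest.csv", index=False
    )


def read_frames(directory: str | Path) -> FrameSeries:
    """Read a frame directory written by :func:`write_frames` (or equivalent)."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    frames = np.stack(
        [np.asarray(Image.open(directory / name).convert("RGB")) for name in manifest["filename"]]
    )
    return FrameSeries(timestamps=manifest["t_s"].to_numpy(), frames=frames)
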