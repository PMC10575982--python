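"""File formats: flat key/value configs, TSV traces, AFM images, point sets.

All tabular data travels as TSV with a header row.  Force-extension traces
use columns ``time_s, force_pN, extension_nm, direction``; force-jump traces
use ``time_s, force_pN, extension_nm``.  AFM images are 32-bit float TIFF or
whitespace-delimited text matrices in nm.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError


# ---------------------------------------------------------------- flat config

def write_config(path, values: dict, comments: dict | None = None) -> None:
    """Write a flat ``name = value`` config file (one entry per line).

    ``comments`` maps names to unit/comment strings appended after ``#``.
    """
    comments = comments or {}
    lines = []
    for name, value in values.items():
        line = f"{name} = {value!r}" if isinstance(value, str) else f"{name} = {value}"
        if name in comments:
            line += f"  # {comments[name]}"
        lines.append(line)
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path) -> dict:
    """Read a flat ``name = value`` config file; values parsed as int, float
    or (quoted or bare) string."""
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{path}:{lineno}: expected 'name = value', got {raw!r}")
        name, _, sval = line.partition("=")
        name, sval = name.strip(), sval.strip()
        if not name:
            raise ParseError(f"{path}:{lineno}: empty name")
        if sval.startswith(("'", '"')) and sval.endswith(sval[0]) and len(sval) >= 2:
            values[name] = sval[1:-1]
            continue
        try:
            values[name] = int(sval)
        except ValueError:
            try:
                values[name] = float(sval)
            except ValueError:
                values[name] = sval
    return values


# ----------------------------------------------------------------- TSV traces

def write_force_extension_tsv(path, traces) -> None:
    """Write one or more ForceExtensionTrace objects as a single TSV."""
    frames = []
    for tr in np.atleast_1d(np.asarray(traces, dtype=object)):
        t = tr.time_s if tr.time_s is not None else np.full(len(tr.force_pN), np.nan)
        frames.append(pd.DataFrame({
            "time_s": t,
            "force_pN": tr.force_pN,
            "extension_nm": tr.extension_nm,
            "direction": tr.direction,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_force_extension_tsv(path):
    """Read force-extension traces from TSV; returns list of ForceExtensionTrace
    (one per distinct ``direction`` value, in file order)."""
    from .ramp import ForceExtensionTrace

    df = pd.read_csv(path, sep="\t")
    required = {"force_pN", "extension_nm", "direction"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    traces = []
    for direction in df["direction"].unique():
        sub = df[df["direction"] == direction]
        time = sub["time_s"].to_numpy() if "time_s" in sub else None
        if time is not None and np.all(np.isnan(time)):
            time = None
        traces.append(ForceExtensionTrace(
            force_pN=sub["force_pN"].to_numpy(),
            extension_nm=sub["extension_nm"].to_numpy(),
            direction=str(direction),
            time_s=time,
        ))
    return traces


def write_force_jump_tsv(path, trace) -> None:
    pd.DataFrame({
        "time_s": trace.time_s,
        "force_pN": trace.force_pN,
        "extension_nm": trace.extension_nm,
    }).to_csv(path, sep="\t", index=False)


def read_force_jump_tsv(path):
    from .jump import ForceJumpTrace

    df = pd.read_csv(path, sep="\t")
    required = {"time_s", "force_pN", "extension_nm"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return ForceJumpTrace(
        time_s=df["time_s"].to_numpy(),
        force_pN=df["force_pN"].to_numpy(),
        extension_nm=df["extension_nm"].to_numpy(),
    )


# ----------------------------------------------------------------- AFM images

def read_afm_image(path, pixel_size_nm: float | None = None):
    """Read an AFM height map from float TIFF or whitespace text matrix (nm).

    ``pixel_size_nm`` must be given for text matrices; for TIFF it may come
    from the file's resolution tags if present, else it is required.
    """
    from .afm import AFMImage

    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        heights = np.asarray(tifffile.imread(path), dtype=float)
    else:
        try:
            heights = np.loadtxt(path, dtype=float)
        except ValueError as exc:
            raise ParseError(f"{path}: not a numeric matrix: {exc}") from exc
    if pixel_size_nm is None:
        raise ParseError("pixel_size_nm is required")
    return AFMImage(heights=heights, pixel_size_nm=pixel_size_nm)


def write_afm_image(path, img) -> None:
    """Write an AFM height map; TIFF (float32) by extension, else text matrix."""
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, img.heights.astype(np.float32))
    else:
        np.savetxt(path, img.heights, fmt="%.6g")


# ----------------------------------------------------------------- point sets

def write_points_tsv(path, points) -> None:
    pd.DataFrame(np.asarray(points, dtype=float), columns=["x_nm", "y_nm", "z_nm"]).to_csv(
        path, sep="\t", index=False
    )


def read_points_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    cols = ["x_nm", "y_nm", "z_nm"]
    if not set(cols).issubset(df.columns):
        raise ParseError(f"{path}: expected columns {cols}")
    return df[cols].to_numpy(dtype=float)


def read_index_pairs_tsv(path) -> list[tuple[int, int]]:
    """Guide-point index pairs: TSV with columns ``i`` and ``j`` (0-based)."""
    df = pd.read_csv(path, sep="\t")
    if not {"i", "j"}.issubset(df.columns):
        raise ParseError(f"{path}: expected columns i, j")
    return [(int(a), int(b)) for a, b in zip(df["i"], df["j"])]
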