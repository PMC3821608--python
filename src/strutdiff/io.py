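"""Reading and writing FRAP traces and derived tables.

CSV trace format: a header row plus either ``time_s,intensity`` (raw
trace) or ``time_s,f`` (already-normalized fractional fluorescence).
TIFF time-stacks are reduced to a raw trace as the mean intensity within
a circular region of interest.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .errors import MalformedInputError
from .frap import RecoveryCurve


def read_trace_csv(path) -> tuple[np.ndarray, np.ndarray, str]:
    """Read a trace CSV; returns (times, values, kind).

    ``kind`` is "intensity" for a raw trace or "f" for a normalized one,
    inferred from the header.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "time_s" not in cols:
        raise MalformedInputError(f"{path}: missing required column 'time_s'")
    for kind in ("intensity", "f"):
        if kind in cols:
            return (
                df[cols["time_s"]].to_numpy(dtype=float),
                df[cols[kind]].to_numpy(dtype=float),
                kind,
            )
    raise MalformedInputError(f"{path}: need a column 'intensity' (raw) or 'f' (normalized)")


def write_curve_csv(path, curve: RecoveryCurve) -> None:
    """Write a normalized curve as ``time_s,f``."""
    pd.DataFrame({"time_s": curve.times, "f": curve.f}).to_csv(path, index=False)


def roi_mean_trace(
    tiff_path,
    center_px: tuple[float, float],
    radius_px: float,
    frame_interval_s: float,
    um_per_px: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray, Optional[float]]:
    """Mean intensity within a circular ROI of a TIFF time-stack.

    Returns (times, intensities, omega_um); ``omega_um`` is the ROI
    radius in micrometers when a pixel scale is given, else None.
    Frames are assumed evenly spaced at ``frame_interval_s``.
    """
    import tifffile

    stack = np.asarray(tifffile.imread(tiff_path), dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise MalformedInputError(
            f"{tiff_path}: expected a (frames, y, x) time-stack, got shape {stack.shape}"
        )
    n, ny, nx = stack.shape
    cy, cx = center_px
    yy, xx = np.mgrid[0:ny, 0:nx]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2
    if not mask.any():
        raise MalformedInputError("circular ROI contains no pixels")
    times = np.arange(n) * frame_interval_s
    intensities = stack[:, mask].mean(axis=1)
    omega = radius_px * um_per_px if um_per_px else None
    return times, intensities, omega
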