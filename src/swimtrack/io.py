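"""Reading and writing the pipeline's file formats.

Midline tables use one row per (frame, point): columns ``frame``,
``point_index``, ``x``, ``y`` (pixel or BL units), optionally prefixed by
trial metadata columns (``individual_id``, ``treatment``,
``regeneration_pct``, ``trial``) when several trials share one file.
Frame stacks are multi-page TIFF or numbered PNG directories.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import MidlineSequence
from .errors import ValidationError

__all__ = [
    "write_midlines_csv",
    "read_midlines_csv",
    "write_frames",
    "read_frames",
]

_FLOAT_FMT = "%.6f"


def write_midlines_csv(seq: MidlineSequence, path, meta: dict | None = None) -> None:
    """Write a midline sequence to CSV (one row per frame and point)."""
    n_f, n_p = seq.n_frames, seq.n_points
    df = pd.DataFrame({
        "frame": np.repeat(np.arange(n_f), n_p),
        "point_index": np.tile(np.arange(n_p), n_f),
        "x": seq.xy[..., 0].ravel(),
        "y": seq.xy[..., 1].ravel(),
    })
    for k, v in reversed(list((meta or {}).items())):
        df.insert(0, k, v)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_midlines_csv(
    path,
    frame_rate_hz: float,
    pixels_per_bl: float | None = None,
    y_down: bool = True,
    length_tol: float = 0.05,
) -> MidlineSequence:
    """Read one trial's midline CSV back into a MidlineSequence.

    The frame rate is not stored in the CSV and must be supplied.  Set
    ``y_down=False`` for data recorded in a right-handed (y-up) frame.
    """
    df = pd.read_csv(path)
    for col in ("frame", "point_index", "x", "y"):
        if col not in df.columns:
            raise ValidationError(f"midline CSV is missing column {col!r}")
    frames = np.sort(df["frame"].unique())
    n_p = df["point_index"].nunique()
    if len(df) != len(frames) * n_p:
        raise ValidationError("midline CSV is not a complete frame x point grid")
    df = df.sort_values(["frame", "point_index"])
    xy = df[["x", "y"]].to_numpy(float).reshape(len(frames), n_p, 2)
    return MidlineSequence(
        xy, frame_rate_hz, pixels_per_bl=pixels_per_bl, y_down=y_down,
        length_tol=length_tol,
    )


def write_frames(frames: np.ndarray, path) -> None:
    """Write a frame stack as multi-page TIFF (.tif) or numbered PNGs (dir)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(frames, dtype=np.uint8))
        return
    path.mkdir(parents=True, exist_ok=True)
    for j, frame in enumerate(frames):
        iio.imwrite(path / f"frame_{j:05d}.png", np.asarray(frame, dtype=np.uint8))


def read_frames(path) -> np.ndarray:
    """Read a stack written by :func:`write_frames`."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("frame_*.png"))
        if not files:
            raise ValidationError(f"no frame_*.png files in {path}")
        return np.stack([iio.imread(f) for f in files])
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        return arr[None] if arr.ndim == 2 else arr
    raise ValidationError(f"unsupported frame-stack path: {path}")
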