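"""Calibrated video I/O and tabular serialization.

Conventions fixed here and used package-wide:

* Pixel arrays are indexed ``(row y, col x, frame t)`` with dimensions
  ``D1 (rows) x D2 (cols) x T (frames)``; ``x`` is the column index and
  ``y`` the row index, both 0-based.
* Frame indices are 0-based internally; CSV outputs report 1-based frame
  numbers so that a video spans frames ``1..T`` as in standard time-lapse
  bookkeeping.
* Intensities are converted to ``float64`` at read time; no per-frame
  rescaling is applied (background normalization happens downstream, per
  ROI, in the kinetics module).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

from .errors import FormatError, ValidationError

CHANNELS = ("red", "green", "transmission")

EVENT_COLUMNS = ["track_id", "x", "y", "radius", "death_frame"]


@dataclass
class Calibration:
    """Spatial and temporal scaling of a video.

    Parameters
    ----------
    pixel_size_um:
        Side of one pixel in micrometers (> 0).
    frame_interval_h:
        Time between consecutive frames in hours (> 0). Defaults to 1 h,
        the acquisition cadence the whole analysis is designed around.
    """

    pixel_size_um: float
    frame_interval_h: float = 1.0

    def __post_init__(self) -> None:
        if not (self.pixel_size_um > 0 and self.frame_interval_h > 0):
            raise ValidationError(
                "pixel_size_um and frame_interval_h must be strictly positive"
            )

    def um_to_px(self, um: float) -> float:
        return um / self.pixel_size_um

    def px_to_um(self, px: float) -> float:
        return px * self.pixel_size_um

    def hours_to_frames(self, hours: float) -> int:
        """Convert a duration in hours to a whole number of frames (rounded)."""
        return int(round(hours / self.frame_interval_h))

    def frames_to_hours(self, frames: float) -> float:
        return frames * self.frame_interval_h


@dataclass
class FrameStack:
    """A calibrated single-channel image sequence, indexed (y, x, t)."""

    pixels: np.ndarray
    channel: str = "red"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3:
            raise ValidationError(f"pixels must be 3-D (D1, D2, T); got {px.ndim}-D")
        if min(px.shape) < 1:
            raise ValidationError("all stack dimensions must be >= 1")
        if not np.all(np.isfinite(px)):
            raise ValidationError("intensities must be finite")
        if px.min() < 0:
            raise ValidationError("intensities must be non-negative")
        if self.channel not in CHANNELS:
            raise ValidationError(f"channel must be one of {CHANNELS}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape  # (D1, D2, T)

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[2]

    def frame(self, t: int) -> np.ndarray:
        """Return frame ``t`` (0-based) as a (D1, D2) view."""
        return self.pixels[:, :, t]


def _read_sequence_dir(path: Path) -> np.ndarray:
    files = sorted(
        p for p in path.iterdir()
        if p.suffix.lower() in {".png", ".tif", ".tiff"}
    )
    if not files:
        raise FormatError(f"no image files found in {path}")
    frames = []
    for f in files:
        try:
            frames.append(np.asarray(iio.imread(f)))
        except Exception as exc:  # pragma: no cover - backend specific
            raise FormatError(f"unreadable frame {f}: {exc}") from exc
    shapes = {fr.shape for fr in frames}
    if len(shapes) != 1:
        raise FormatError(f"mixed frame dimensions in {path}: {sorted(shapes)}")
    return np.stack(frames, axis=-1)


def read_stack(path: str | os.PathLike, channel: str = "red") -> FrameStack:
    """Read a multipage TIFF or an ordered image-sequence directory.

    Frames are ordered by page order (TIFF) or lexical file name order
    (directory). All frames must share the same dimensions.
    """
    path = Path(path)
    if path.is_dir():
        pixels = _read_sequence_dir(path)
    else:
        if not path.exists():
            raise FormatError(f"no such file: {path}")
        try:
            arr = tifffile.imread(path)
        except Exception as exc:
            raise FormatError(f"unreadable TIFF {path}: {exc}") from exc
        arr = np.asarray(arr)
        if arr.dtype == object:
            raise FormatError(f"mixed frame dimensions in {path}")
        if arr.ndim == 2:  # single frame
            arr = arr[None]
        if arr.ndim != 3:
            raise FormatError(f"expected a 2-D or 3-D TIFF, got shape {arr.shape}")
        pixels = np.moveaxis(arr, 0, -1)  # (T, D1, D2) -> (D1, D2, T)
    return FrameStack(pixels=pixels, channel=channel)


def write_stack(stack: FrameStack, path: str | os.PathLike) -> None:
    """Write a FrameStack as a multipage TIFF (one page per frame)."""
    arr = np.moveaxis(stack.pixels, -1, 0)
    tifffile.imwrite(os.fspath(path), arr, photometric="minisblack")


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

def validate_event_table(
    table: pd.DataFrame,
    dims: tuple[int, int] | None = None,
    n_frames: int | None = None,
) -> pd.DataFrame:
    """Validate an event table; ``death_frame`` is 1-based, NaN = no death.

    ``dims`` is (D1, D2) = (rows, cols); x is checked against D2, y against D1.
    """
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"event table missing columns: {missing}")
    t = table[EVENT_COLUMNS].copy()
    if len(t):
        if (t["x"] < 0).any() or (t["y"] < 0).any():
            raise ValidationError("event coordinates must be non-negative")
        if (t["radius"] <= 0).any():
            raise ValidationError("event radii must be positive")
        if dims is not None:
            d1, d2 = dims
            if (t["x"] >= d2).any() or (t["y"] >= d1).any():
                raise ValidationError("event coordinates outside frame bounds")
        df = t["death_frame"].dropna()
        if (df < 1).any():
            raise ValidationError("death_frame is 1-based; values must be >= 1")
        if n_frames is not None and (df > n_frames).any():
            raise ValidationError(f"death_frame exceeds video length T={n_frames}")
    return t


def write_event_table(
    table: pd.DataFrame,
    path: str | os.PathLike,
    dims: tuple[int, int] | None = None,
    n_frames: int | None = None,
) -> None:
    """Write a validated event table to CSV (lossless round trip)."""
    validate_event_table(table, dims=dims, n_frames=n_frames).to_csv(
        path, index=False
    )


def read_event_table(
    path: str | os.PathLike,
    dims: tuple[int, int] | None = None,
    n_frames: int | None = None,
) -> pd.DataFrame:
    """Read and validate an event table CSV."""
    table = pd.read_csv(path)
    return validate_event_table(table, dims=dims, n_frames=n_frames)


def events_to_table(events: Iterable) -> pd.DataFrame:
    """Serialize DeathEvent-like records to an event table (1-based frames)."""
    rows = []
    for e in events:
        frame = getattr(e, "death_frame", None)
        rows.append(
            dict(
                track_id=getattr(e, "track_id", -1),
                x=e.x,
                y=e.y,
                radius=e.radius,
                death_frame=np.nan if frame is None else frame + 1,
            )
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)
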