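"""Cell localization and tracking in the red channel.

Pre-stained cancer cells are detected per frame by Otsu binarization
followed by a Circular Hough Transform over an imposed radius range, and
linked across frames by solving the optimal assignment problem on squared
displacement with distance gating. Short detection dropouts are bridged by
linear interpolation so each track covers a contiguous frame interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage.filters import threshold_otsu
from skimage.morphology import disk, erosion
from skimage.transform import hough_circle, hough_circle_peaks

from .errors import ConfigError, DegenerateInputError

_BIG = 1e12  # sentinel cost for gated-out pairs


@dataclass
class Detection:
    """One circular cell detection: center (x=col, y=row), radius, frame (0-based)."""

    x: float
    y: float
    radius: float
    frame: int
    score: float = 0.0


@dataclass
class CellTrack:
    """One cell's per-frame position and radius over a contiguous frame set F."""

    track_id: int
    frames: np.ndarray  # contiguous 0-based frame indices
    x: np.ndarray
    y: np.ndarray
    radius: np.ndarray

    @property
    def t_start(self) -> int:
        return int(self.frames[0])

    @property
    def t_end(self) -> int:
        return int(self.frames[-1])

    def __len__(self) -> int:
        return len(self.frames)

    def index_of(self, frame: int) -> int | None:
        """Index into the per-frame arrays for video frame ``frame``, or None."""
        if self.t_start <= frame <= self.t_end:
            return frame - self.t_start
        return None

    def at(self, frame: int) -> tuple[float, float, float]:
        i = self.index_of(frame)
        if i is None:
            raise IndexError(f"frame {frame} outside track F=[{self.t_start},{self.t_end}]")
        return float(self.x[i]), float(self.y[i]), float(self.radius[i])


@dataclass
class TrackingConfig:
    """Detector and linker settings.

    The imposed radius range bounds the Hough search; the gating distance
    caps per-frame displacement (cells drift slowly at 1 h/frame, so the
    default is 3x the maximum radius); ``max_gap`` is the longest detection
    dropout bridged by interpolation before a track is terminated.
    """

    radius_min_px: int = 4
    radius_max_px: int = 9
    gating_px: float | None = None  # default: 3 * radius_max_px
    max_gap_frames: int = 2
    accumulator_threshold: float = 0.4  # min fraction of circle perimeter found

    def __post_init__(self) -> None:
        if self.radius_min_px > self.radius_max_px:
            raise ConfigError("radius_min_px must be <= radius_max_px")
        if self.radius_min_px < 1:
            raise ConfigError("radius_min_px must be >= 1")
        if self.gating_px is None:
            self.gating_px = 3.0 * self.radius_max_px
        if self.gating_px <= 0:
            raise ConfigError("gating_px must be > 0")
        if self.max_gap_frames < 0:
            raise ConfigError("max_gap_frames must be >= 0")


def binarize_red(frame: np.ndarray) -> np.ndarray:
    """Otsu-binarize one red-channel frame: mask = intensity > threshold.

    The threshold maximizes between-class variance of the intensity
    histogram. A constant frame admits no threshold.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.min() == frame.max():
        raise DegenerateInputError("constant frame: Otsu threshold undefined")
    th = threshold_otsu(frame)
    return frame > th


def detect_cells(
    mask_or_frame: np.ndarray,
    cfg: TrackingConfig,
    frame: int = 0,
) -> list[Detection]:
    """Detect circular cells in one binarized frame via the Hough transform.

    A grayscale frame is Otsu-binarized first. Accumulator peaks are kept
    above ``cfg.accumulator_threshold`` (fraction of the circle perimeter
    supported by mask-boundary pixels) and greedily non-maximum-suppressed
    so no two detections are closer than the minimum radius.
    """
    arr = np.asarray(mask_or_frame)
    if arr.dtype != bool:
        if arr.min() == arr.max():
            return []
        arr = binarize_red(arr)
    if not arr.any():
        return []
    # circle perimeters live on the mask boundary
    edges = arr & ~erosion(arr, footprint=disk(1))
    radii = np.arange(cfg.radius_min_px, cfg.radius_max_px + 1)
    hspaces = hough_circle(edges, radii, normalize=True)
    accums, cx, cy, rad = hough_circle_peaks(
        hspaces,
        radii,
        min_xdistance=cfg.radius_min_px,
        min_ydistance=cfg.radius_min_px,
        threshold=cfg.accumulator_threshold,
    )
    # greedy NMS across radii: strongest peak wins, suppress within r_min
    order = np.argsort(accums)[::-1]
    kept: list[Detection] = []
    min_sep2 = float(cfg.radius_min_px) ** 2
    for i in order:
        x, y = float(cx[i]), float(cy[i])
        if any((x - d.x) ** 2 + (y - d.y) ** 2 < min_sep2 for d in kept):
            continue
        kept.append(Detection(x=x, y=y, radius=float(rad[i]), frame=frame,
                              score=float(accums[i])))
    return kept


def detect_stack(stack, cfg: TrackingConfig) -> list[list[Detection]]:
    """Run Otsu + Hough detection on every frame of a red-channel stack."""
    out = []
    for t in range(stack.n_frames):
        fr = stack.frame(t)
        if fr.min() == fr.max():
            out.append([])
            continue
        out.append(detect_cells(binarize_red(fr), cfg, frame=t))
    return out


class _OpenTrack:
    __slots__ = ("frames", "x", "y", "r", "last_frame")

    def __init__(self, det: Detection):
        self.frames = [det.frame]
        self.x = [det.x]
        self.y = [det.y]
        self.r = [det.radius]
        self.last_frame = det.frame

    def extend(self, det: Detection) -> None:
        gap = det.frame - self.last_frame
        if gap > 1:  # bridge dropout by linear interpolation
            x0, y0, r0 = self.x[-1], self.y[-1], self.r[-1]
            for k in range(1, gap):
                w = k / gap
                self.frames.append(self.last_frame + k)
                self.x.append(x0 * (1 - w) + det.x * w)
                self.y.append(y0 * (1 - w) + det.y * w)
                self.r.append(r0 * (1 - w) + det.radius * w)
        self.frames.append(det.frame)
        self.x.append(det.x)
        self.y.append(det.y)
        self.r.append(det.radius)
        self.last_frame = det.frame


def assign_frame(
    prev_xy: np.ndarray, next_xy: np.ndarray, gating_px: float
) -> list[tuple[int, int]]:
    """Optimal assignment between two point sets under squared-distance cost.

    Returns matched (prev_index, next_index) pairs; pairs farther apart than
    the gating distance are never matched. Minimizes total squared
    displacement over admissible pairs (Hungarian algorithm).
    """
    if len(prev_xy) == 0 or len(next_xy) == 0:
        return []
    d2 = ((prev_xy[:, None, :] - next_xy[None, :, :]) ** 2).sum(-1)
    cost = np.where(d2 <= gating_px**2, d2, _BIG)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if cost[i, j] < _BIG]


def link_tracks(
    detections_per_frame: list[list[Detection]], cfg: TrackingConfig
) -> list[CellTrack]:
    """Link per-frame detections into tracks.

    Frame-to-frame matching minimizes total squared displacement among
    pairs within the gating distance; unmatched detections start new
    tracks; tracks unmatched for more than ``max_gap_frames`` terminate.
    """
    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []
    for t, dets in enumerate(detections_per_frame):
        # retire tracks whose dropout exceeded the allowed gap
        still_open = []
        for tr in open_tracks:
            if t - tr.last_frame > cfg.max_gap_frames + 1:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        prev_xy = np.array([[tr.x[-1], tr.y[-1]] for tr in open_tracks], dtype=float)
        next_xy = np.array([[d.x, d.y] for d in dets], dtype=float)
        if prev_xy.size == 0:
            prev_xy = prev_xy.reshape(0, 2)
        if next_xy.size == 0:
            next_xy = next_xy.reshape(0, 2)
        matches = assign_frame(prev_xy, next_xy, cfg.gating_px)
        matched_prev = {i for i, _ in matches}
        matched_next = {j for _, j in matches}
        for i, j in matches:
            open_tracks[i].extend(dets[j])
        for j, d in enumerate(dets):
            if j not in matched_next:
                open_tracks.append(_OpenTrack(d))
        # tracks not matched this frame stay open until the gap runs out
        _ = matched_prev
    closed.extend(open_tracks)

    tracks = []
    for tid, tr in enumerate(closed):
        tracks.append(
            CellTrack(
                track_id=tid,
                frames=np.asarray(tr.frames, dtype=int),
                x=np.asarray(tr.x, dtype=float),
                y=np.asarray(tr.y, dtype=float),
                radius=np.asarray(tr.r, dtype=float),
            )
        )
    tracks.sort(key=lambda tr: (tr.t_start, tr.track_id))
    for tid, tr in enumerate(tracks):
        tr.track_id = tid
    return tracks


def tracks_to_table(tracks: list[CellTrack]):
    """Long-format track table (track_id, frame [1-based], x, y, radius)."""
    import pandas as pd

    rows = []
    for tr in tracks:
        for i, f in enumerate(tr.frames):
            rows.append(
                dict(track_id=tr.track_id, frame=int(f) + 1,
                     x=tr.x[i], y=tr.y[i], radius=tr.radius[i])
            )
    return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "radius"])
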