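"""Caspase-reporter signal extraction and apoptosis kinetics.

For every tracked cell a square ROI is cut from the green channel at each
frame; the mean green intensity over the detected cell disk (foreground)
is background-corrected against the surrounding annulus and min-normalized
over the track's lifetime, yielding the per-track signal mu(t):

    mu(t) = (mu_fg(t) - mu_bg(t)) / mu_bg(t)
            - min over the track of the same ratio

so that min over the track of mu is exactly 0. A single threshold ``th``
is estimated over the pooled samples of all tracks of one video by exact
between-class-variance (Otsu) maximization; a cell is called apoptotic at
the first frame where mu exceeds th.

From the calls, two population curves are derived:

* apoptosis rate  O(t) = 100 * N_ap(t) / N_avg(t), with N_ap the event
  count in the trailing window of T_LAG frames and N_avg the mean number
  of living tracks over that window;
* overall survival  OS(t) = 100 * N_avg2(t) / N_avg2(start), where N_avg2
  is the 3-frame centered moving average of the living-track count and the
  reference is that average over the first three frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError, ValidationError
from .tracking import CellTrack
from .video_io import Calibration, FrameStack


@dataclass
class RoiGeometry:
    """Square ROI side, plus the background-neighborhood radius.

    The foreground disk uses each track's own detected radius; the
    background is the annulus between that disk and a circle of radius
    ``bg_radius_px`` (conventionally twice the experiment-average cell
    radius), clipped to the ROI.
    """

    roi_side_px: int = 31
    bg_radius_px: float = 12.0
    epsilon_bg: float = 1e-6  # relative floor on mu_bg (fraction of channel max)

    def __post_init__(self) -> None:
        if self.roi_side_px % 2 != 1:
            raise ConfigError("roi_side_px must be odd so the ROI is centerable")
        if self.bg_radius_px > self.roi_side_px / 2:
            raise ConfigError("bg_radius_px must fit inside the ROI")


@dataclass
class GreenTrace:
    """Normalized caspase signal for one track over its frame set F."""

    track_id: int
    frames: np.ndarray
    mu_fg: np.ndarray
    mu_bg: np.ndarray
    mu: np.ndarray

    def mu_at(self, frame: int) -> float | None:
        if self.frames[0] <= frame <= self.frames[-1]:
            return float(self.mu[frame - int(self.frames[0])])
        return None


@dataclass
class DeathEvent:
    """One called apoptosis: first threshold crossing of a track's mu."""

    track_id: int
    death_frame: int  # 0-based internal
    x: float
    y: float
    radius: float


def extract_green_trace(
    track: CellTrack, green: FrameStack, geom: RoiGeometry
) -> GreenTrace:
    """Extract mu_fg, mu_bg and the min-normalized mu for one track.

    ROIs partially outside the frame are averaged over in-frame pixels
    only. Frames whose background mean falls below the epsilon floor are
    interpolated from neighboring frames rather than divided through.
    """
    d1, d2, n_frames = green.shape
    if track.t_end >= n_frames:
        raise ValidationError("track extends past the green stack")
    half = geom.roi_side_px // 2
    chan_max = float(green.pixels.max())
    floor = geom.epsilon_bg * max(chan_max, 1.0)

    mu_fg = np.empty(len(track))
    mu_bg = np.empty(len(track))
    ok = np.ones(len(track), dtype=bool)
    for i, t in enumerate(track.frames):
        cx, cy = int(round(track.x[i])), int(round(track.y[i]))
        r_fg = track.radius[i]
        y0, y1 = max(cy - half, 0), min(cy + half + 1, d1)
        x0, x1 = max(cx - half, 0), min(cx + half + 1, d2)
        roi = green.pixels[y0:y1, x0:x1, t]
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist2 = (yy - cy) ** 2 + (xx - cx) ** 2
        fg = dist2 <= r_fg**2
        bg = (dist2 > r_fg**2) & (dist2 <= geom.bg_radius_px**2)
        mu_fg[i] = roi[fg].mean() if fg.any() else np.nan
        mu_bg[i] = roi[bg].mean() if bg.any() else np.nan
        if not fg.any() or not bg.any() or mu_bg[i] < floor:
            ok[i] = False

    ratio = np.full(len(track), np.nan)
    ratio[ok] = (mu_fg[ok] - mu_bg[ok]) / mu_bg[ok]
    if not ok.any():
        raise DegenerateInputError(
            f"track {track.track_id}: no frame has a usable background"
        )
    if not ok.all():  # interpolate flagged frames from valid neighbors
        idx = np.arange(len(track))
        ratio[~ok] = np.interp(idx[~ok], idx[ok], ratio[ok])
        mu_fg[~ok] = np.interp(idx[~ok], idx[ok], mu_fg[ok])
        mu_bg[~ok] = np.interp(idx[~ok], idx[ok], mu_bg[ok])
    mu = ratio - ratio.min()
    return GreenTrace(
        track_id=track.track_id,
        frames=track.frames.copy(),
        mu_fg=mu_fg,
        mu_bg=mu_bg,
        mu=mu,
    )


def otsu_exact(values: np.ndarray) -> float:
    """Exact Otsu threshold of a 1-D sample: the midpoint between
    consecutive sorted values that maximizes between-class variance.

    Works on the raw multiset (no histogram binning), so it agrees with an
    exhaustive search over all candidate split points.
    """
    x = np.sort(np.asarray(values, dtype=np.float64).ravel())
    n = x.size
    if n < 2 or x[0] == x[-1]:
        raise DegenerateInputError("need >= 2 distinct values for a threshold")
    csum = np.cumsum(x)
    total = csum[-1]
    k = np.arange(1, n)  # class 0 = x[:k], class 1 = x[k:]
    mu0 = csum[:-1] / k
    mu1 = (total - csum[:-1]) / (n - k)
    w0 = k / n
    bcv = w0 * (1 - w0) * (mu0 - mu1) ** 2
    # only splits between distinct values are meaningful thresholds
    valid = x[1:] > x[:-1]
    bcv = np.where(valid, bcv, -np.inf)
    best = int(np.argmax(bcv))
    return float(0.5 * (x[best] + x[best + 1]))


def estimate_threshold(traces: list[GreenTrace]) -> float:
    """Pool every mu sample of every track and return the exact Otsu
    threshold separating quiescent from caspase-positive signal levels."""
    pooled = np.concatenate([tr.mu for tr in traces]) if traces else np.array([])
    return otsu_exact(pooled)


def call_death_times(
    tracks: list[CellTrack], traces: list[GreenTrace], th: float
) -> list[DeathEvent]:
    """First-crossing death calls: one event per track whose mu ever
    exceeds th, at the earliest such frame. Later dips below th (reporter
    bleaching) never retract a call."""
    if not np.isfinite(th):
        raise ValidationError("threshold must be finite")
    by_id = {tr.track_id: tr for tr in tracks}
    events = []
    for trace in traces:
        above = trace.mu > th
        if not above.any():
            continue
        i = int(np.argmax(above))
        t = int(trace.frames[i])
        track = by_id[trace.track_id]
        x, y, r = track.at(t)
        events.append(DeathEvent(track_id=trace.track_id, death_frame=t,
                                 x=x, y=y, radius=r))
    return events


def living_track_counts(
    tracks: list[CellTrack], traces: list[GreenTrace], th: float, n_frames: int
) -> np.ndarray:
    """N_track(t): number of tracks existing at t whose mu(t) < th."""
    counts = np.zeros(n_frames, dtype=int)
    for trace in traces:
        lo, hi = int(trace.frames[0]), int(trace.frames[-1])
        alive = trace.mu < th
        counts[lo: hi + 1] += alive.astype(int)
    return counts


def apoptosis_rate(
    events: list[DeathEvent],
    tracks: list[CellTrack],
    traces: list[GreenTrace],
    th: float,
    t_lag_frames: int,
    n_frames: int,
    cal: Calibration | None = None,
) -> pd.DataFrame:
    """Apoptosis-rate series O(t) = 100 * N_ap / N_avg.

    N_ap(t) counts events in the trailing window of ``t_lag_frames``
    frames ending at t (frames t - T_LAG + 1 .. t), so a constant
    per-frame hazard h yields O ~= 100 * h * T_LAG. N_avg(t) is the mean
    living-track count over [t - T_LAG, t]. O is reported from the first
    frame with a full trailing window; earlier frames are emitted as
    missing. Frames with N_avg = 0 are also missing.
    """
    if t_lag_frames < 1:
        raise ConfigError("t_lag_frames must be >= 1")
    cal = cal or Calibration(pixel_size_um=1.0)
    n_track = living_track_counts(tracks, traces, th, n_frames)
    death_frames = np.array([e.death_frame for e in events], dtype=int)

    rows = []
    for t in range(n_frames):
        lo_ap = t - t_lag_frames + 1
        n_ap = int(((death_frames > lo_ap - 1) & (death_frames <= t)).sum())
        lo_avg = max(t - t_lag_frames, 0)
        n_avg = float(n_track[lo_avg: t + 1].mean())
        if t < t_lag_frames or n_avg == 0:
            o = np.nan
        else:
            o = 100.0 * n_ap / n_avg
        rows.append(
            dict(frame=t + 1, hours=cal.frames_to_hours(t + 1),
                 n_ap=n_ap, n_track=int(n_track[t]), n_avg=n_avg, o_percent=o)
        )
    return pd.DataFrame(rows)


def overall_survival(
    tracks: list[CellTrack],
    traces: list[GreenTrace],
    th: float,
    n_frames: int,
    cal: Calibration | None = None,
) -> pd.DataFrame:
    """Overall-survival series OS(t) = 100 * N_avg2(t) / N_avg2(start).

    N_avg2 is the 3-frame centered mean of the living-track count
    (truncated at the sequence ends); the reference is the mean over the
    first three frames, so OS starts at 100% by construction.
    """
    if n_frames < 3:
        raise ConfigError("overall survival needs at least 3 frames")
    cal = cal or Calibration(pixel_size_um=1.0)
    n_track = living_track_counts(tracks, traces, th, n_frames)
    n_avg2 = np.array(
        [n_track[max(t - 1, 0): t + 2].mean() for t in range(n_frames)]
    )
    ref = float(n_track[:3].mean())
    if ref == 0:
        raise DegenerateInputError("no living tracks in the first three frames")
    return pd.DataFrame(
        dict(
            frame=np.arange(1, n_frames + 1),
            hours=cal.frames_to_hours(np.arange(1, n_frames + 1)),
            n_avg2=n_avg2,
            os_percent=100.0 * n_avg2 / ref,
        )
    )


def traces_to_table(traces: list[GreenTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for i, f in enumerate(tr.frames):
            rows.append(dict(track_id=tr.track_id, frame=int(f) + 1,
                             mu_fg=tr.mu_fg[i], mu_bg=tr.mu_bg[i], mu=tr.mu[i]))
    return pd.DataFrame(rows, columns=["track_id", "frame", "mu_fg", "mu_bg", "mu"])
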