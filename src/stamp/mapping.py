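"""Spatiotemporal death maps and the potential of death induction.

Each called death seeds a binary disk at its position and frame (the seed
video MD). A wake video M is built iteratively,

    M(t) = erode(M(t-1), B_r) + MD(t),        M(1) = MD(1),

where erode is grayscale morphological erosion with a disk structuring
element B_r = {(x, y) : x^2 + y^2 <= r^2}. Erosion shaves r pixels off
every object radius per frame, so a dying cell of radius r0 leaves a
"wake" that vanishes after about r0 / r frames; with r = r0 / 3 the wake
persists for at least three hourly frames.

The cumulative map squares and sums M over a forward window of T-tilde
frames; its 8-connected non-zero regions are the death objects. The
potential of death induction over an object set S is

    P_death = 1 / (2 |S|) * sum over pairs i < j of
              (mean MC over s_i + mean MC over s_j) / dbar(s_i, s_j)

with dbar the Euclidean distance between the objects' boundary centroids,
normalized by the largest dimension of the evaluation region. Deaths that
are many, intense and mutually close score high; isolated or sparse
deaths score low, which is what separates transmissible from random
death. P_death is evaluated inside sliding windows of 283 um per side to
confine the statistic spatially.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import grey_erosion
from skimage.measure import label, regionprops
from skimage.morphology import disk
from skimage.segmentation import find_boundaries

from .errors import ConfigError
from .kinetics import DeathEvent
from .video_io import Calibration

logger = logging.getLogger(__name__)

WINDOW_UM_DEFAULT = 283.0  # side of the sliding evaluation window
T_TILDE_HOURS_DEFAULT = 16.0  # cumulative-map window, calibrated on chain durations


def rasterize_disk(
    shape: tuple[int, int], cx: float, cy: float, radius: float
) -> np.ndarray:
    """Boolean disk {(x,y): (x-cx)^2 + (y-cy)^2 <= radius^2}, clipped to shape."""
    d1, d2 = shape
    yy, xx = np.ogrid[:d1, :d2]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def build_seed_video(
    events: list[DeathEvent], dims: tuple[int, int], n_frames: int
) -> np.ndarray:
    """Binary seed video MD: a value-1 disk per event at its death frame.

    Overlapping same-frame disks are unioned, so MD stays binary.
    """
    d1, d2 = dims
    md = np.zeros((d1, d2, n_frames), dtype=np.float64)
    for e in events:
        if not (0 <= e.x < d2 and 0 <= e.y < d1):
            raise ConfigError(f"event at ({e.x}, {e.y}) outside dims {dims}")
        if not (0 <= e.death_frame < n_frames):
            raise ConfigError(f"event frame {e.death_frame} outside 0..{n_frames - 1}")
        md[:, :, e.death_frame][rasterize_disk((d1, d2), e.x, e.y, e.radius)] = 1.0
    return md


def propagate_wake(md: np.ndarray, r: int) -> np.ndarray:
    """Wake video M: per-frame grayscale erosion of the previous frame plus
    the current frame's seeds. Frame borders use edge replication so the
    minimum is effectively taken over in-frame pixels only."""
    if r <= 0:
        raise ConfigError("structuring-element radius r must be > 0")
    footprint = disk(int(r)).astype(bool)
    m = np.zeros_like(md)
    m[:, :, 0] = md[:, :, 0]
    for t in range(1, md.shape[2]):
        eroded = grey_erosion(m[:, :, t - 1], footprint=footprint, mode="nearest")
        m[:, :, t] = eroded + md[:, :, t]
    return m


def cumulative_map(m: np.ndarray, t_tilde: int) -> np.ndarray:
    """Cumulative map MC(t) = sum over t' in [t, t + t_tilde] of M(t')^2,
    defined for t in 0 .. T - t_tilde - 1 (so the window always fits)."""
    n_frames = m.shape[2]
    if not (0 < t_tilde < n_frames):
        raise ConfigError(f"t_tilde must be in 1..{n_frames - 1}, got {t_tilde}")
    sq = m**2
    csum = np.cumsum(sq, axis=2)
    out = np.empty(m.shape[:2] + (n_frames - t_tilde,), dtype=np.float64)
    out[:, :, 0] = csum[:, :, t_tilde]
    out[:, :, 1:] = csum[:, :, t_tilde + 1:] - csum[:, :, : n_frames - t_tilde - 1]
    return out


@dataclass
class DeathObject:
    """One 8-connected non-zero region of a cumulative-map frame."""

    label: int
    pixels: np.ndarray  # (n, 2) array of (row y, col x)
    mean_mc: float
    centroid: tuple[float, float]  # boundary centroid (x, y)


def extract_objects(mc_frame: np.ndarray) -> list[DeathObject]:
    """Connected components of the non-zero support under 8-connectivity,
    with each object's mean MC value and boundary centroid."""
    support = mc_frame > 0
    if not support.any():
        return []
    labels = label(support, connectivity=2)
    objects = []
    for prop in regionprops(labels):
        mask = labels == prop.label
        boundary = find_boundaries(mask, mode="inner", connectivity=2)
        if not boundary.any():  # whole-frame object has no inner boundary
            boundary = mask
        ys, xs = np.nonzero(boundary)
        objects.append(
            DeathObject(
                label=int(prop.label),
                pixels=np.array(prop.coords),
                mean_mc=float(mc_frame[mask].mean()),
                centroid=(float(xs.mean()), float(ys.mean())),
            )
        )
    return objects


def potential_of_death(
    objects: list[DeathObject], frame_dims: tuple[int, int]
) -> float:
    """Potential of death induction for one object set (see module docs).

    Zero when fewer than two objects exist. Pairs with coincident boundary
    centroids (possible for nested objects after window clipping) are
    skipped and counted in a warning rather than dividing by zero.
    """
    n = len(objects)
    if n < 2:
        return 0.0
    norm = float(max(frame_dims))
    total = 0.0
    skipped = 0
    for i in range(n):
        xi, yi = objects[i].centroid
        for j in range(i + 1, n):
            xj, yj = objects[j].centroid
            dbar = np.hypot(xi - xj, yi - yj) / norm
            if dbar == 0:
                skipped += 1
                continue
            total += (objects[i].mean_mc + objects[j].mean_mc) / dbar
    if skipped:
        logger.warning("potential_of_death: skipped %d coincident-centroid pairs",
                       skipped)
    return total / (2 * n)


def _window_starts(extent: int, side: int, stride: int) -> list[int]:
    """Tile starts covering [0, extent); the last window anchors to the edge."""
    if side >= extent:
        return [0]
    starts = list(range(0, extent - side + 1, stride))
    if starts[-1] != extent - side:
        starts.append(extent - side)
    return starts


def windowed_pdeath(
    mc: np.ndarray,
    cal: Calibration,
    window_um: float = WINDOW_UM_DEFAULT,
    stride_um: float | None = None,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Evaluate P_death inside sliding square windows on every MC frame.

    The window side is converted from micrometers via the calibration;
    objects are clipped to each window and the distance normalization uses
    the window side. The per-frame aggregate is the mean (or max) over
    windows holding at least one object; frames with no objects anywhere
    score 0. A window larger than the frame degrades to a single
    whole-frame evaluation (with a warning).
    """
    if aggregate not in ("mean", "max"):
        raise ConfigError("aggregate must be 'mean' or 'max'")
    d1, d2, n_frames = mc.shape
    side = int(round(cal.um_to_px(window_um)))
    if side < 8:
        raise ConfigError(f"window of {window_um} um is {side} px; need >= 8 px")
    if side > max(d1, d2):
        logger.warning("window (%d px) exceeds frame (%dx%d); using whole frame",
                       side, d1, d2)
    stride = side if stride_um is None else max(int(round(cal.um_to_px(stride_um))), 1)
    ys = _window_starts(d1, side, stride)
    xs = _window_starts(d2, side, stride)

    rows = []
    for t in range(n_frames):
        frame = mc[:, :, t]
        vals = []
        for y0 in ys:
            for x0 in xs:
                sub = frame[y0: y0 + side, x0: x0 + side]
                if not (sub > 0).any():
                    continue
                objs = extract_objects(sub)
                vals.append(potential_of_death(objs, sub.shape))
        if vals:
            agg = float(np.mean(vals) if aggregate == "mean" else np.max(vals))
        else:
            agg = 0.0
        rows.append(
            dict(frame=t + 1, hours=cal.frames_to_hours(t + 1),
                 pdeath=agg, n_windows=len(vals))
        )
    return pd.DataFrame(rows)


@dataclass
class ChainOfDeath:
    """Deaths linked in space (within 10x the seed's radius) and in time
    (consecutive members within T_LAG); the chain's total duration is the
    seed cell's induction interval."""

    seed: DeathEvent
    members: list[DeathEvent] = field(default_factory=list)
    induction_interval_h: float = 0.0

    def __len__(self) -> int:
        return len(self.members)


def chain_of_death(
    events: list[DeathEvent],
    t_lag_frames: int,
    cal: Calibration | None = None,
    radius_factor: float = 10.0,
) -> list[ChainOfDeath]:
    """Grow one chain per event (every event seeds a chain, even if it is
    already a member of an earlier one).

    Candidates are the deaths within ``radius_factor`` times the seed's
    radius of the seed's position; walking them in death-time order, each
    is added while its time gap to the latest chain member is at most
    T_LAG frames. The induction interval is the time from the seed's death
    to the last member's, in hours.
    """
    cal = cal or Calibration(pixel_size_um=1.0)
    ordered = sorted(events, key=lambda e: e.death_frame)
    chains = []
    for seed in ordered:
        capture2 = (radius_factor * seed.radius) ** 2
        members = [seed]
        last_t = seed.death_frame
        for e in ordered:
            if e is seed or e.death_frame < seed.death_frame:
                continue
            if (e.x - seed.x) ** 2 + (e.y - seed.y) ** 2 > capture2:
                continue
            if e.death_frame - last_t <= t_lag_frames:
                members.append(e)
                last_t = e.death_frame
        chains.append(
            ChainOfDeath(
                seed=seed,
                members=members,
                induction_interval_h=cal.frames_to_hours(last_t - seed.death_frame),
            )
        )
    return chains


def chains_to_table(chains: list[ChainOfDeath]) -> pd.DataFrame:
    rows = [
        dict(
            seed_id=c.seed.track_id,
            member_ids=";".join(str(m.track_id) for m in c.members),
            n_members=len(c.members),
            induction_interval_h=c.induction_interval_h,
        )
        for c in chains
    ]
    return pd.DataFrame(
        rows, columns=["seed_id", "member_ids", "n_members", "induction_interval_h"]
    )
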