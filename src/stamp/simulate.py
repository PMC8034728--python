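"""Ground-truthed synthetic videos and death-event patterns.

The video generator emulates the imaging model the pipeline assumes: red
pre-stained cancer cells rendered as Gaussian-smoothed disks drifting
slowly on a dark background, and a caspase reporter whose green disk
ramps up at each cell's scheduled death and persists afterwards. Dead
cells stop drifting and keep their red signal. Gaussian read noise is
added to both channels and frames are rounded to integer counts, so a
fixed seed reproduces stacks bit-exactly.

Abstract event-pattern generators produce death tables without rendering:
spatially random or clustered placements with a chosen temporal profile,
and a contagion cohort in which each death transiently raises the hazard
of its neighbors — the positive control for the death-induction
statistic, against the constant-hazard random null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigError
from .kinetics import DeathEvent, GreenTrace
from .tracking import CellTrack
from .video_io import FrameStack


@dataclass
class SimConfig:
    """Synthetic-video settings; defaults give a desk-scale culture
    (512x512 px, 48 hourly frames, ~100 cells) dense enough for pairwise
    spatial statistics yet tractable in test runs."""

    dims: tuple[int, int] = (512, 512)  # (D1 rows, D2 cols)
    n_frames: int = 48
    n_cells: int = 100
    cell_radius_mean: float = 6.0
    cell_radius_sd: float = 1.0
    drift_px_per_frame: float = 0.5
    red_peak: float = 180.0
    green_peak: float = 180.0
    background_mean: float = 20.0
    noise_sd: float = 5.0
    green_rise_frames: int = 2
    smooth_sigma: float = 1.0
    # death programming: explicit schedule wins over the hazard model
    death_schedule: list[tuple[int, int]] | None = None  # (cell_index, frame)
    hazard_per_frame: float = 0.0
    contagion: dict | None = None  # {boost, capture_radius_px, lag_frames}
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dims) < 16 or self.n_frames < 1:
            raise ConfigError("dims must be >= 16 px and n_frames >= 1")
        if not (0.0 <= self.hazard_per_frame <= 1.0):
            raise ConfigError("hazard_per_frame must be in [0, 1]")
        if self.green_rise_frames < 1:
            raise ConfigError("green_rise_frames must be >= 1")


@dataclass
class GroundTruth:
    """Per-cell trajectories and true death frames backing a simulated video."""

    x: np.ndarray  # (n_cells, n_frames)
    y: np.ndarray
    radius: np.ndarray  # (n_cells,)
    death_frame: np.ndarray  # (n_cells,) int, -1 = never dies
    config: SimConfig

    def events_table(self) -> pd.DataFrame:
        """True deaths as an event table (1-based death_frame)."""
        rows = []
        for c in np.nonzero(self.death_frame >= 0)[0]:
            t = int(self.death_frame[c])
            rows.append(dict(track_id=int(c), x=self.x[c, t], y=self.y[c, t],
                             radius=float(self.radius[c]), death_frame=t + 1))
        return pd.DataFrame(
            rows, columns=["track_id", "x", "y", "radius", "death_frame"]
        )


def _place_cells(rng, dims, n_cells, radius_mean, margin):
    """Random non-overlapping placement by rejection (best effort)."""
    d1, d2 = dims
    min_sep2 = (2.5 * radius_mean) ** 2
    xs, ys = [], []
    tries = 0
    while len(xs) < n_cells and tries < 200 * n_cells:
        tries += 1
        x = rng.uniform(margin, d2 - margin)
        y = rng.uniform(margin, d1 - margin)
        if all((x - xi) ** 2 + (y - yi) ** 2 >= min_sep2 for xi, yi in zip(xs, ys)):
            xs.append(x)
            ys.append(y)
    if len(xs) < n_cells:
        raise ConfigError(
            f"could not place {n_cells} cells of radius ~{radius_mean} in {dims}"
        )
    return np.array(xs), np.array(ys)


def _schedule_deaths(cfg: SimConfig, rng, x, y, radius) -> np.ndarray:
    n = cfg.n_cells
    death = np.full(n, -1, dtype=int)
    if cfg.death_schedule is not None:
        for cell, t in cfg.death_schedule:
            if not (0 <= t < cfg.n_frames):
                raise ConfigError(f"scheduled death frame {t} outside video")
            death[cell] = t
        return death
    if cfg.hazard_per_frame == 0.0:
        return death
    boost = cfg.contagion or {}
    b = float(boost.get("boost", 0.0))
    cap2 = float(boost.get("capture_radius_px", 0.0)) ** 2
    lag = int(boost.get("lag_frames", 0))
    recent: list[tuple[int, float, float]] = []  # (frame, x, y)
    for t in range(cfg.n_frames):
        alive = np.nonzero(death < 0)[0]
        if alive.size == 0:
            break
        h = np.full(alive.size, cfg.hazard_per_frame)
        if b > 0 and recent:
            near = np.zeros(alive.size, dtype=bool)
            for tf, xf, yf in recent:
                if t - tf > lag:
                    continue
                near |= (x[alive, 0] - xf) ** 2 + (y[alive, 0] - yf) ** 2 <= cap2
            h[near] = np.minimum(h[near] + b, 1.0)
        dies = rng.random(alive.size) < h
        for c in alive[dies]:
            death[c] = t
            recent.append((t, float(x[c, 0]), float(y[c, 0])))
        recent = [rec for rec in recent if t - rec[0] <= lag]
    return death


def simulate_video(cfg: SimConfig) -> tuple[FrameStack, FrameStack, GroundTruth]:
    """Render a two-channel video plus its ground truth (see module docs)."""
    rng = np.random.default_rng(cfg.seed)
    d1, d2 = cfg.dims
    margin = cfg.cell_radius_mean * 2 + 2
    x0, y0 = _place_cells(rng, cfg.dims, cfg.n_cells, cfg.cell_radius_mean, margin)
    radius = np.clip(
        rng.normal(cfg.cell_radius_mean, cfg.cell_radius_sd, cfg.n_cells),
        max(cfg.cell_radius_mean - 3 * cfg.cell_radius_sd, 2.0),
        cfg.cell_radius_mean + 3 * cfg.cell_radius_sd,
    )

    x = np.empty((cfg.n_cells, cfg.n_frames))
    y = np.empty_like(x)
    x[:, 0], y[:, 0] = x0, y0
    steps_x = rng.normal(0.0, cfg.drift_px_per_frame, (cfg.n_cells, cfg.n_frames))
    steps_y = rng.normal(0.0, cfg.drift_px_per_frame, (cfg.n_cells, cfg.n_frames))
    death = _schedule_deaths(cfg, rng, x, y, radius)
    for t in range(1, cfg.n_frames):
        moving = (death < 0) | (death >= t)  # dead cells stop drifting
        x[:, t] = x[:, t - 1]
        y[:, t] = y[:, t - 1]
        x[moving, t] = np.clip(x[moving, t - 1] + steps_x[moving, t], margin, d2 - margin)
        y[moving, t] = np.clip(y[moving, t - 1] + steps_y[moving, t], margin, d1 - margin)

    red = np.empty((d1, d2, cfg.n_frames))
    green = np.empty_like(red)
    yy, xx = np.mgrid[:d1, :d2]
    for t in range(cfg.n_frames):
        r_frame = np.zeros((d1, d2))
        g_frame = np.zeros((d1, d2))
        for c in range(cfg.n_cells):
            m = (yy - y[c, t]) ** 2 + (xx - x[c, t]) ** 2 <= radius[c] ** 2
            r_frame[m] = cfg.red_peak
            if death[c] >= 0 and t >= death[c]:
                ramp = min((t - death[c] + 1) / cfg.green_rise_frames, 1.0)
                g_frame[m] = np.maximum(g_frame[m], cfg.green_peak * ramp)
        r_frame = gaussian_filter(r_frame, cfg.smooth_sigma)
        g_frame = gaussian_filter(g_frame, cfg.smooth_sigma)
        red[:, :, t] = r_frame
        green[:, :, t] = g_frame
    red += cfg.background_mean + rng.normal(0.0, cfg.noise_sd, red.shape)
    green += cfg.background_mean + rng.normal(0.0, cfg.noise_sd, green.shape)
    red = np.rint(np.clip(red, 0, None))
    green = np.rint(np.clip(green, 0, None))
    gt = GroundTruth(x=x, y=y, radius=radius, death_frame=death, config=cfg)
    return (
        FrameStack(pixels=red, channel="red"),
        FrameStack(pixels=green, channel="green"),
        gt,
    )


# ---------------------------------------------------------------------------
# Abstract death-event patterns (no rendering)
# ---------------------------------------------------------------------------

def simulate_death_pattern(
    n_events: int,
    mode: str,
    dims: tuple[int, int],
    n_frames: int,
    radius: float = 6.0,
    k_clusters: int = 3,
    cluster_spread_px: float = 10.0,
    frames: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    margin: float | None = None,
) -> pd.DataFrame:
    """Death-event table with controlled spatial structure.

    ``mode='random'`` draws i.i.d. uniform positions; ``mode='clustered'``
    draws positions around ``k_clusters`` uniform cluster centers with
    isotropic Gaussian spread. Death frames are uniform over the video
    unless an explicit per-event ``frames`` array is given (e.g. to match
    a reference series' temporal profile). Returns 1-based death frames.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d1, d2 = dims
    margin = radius + 1 if margin is None else margin
    if mode == "random":
        xs = rng.uniform(margin, d2 - margin, n_events)
        ys = rng.uniform(margin, d1 - margin, n_events)
    elif mode == "clustered":
        centers_x = rng.uniform(margin + 3 * cluster_spread_px,
                                d2 - margin - 3 * cluster_spread_px, k_clusters)
        centers_y = rng.uniform(margin + 3 * cluster_spread_px,
                                d1 - margin - 3 * cluster_spread_px, k_clusters)
        which = rng.integers(0, k_clusters, n_events)
        xs = np.clip(centers_x[which] + rng.normal(0, cluster_spread_px, n_events),
                     margin, d2 - margin)
        ys = np.clip(centers_y[which] + rng.normal(0, cluster_spread_px, n_events),
                     margin, d1 - margin)
    else:
        raise ConfigError("mode must be 'random' or 'clustered'")
    if frames is None:
        frames = rng.integers(1, n_frames + 1, n_events)
    frames = np.asarray(frames, dtype=int)
    if len(frames) != n_events:
        raise ConfigError("frames must have one entry per event")
    return pd.DataFrame(
        dict(track_id=np.arange(n_events), x=xs, y=ys,
             radius=np.full(n_events, float(radius)), death_frame=frames)
    )


def table_to_events(table: pd.DataFrame) -> list[DeathEvent]:
    """Event-table rows (1-based frames) to internal DeathEvent records."""
    events = []
    for row in table.itertuples(index=False):
        events.append(
            DeathEvent(track_id=int(row.track_id), death_frame=int(row.death_frame) - 1,
                       x=float(row.x), y=float(row.y), radius=float(row.radius))
        )
    return events


def simulate_cohort(
    n_cells: int,
    n_frames: int,
    hazard_per_frame: float,
    dims: tuple[int, int] = (2048, 2048),
    radius: float = 6.0,
    seed: int = 0,
) -> tuple[list[CellTrack], list[GreenTrace], float]:
    """Idealized constant-hazard cohort: static full-length tracks whose
    traces step from 0 to 1 at the cell's drawn death frame.

    Returns (tracks, traces, th) with th = 0.5 separating the two levels;
    the analytic check is that the apoptosis rate recovers the programmed
    hazard. Positions are uniform (no rendering, no detection noise).
    """
    rng = np.random.default_rng(seed)
    d1, d2 = dims
    frames = np.arange(n_frames)
    # geometric death times from the per-frame hazard; -1 = survives the video
    u = rng.random((n_cells, n_frames)) < hazard_per_frame
    death = np.where(u.any(axis=1), u.argmax(axis=1), -1)
    xs = rng.uniform(radius, d2 - radius, n_cells)
    ys = rng.uniform(radius, d1 - radius, n_cells)
    tracks, traces = [], []
    for c in range(n_cells):
        tracks.append(
            CellTrack(track_id=c, frames=frames.copy(),
                      x=np.full(n_frames, xs[c]), y=np.full(n_frames, ys[c]),
                      radius=np.full(n_frames, radius))
        )
        mu = np.zeros(n_frames)
        if death[c] >= 0:
            mu[death[c]:] = 1.0
        traces.append(
            GreenTrace(track_id=c, frames=frames.copy(),
                       mu_fg=mu.copy(), mu_bg=np.ones(n_frames), mu=mu)
        )
    return tracks, traces, 0.5


def simulate_contagion_pattern(
    n_frames: int,
    dims: tuple[int, int] = (300, 300),
    base_hazard: float = 1e-4,
    boost: float = 0.2,
    capture_radius_px: float = 16.0,
    lag_frames: int = 3,
    grid_spacing_px: float = 12.0,
    jitter_px: float = 2.0,
    radius: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Death-event table from a transmissible-death (contagion) hazard.

    Cells sit on a jittered grid (a confluent culture); one initiating
    death is forced near the field center, and every death raises the
    per-frame hazard of cells within the capture radius for
    ``lag_frames`` frames, so a wave of death spreads outward for the
    rest of the video. The expanding front makes the per-frame death
    count — and with it the induction potential — rise over time: the
    positive control against the constant-hazard random null. Returns
    1-based death frames.
    """
    rng = np.random.default_rng(seed)
    d1, d2 = dims
    gy = np.arange(radius + 3, d1 - radius - 2, grid_spacing_px)
    gx = np.arange(radius + 3, d2 - radius - 2, grid_spacing_px)
    xs, ys = np.meshgrid(gx, gy)
    xs = np.clip((xs + rng.normal(0, jitter_px, xs.shape)).ravel(), 1, d2 - 2)
    ys = np.clip((ys + rng.normal(0, jitter_px, ys.shape)).ravel(), 1, d1 - 2)
    n_cells = xs.size
    death = np.full(n_cells, -1, dtype=int)
    recent: list[tuple[int, float, float]] = []
    c0 = int(np.argmin((xs - d2 / 2) ** 2 + (ys - d1 / 2) ** 2))
    death[c0] = min(1, n_frames - 1)
    recent.append((death[c0], xs[c0], ys[c0]))
    cap2 = capture_radius_px**2
    for t in range(death[c0] + 1, n_frames):
        alive = np.nonzero(death < 0)[0]
        if alive.size == 0:
            break
        h = np.full(alive.size, base_hazard)
        for tf, xf, yf in recent:
            near = (xs[alive] - xf) ** 2 + (ys[alive] - yf) ** 2 <= cap2
            h[near] = np.minimum(h[near] + boost, 1.0)
        dies = rng.random(alive.size) < h
        for c in alive[dies]:
            death[c] = t
            recent.append((t, xs[c], ys[c]))
        recent = [rec for rec in recent if t - rec[0] < lag_frames]
    idx = np.nonzero(death >= 0)[0]
    return pd.DataFrame(
        dict(track_id=idx, x=xs[idx], y=ys[idx],
             radius=np.full(idx.size, float(radius)), death_frame=death[idx] + 1)
    )


def three_death_scenario() -> tuple[pd.DataFrame, dict]:
    """Three-death demonstration scenario for the induction potential.

    Three deaths at hours 2, 9 and 11 on a 150x150 frame: the first two
    close together, the third a little farther, all of radius 9 px, eroded
    with r = 3 (one third of the radius) and accumulated with a 6-frame
    window. The resulting potential is zero while a single death object
    exists, rises when the second and again when the third death enters
    the map, and falls once the first death's wake leaves the window.
    """
    table = pd.DataFrame(
        dict(track_id=[0, 1, 2],
             x=[40.0, 64.0, 52.0],
             y=[40.0, 40.0, 68.0],
             radius=[9.0, 9.0, 9.0],
             death_frame=[2, 9, 11])
    )
    config = dict(dims=(150, 150), n_frames=20, se_radius_px=3, t_tilde_frames=6)
    return table, config
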