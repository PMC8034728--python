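"""End-to-end orchestration: video -> tracks -> traces -> events ->
kinetics -> death maps -> induction potential -> chains.

A run consumes a config mapping (YAML/JSON via the CLI, or a dict in
code), writes every intermediate as CSV plus a MANIFEST with checksums,
and is deterministic: identical config and inputs give identical outputs.
All user-facing durations are hours; conversion to frames goes through
the calibration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinetics, mapping, tracking, video_io
from .errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated, fully-serializable configuration of one pipeline run."""

    red_path: str
    green_path: str
    output_dir: str
    pixel_size_um: float
    frame_interval_h: float = 1.0
    radius_min_px: int = 4
    radius_max_px: int = 9
    gating_px: float | None = None
    max_gap_frames: int = 2
    roi_side_px: int = 31
    bg_radius_factor: float = 2.0
    epsilon_bg: float = 1e-6
    t_lag_hours: float = 4.0
    t_tilde_hours: float = mapping.T_TILDE_HOURS_DEFAULT
    se_radius_px: int | None = None  # None -> ceil(mean detected radius / 3)
    window_um: float = mapping.WINDOW_UM_DEFAULT
    stride_um: float | None = None
    aggregate: str = "mean"
    chain_radius_factor: float = 10.0
    chain_t_lag_hours: float | None = None  # None -> t_lag_hours
    seed: int = 0

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"red_path", "green_path", "output_dir", "pixel_size_um"} - set(data)
        if missing:
            raise ConfigError(f"missing required config keys: {sorted(missing)}")
        cfg = cls(**data)
        for p in (cfg.red_path, cfg.green_path):
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if cfg.aggregate not in ("mean", "max"):
            raise ConfigError("aggregate must be 'mean' or 'max'")
        return cfg

    @property
    def calibration(self) -> video_io.Calibration:
        return video_io.Calibration(
            pixel_size_um=self.pixel_size_um, frame_interval_h=self.frame_interval_h
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns a result dict with key tables.

    Artifacts written to ``cfg.output_dir``: tracks.csv, traces.csv,
    events.csv, kinetics.csv, survival.csv, pdeath.csv, chains.csv,
    run_config.json, MANIFEST.json. Stage failures abort with a
    stage-tagged error after flushing the MANIFEST.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cal = cfg.calibration
    manifest: dict = {"completed": [], "artifacts": {}}

    def flush_manifest() -> None:
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))

    def save(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.6g")
        manifest["artifacts"][name] = _sha256(path)

    # the config dump embeds machine-specific paths, so it is not checksummed
    (out / "run_config.json").write_text(json.dumps(asdict(cfg), indent=2))

    stage = "read"
    try:
        red = video_io.read_stack(cfg.red_path, channel="red")
        green = video_io.read_stack(cfg.green_path, channel="green")
        if red.shape != green.shape:
            raise ConfigError(
                f"channel shape mismatch: red {red.shape} vs green {green.shape}"
            )
        n_frames = red.n_frames
        manifest["completed"].append(stage)

        stage = "tracking"
        tcfg = tracking.TrackingConfig(
            radius_min_px=cfg.radius_min_px, radius_max_px=cfg.radius_max_px,
            gating_px=cfg.gating_px, max_gap_frames=cfg.max_gap_frames,
        )
        detections = tracking.detect_stack(red, tcfg)
        tracks = tracking.link_tracks(detections, tcfg)
        save("tracks.csv", tracking.tracks_to_table(tracks))
        manifest["completed"].append(stage)

        stage = "traces"
        mean_radius = (
            float(np.mean([tr.radius.mean() for tr in tracks])) if tracks
            else cfg.radius_max_px
        )
        geom = kinetics.RoiGeometry(
            roi_side_px=cfg.roi_side_px,
            bg_radius_px=min(cfg.bg_radius_factor * mean_radius, cfg.roi_side_px / 2),
            epsilon_bg=cfg.epsilon_bg,
        )
        traces = [kinetics.extract_green_trace(tr, green, geom) for tr in tracks]
        save("traces.csv", kinetics.traces_to_table(traces))
        manifest["completed"].append(stage)

        stage = "death_calls"
        th = kinetics.estimate_threshold(traces)
        events = kinetics.call_death_times(tracks, traces, th)
        save("events.csv", video_io.events_to_table(events))
        manifest["completed"].append(stage)

        stage = "kinetics"
        t_lag = max(cal.hours_to_frames(cfg.t_lag_hours), 1)
        rate = kinetics.apoptosis_rate(
            events, tracks, traces, th, t_lag, n_frames, cal
        )
        save("kinetics.csv", rate)
        surv = kinetics.overall_survival(tracks, traces, th, n_frames, cal)
        save("survival.csv", surv)
        manifest["completed"].append(stage)

        stage = "death_mapping"
        t_tilde = max(cal.hours_to_frames(cfg.t_tilde_hours), 1)
        se_r = cfg.se_radius_px or max(int(np.ceil(mean_radius / 3.0)), 1)
        md = mapping.build_seed_video(events, red.shape[:2], n_frames)
        m = mapping.propagate_wake(md, se_r)
        if t_tilde < n_frames:
            mc = mapping.cumulative_map(m, t_tilde)
            pdeath = mapping.windowed_pdeath(
                mc, cal, window_um=cfg.window_um, stride_um=cfg.stride_um,
                aggregate=cfg.aggregate,
            )
        else:
            logger.warning("t_tilde (%d frames) >= video length; skipping P_death",
                           t_tilde)
            pdeath = pd.DataFrame(columns=["frame", "hours", "pdeath", "n_windows"])
        save("pdeath.csv", pdeath)
        manifest["completed"].append(stage)

        stage = "chains"
        chain_lag_h = cfg.chain_t_lag_hours or cfg.t_lag_hours
        chains = mapping.chain_of_death(
            events, max(cal.hours_to_frames(chain_lag_h), 1), cal,
            radius_factor=cfg.chain_radius_factor,
        )
        save("chains.csv", mapping.chains_to_table(chains))
        manifest["completed"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        flush_manifest()
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    flush_manifest()
    return dict(
        tracks=tracks, traces=traces, events=events, threshold=th,
        kinetics=rate, survival=surv, pdeath=pdeath, chains=chains,
        manifest=manifest,
    )


def plot_outputs(run_dir: str | Path) -> list[Path]:
    """Render kinetics, survival, P_death and death-map figures from a
    completed run directory; returns the figure paths (also appended to
    the MANIFEST)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    figures: list[Path] = []

    def finish(fig, name: str) -> None:
        path = run_dir / name
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        figures.append(path)

    kin = pd.read_csv(run_dir / "kinetics.csv")
    fig, ax = plt.subplots(figsize=(5, 3.2))
    if kin.empty or kin["o_percent"].dropna().empty:
        ax.annotate("no apoptosis events", (0.5, 0.5), ha="center",
                    xycoords="axes fraction")
    else:
        ax.plot(kin["hours"], kin["o_percent"], color="crimson")
    ax.set(xlabel="time (h)", ylabel="apoptosis rate O (%)")
    finish(fig, "fig_apoptosis_rate.png")

    surv = pd.read_csv(run_dir / "survival.csv")
    fig, ax = plt.subplots(figsize=(5, 3.2))
    if not surv.empty:
        ax.plot(surv["hours"], surv["os_percent"], color="navy")
    ax.set(xlabel="time (h)", ylabel="overall survival OS (%)")
    finish(fig, "fig_overall_survival.png")

    pdeath = pd.read_csv(run_dir / "pdeath.csv")
    fig, ax = plt.subplots(figsize=(5, 3.2))
    if pdeath.empty:
        ax.annotate("P_death not computed", (0.5, 0.5), ha="center",
                    xycoords="axes fraction")
    else:
        ax.plot(pdeath["hours"], pdeath["pdeath"], color="darkgreen")
    ax.set(xlabel="time (h)", ylabel="potential of death induction")
    finish(fig, "fig_pdeath.png")

    events = pd.read_csv(run_dir / "events.csv")
    fig, ax = plt.subplots(figsize=(4.2, 4))
    if not events.empty:
        sc = ax.scatter(events["x"], events["y"], c=events["death_frame"],
                        s=25, cmap="viridis")
        fig.colorbar(sc, ax=ax, label="death frame")
    ax.invert_yaxis()
    ax.set(xlabel="x (px)", ylabel="y (px)", title="death events")
    finish(fig, "fig_death_map.png")

    manifest_path = run_dir / "MANIFEST.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        for p in figures:
            manifest["artifacts"][p.name] = _sha256(p)
        manifest_path.write_text(json.dumps(manifest, indent=2))
    return figures
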