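"""Shared fixtures: a small ground-truthed scene processed once per session."""

import numpy as np
import pytest

from stamp import kinetics, simulate, tracking


@pytest.fixture(scope="session")
def small_scene():
    """256x256, 24 h, 25 cells, ~1%/h death hazard — a desk-scale culture."""
    cfg = simulate.SimConfig(
        dims=(256, 256), n_frames=24, n_cells=25, seed=3, hazard_per_frame=0.01
    )
    red, green, gt = simulate.simulate_video(cfg)
    return red, green, gt


@pytest.fixture(scope="session")
def scene_tracking_cfg():
    """Radius range matching the simulator's truth (mean 6, sd 1, clipped +-3 sd)."""
    return tracking.TrackingConfig(radius_min_px=3, radius_max_px=9)


@pytest.fixture(scope="session")
def small_scene_tracks(small_scene, scene_tracking_cfg):
    red, _, _ = small_scene
    detections = tracking.detect_stack(red, scene_tracking_cfg)
    return tracking.link_tracks(detections, scene_tracking_cfg)


@pytest.fixture(scope="session")
def small_scene_traces(small_scene, small_scene_tracks):
    _, green, _ = small_scene
    geom = kinetics.RoiGeometry(roi_side_px=31, bg_radius_px=12.0)
    return [
        kinetics.extract_green_trace(tr, green, geom) for tr in small_scene_tracks
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
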