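"""Death maps: seed video, wake erosion law, cumulative map, objects, the
induction potential (with an independent pixel-level recomputation), the
sliding-window evaluation, and chains of death."""

from collections import deque

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stamp import mapping
from stamp.errors import ConfigError
from stamp.kinetics import DeathEvent
from stamp.mapping import DeathObject
from stamp.video_io import Calibration


def event(x, y, t, r=6.0, track_id=0):
    return DeathEvent(track_id=track_id, death_frame=t, x=x, y=y, radius=r)


# ---------------------------------------------------------------------------
# independent pixel-level oracle for the induction potential
# ---------------------------------------------------------------------------

def _flood_components(support):
    """8-connected components by BFS over the nonzero support."""
    seen = np.zeros_like(support, dtype=bool)
    comps = []
    d1, d2 = support.shape
    for sy in range(d1):
        for sx in range(d2):
            if not support[sy, sx] or seen[sy, sx]:
                continue
            comp = []
            q = deque([(sy, sx)])
            seen[sy, sx] = True
            while q:
                y, x = q.popleft()
                comp.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if (0 <= ny < d1 and 0 <= nx < d2
                                and support[ny, nx] and not seen[ny, nx]):
                            seen[ny, nx] = True
                            q.append((ny, nx))
            comps.append(comp)
    return comps


def brute_force_pdeath(mc_frame):
    """Recompute the potential directly from raw pixel sets."""
    support = mc_frame > 0
    comps = _flood_components(support)
    if len(comps) < 2:
        return 0.0
    d1, d2 = mc_frame.shape
    means, cents = [], []
    for comp in comps:
        means.append(np.mean([mc_frame[y, x] for y, x in comp]))
        boundary = []
        for y, x in comp:
            on_edge = False
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < d1 and 0 <= nx < d2 and not support[ny, nx]:
                        on_edge = True
            if on_edge:
                boundary.append((y, x))
        if not boundary:
            boundary = comp
        cents.append((np.mean([x for _, x in boundary]),
                      np.mean([y for y, _ in boundary])))
    total = 0.0
    norm = max(d1, d2)
    for i in range(len(comps)):
        for j in range(i + 1, len(comps)):
            d = np.hypot(cents[i][0] - cents[j][0], cents[i][1] - cents[j][1]) / norm
            if d == 0:
                continue
            total += (means[i] + means[j]) / d
    return total / (2 * len(comps))


def random_object_frame(rng, shape=(40, 40), max_disks=5):
    frame = np.zeros(shape)
    for _ in range(rng.integers(0, max_disks + 1)):
        cx, cy = rng.uniform(4, shape[1] - 4), rng.uniform(4, shape[0] - 4)
        r = rng.uniform(1.5, 4.0)
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        m = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        frame[m] += rng.uniform(0.5, 4.0)
    return frame


class TestSeedVideo:
    def test_no_events_all_zero(self):
        md = mapping.build_seed_video([], (32, 32), 5)
        assert not md.any()

    def test_single_disk_area(self):
        md = mapping.build_seed_video([event(20, 25, 3, r=6)], (50, 50), 6)
        assert md[:, :, [0, 1, 2, 4, 5]].sum() == 0
        area = md[:, :, 3].sum()
        assert abs(area - np.pi * 36) < 0.1 * np.pi * 36  # rasterization slack
        assert md.max() == 1.0

    def test_overlapping_disks_unioned_not_summed(self):
        md = mapping.build_seed_video(
            [event(20, 20, 1, r=6), event(24, 20, 1, r=6)], (40, 40), 3
        )
        assert md.max() == 1.0

    def test_out_of_bounds_event_rejected(self):
        with pytest.raises(ConfigError):
            mapping.build_seed_video([event(100, 10, 0)], (32, 32), 2)


class TestWake:
    def test_empty_seed_empty_wake(self):
        md = np.zeros((20, 20, 6))
        assert not mapping.propagate_wake(md, 2).any()

    def test_invalid_radius_rejected(self):
        with pytest.raises(ConfigError):
            mapping.propagate_wake(np.zeros((10, 10, 3)), 0)

    @pytest.mark.parametrize("r0,r", [(9, 3), (30, 10), (12, 4), (10, 3)])
    def test_wake_duration_law(self, r0, r):
        """An isolated disk of radius r0 eroded by a disk of radius r has
        non-empty support (death frame inclusive) for ceil(r0/r) frames,
        plus at most one extra from rasterization."""
        side = 4 * r0 + 9
        md = np.zeros((side, side, 10))
        md[:, :, 1][mapping.rasterize_disk((side, side), side // 2, side // 2, r0)] = 1
        m = mapping.propagate_wake(md, r)
        frames_alive = sum((m[:, :, t] > 0).any() for t in range(1, 10))
        expected = int(np.ceil(r0 / r))
        assert expected <= frames_alive <= expected + 1

    def test_third_of_radius_keeps_wake_three_frames(self):
        """With r = r0/3 the wake survives at least three hourly frames."""
        md = np.zeros((60, 60, 8))
        md[:, :, 0][mapping.rasterize_disk((60, 60), 30, 30, 9)] = 1
        m = mapping.propagate_wake(md, 3)
        assert all((m[:, :, t] > 0).any() for t in range(3))

    def test_erosion_anti_extensive(self, rng):
        """Before seed addition, each eroded frame <= previous frame pointwise."""
        md = np.zeros((40, 40, 8))
        for t, (x, y) in enumerate([(10, 10), (30, 12), (20, 30)]):
            md[:, :, 2 * t][mapping.rasterize_disk((40, 40), x, y, 7)] = 1
        m = mapping.propagate_wake(md, 2)
        for t in range(1, 8):
            eroded = m[:, :, t] - md[:, :, t]
            assert (eroded <= m[:, :, t - 1] + 1e-12).all()
            assert (m[:, :, t] >= 0).all()

    def test_death_on_surviving_wake_can_exceed_one(self):
        md = np.zeros((40, 40, 3))
        md[:, :, 0][mapping.rasterize_disk((40, 40), 20, 20, 9)] = 1
        md[:, :, 1][mapping.rasterize_disk((40, 40), 20, 20, 9)] = 1
        m = mapping.propagate_wake(md, 3)
        assert m[:, :, 1].max() == 2.0  # additive seeding on a live wake


class TestCumulativeMap:
    def test_zero_in_zero_out(self):
        assert not mapping.cumulative_map(np.zeros((8, 8, 10)), 4).any()

    def test_window_is_inclusive(self):
        """A pixel at 1 on every frame accumulates T~+1 (inclusive bounds)."""
        m = np.ones((4, 4, 10))
        mc = mapping.cumulative_map(m, 6)
        assert mc.shape[2] == 4
        np.testing.assert_allclose(mc, 7.0)

    def test_matches_direct_summation(self, rng):
        m = rng.uniform(0, 2, (12, 12, 15))
        t_tilde = 5
        mc = mapping.cumulative_map(m, t_tilde)
        for t in range(mc.shape[2]):
            np.testing.assert_allclose(
                mc[:, :, t], (m[:, :, t: t + t_tilde + 1] ** 2).sum(axis=2)
            )

    def test_window_must_fit(self):
        with pytest.raises(ConfigError):
            mapping.cumulative_map(np.zeros((4, 4, 5)), 5)


class TestObjects:
    def test_diagonal_touch_is_one_object(self):
        frame = np.zeros((6, 6))
        frame[2, 2] = frame[3, 3] = 1.0
        assert len(mapping.extract_objects(frame)) == 1

    def test_separated_disks_are_two_objects(self):
        frame = np.zeros((40, 40))
        frame[mapping.rasterize_disk((40, 40), 10, 10, 4)] = 2.0
        frame[mapping.rasterize_disk((40, 40), 30, 30, 4)] = 3.0
        objs = mapping.extract_objects(frame)
        assert len(objs) == 2
        assert sorted(o.mean_mc for o in objs) == [2.0, 3.0]

    def test_empty_frame_empty_set(self):
        assert mapping.extract_objects(np.zeros((10, 10))) == []

    def test_boundary_centroid_of_disk_is_center(self):
        frame = np.zeros((30, 30))
        frame[mapping.rasterize_disk((30, 30), 14, 12, 5)] = 1.0
        (obj,) = mapping.extract_objects(frame)
        assert obj.centroid == pytest.approx((14.0, 12.0), abs=0.1)


class TestPotential:
    def test_single_object_scores_zero(self):
        obj = DeathObject(label=1, pixels=np.zeros((1, 2)), mean_mc=5.0,
                          centroid=(3.0, 3.0))
        assert mapping.potential_of_death([obj], (100, 100)) == 0.0

    def test_hand_computed_two_object_value(self):
        """Means 2 and 4, centroid distance 100 px on a 100x100 frame
        (normalized distance 1.0) -> (1/4) * (2+4) / 1 = 1.5."""
        a = DeathObject(1, np.zeros((1, 2)), 2.0, (10.0, 10.0))
        b = DeathObject(2, np.zeros((1, 2)), 4.0, (70.0, 90.0))
        assert mapping.potential_of_death([a, b], (100, 100)) == pytest.approx(1.5)

    def test_translation_invariance(self, rng):
        objs = [DeathObject(i, np.zeros((1, 2)), float(m), (float(x), float(y)))
                for i, (m, x, y) in enumerate(rng.uniform(1, 50, (5, 3)))]
        shifted = [DeathObject(o.label, o.pixels, o.mean_mc,
                               (o.centroid[0] + 13.5, o.centroid[1] - 7.25))
                   for o in objs]
        assert mapping.potential_of_death(objs, (200, 200)) == pytest.approx(
            mapping.potential_of_death(shifted, (200, 200))
        )

    def test_doubling_distances_halves_potential(self, rng):
        pts = rng.uniform(10, 40, (4, 2))
        objs = [DeathObject(i, np.zeros((1, 2)), 2.0, tuple(p))
                for i, p in enumerate(pts)]
        doubled = [DeathObject(i, np.zeros((1, 2)), 2.0, tuple(2 * p))
                   for i, p in enumerate(pts)]
        p1 = mapping.potential_of_death(objs, (100, 100))
        p2 = mapping.potential_of_death(doubled, (100, 100))
        assert p2 == pytest.approx(p1 / 2)

    def test_coincident_centroids_skipped_not_infinite(self):
        a = DeathObject(1, np.zeros((1, 2)), 2.0, (10.0, 10.0))
        b = DeathObject(2, np.zeros((1, 2)), 4.0, (10.0, 10.0))
        assert np.isfinite(mapping.potential_of_death([a, b], (50, 50)))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_pipeline_equals_pixel_level_recomputation(self, seed):
        """Object-pipeline potential equals brute-force recomputation from
        raw pixel sets on random frames with <= 5 objects."""
        r = np.random.default_rng(seed)
        frame = random_object_frame(r)
        via_objects = mapping.potential_of_death(
            mapping.extract_objects(frame), frame.shape
        )
        assert via_objects == pytest.approx(brute_force_pdeath(frame))
        assert via_objects >= 0.0


class TestWindowedPdeath:
    CAL = Calibration(pixel_size_um=2.83)  # 283 um window -> 100 px

    def test_empty_map_zero_series(self):
        mc = np.zeros((200, 200, 4))
        out = mapping.windowed_pdeath(mc, self.CAL)
        assert (out.pdeath == 0).all()
        assert (out.n_windows == 0).all()

    def test_single_window_reduction(self):
        """All deaths inside one tile: the aggregate equals that tile's value."""
        mc = np.zeros((200, 200, 1))
        mc[:, :, 0][mapping.rasterize_disk((200, 200), 30, 30, 5)] = 2.0
        mc[:, :, 0][mapping.rasterize_disk((200, 200), 70, 60, 5)] = 3.0
        out = mapping.windowed_pdeath(mc, self.CAL)
        sub = mc[0:100, 0:100, 0]
        expected = mapping.potential_of_death(mapping.extract_objects(sub),
                                              (100, 100))
        assert out.pdeath.iloc[0] == pytest.approx(expected)
        assert out.n_windows.iloc[0] == 1

    def test_window_larger_than_frame_degrades_to_whole_frame(self):
        mc = np.zeros((50, 50, 1))
        mc[:, :, 0][mapping.rasterize_disk((50, 50), 10, 10, 3)] = 1.0
        mc[:, :, 0][mapping.rasterize_disk((50, 50), 40, 40, 3)] = 1.0
        out = mapping.windowed_pdeath(mc, self.CAL)
        expected = mapping.potential_of_death(
            mapping.extract_objects(mc[:, :, 0]), (50, 50)
        )
        assert out.pdeath.iloc[0] == pytest.approx(expected)

    def test_tiny_window_rejected(self):
        with pytest.raises(ConfigError):
            mapping.windowed_pdeath(np.zeros((50, 50, 1)),
                                    Calibration(pixel_size_um=100.0))

    def test_max_aggregate_bounds_mean(self, rng):
        mc = np.zeros((200, 200, 1))
        for _ in range(12):
            cx, cy = rng.uniform(10, 190, 2)
            mc[:, :, 0][mapping.rasterize_disk((200, 200), cx, cy, 4)] += 1.0
        mean_out = mapping.windowed_pdeath(mc, self.CAL, aggregate="mean")
        max_out = mapping.windowed_pdeath(mc, self.CAL, aggregate="max")
        assert max_out.pdeath.iloc[0] >= mean_out.pdeath.iloc[0]


class TestChains:
    def test_isolated_event_trivial_chain(self):
        chains = mapping.chain_of_death([event(10, 10, 5)], t_lag_frames=4)
        assert len(chains) == 1
        assert len(chains[0].members) == 1
        assert chains[0].induction_interval_h == 0.0

    def test_hand_simulated_chain(self):
        """Seed at t=5 plus in-radius events at t=8 and t=12 with T_LAG=4:
        one chain spanning 7 h."""
        events = [event(50, 50, 5, r=6, track_id=0),
                  event(60, 50, 8, r=6, track_id=1),
                  event(45, 55, 12, r=6, track_id=2)]
        chains = mapping.chain_of_death(events, t_lag_frames=4)
        seed_chain = next(c for c in chains if c.seed.track_id == 0)
        assert [m.track_id for m in seed_chain.members] == [0, 1, 2]
        assert seed_chain.induction_interval_h == pytest.approx(7.0)

    def test_time_gap_beyond_lag_excluded(self):
        events = [event(50, 50, 5, track_id=0), event(50, 50, 15, track_id=1)]
        chains = mapping.chain_of_death(events, t_lag_frames=4)
        seed_chain = next(c for c in chains if c.seed.track_id == 0)
        assert len(seed_chain.members) == 1

    def test_spatially_distant_event_excluded(self):
        events = [event(50, 50, 5, r=6, track_id=0),
                  event(150, 150, 7, r=6, track_id=1)]  # beyond 10 * 6 px
        chains = mapping.chain_of_death(events, t_lag_frames=4)
        seed_chain = next(c for c in chains if c.seed.track_id == 0)
        assert len(seed_chain.members) == 1

    def test_every_event_seeds_a_chain(self):
        events = [event(50, 50, 2, track_id=0), event(55, 50, 4, track_id=1)]
        chains = mapping.chain_of_death(events, t_lag_frames=4)
        assert {c.seed.track_id for c in chains} == {0, 1}
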