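"""Distance series, event extraction, state classification, corner enrichment."""

import itertools

import numpy as np
import pytest

import huddlekit as hk



def _rec_from_positions(pos, fps=30.0, valid=None):
    """pos: (4, n_frames, 2) -> GroupRecording."""
    pos = np.asarray(pos, float)
    n = pos.shape[1]
    trajs = [
        hk.Trajectory(f"m{a}", pos[a], np.ones(n, bool) if valid is None else valid[a], fps)
        for a in range(4)
    ]
    return hk.GroupRecording(trajs)


def _static(points, n_frames):
    return _rec_from_positions(np.repeat(np.asarray(points, float)[:, None, :], n_frames, axis=1))


class TestMinDyadic:
    def test_coincident_points_give_zero(self):
        rec = _static([[10, 10]] * 4, 5)
        assert np.all(hk.min_dyadic_series(rec) == 0)

    def test_three_four_five_geometry(self):
        rec = _static([[0, 0], [3, 4], [50, 50], [70, 70]], 3)
        np.testing.assert_allclose(hk.min_dyadic_series(rec), 5.0)

    def test_matches_exhaustive_pairs(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 76, size=(4, 500, 2))
        rec = _rec_from_positions(pos)
        got = hk.min_dyadic_series(rec)
        brute = np.min(
            [np.linalg.norm(pos[i] - pos[j], axis=1) for i, j in itertools.combinations(range(4), 2)],
            axis=0,
        )
        np.testing.assert_allclose(got, brute)

    def test_invalid_animal_frame_is_nan(self):
        pos = np.ones((4, 10, 2))
        valid = np.ones((4, 10), bool)
        valid[2, 4] = False
        rec = _rec_from_positions(pos, valid=valid)
        assert np.isnan(hk.min_dyadic_series(rec)[4])


class TestBinByMinute:
    def test_constant_series(self):
        out = hk.bin_by_minute(np.full(3600, 7.0), fps=30.0)
        assert len(out) == 2
        assert np.all(out["mean"] == 7.0)

    def test_two_minute_series_gives_two_bins(self):
        assert len(hk.bin_by_minute(np.zeros(120 * 30), fps=30.0)) == 2

    def test_ramp_mean_half(self):
        series = np.linspace(0, 1, 1800)
        out = hk.bin_by_minute(series, fps=30.0)
        assert out["mean"][0] == pytest.approx(0.5, abs=1 / 3600)


class TestExtractEvents:
    def test_never_below_threshold(self):
        assert hk.extract_events(np.full(1000, 10.0), 5.0, 60.0, 30.0) == []

    def test_single_long_run(self):
        ev = hk.extract_events(np.full(120 * 30, 1.0), 5.0, 60.0, 30.0)
        assert len(ev) == 1
        assert ev[0].duration == pytest.approx(120.0)

    def test_nan_breaks_runs(self):
        s = np.full(240 * 30, 1.0)
        s[110 * 30] = np.nan
        ev = hk.extract_events(s, 5.0, 60.0, 30.0)
        assert len(ev) == 2

    def test_exactly_at_threshold_is_outside(self):
        assert hk.extract_events(np.full(3600, 5.0), 5.0, 0.0, 30.0) == []


class TestThresholdSweep:
    def test_counts_nondecreasing_in_threshold(self):
        rng = np.random.default_rng(4)
        s = rng.uniform(0, 12, size=50_000)
        out = hk.threshold_sweep(s, [3, 5, 8], 0.5, 30.0)
        assert out["n_events"].is_monotonic_increasing or len(set(out["n_events"])) == 1

    def test_all_far_series(self):
        out = hk.threshold_sweep(np.full(1000, 10.0), [1, 5], 1.0, 30.0)
        assert list(out["n_events"]) == [0, 0]

    def test_matches_extract_events(self):
        rng = np.random.default_rng(5)
        s = rng.uniform(0, 10, size=20_000)
        out = hk.threshold_sweep(s, [2, 4, 6], 0.2, 30.0)
        for thr, n in zip(out["threshold_cm"], out["n_events"]):
            assert n == len(hk.extract_events(s, thr, 0.2, 30.0))


class TestClassifyStates:
    def test_all_far_is_none(self):
        rec = _static([[0, 0], [20, 0], [40, 0], [60, 0]], 100)
        states, events = hk.classify_state_series(rec)
        assert np.all(states == 0) and events == []

    def test_close_pair_two_minutes_is_one_dyad(self):
        n = 120 * 30
        rec = _static([[10, 10], [10, 14], [50, 50], [70, 20]], n)
        states, events = hk.classify_state_series(rec)
        assert np.all(states == 2)
        assert len(events) == 1
        assert events[0].state == 2 and set(events[0].members) == {0, 1}
        assert events[0].duration == pytest.approx(120.0)

    @pytest.mark.parametrize("side,expect_quartet", [(3.0, True), (3.6, False)])
    def test_square_quartet_rule_uses_animal_max_mean(self, side, expect_quartet):
        """Four mice on a square of side s: quartet iff the diagonal s*sqrt(2) < 5."""
        n = 90 * 30
        pts = [[10, 10], [10 + side, 10], [10, 10 + side], [10 + side, 10 + side]]
        rec = _static(pts, n)
        states, _ = hk.classify_state_series(rec)
        if expect_quartet:
            assert np.all(states == 4)
        else:
            assert not np.any(states == 4)
            assert np.all(states > 0)  # adjacent pairs still huddle

    def test_pair_top3_quartet_rule_differs(self):
        """side 3.3: top-3-pairs mean = (2 diagonals + side)/3 = 4.21 < 5 qualifies,
        while the per-animal-max mean = diagonal = 4.67 < 5 also qualifies; at 3.6
        only the top3 reading (5.09*2+3.6)/3 = 4.59 < 5 still does."""
        n = 70 * 30
        side = 3.6
        pts = [[10, 10], [10 + side, 10], [10, 10 + side], [10 + side, 10 + side]]
        rec = _static(pts, n)
        states_top3, _ = hk.classify_state_series(rec, hk.HuddleCriteria(quartet_rule="pair_top3"))
        states_amax, _ = hk.classify_state_series(rec)
        assert np.all(states_top3 == 4)
        assert not np.any(states_amax == 4)

    def test_short_quartet_blip_demotes_into_sustained_dyad(self):
        """A 10 s quartet excursion inside a 5 min dyad stays one dyad run."""
        n = 300 * 30
        pos = np.repeat(np.asarray([[10.0, 10], [10, 13], [40, 40], [40, 43]])[:, None, :], n, axis=1)
        blip = slice(150 * 30, 160 * 30)
        pos[2, blip] = [13.0, 10.0]
        pos[3, blip] = [13.0, 13.0]
        rec = _rec_from_positions(pos)
        states, _ = hk.classify_state_series(rec)
        assert not np.any(states == 4)
        assert np.all(states[: 150 * 30] == 2)

    def test_permutation_invariance_under_relabeling(self, impaired_hour):
        rec, _, states, _ = impaired_hour
        perm = [2, 0, 3, 1]
        rec2 = hk.GroupRecording(
            [rec.trajectories[p] for p in perm], arena=rec.arena, condition=rec.condition
        )
        states2, _ = hk.classify_state_series(rec2)
        np.testing.assert_array_equal(states, states2)

    def test_huddle_frames_imply_proximity(self, impaired_hour):
        rec, _, states, _ = impaired_hour
        md = hk.min_dyadic_series(rec)
        assert np.all(md[states > 0] < 5.0)

    def test_member_growth_links_parent_events(self, impaired_hour):
        _, _, _, events = impaired_hour
        children = [e for e in events if e.parent_id is not None]
        assert children, "growth should split events with parent links"
        by_id = {e.event_id: e for e in events}
        for c in children:
            assert by_id[c.parent_id].end_frame == c.start_frame


class TestHuddlingFraction:
    def test_all_none_gives_zero(self):
        rec = _static([[0, 0], [20, 0], [40, 0], [60, 0]], 1000)
        assert hk.huddling_fraction(rec) == 0.0

    def test_six_minute_dyad_in_hour_gives_tenth(self):
        n = 3600 * 30
        pos = np.repeat(np.asarray([[10.0, 10], [30, 10], [50, 10], [70, 10]])[:, None, :], n, axis=1)
        pos[1, : 360 * 30] = [13.0, 10.0]
        rec = _rec_from_positions(pos)
        assert hk.huddling_fraction(rec) == pytest.approx(0.1, abs=1e-6)

    def test_matches_ground_truth_fraction(self, impaired_hour):
        rec, gt, states, _ = impaired_hour
        frac = hk.huddling_fraction(rec, states=states)
        assert abs(frac - (gt.group_state > 0).mean()) <= 0.02

    def test_monotone_in_criteria(self, impaired_hour):
        rec, _, _, _ = impaired_hour
        f_tight = hk.huddling_fraction(rec, hk.HuddleCriteria(distance_threshold=3.0))
        f_mid = hk.huddling_fraction(rec, hk.HuddleCriteria(distance_threshold=5.0))
        f_loose = hk.huddling_fraction(rec, hk.HuddleCriteria(distance_threshold=8.0))
        assert f_tight <= f_mid <= f_loose
        f_long = hk.huddling_fraction(rec, hk.HuddleCriteria(min_duration=120.0))
        assert f_long <= f_mid


class TestCornerEnrichment:
    def _events(self, centroids, members=(0, 1)):
        return [
            hk.HuddleEvent(i, 2, tuple(members), 0, 1800, 30.0, tuple(c))
            for i, c in enumerate(centroids)
        ]

    def test_all_corner_centroids_give_proportion_one(self):
        evs = self._events([(5, 5), (70, 70), (5, 70)])
        out = hk.corner_enrichment({"r": evs})
        assert all(p == 1.0 for p in out["proportions"].values())

    def test_center_point_tie_rule(self):
        grid = hk.RegionGrid()
        assert grid.cell_class(76.2 / 2, 76.2 / 2) == "center"
        assert grid.cell_class(0.0, 0.0) == "corner"
        assert grid.cell_class(76.2, 76.2) == "corner"

    def test_uniform_centroids_near_quarter(self):
        rng = np.random.default_rng(8)
        n = 20_000
        centroids = rng.uniform(0, 76.2, size=(n, 2))
        out = hk.corner_enrichment({"r": self._events(centroids, members=(0, 1, 2, 3))})
        vals = list(out["proportions"].values())
        se = np.sqrt(0.25 * 0.75 / n)
        assert all(abs(v - 0.25) < 3 * se for v in vals)

    def test_mice_without_events_excluded(self):
        out = hk.corner_enrichment({"r": self._events([(5, 5)], members=(0, 1))})
        assert ("r", 2) in out["excluded"] and ("r", 3) in out["excluded"]
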