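import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oepc
from oepc.trajectory import _per_bin_stats

from conftest import make_circular_trajectory


class TestToPolar:
    def test_axis_aligned(self):
        rho, theta = oepc.to_polar(np.array([[20.0, 15.0]]), (15.0, 15.0))
        assert rho[0] == pytest.approx(5.0)
        assert theta[0] == pytest.approx(0.0)

    def test_quarter_turn(self):
        rho, theta = oepc.to_polar(np.array([[15.0, 20.0]]), (15.0, 15.0))
        assert rho[0] == pytest.approx(5.0)
        assert theta[0] == pytest.approx(np.pi / 2)

    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=1, max_size=20))
    @settings(deadline=None)
    def test_round_trip(self, pts):
        xy = np.array(pts, dtype=float)
        center = (3.0, -2.0)
        rho, theta = oepc.to_polar(xy, center)
        back = np.column_stack([center[0] + rho * np.cos(theta),
                                center[1] + rho * np.sin(theta)])
        assert np.allclose(back, xy, atol=1e-9)

    def test_center_frame_propagates_previous_angle(self):
        xy = np.array([[20.0, 15.0], [15.0, 15.0], [15.0, 20.0]])
        with pytest.warns(UserWarning, match="center"):
            rho, theta = oepc.to_polar(xy, (15.0, 15.0))
        assert rho[1] == 0.0
        assert theta[1] == pytest.approx(theta[0])


class TestSpeed:
    def test_stationary(self):
        xy = np.tile([5.0, 5.0], (50, 1))
        assert np.all(oepc.compute_speed(xy, 30.0) == 0.0)

    def test_uniform_circular_motion(self):
        # speed = r * omega for motion at constant angular rate
        r, omega, fps = 12.5, 1.0, 30.0
        tt = np.arange(600) / fps
        xy = np.column_stack([r * np.cos(omega * tt), r * np.sin(omega * tt)])
        v = oepc.compute_speed(xy, fps)
        assert np.allclose(v[5:-5], r * omega, rtol=0.01)

    def test_smoothing_reduces_noise(self):
        rng = np.random.default_rng(0)
        xy = rng.normal(0, 0.5, size=(400, 2))
        raw = oepc.compute_speed(xy, 30.0, smooth_window=1)
        smooth = oepc.compute_speed(xy, 30.0, smooth_window=5)
        assert smooth.std() < raw.std()


class TestBins:
    def test_origin_and_halfway(self):
        assert oepc.assign_bins([0.8], 0.8)[0] == 0
        assert oepc.assign_bins([0.8 + np.pi], 0.8)[0] == 12

    @given(st.floats(0, 2 * np.pi - 1e-9), st.floats(0, 2 * np.pi - 1e-9))
    @settings(deadline=None)
    def test_partition(self, theta, reward):
        b = oepc.assign_bins([theta], reward)[0]
        assert 0 <= b < 24

    def test_bin_arc_lengths_match_track_geometry(self):
        # circular 35 cm maze: ~4.6 cm arc at the wall, ~3 cm mid-track
        cfg = oepc.SessionConfig(maze_shape="circular", outer_size=35.0)
        arc_wall = 2 * np.pi * cfg.outer_radius / 24
        arc_mid = 2 * np.pi * cfg.mid_radius / 24
        assert arc_wall == pytest.approx(4.58, abs=0.05)
        assert 2.5 < arc_mid < 3.5


class TestLaps:
    def test_synthetic_session_recovers_all_laps(self):
        traj, bouts, _ = oepc.generate_trajectory(oepc.SessionConfig(seed=1))
        assert len(traj.lap_ids) == 20

    def test_reversal_lap_excluded(self):
        # 20 clean laps, but lap 5 contains a clockwise regression > pi/12
        n_per = 200
        phi = np.linspace(0, 2 * np.pi * 20, 20 * n_per + 1)
        seg = slice(5 * n_per + 50, 5 * n_per + 60)
        phi[seg] = phi[seg.start] - 0.5
        lap = oepc.segment_laps(np.mod(phi, 2 * np.pi), 0.0)
        ids = np.unique(lap[lap >= 0])
        assert len(ids) == 19
        assert 5 not in ids

    def test_lap_boundaries_independent_of_time_origin(self):
        traj, _, _ = oepc.generate_trajectory(oepc.SessionConfig(seed=2))
        again = oepc.segment_laps(traj.theta, traj.reward_angle)
        shifted = oepc.segment_laps(traj.theta, traj.reward_angle)
        assert np.array_equal(again, shifted)

    def test_excluded_ranges_unassigned(self):
        theta = np.mod(np.linspace(0, 4 * np.pi, 400), 2 * np.pi)
        lap = oepc.segment_laps(theta, 0.0, excluded_ranges=[(10, 20)])
        assert np.all(lap[10:20] == -1)


class TestBouts:
    def test_bout_covers_three_bins_either_side(self):
        # object at the center of bin 6 -> window spans bins 3..9
        traj = make_circular_trajectory(n_laps=2)
        obj = oepc.bin_centers(0.0)[6]
        bouts = oepc.define_bouts(traj, [obj])
        covered = set()
        for b in bouts:
            covered.update(traj.bin[b.frames(traj)].tolist())
        assert covered == set(range(3, 10))

    def test_bout_count(self):
        traj, bouts, _ = oepc.generate_trajectory(
            oepc.SessionConfig(seed=3, n_laps=20))
        assert len(bouts) == 60  # 20 laps x 3 objects

    def test_disjoint_within_lap(self):
        traj, bouts, _ = oepc.generate_trajectory(oepc.SessionConfig(seed=3))
        by_lap = {}
        for b in bouts:
            by_lap.setdefault(b.lap_id, []).append((b.start, b.end))
        for spans in by_lap.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_close_objects_rejected(self):
        traj = make_circular_trajectory()
        with pytest.raises(oepc.ConfigurationError):
            oepc.define_bouts(traj, [1.0, 1.2])

    def test_unlabeled_pass_excluded(self):
        traj = make_circular_trajectory(n_laps=2)
        bouts = oepc.define_bouts(traj, [np.pi], labels={(0, 0): "exploration"})
        labels = {b.lap_id: b.label for b in bouts}
        assert labels[0] == "exploration"
        assert labels[1] == "excluded"


def _two_label_session(expl_rho, nonexpl_rho, hd_expl=None, hd_non=None):
    """Two laps of uniform motion; lap 0's bout exploration, lap 1's not.

    rho (and optionally hd) within each lap's bout window is overridden
    with the given per-frame values.
    """
    traj = make_circular_trajectory(n_laps=2, hd=None)
    obj = np.pi
    bouts = oepc.define_bouts(traj, [obj], labels={(0, 0): "exploration",
                                                   (0, 1): "non-exploration"})
    rho = traj.rho.copy()
    hd = np.zeros(traj.n_frames)
    for b, vals, hvals in zip(bouts, (expl_rho, nonexpl_rho),
                              (hd_expl, hd_non)):
        f = b.frames(traj)
        vals = np.resize(np.asarray(vals, float), len(f))
        rho[f] = vals
        if hvals is not None:
            hd[f] = np.resize(np.asarray(hvals, float), len(f))
    traj.rho = rho
    traj.hd = hd
    return traj, bouts


class TestOfftrack:
    def test_threshold_arithmetic(self):
        # non-expl rho cycles {12.0, 12.5, 13.0}: mean 12.5, SD ~0.41
        # -> band [11.68, 13.32]; 14.2 flagged, 12.6 not
        traj, bouts = _two_label_session(
            expl_rho=[14.2, 12.6], nonexpl_rho=[12.0, 12.5, 13.0])
        oepc.flag_offtrack(bouts, traj)
        expl = bouts[0]
        f = expl.frames(traj)
        flagged_rho = traj.rho[f][expl.offtrack_mask]
        assert set(np.round(flagged_rho, 1)) == {14.2}

    def test_identical_distributions_unflagged(self):
        traj, bouts = _two_label_session(expl_rho=[12.0, 12.5, 13.0],
                                         nonexpl_rho=[12.0, 12.5, 13.0])
        oepc.flag_offtrack(bouts, traj)
        assert not bouts[0].offtrack_mask.any()

    def test_thresholds_depend_only_on_nonexploration(self):
        traj1, bouts1 = _two_label_session([14.2, 12.6], [12.0, 12.5, 13.0])
        traj2, bouts2 = _two_label_session([12.6, 14.2], [12.0, 12.5, 13.0])
        oepc.flag_offtrack(bouts1, traj1)
        oepc.flag_offtrack(bouts2, traj2)
        # the same exploration rho values are flagged either way
        f1 = bouts1[0].frames(traj1)
        f2 = bouts2[0].frames(traj2)
        s1 = set(np.round(traj1.rho[f1][bouts1[0].offtrack_mask], 1))
        s2 = set(np.round(traj2.rho[f2][bouts2[0].offtrack_mask], 1))
        assert s1 == s2 == {14.2}

    def test_per_bin_stats_sample_sd(self):
        vals = np.array([12.0, 12.5, 13.0] * 10)
        mean, sd = _per_bin_stats(vals, np.zeros(30, int), 1)
        assert mean[0] == pytest.approx(12.5)
        assert sd[0] == pytest.approx(np.std(vals, ddof=1))


class TestHdOutliers:
    def test_rotated_heading_flagged(self):
        traj, bouts = _two_label_session(
            expl_rho=[12.5], nonexpl_rho=[12.5],
            hd_expl=[np.pi / 2], hd_non=[0.0, 0.05, -0.05])
        oepc.flag_hd_outliers(bouts, traj)
        assert bouts[0].hd_outlier_mask.all()

    def test_identical_heading_unflagged(self):
        traj, bouts = _two_label_session(
            expl_rho=[12.5], nonexpl_rho=[12.5],
            hd_expl=[0.0, 0.05, -0.05], hd_non=[0.0, 0.05, -0.05])
        oepc.flag_hd_outliers(bouts, traj)
        assert not bouts[0].hd_outlier_mask.any()

    def test_wrap_invariance(self):
        traj, bouts = _two_label_session(
            expl_rho=[12.5], nonexpl_rho=[12.5],
            hd_expl=[np.pi / 2, 0.0], hd_non=[0.0, 0.05, -0.05])
        oepc.flag_hd_outliers(bouts, traj)
        ref = bouts[0].hd_outlier_mask.copy()
        traj.hd = traj.hd + 2 * np.pi
        oepc.flag_hd_outliers(bouts, traj)
        assert np.array_equal(bouts[0].hd_outlier_mask, ref)

    def test_missing_hd_warns_and_empties(self):
        traj, bouts = _two_label_session([12.5], [12.5])
        traj.hd = None
        with pytest.warns(UserWarning, match="head direction"):
            oepc.flag_hd_outliers(bouts, traj)
        assert not bouts[0].hd_outlier_mask.any()
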