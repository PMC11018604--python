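import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oepc

from conftest import make_circular_trajectory

UNIFORM_P = np.full(24, 1 / 24)


class TestSpatialInformation:
    def test_uniform_rate_is_zero_bits(self):
        assert oepc.spatial_information(UNIFORM_P, np.full(24, 3.0)) == 0.0

    def test_single_bin_is_log2_nbins(self):
        r = np.zeros(24)
        r[5] = 7.0
        si = oepc.spatial_information(UNIFORM_P, r)
        assert si == pytest.approx(np.log2(24))

    def test_two_bins_is_log2_half_nbins(self):
        r = np.zeros(24)
        r[3] = r[17] = 7.0
        si = oepc.spatial_information(UNIFORM_P, r)
        assert si == pytest.approx(np.log2(12))

    def test_zero_rate_undefined(self):
        assert np.isnan(oepc.spatial_information(UNIFORM_P, np.zeros(24)))

    @given(st.lists(st.floats(0, 100, allow_subnormal=False),
                    min_size=4, max_size=24),
           st.floats(0.01, 1000))
    @settings(deadline=None)
    def test_nonnegative_and_scale_invariant(self, rates, scale):
        r = np.array(rates)
        p = np.full(len(r), 1 / len(r))
        si = oepc.spatial_information(p, r)
        if np.isnan(si):
            assert r.sum() == 0
            return
        assert si >= -1e-12
        assert oepc.spatial_information(p, scale * r) == pytest.approx(
            si, rel=1e-6, abs=1e-9)

    def test_zero_iff_constant_on_occupied_bins(self):
        r = np.full(24, 2.0)
        assert oepc.spatial_information(UNIFORM_P, r) == 0.0
        r[4] = 2.5
        assert oepc.spatial_information(UNIFORM_P, r) > 0.0


class TestTuningCurve:
    def test_constant_activity(self):
        traj = make_circular_trajectory(n_laps=3)
        c = oepc.tuning_curve(np.full(traj.n_frames, 2.5), traj)
        assert np.allclose(c.mean_rate_per_bin, 2.5)
        assert c.overall_mean == pytest.approx(2.5)
        assert c.occupancy_p.sum() == pytest.approx(1.0)

    def test_single_bin_support(self):
        traj = make_circular_trajectory(n_laps=3)
        a = np.where(traj.bin == 5, 4.0, 0.0)
        c = oepc.tuning_curve(a, traj)
        assert c.mean_rate_per_bin[5] > 0
        others = np.delete(np.nan_to_num(c.mean_rate_per_bin), 5)
        assert np.all(others == 0)

    def test_rate_invariant_to_frame_rate(self):
        # doubling the sampling rate (repeating every frame) leaves the
        # per-bin mean rates unchanged: they are rates, not sums
        traj = make_circular_trajectory(n_laps=2)
        a = np.where(traj.bin == 7, 3.0, 1.0)
        c1 = oepc.tuning_curve(a, traj)
        traj2 = make_circular_trajectory(n_laps=2, frames_per_lap=480)
        a2 = np.where(traj2.bin == 7, 3.0, 1.0)
        c2 = oepc.tuning_curve(a2, traj2)
        assert np.allclose(np.nan_to_num(c1.mean_rate_per_bin),
                           np.nan_to_num(c2.mean_rate_per_bin), atol=1e-9)

    def test_all_zero_cell_valid(self):
        traj = make_circular_trajectory(n_laps=2)
        c = oepc.tuning_curve(np.zeros(traj.n_frames), traj)
        assert np.all(np.nan_to_num(c.mean_rate_per_bin) == 0)


class TestSiZscore:
    def test_sharply_tuned_cell_significant(self):
        traj = make_circular_trajectory(n_laps=5)
        rng = np.random.default_rng(1)
        a = np.where(traj.bin == 8, 5.0, 0.0) * rng.random(traj.n_frames)
        si, z, _ = oepc.si_zscore(a, traj, 100, np.random.default_rng(2))
        assert z >= 1.65

    def test_scale_invariance(self):
        traj = make_circular_trajectory(n_laps=5)
        rng = np.random.default_rng(3)
        a = rng.poisson(0.2, traj.n_frames).astype(float)
        si1, z1, _ = oepc.si_zscore(a, traj, 50, np.random.default_rng(4))
        si2, z2, _ = oepc.si_zscore(3.7 * a, traj, 50,
                                    np.random.default_rng(4))
        assert z2 == pytest.approx(z1, abs=1e-9)
        assert si2 == pytest.approx(si1, abs=1e-9)

    def test_constant_activity_undefined(self):
        traj = make_circular_trajectory(n_laps=3)
        si, z, _ = oepc.si_zscore(np.full(traj.n_frames, 1.0), traj, 20,
                                  np.random.default_rng(5))
        assert np.isnan(z)

    def test_threshold_boundary(self):
        assert oepc.classify_place_cell(1.65)
        assert not oepc.classify_place_cell(1.64999)
        assert not oepc.classify_place_cell(np.nan)


class TestPlaceFields:
    def test_contiguous_field(self):
        a = np.zeros(24)
        a[10:13] = [5, 10, 5]
        a[9] = a[13] = 1.0  # below the 20% threshold (2.0)
        fields = oepc.detect_place_fields(a)
        assert len(fields) == 1
        assert sorted(fields[0].bins) == [10, 11, 12]
        assert fields[0].peak_bin == 11

    def test_wrapped_field(self):
        a = np.zeros(24)
        a[23] = a[0] = 10.0
        fields = oepc.detect_place_fields(a)
        assert len(fields) == 1
        assert set(fields[0].bins) == {23, 0}

    def test_uniform_positive_single_field(self):
        fields = oepc.detect_place_fields(np.full(24, 3.0))
        assert len(fields) == 1
        assert len(fields[0].bins) == 24

    def test_all_zero_no_fields(self):
        assert oepc.detect_place_fields(np.zeros(24)) == []

    @given(st.lists(st.floats(0, 10), min_size=24, max_size=24))
    @settings(deadline=None)
    def test_fields_partition_suprathreshold_bins(self, vals):
        a = np.array(vals)
        fields = oepc.detect_place_fields(a)
        covered = [b for f in fields for b in f.bins]
        assert len(covered) == len(set(covered))
        if a.max() > 0:
            assert set(covered) == set(np.where(a > 0.2 * a.max())[0])


class TestCom:
    def test_symmetric_curve(self):
        centers = oepc.bin_centers(0.0)
        a = np.exp(-oepc.utils.circdiff(centers, centers[6]) ** 2 / 0.2)
        com = oepc.compute_com(a)
        assert com == pytest.approx(centers[6], abs=1e-6)

    def test_single_dominant_bin_limit(self):
        centers = oepc.bin_centers(0.0)
        a = np.full(24, 1e-9)
        a[4] = 10.0
        com = oepc.compute_com(a)
        assert com == pytest.approx(centers[4], abs=1e-3)

    def test_matches_independent_shoelace_oracle(self):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import Polygon
        centers = oepc.bin_centers(0.0)
        a = np.full(24, 0.5)
        a[7:10] = [2.0, 10.0, 4.0]
        com = oepc.compute_com(a)
        pts = [(r * np.cos(th), r * np.sin(th)) for r, th in zip(a, centers)]
        cen = Polygon(pts).centroid
        expected = np.mod(np.arctan2(cen.y, cen.x), 2 * np.pi)
        assert com == pytest.approx(expected, abs=1e-9)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(6)
        a = rng.random(24) + 0.1
        com = oepc.compute_com(a)
        for k in (1, 5, 11):
            rot = oepc.compute_com(np.roll(a, k))
            expected = np.mod(com + k * 2 * np.pi / 24, 2 * np.pi)
            assert rot == pytest.approx(expected, abs=1e-9)

    def test_degenerate_polygon_falls_back(self):
        a = np.zeros(24)
        a[3] = 5.0
        with pytest.warns(UserWarning, match="degenerate"):
            com = oepc.compute_com(a)
        assert com == pytest.approx(oepc.bin_centers(0.0)[3], abs=1e-9)

    def test_delta_com_is_circular(self):
        assert oepc.delta_com(0.1, 2 * np.pi - 0.1) == pytest.approx(0.2)


class TestSpatialCorrelation:
    def test_identity(self):
        v = np.sin(np.linspace(0, 2 * np.pi, 24)) + 2
        r, pct = oepc.spatial_correlation(v, v, rng=0)
        assert r == pytest.approx(1.0)
        assert pct > 0.9

    def test_antialigned_bump(self):
        v = np.exp(-((np.arange(24) - 6) ** 2) / 4)
        r, _ = oepc.spatial_correlation(v, np.roll(v, 12), rng=0)
        assert r < 0

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a, b = rng.random(24), rng.random(24)
        ra, _ = oepc.spatial_correlation(a, b, rng=1)
        rb, _ = oepc.spatial_correlation(b, a, rng=1)
        assert ra == pytest.approx(rb)

    def test_zero_variance_undefined(self):
        r, pct = oepc.spatial_correlation(np.full(24, 2.0),
                                          np.arange(24.0), rng=0)
        assert np.isnan(r)
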