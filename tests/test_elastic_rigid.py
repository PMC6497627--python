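import numpy as np
import pytest

from vmamct import (
    AngleGrid,
    MarkerTrajectory,
    Sinogram,
    TrajectoryFit,
    WarpedRows,
    convert_elliptic,
    convert_regular,
    estimate_scale_elliptic,
    estimate_scale_regular,
    make_scale_series,
    resample_angles,
    select_periodic,
    warped_angle,
)
from vmamct.simulate import exact_marker_positions

from .conftest import rel_l2


class TestConvertRegular:
    def test_unit_scales_identity(self, small_scene):
        sino = small_scene.elastic[2]
        m = make_scale_series("regular", 0.0, n_angles=sino.n_angles)
        out = convert_regular(sino, m, small_scene.center_fits[2])
        assert np.array_equal(out.data, sino.data)

    def test_round_trip_recovers_rigid_reference(self, small_scene, small_refs):
        out = convert_regular(
            small_scene.elastic[2], small_scene.motions[2], small_scene.center_fits[2]
        )
        assert rel_l2(out.data, small_refs[2].data) < 0.03

    def test_per_row_mass_preserved(self, small_scene):
        sino = small_scene.elastic[2]
        out = convert_regular(sino, small_scene.motions[2], small_scene.center_fits[2])
        assert np.allclose(out.row_mass(), sino.row_mass(), rtol=0.005)

    def test_anisotropic_scales_rejected(self, small_scene):
        with pytest.raises(ValueError, match="isotropic"):
            convert_regular(small_scene.elastic[1], small_scene.motions[1])

    def test_nonpositive_scale_rejected(self, small_scene):
        from vmamct import ScaleSeries

        n = small_scene.elastic[2].n_angles
        bad = ScaleSeries(np.full(n, -1.0), np.full(n, -1.0), np.zeros(n, bool))
        with pytest.raises(ValueError):
            convert_regular(small_scene.elastic[2], bad)


class TestConvertElliptic:
    def test_round_trip_recovers_rigid_reference(self, small_scene, small_refs):
        wr = convert_elliptic(
            small_scene.elastic[1], small_scene.motions[1], small_scene.center_fits[1]
        )
        out = resample_angles(wr, small_scene.grid, out_of_range="clamp")
        assert rel_l2(out.data, small_refs[1].data) < 0.03

    def test_isotropic_limit_reduces_to_regular(self, small_scene):
        sino = small_scene.elastic[2]
        m = small_scene.motions[2]
        wr = convert_elliptic(sino, m, small_scene.center_fits[2])
        reg = convert_regular(sino, m, small_scene.center_fits[2])
        assert np.allclose(wr.warped_angles, sino.angle_grid.angles, atol=1e-9)
        assert np.allclose(wr.rows, reg.data, atol=1e-9)

    def test_per_row_mass_preserved(self, small_scene):
        sino = small_scene.elastic[1]
        wr = convert_elliptic(sino, small_scene.motions[1], small_scene.center_fits[1])
        assert np.allclose(wr.rows.sum(axis=1), sino.row_mass(), rtol=0.005)


class TestWarpedAngle:
    def test_closed_form_arctangent(self):
        assert warped_angle(45.0, 2.0, 1.0, 0.0) == pytest.approx(
            np.degrees(np.arctan(0.5)), abs=1e-9
        )

    def test_pure_minor_axis_view_unchanged(self):
        assert warped_angle(90.0, 2.0, 1.0, 0.0) == pytest.approx(90.0, abs=1e-9)

    def test_warp_is_increasing_for_slow_scale_drift(self, small_scene):
        m = small_scene.motions[1]
        thp = warped_angle(small_scene.grid.angles, m.a, m.b, m.axis_angle_deg)
        assert np.all(np.diff(thp) > 0)


class TestResampleAngles:
    def test_identity_when_grids_match(self):
        grid = AngleGrid.uniform(50, 3.0)
        rows = np.random.default_rng(0).uniform(0, 1, (50, 32))
        out = resample_angles(WarpedRows(rows, grid.angles), grid)
        assert np.allclose(out.data, rows)

    def test_non_monotone_warped_angles_rejected(self):
        wa = np.array([0.0, 2.0, 1.0, 3.0])
        with pytest.raises(ValueError, match="increasing"):
            resample_angles(WarpedRows(np.zeros((4, 8)), wa), AngleGrid.uniform(4, 1.0))

    def test_out_of_range_target_rejected_by_default(self):
        wa = np.array([1.0, 2.0, 3.0])
        wr = WarpedRows(np.zeros((3, 8)), wa)
        with pytest.raises(ValueError, match="exceed"):
            resample_angles(wr, AngleGrid.uniform(3, 1.0))  # starts at 0 < 1
        resample_angles(wr, AngleGrid.uniform(3, 1.0), out_of_range="clamp")

    def test_smooth_data_resampled_from_perturbed_grid(self):
        grid = AngleGrid.uniform(180, 1.0)
        rng = np.random.default_rng(1)
        warped = grid.angles + np.concatenate([[0], rng.uniform(0, 0.4, 178), [0]])
        t = np.arange(64)
        truth = lambda th: np.outer(np.cos(np.radians(th)), np.ones(64)) * np.sin(t / 9)
        out = resample_angles(WarpedRows(truth(warped), warped), grid)
        assert rel_l2(out.data, truth(grid.angles)) < 0.01


class TestSelectPeriodic:
    @pytest.mark.parametrize(
        "n,P,expected_len", [(1200, 8, 150), (10, 1, 10), (10, 3, 4)]
    )
    def test_index_arithmetic(self, n, P, expected_len):
        idx = select_periodic(n, P)
        assert len(idx) == expected_len
        assert np.all(idx % P == 0)

    def test_explicit_small_case(self):
        assert select_periodic(10, 3).tolist() == [0, 3, 6, 9]

    def test_invalid_period_rejected(self):
        with pytest.raises(ValueError):
            select_periodic(10, 0)


def _exact_trajs(scene, label):
    mks = [m for m in scene.phantom.markers if m.section == label]
    W = scene.phantom.shape[1]
    n = len(scene.grid)
    return mks, [
        MarkerTrajectory(
            exact_marker_positions(m, scene.motions[label], scene.grid, W),
            np.ones(n, bool),
        )
        for m in mks
    ]


def _sep_fit(m1, m2):
    return TrajectoryFit(
        0.0,
        float(np.hypot(m1.col - m2.col, m1.row - m2.row)),
        float(np.degrees(np.arctan2(-(m1.row - m2.row), m1.col - m2.col))),
    )


class TestScaleEstimation:
    def test_rigid_input_gives_unit_scales(self):
        grid = AngleGrid.uniform(360, 0.5)
        from vmamct import trajectory_value

        u1 = 64 + trajectory_value(20.0, 0.0, grid.angles)
        u2 = 64 + trajectory_value(20.0, 180.0, grid.angles)
        valid = np.ones(len(grid), bool)
        ref = TrajectoryFit(0.0, 40.0, 0.0)
        ss = estimate_scale_regular(
            MarkerTrajectory(u1, valid), MarkerTrajectory(u2, valid), ref, grid
        )
        assert np.allclose(ss.a, 1.0, atol=0.01)

    def test_noiseless_regular_recovery_exact(self, small_scene):
        mks, trajs = _exact_trajs(small_scene, 2)
        ss = estimate_scale_regular(trajs[0], trajs[1], _sep_fit(*mks), small_scene.grid)
        truth = small_scene.motions[2].a
        assert np.max(np.abs(ss.a[ss.valid] - truth[ss.valid])) < 1e-9

    def test_singular_angles_masked(self, small_scene):
        """The pair separation vanishes where the marker line is parallel
        to the beam; those angles must be flagged invalid."""
        mks, trajs = _exact_trajs(small_scene, 2)
        ss = estimate_scale_regular(trajs[0], trajs[1], _sep_fit(*mks), small_scene.grid)
        ref = _sep_fit(*mks)
        cosine = np.cos(np.radians(small_scene.grid.angles - ref.phi_deg))
        assert not ss.valid[np.abs(cosine) < 0.19].any()
        assert ss.valid[np.abs(cosine) > 0.21].all()

    def test_noiseless_elliptic_recovery_exact(self, small_scene):
        mks, trajs = _exact_trajs(small_scene, 1)
        ss = estimate_scale_elliptic(
            (trajs[0], trajs[1]),
            (trajs[2], trajs[3]),
            _sep_fit(mks[0], mks[1]),
            _sep_fit(mks[2], mks[3]),
            small_scene.grid,
        )
        m = small_scene.motions[1]
        assert np.max(np.abs(ss.a[ss.valid] - m.a[ss.valid])) < 1e-9
        assert np.max(np.abs(ss.b[ss.valid] - m.b[ss.valid])) < 1e-9

    def test_unequal_rates_drift_apart(self, small_scene):
        mks, trajs = _exact_trajs(small_scene, 1)
        ss = estimate_scale_elliptic(
            (trajs[0], trajs[1]),
            (trajs[2], trajs[3]),
            _sep_fit(mks[0], mks[1]),
            _sep_fit(mks[2], mks[3]),
            small_scene.grid,
        )
        ratio = ss.a / ss.b
        assert ratio[-1] < ratio[0] - 0.05  # major contracts faster

    def test_zero_reference_amplitude_rejected(self):
        grid = AngleGrid.uniform(10, 10.0)
        t = MarkerTrajectory(np.zeros(10), np.ones(10, bool))
        with pytest.raises(ValueError):
            estimate_scale_regular(t, t, TrajectoryFit(0.0, 0.0, 0.0), grid)
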