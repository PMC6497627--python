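import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vmamct import (
    AngleGrid,
    MarkerTrajectory,
    Sinogram,
    TrackingError,
    TrajectoryFit,
    center_cor,
    fit_trajectory,
    track_marker,
    trajectory_value,
    zero_crossing_angle,
)

GRID = AngleGrid.uniform(1200, 0.15)


class TestTrajectoryValue:
    @pytest.mark.parametrize(
        "r,phi,theta,expected",
        [(0.0, 123.0, 45.0, 0.0), (5.0, 30.0, 30.0, 5.0), (2.0, 60.0, 0.0, 1.0)],
    )
    def test_closed_form(self, r, phi, theta, expected):
        assert trajectory_value(r, phi, theta) == pytest.approx(expected, abs=1e-12)


class TestFitTrajectory:
    def test_noiseless_recovery_to_six_digits(self):
        c, r, phi = 5.0, 10.0, 30.0
        u = c + trajectory_value(r, phi, GRID.angles)
        fit = fit_trajectory(MarkerTrajectory(u, np.ones(len(GRID), bool)), GRID)
        assert fit.c == pytest.approx(c, rel=1e-9)
        assert fit.r == pytest.approx(r, rel=1e-9)
        assert fit.phi_deg == pytest.approx(phi, abs=1e-6)
        assert fit.rms_residual < 1e-9

    def test_constant_trajectory_gives_zero_amplitude(self):
        u = np.full(len(GRID), 7.0)
        fit = fit_trajectory(MarkerTrajectory(u, np.ones(len(GRID), bool)), GRID)
        assert fit.c == pytest.approx(7.0)
        assert fit.r == pytest.approx(0.0, abs=1e-9)

    def test_minimum_at_156_deg_means_phase_minus_24(self):
        """A sinusoid r·cos(θ−φ) has its minimum at φ+180°; a trajectory
        bottoming out at 156° therefore has φ ≡ −24° (mod 360°)."""
        u = 50 + trajectory_value(12.0, 156.0 - 180.0, GRID.angles)
        fit = fit_trajectory(MarkerTrajectory(u, np.ones(len(GRID), bool)), GRID)
        assert fit.phi_deg == pytest.approx(336.0, abs=1e-6)

    def test_invalid_samples_excluded(self):
        u = 5 + trajectory_value(3.0, 10.0, GRID.angles)
        valid = np.ones(len(GRID), bool)
        u[100:200] = 999.0
        valid[100:200] = False
        fit = fit_trajectory(MarkerTrajectory(u, valid), GRID)
        assert fit.r == pytest.approx(3.0, rel=1e-9)

    def test_too_few_distinct_angles_rejected(self):
        grid = AngleGrid(np.array([10.0, 20.0, 30.0]))
        traj = MarkerTrajectory(np.array([1.0, 2.0, 3.0]), np.array([True, True, False]))
        with pytest.raises(ValueError):
            fit_trajectory(traj, grid)

    @settings(max_examples=40, deadline=None)
    @given(
        c=st.floats(-50, 50),
        r=st.floats(0, 40),
        phi=st.floats(0, 360, exclude_max=True),
    )
    def test_exact_recovery_property(self, c, r, phi):
        u = c + trajectory_value(r, phi, GRID.angles)
        fit = fit_trajectory(MarkerTrajectory(u, np.ones(len(GRID), bool)), GRID)
        assert fit.c == pytest.approx(c, abs=1e-7)
        assert fit.r == pytest.approx(r, abs=1e-7)
        if r > 1e-6:
            assert abs((fit.phi_deg - phi + 180) % 360 - 180) < 1e-5


class TestZeroCrossing:
    @pytest.mark.parametrize(
        "min_angle,expected", [(156.0, 66.0), (172.0, 82.0), (180.0, 90.0)]
    )
    def test_crossing_from_minimum(self, min_angle, expected):
        fit = TrajectoryFit(c=0.0, r=5.0, phi_deg=min_angle - 180.0)
        assert zero_crossing_angle(fit) == pytest.approx(expected, abs=1e-9)

    def test_zero_amplitude_undefined(self):
        with pytest.raises(ValueError):
            zero_crossing_angle(TrajectoryFit(0.0, 0.0, 0.0))

    @settings(max_examples=40, deadline=None)
    @given(phi=st.floats(0, 360, exclude_max=True))
    def test_crossing_is_minimum_minus_90_mod_180(self, phi):
        fit = TrajectoryFit(0.0, 1.0, phi)
        min_angle = (phi + 180.0) % 360.0
        assert zero_crossing_angle(fit) == pytest.approx(
            (min_angle - 90.0) % 180.0, abs=1e-9
        )


def _gauss_sino(grid, u_true, W=128, sigma=2.0, amp=10.0):
    t = np.arange(W)
    data = amp * np.exp(-((t[None, :] - u_true[:, None]) ** 2) / (2 * sigma**2))
    return Sinogram(data, grid)


class TestTrackMarker:
    def test_gaussian_blob_recovered_within_tenth_pixel(self):
        grid = AngleGrid.uniform(360, 0.5)
        u_true = 64 + trajectory_value(20.0, 40.0, grid.angles)
        traj = track_marker(_gauss_sino(grid, u_true), (71, 87))
        assert traj.valid.all()
        assert np.max(np.abs(traj.u - u_true)) < 0.1

    def test_two_separated_markers_tracked_independently(self):
        grid = AngleGrid.uniform(180, 1.0)
        u1 = 30 + trajectory_value(5.0, 0.0, grid.angles)
        u2 = 100 + trajectory_value(5.0, 90.0, grid.angles)
        s1, s2 = _gauss_sino(grid, u1), _gauss_sino(grid, u2)
        both = Sinogram(s1.data + s2.data, grid)
        t1 = track_marker(both, (28, 42), half_width=10)
        t2 = track_marker(both, (93, 107), half_width=10)
        assert np.max(np.abs(t1.u - u1)) < 0.1
        assert np.max(np.abs(t2.u - u2)) < 0.1

    def test_all_zero_sinogram_reports_failure(self):
        sino = Sinogram(np.zeros((100, 64)), AngleGrid.uniform(100, 1.0))
        with pytest.raises(TrackingError):
            track_marker(sino, (20, 40))

    def test_empty_seed_window_rejected(self):
        sino = Sinogram(np.ones((10, 64)), AngleGrid.uniform(10, 1.0))
        with pytest.raises(ValueError):
            track_marker(sino, (40, 20))


class TestCenterCor:
    def _sino(self, W, n=10):
        rng = np.random.default_rng(0)
        return Sinogram(rng.uniform(1, 2, (n, W)), AngleGrid.uniform(n, 1.0))

    def test_pad_low_side(self):
        out = center_cor(self._sino(101), 45.0)
        assert out.width == 111
        assert out.cor_col == pytest.approx(55.0)
        assert out.cor_col == pytest.approx(out.center_col)

    def test_already_centered_unchanged(self):
        sino = self._sino(101)
        out = center_cor(sino, 50.0)
        assert np.array_equal(out.data, sino.data)

    def test_detector_1340_cor_661_pads_17(self):
        out = center_cor(self._sino(1340, n=4), 661.0)
        assert out.width == 1340 + 17
        assert np.all(out.data[:, :17] == 0)

    def test_pad_high_side_for_cor_past_center(self):
        out = center_cor(self._sino(101), 55.0)
        assert out.width == 111
        assert np.all(out.data[:, -10:] == 0)

    def test_mass_and_values_preserved(self):
        sino = self._sino(101)
        out = center_cor(sino, 40.0)
        assert out.row_mass() == pytest.approx(sino.row_mass())
        assert np.array_equal(np.sort(out.data[out.data > 0]), np.sort(sino.data[sino.data > 0]))

    def test_out_of_range_cor_rejected(self):
        with pytest.raises(ValueError):
            center_cor(self._sino(101), 101.0)
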