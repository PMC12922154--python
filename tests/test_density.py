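"""Direction and joint KDEs against brute-force oracles, plus histograms."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from saccadekde import (
    AmplitudeUnit,
    Normalization,
    ValidationError,
    amplitude_bandwidth,
    bin_center_polyline,
    classify_orientation,
    histogram_direction,
    kde_direction,
    kde_direction_gaussian,
    kde_joint_gaussian,
    kde_joint_mixed,
    load_joint_grid,
    matched_gaussian_bandwidth_deg,
    orientation_frequencies,
    save_joint_grid,
    smoothing_concentration,
)

from conftest import make_table


def brute_force_vm_kde(angles_deg, nu, grid_deg):
    """Independent direct summation using scipy's von Mises pdf."""
    out = np.zeros(len(grid_deg))
    for j, t in enumerate(grid_deg):
        for a in angles_deg:
            out[j] += scipy.stats.vonmises.pdf(np.deg2rad(t), nu, loc=np.deg2rad(a))
    return out / len(angles_deg)


def brute_force_gauss_kde(angles_deg, h_deg, grid_deg):
    """Independent direct summation with linear normal kernels (per radian)."""
    h = np.deg2rad(h_deg)
    out = np.zeros(len(grid_deg))
    for j, t in enumerate(grid_deg):
        for a in angles_deg:
            out[j] += scipy.stats.norm.pdf(np.deg2rad(t), loc=np.deg2rad(a), scale=h)
    return out / len(angles_deg)


class TestDirectionKDE:
    def test_single_kernel_mode(self):
        est = kde_direction([90.0], nu=10.0)
        assert est.mode_deg() == 90.0

    def test_matches_brute_force(self, rng):
        angles = rng.uniform(0, 360, 100)
        est = kde_direction(angles, nu=4.0, grid_step_deg=1.0)
        oracle = brute_force_vm_kde(angles, 4.0, est.theta_grid_deg)
        np.testing.assert_allclose(est.values, oracle, atol=1e-12)

    def test_rotation_equivariance_grid_aligned(self, rng):
        angles = rng.uniform(0, 360, 50)
        base = kde_direction(angles, nu=6.0, grid_step_deg=1.0)
        rot = kde_direction((angles + 40.0) % 360.0, nu=6.0, grid_step_deg=1.0)
        np.testing.assert_allclose(rot.values, np.roll(base.values, 40), atol=1e-12)

    @pytest.mark.parametrize("nu", [0.0, 2.0, 50.0])
    def test_integrates_to_one(self, rng, nu):
        est = kde_direction(rng.uniform(0, 360, 80), nu=nu, grid_step_deg=0.5)
        assert est.integral() == pytest.approx(1.0, abs=1e-6)

    def test_periodic_boundary_continuity(self, rng):
        angles = np.concatenate([rng.normal(358, 3, 100), rng.normal(2, 3, 100)]) % 360
        est = kde_direction(angles, nu=30.0, grid_step_deg=1.0)
        bound = est.values.max() * np.deg2rad(est.step_deg) * 10.0
        assert abs(est.values[0] - est.values[-1]) < bound

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            kde_direction([], nu=1.0)

    def test_bad_grid_step_rejected(self):
        with pytest.raises(ValidationError):
            kde_direction([0.0], nu=1.0, grid_step_deg=7.0)


class TestDirectionGaussianBaseline:
    def test_matches_brute_force(self, rng):
        angles = rng.uniform(0, 360, 60)
        est = kde_direction_gaussian(angles, bandwidth_deg=12.0, grid_step_deg=1.0)
        oracle = brute_force_gauss_kde(angles, 12.0, est.theta_grid_deg)
        np.testing.assert_allclose(est.values, oracle, atol=1e-12)

    def test_interior_mode_matches_von_mises(self):
        ga = kde_direction_gaussian([180.0], bandwidth_deg=3.0)
        vm = kde_direction([180.0], nu=matched_gaussian_bandwidth_deg(300.0))
        assert ga.mode_deg() == 180.0 == vm.mode_deg()

    def test_boundary_artifact_vs_von_mises(self):
        """Mass at 355 does not reach the 0-deg grid point without wrapping."""
        angles = [355.0] * 50 + [5.0] * 50
        nu = 1.0 / np.deg2rad(5.0) ** 2  # kernel sd approx 5 deg
        vm = kde_direction(angles, nu=nu, grid_step_deg=1.0)
        ga = kde_direction_gaussian(angles, bandwidth_deg=5.0, grid_step_deg=1.0)
        assert vm.values[0] > ga.values[0]

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValidationError):
            kde_direction_gaussian([0.0], bandwidth_deg=0.0)


def brute_force_joint(table, angular_pdf, h_r, theta_grid, r_grid):
    """Independent product-kernel double loop with reflected radial Gaussian."""
    n = len(table)
    dirs, amps = table.directions_deg, table.amplitudes
    out = np.zeros((len(theta_grid), len(r_grid)))
    for j, t in enumerate(theta_grid):
        for k, r in enumerate(r_grid):
            acc = 0.0
            for i in range(n):
                g = scipy.stats.norm.pdf(r, loc=amps[i], scale=h_r) + scipy.stats.norm.pdf(
                    r, loc=-amps[i], scale=h_r
                )
                acc += angular_pdf(t, dirs[i]) * g
            out[j, k] = acc / n
    return out


class TestJointMixedKDE:
    def test_single_saccade_mode(self):
        t = make_table([90.0], [100.0])
        grid = kde_joint_mixed(t, nu=400.0, h=3.0, r_max=200.0, r_steps=201)
        mode = grid.mode()
        assert mode[0] == 90.0
        assert abs(mode[1] - 100.0) <= grid.dr

    def test_polar_mass_is_one(self, rng):
        t = make_table(rng.uniform(0, 360, 200), rng.gamma(4, 30, 200))
        grid = kde_joint_mixed(t, nu=8.0, h=15.0)
        assert grid.polar_mass() == pytest.approx(1.0, abs=1e-6)

    def test_prenormalization_matches_brute_force(self, rng):
        t = make_table(rng.uniform(0, 360, 50), rng.gamma(3, 20, 50))
        grid = kde_joint_mixed(
            t, nu=3.0, h=10.0, theta_step_deg=30.0, r_max=150.0, r_steps=8,
            normalization=Normalization.COORDINATE_AREA,
        )
        ang = lambda t_deg, a_deg: scipy.stats.vonmises.pdf(
            np.deg2rad(t_deg), 3.0, loc=np.deg2rad(a_deg)
        )
        oracle = brute_force_joint(t, ang, 10.0, grid.theta_grid_deg, grid.r_grid)
        np.testing.assert_allclose(grid.values, oracle, atol=1e-12)

    def test_truncation_warning_recorded(self, rng):
        t = make_table(rng.uniform(0, 360, 100), rng.gamma(4, 30, 100))
        grid = kde_joint_mixed(t, nu=4.0, h=10.0, r_max=float(np.percentile(t.amplitudes, 50)))
        assert "truncation_warning" in grid.meta

    def test_roundtrip_serialization(self, tmp_path, rng):
        t = make_table(rng.uniform(0, 360, 30), rng.gamma(4, 30, 30))
        grid = kde_joint_mixed(t, nu=4.0, h=10.0, theta_step_deg=10.0, r_steps=20)
        save_joint_grid(grid, tmp_path / "g.csv", tmp_path / "g.json")
        back = load_joint_grid(tmp_path / "g.csv", tmp_path / "g.json")
        np.testing.assert_array_equal(back.values, grid.values)
        assert back.normalization is grid.normalization
        assert back.kernels == grid.kernels


class TestJointGaussianBaseline:
    def test_prenormalization_matches_brute_force(self, rng):
        t = make_table(rng.uniform(0, 360, 50), rng.gamma(3, 20, 50))
        grid = kde_joint_gaussian(
            t, h_theta_deg=20.0, h_r=10.0, theta_step_deg=30.0, r_max=150.0, r_steps=8,
            normalization=Normalization.COORDINATE_AREA,
        )
        ang = lambda t_deg, a_deg: scipy.stats.norm.pdf(
            np.deg2rad(t_deg), loc=np.deg2rad(a_deg), scale=np.deg2rad(20.0)
        )
        oracle = brute_force_joint(t, ang, 10.0, grid.theta_grid_deg, grid.r_grid)
        np.testing.assert_allclose(grid.values, oracle, atol=1e-12)

    def test_polar_mass_is_one(self, rng):
        t = make_table(rng.uniform(0, 360, 100), rng.gamma(4, 30, 100))
        grid = kde_joint_gaussian(t, h_theta_deg=15.0, h_r=12.0)
        assert grid.polar_mass() == pytest.approx(1.0, abs=1e-6)

    def test_interior_data_agrees_with_mixed(self, rng):
        """Away from the 0/360 boundary, variance-matched kernels nearly coincide."""
        from saccadekde import compare_estimators, EstimatorSettings

        d = np.rad2deg(rng.vonmises(np.pi, 30.0, 300)) % 360.0  # concentrated at 180
        t = make_table(d, rng.gamma(4, 30, 300))
        nu = 30.0
        rep = compare_estimators(
            t, EstimatorSettings(nu=nu, h_theta_deg=matched_gaussian_bandwidth_deg(nu))
        )
        assert rep.jsd < 0.02


class TestHistogram:
    def test_single_occupied_bin(self, rng):
        h = histogram_direction(rng.uniform(0, 90, 10), n_bins=4)
        assert list(h.counts) == [10, 0, 0, 0]

    def test_relative_sums_to_one(self, rng):
        h = histogram_direction(rng.uniform(0, 360, 97), n_bins=12, mode="relative")
        assert h.counts.sum() == pytest.approx(1.0, abs=1e-12)

    def test_half_open_binning_at_wrap(self):
        h = histogram_direction([359.999, 0.0], n_bins=36)
        assert h.counts[0] == 1 and h.counts[-1] == 1

    def test_relative_empty_rejected(self):
        with pytest.raises(ValidationError):
            histogram_direction([], n_bins=4, mode="relative")

    def test_polyline_closed_at_bin_centers(self):
        h = histogram_direction([10.0, 100.0, 190.0, 280.0], n_bins=4)
        verts = bin_center_polyline(h)
        assert [v[0] for v in verts] == [45.0, 135.0, 225.0, 315.0, 405.0]
        assert [v[1] for v in verts[:4]] == list(h.counts)
        assert verts[-1][1] == verts[0][1]


class TestOrientation:
    @pytest.mark.parametrize(
        "angle,expected",
        [
            (10.0, "horizontal"),
            (100.0, "vertical"),
            (45.0, "vertical"),
            (135.0, "horizontal"),
            (225.0, "vertical"),
            (315.0, "horizontal"),
            (359.9, "horizontal"),
        ],
    )
    def test_wedges(self, angle, expected):
        assert classify_orientation(angle) == expected

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(angle=st.floats(0, 360, exclude_max=True))
    def test_partition(self, angle):
        assert classify_orientation(angle) in ("horizontal", "vertical")

    def test_frequencies_sum_to_one(self, rng):
        f = orientation_frequencies(rng.uniform(0, 360, 500))
        assert f["horizontal"] + f["vertical"] == pytest.approx(1.0)

    def test_frequencies_match_scalar_classifier(self, rng):
        a = rng.uniform(0, 360, 200)
        f = orientation_frequencies(a)
        scalar = np.mean([classify_orientation(x) == "horizontal" for x in a])
        assert f["horizontal"] == pytest.approx(scalar)


class TestAmplitudeBandwidth:
    def test_silverman_formula(self, rng):
        r = rng.gamma(4, 25, 400)
        sd = np.std(r, ddof=1)
        iqr = np.percentile(r, 75) - np.percentile(r, 25)
        expected = 0.9 * min(sd, iqr / 1.34) * 400 ** (-0.2)
        assert amplitude_bandwidth(r) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_sample_still_positive(self):
        assert amplitude_bandwidth([50.0, 50.0, 50.0]) > 0
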