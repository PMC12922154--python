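"""Probability grids, normalized Jensen-Shannon divergence, comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon

from saccadekde import (
    EstimatorSettings,
    ProbabilityGrid,
    ValidationError,
    compare_estimators,
    compare_groups,
    grid_to_mass,
    jsd_normalized,
    kde_joint_mixed,
)
from saccadekde.density import JointDensityGrid, KernelKind, Normalization
from saccadekde.io import AmplitudeUnit

from conftest import make_table


def _const_density(value=1.0, n_theta=12, n_r=10):
    return JointDensityGrid(
        theta_grid_deg=np.arange(n_theta) * (360.0 / n_theta),
        r_grid=np.linspace(0, 90, n_r),
        r_unit=AmplitudeUnit.PX,
        values=np.full((n_theta, n_r), value),
        normalization=Normalization.POLAR_AREA,
        kernels=(KernelKind.VON_MISES, KernelKind.GAUSSIAN_LINEAR),
        bandwidths=(1.0, 1.0),
        n_samples=1,
    )


def _mass_from(matrix):
    m = np.asarray(matrix, dtype=float)
    m = m / m.sum()
    return ProbabilityGrid(
        theta_grid_deg=np.arange(m.shape[0], dtype=float),
        r_grid=np.arange(m.shape[1], dtype=float),
        masses=m,
    )


class TestGridToMass:
    def test_constant_density_mass_linear_in_r(self):
        p = grid_to_mass(_const_density())
        # area element r*dr*dtheta: doubling r doubles the cell mass
        col = p.masses[0, :]
        r = _const_density().r_grid
        assert col[4] / col[2] == pytest.approx(r[4] / r[2], rel=1e-9)
        assert np.all(p.masses[:, 0] == 0.0)  # r = 0 ring carries no mass

    def test_masses_sum_to_one(self, rng):
        d = _const_density()
        d = JointDensityGrid(**{**d.__dict__, "values": rng.random(d.values.shape)})
        assert grid_to_mass(d).masses.sum() == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        vals = rng.random((12, 10))
        d1 = JointDensityGrid(**{**_const_density().__dict__, "values": vals})
        d2 = JointDensityGrid(**{**_const_density().__dict__, "values": 7.3 * vals})
        np.testing.assert_allclose(grid_to_mass(d1).masses, grid_to_mass(d2).masses)

    def test_delta_density_concentrates_mass(self):
        t = make_table([90.0], [100.0])
        grid = kde_joint_mixed(t, nu=5e4, h=0.5, theta_step_deg=1.0, r_max=200.0, r_steps=201)
        p = grid_to_mass(grid)
        assert p.masses.max() > 0.2  # sharply concentrated
        # nearly all mass within a few cells of the saccade
        j, k = np.unravel_index(np.argmax(p.masses), p.masses.shape)
        window = p.masses[j - 3 : j + 4, k - 3 : k + 4]
        assert window.sum() > 0.99

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            grid_to_mass(_const_density(value=0.0))


def brute_force_jsd(p, q):
    """Elementwise KL summation in base 2, written independently."""
    m = 0.5 * (p + q)
    kl_pm = sum(pi * math.log2(pi / mi) for pi, mi in zip(p.ravel(), m.ravel()) if pi > 0)
    kl_qm = sum(qi * math.log2(qi / mi) for qi, mi in zip(q.ravel(), m.ravel()) if qi > 0)
    return 0.5 * kl_pm + 0.5 * kl_qm


class TestJSD:
    def test_identity_is_zero(self, rng):
        p = _mass_from(rng.random((6, 5)))
        assert jsd_normalized(p, p) == 0.0

    def test_disjoint_supports_maximal(self):
        a = np.zeros((2, 2)); a[0, 0] = 1.0
        b = np.zeros((2, 2)); b[1, 1] = 1.0
        assert jsd_normalized(_mass_from(a), _mass_from(b)) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_and_brute_force_agreement(self, rng):
        for _ in range(20):
            p = _mass_from(rng.random((7, 4)))
            q = _mass_from(rng.random((7, 4)))
            v = jsd_normalized(p, q)
            assert v == pytest.approx(jsd_normalized(q, p), abs=1e-15)
            assert v == pytest.approx(brute_force_jsd(p.masses, q.masses), abs=1e-12)

    def test_agrees_with_scipy(self, rng):
        p = _mass_from(rng.random((8, 8)))
        q = _mass_from(rng.random((8, 8)))
        oracle = jensenshannon(p.masses.ravel(), q.masses.ravel(), base=2.0) ** 2
        assert jsd_normalized(p, q) == pytest.approx(oracle, abs=1e-12)

    def test_natural_log_base_scales(self, rng):
        p = _mass_from(rng.random((5, 5)))
        q = _mass_from(rng.random((5, 5)))
        assert jsd_normalized(p, q, log_base=math.e) == pytest.approx(
            jsd_normalized(p, q) * math.log(2.0), rel=1e-12
        )

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            jsd_normalized(_mass_from(rng.random((4, 4))), _mass_from(rng.random((5, 4))))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_bounds_property(self, seed):
        r = np.random.default_rng(seed)
        p = _mass_from(r.random((6, 6)) ** 3)
        q = _mass_from(r.random((6, 6)) ** 3)
        v = jsd_normalized(p, q)
        assert 0.0 <= v <= 1.0 + 1e-12


class TestCompareEstimators:
    def test_interior_degenerate_case_agrees(self):
        # single interior angle, matched circular-variance bandwidths, tight
        t = make_table([180.0] * 20, np.linspace(80, 120, 20))
        rep = compare_estimators(t, EstimatorSettings(nu=100.0))
        assert rep.jsd < 0.02

    def test_boundary_exceeds_interior(self, rng):
        n = 400
        amps = rng.gamma(4, 30, n)
        d_interior = np.rad2deg(rng.vonmises(np.pi, 20.0, n)) % 360
        d_boundary = (d_interior + 180.0) % 360.0  # same shape, centred at 0
        s = EstimatorSettings(nu=20.0)
        jsd_int = compare_estimators(make_table(d_interior, amps), s).jsd
        jsd_bnd = compare_estimators(make_table(d_boundary, amps), s).jsd
        assert jsd_bnd > jsd_int

    def test_report_internally_consistent(self, small_table):
        rep = compare_estimators(small_table)
        assert rep.jsd == pytest.approx(jsd_normalized(rep.mixed, rep.gaussian_only))
        assert rep.mixed.masses.shape == rep.gaussian_only.masses.shape


class TestCompareGroups:
    def test_identical_groups_zero_jsd(self, small_table):
        rep = compare_groups(small_table, small_table)
        assert rep.jsd == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_in_group_order(self, rng):
        a = make_table(rng.uniform(0, 360, 150), rng.gamma(4, 25, 150))
        b = make_table(rng.uniform(0, 360, 150), rng.gamma(4, 60, 150))
        assert compare_groups(a, b).jsd == pytest.approx(compare_groups(b, a).jsd, abs=1e-12)

    def test_row_order_invariance(self, rng):
        d, amps = rng.uniform(0, 360, 100), rng.gamma(4, 25, 100)
        perm = rng.permutation(100)
        a = make_table(d, amps)
        b = make_table(d[perm], amps[perm])
        ra, rb = compare_groups(a, a), compare_groups(b, b)
        assert ra.summary_a["circular_mean_deg"] == pytest.approx(
            rb.summary_a["circular_mean_deg"]
        )
        assert ra.summary_a["amplitude_median"] == rb.summary_a["amplitude_median"]

    def test_unit_mismatch_rejected(self, rng):
        a = make_table([0.0, 1.0], [1.0, 2.0], unit=AmplitudeUnit.PX)
        b = make_table([0.0, 1.0], [1.0, 2.0], unit=AmplitudeUnit.DEG)
        with pytest.raises(ValidationError, match="unit mismatch"):
            compare_groups(a, b)

    def test_summaries_describe_each_group(self, rng):
        a = make_table(np.full(100, 10.0), np.full(100, 50.0))
        b = make_table(np.full(100, 100.0), np.full(100, 150.0))
        rep = compare_groups(a, b)
        assert rep.summary_a["orientation"]["horizontal"] == 1.0
        assert rep.summary_b["orientation"]["vertical"] == 1.0
        assert rep.summary_a["amplitude_median"] == 50.0
        assert rep.summary_b["amplitude_median"] == 150.0
        assert rep.jsd > 0.05
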