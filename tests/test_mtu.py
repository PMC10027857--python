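"""Unit tests of the Hill-type MTU force laws and equilibrium solver."""

import math

import numpy as np
import pytest

from preflex import mtu
from preflex.params import MuscleParams


@pytest.fixture()
def mp():
    return MuscleParams()


class TestForceLength:
    def test_unity_at_optimal_length(self, mp):
        assert mtu.force_length_factor(mp.l_opt, mp) == pytest.approx(1.0)

    def test_monotone_decay_from_optimum(self, mp):
        f8 = mtu.force_length_factor(0.08, mp)
        f9 = mtu.force_length_factor(0.09, mp)
        assert 0.0 < f8 < f9 < 1.0
        # descending limb mirrors
        assert (mtu.force_length_factor(0.12, mp)
                < mtu.force_length_factor(0.11, mp) < 1.0)

    def test_closed_form_value(self, mp):
        # direct evaluation of the documented bell formula
        expected = math.exp(-abs((0.09 / mp.l_opt - 1.0) / mp.fl_width)
                            ** mp.fl_exponent)
        assert mtu.force_length_factor(0.09, mp) == pytest.approx(
            expected, rel=1e-12)

    def test_nonpositive_length_rejected(self, mp):
        with pytest.raises(ValueError):
            mtu.force_length_factor(0.0, mp)


class TestForceVelocity:
    def test_isometric_at_optimum_gives_f_max(self, mp):
        assert mtu.contractile_force(0.0, mp.l_opt, mp.a_max, mp) \
            == pytest.approx(mp.f_max)

    def test_zero_at_max_shortening_velocity(self, mp):
        assert mtu.contractile_force(-mp.v_max, mp.l_opt, 1.0, mp) \
            == pytest.approx(0.0, abs=1e-9)

    def test_eccentric_asymptote(self, mp):
        # far on the eccentric branch the force approaches the plateau
        f_inf = mtu.contractile_force(100 * mp.v_max, mp.l_opt, 0.5, mp)
        assert f_inf == pytest.approx(mp.f_ecc_plateau * 0.5 * mp.f_max,
                                      rel=0.02)
        assert f_inf < mp.f_ecc_plateau * 0.5 * mp.f_max

    def test_monotone_non_decreasing_in_velocity(self, mp, rng):
        v = np.linspace(-mp.v_max, 3 * mp.v_max, 400)
        for _ in range(10):
            l_ce = rng.uniform(0.06, 0.13)
            a = rng.uniform(mp.a_min, mp.a_max)
            f = np.array([mtu.contractile_force(vi, l_ce, a, mp) for vi in v])
            assert np.all(np.diff(f) >= -1e-9 * mp.f_max)

    def test_eccentric_bounded_by_plateau(self, mp, rng):
        for _ in range(10):
            l_ce = rng.uniform(0.06, 0.13)
            a = rng.uniform(mp.a_min, mp.a_max)
            f_iso = mtu.contractile_force(0.0, l_ce, a, mp)
            v = rng.uniform(0.0, 5 * mp.v_max)
            assert mtu.contractile_force(v, l_ce, a, mp) \
                <= mp.f_ecc_plateau * f_iso + 1e-9

    def test_smooth_at_zero_velocity(self, mp):
        # C1 junction: one-sided difference quotients agree
        h = 1e-8 * mp.v_max
        f0 = mtu.contractile_force(0.0, mp.l_opt, 1.0, mp)
        left = (f0 - mtu.contractile_force(-h, mp.l_opt, 1.0, mp)) / h
        right = (mtu.contractile_force(h, mp.l_opt, 1.0, mp) - f0) / h
        assert right == pytest.approx(left, rel=1e-5)

    def test_activity_bounds_enforced(self, mp):
        with pytest.raises(ValueError):
            mtu.contractile_force(0.0, mp.l_opt, 0.0, mp)
        with pytest.raises(ValueError):
            mtu.contractile_force(0.0, mp.l_opt, 1.5, mp)


class TestPassiveSerial:
    def test_pee_disengaged_below_engagement_length(self, mp):
        f_pee, _, _ = mtu.passive_and_serial_forces(
            0.09, 0.5, 0.0, 0.0, mp)
        assert f_pee == 0.0

    def test_pee_engages_and_increases(self, mp):
        l1 = 0.96 * mp.l_opt
        l2 = 0.99 * mp.l_opt
        assert 0.0 < mtu.parallel_elastic_force(l1, mp) \
            < mtu.parallel_elastic_force(l2, mp)

    def test_see_zero_at_slack(self, mp):
        _, f_see, f_sde = mtu.passive_and_serial_forces(
            0.09, 0.09 + mp.l_see0, 0.0, 0.0, mp)
        assert f_see == 0.0
        assert f_sde == 0.0

    def test_see_linear_region_slope(self, mp):
        # finite-difference slope of F_SEE vs length in the linear region
        # matches the documented linear stiffness
        eps = mp.du_see_nll + 2 * mp.du_see_l
        l_see = mp.l_see0 * (1.0 + eps)
        dl = 1e-7
        slope = (mtu.series_elastic_force(l_see + dl, mp)
                 - mtu.series_elastic_force(l_see - dl, mp)) / (2 * dl)
        assert slope == pytest.approx(
            mp.df_see0 / (mp.du_see_l * mp.l_see0), rel=1e-6)

    def test_see_toe_is_continuous_with_linear_region(self, mp):
        eps = mp.du_see_nll
        l_at = mp.l_see0 * (1.0 + eps)
        below = mtu.series_elastic_force(l_at - 1e-9, mp)
        above = mtu.series_elastic_force(l_at + 1e-9, mp)
        assert above == pytest.approx(below, rel=1e-6)
        assert below == pytest.approx(mp.df_see0, rel=1e-5)

    def test_sde_proportional_to_serial_velocity(self, mp):
        _, _, f1 = mtu.passive_and_serial_forces(0.09, 0.5, 0.1, 1000.0, mp)
        _, _, f2 = mtu.passive_and_serial_forces(0.09, 0.5, 0.2, 1000.0, mp)
        assert f2 == pytest.approx(2 * f1)


class TestFibreVelocityEquilibrium:
    def test_isometric_constructed_equilibrium(self, mp):
        l_mtu = 0.09 + mp.l_see0 * 1.01
        l_ce, state = mtu.isometric_fixed_point(l_mtu, 0.15, mp)
        law = mtu.make_activation_law(mp)
        a = law.activity(state, l_ce)
        fb = mtu.solve_fibre_velocity(l_ce, l_mtu, 0.0, a, mp)
        assert fb.v_ce == pytest.approx(0.0, abs=1e-10)

    def test_self_consistency_of_returned_balance(self, mp, rng):
        for _ in range(20):
            l_ce = rng.uniform(0.06, 0.1)
            l_mtu = l_ce + mp.l_see0 * rng.uniform(0.999, 1.05)
            v_mtu = rng.uniform(-0.5, 0.5)
            a = rng.uniform(mp.a_min, 1.0)
            fb = mtu.solve_fibre_velocity(l_ce, l_mtu, v_mtu, a, mp)
            assert abs(fb.residual) < 1e-6 * mp.f_max
            assert fb.f_mtu == pytest.approx(fb.f_see + fb.f_sde)
            assert fb.f_mtu == pytest.approx(fb.f_ce + fb.f_pee,
                                             abs=1e-6 * mp.f_max)

    def test_against_dense_scan_bisection_oracle(self, mp, rng):
        """Root agrees with a grid-scan + interval-bisection oracle."""
        for _ in range(20):
            l_ce = rng.uniform(0.06, 0.1)
            l_mtu = l_ce + mp.l_see0 * rng.uniform(0.999, 1.05)
            v_mtu = rng.uniform(-0.5, 0.5)
            a = rng.uniform(mp.a_min, 1.0)
            fb = mtu.solve_fibre_velocity(l_ce, l_mtu, v_mtu, a, mp)
            v_oracle = _dense_scan_root(l_ce, l_mtu, v_mtu, a, mp)
            assert fb.v_ce == pytest.approx(v_oracle, abs=1e-8)

    def test_deterministic(self, mp):
        f1 = mtu.solve_fibre_velocity(0.08, 0.08 + mp.l_see0 * 1.02,
                                      0.3, 0.5, mp)
        f2 = mtu.solve_fibre_velocity(0.08, 0.08 + mp.l_see0 * 1.02,
                                      0.3, 0.5, mp)
        assert f1.v_ce == f2.v_ce


def _dense_scan_root(l_ce, l_mtu, v_mtu, a, mp, n=4000, iters=80):
    """Independent oracle: scan the residual on a dense velocity grid and
    bisect the first sign change."""
    def res(v):
        f_ce = mtu.contractile_force(v, l_ce, a, mp)
        f_pee = mtu.parallel_elastic_force(l_ce, mp)
        f_see = mtu.series_elastic_force(l_mtu - l_ce, mp)
        d = mtu.series_damper_coefficient(f_ce + f_pee, mp)
        return (f_ce + f_pee) - (f_see + d * (v_mtu - v))

    grid = np.linspace(-8 * mp.v_max, 30 * mp.v_max, n)
    vals = np.array([res(v) for v in grid])
    idx = np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]
    assert idx.size, "oracle found no sign change"
    lo, hi = grid[idx[0]], grid[idx[0] + 1]
    flo = res(lo)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = res(mid)
        if flo * fm <= 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


class TestActivation:
    def test_linear_rate_at_fixed_point_is_zero(self, mp):
        u = 0.4
        a_ss = mp.a_min + (mp.a_max - mp.a_min) * u
        assert mtu.activation_rate(a_ss, u, mp.l_opt, mp) \
            == pytest.approx(0.0, abs=1e-12)

    def test_linear_rate_from_rest_at_full_drive(self, mp):
        # (1 - 0.005) / 0.0885 at the optimal length
        rate = mtu.activation_rate(mp.a_min, 1.0, mp.l_opt, mp)
        assert rate == pytest.approx((1.0 - 0.005) / 0.0885, rel=1e-10)
        assert rate == pytest.approx(11.24, abs=0.01)

    def test_linear_rate_clamped_at_upper_bound(self, mp):
        for u in (0.0, 0.5, 1.0):
            assert mtu.activation_rate(mp.a_max, u, mp.l_opt, mp) <= 0.0

    def test_saturating_activity_within_bounds(self, mp, rng):
        law = mtu.SaturatingActivation(mp)
        for _ in range(50):
            a = law.activity(rng.uniform(0, 1), rng.uniform(0.05, 0.15))
            assert mp.a_min <= a <= mp.a_max

    def test_saturating_drive_inversion_roundtrip(self, mp):
        law = mtu.SaturatingActivation(mp)
        for a_target in (0.05, 0.11, 0.5, 0.9):
            c = law.drive_for_activity(a_target, 0.08)
            assert law.activity(c, 0.08) == pytest.approx(a_target,
                                                          rel=1e-9)

    def test_out_of_range_stimulation_clamped(self, mp):
        law = mtu.SaturatingActivation(mp)
        assert law.steady_state(1.7) == 1.0
        assert law.steady_state(-0.3) == 0.0
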