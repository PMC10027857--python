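"""End-to-end tests of the hopping-cycle simulator (coarse solver grid)."""

import math

import numpy as np
import pytest

from preflex import mtu
from preflex.engine import (find_periodic_orbit, pin_reference_touchdown,
                            simulate_cycle, _with_expected_td)
from preflex.params import ModelParams, StimProtocol


@pytest.fixture(scope="module")
def const_cycle(mini_params):
    """One const-protocol cycle at the calibrated reference apex."""
    return simulate_cycle(StimProtocol(kind="const"), 0.0, mini_params,
                          0.108)


class TestFlight:
    def test_ballistic_touchdown_speed(self, const_cycle, mini_params):
        h0 = const_cycle.h0
        i_td = const_cycle.stance_slice().start
        v_td = const_cycle.v_y[i_td]
        assert v_td == pytest.approx(
            -math.sqrt(2 * mini_params.leg.g * h0), abs=1e-6)

    def test_flight_geometry_frozen(self, const_cycle, mini_params):
        fl = const_cycle.phase == "flight"
        assert np.all(const_cycle.f_leg[fl] == 0.0)
        assert np.all(const_cycle.v_mtu[fl] == 0.0)
        assert np.ptp(const_cycle.l_mtu[fl]) == 0.0

    def test_fixed_point_initial_condition(self, const_cycle):
        # starting at the flight muscle equilibrium, the internal state
        # stays put until touch-down
        fl = (const_cycle.phase == "flight") & (const_cycle.t
                                                < const_cycle.t_td)
        assert np.ptp(const_cycle.l_ce[fl]) < 1e-7
        assert np.ptp(const_cycle.a[fl]) < 1e-7
        assert np.max(np.abs(const_cycle.v_ce[fl])) < 1e-6


class TestStance:
    def test_event_ordering(self, const_cycle):
        assert 0.0 < const_cycle.t_td < const_cycle.t_to \
            < const_cycle.t_apex_end

    def test_work_energy_bookkeeping(self, const_cycle, mini_params):
        """Integral of F_leg * v_y over stance accounts for the kinetic and
        potential energy change of the point mass."""
        lp = mini_params.leg
        st = const_cycle.stance_slice()
        t = const_cycle.t[st]
        v = const_cycle.v_y[st]
        y = const_cycle.y[st]
        f = const_cycle.f_leg[st]
        w_leg = np.trapezoid(f * v, t)
        d_ke = 0.5 * lp.m * (v[-1] ** 2 - v[0] ** 2)
        d_pe = lp.m * lp.g * (y[-1] - y[0])
        ke_peak = 0.5 * lp.m * np.max(v ** 2)
        assert w_leg == pytest.approx(d_ke + d_pe, abs=1e-3 * ke_peak)

    def test_leg_never_overextends_in_stance(self, const_cycle):
        st = const_cycle.stance_slice()
        assert np.all(const_cycle.phi[st] < math.pi - 1e-6)

    def test_equilibrium_residual_at_samples(self, const_cycle, mini_params):
        """Element forces recomputed from the sampled state satisfy the
        four-element equilibrium everywhere."""
        mp = mini_params.muscle
        st = const_cycle.stance_slice()
        for i in range(st.start, st.stop, 25):
            f_ce = mtu.contractile_force(const_cycle.v_ce[i],
                                         const_cycle.l_ce[i],
                                         const_cycle.a[i], mp)
            f_pee = mtu.parallel_elastic_force(const_cycle.l_ce[i], mp)
            f_see = mtu.series_elastic_force(
                const_cycle.l_mtu[i] - const_cycle.l_ce[i], mp)
            f_sde = mtu.series_damper_coefficient(f_ce + f_pee, mp) * (
                const_cycle.v_mtu[i] - const_cycle.v_ce[i])
            assert abs((f_ce + f_pee) - (f_see + f_sde)) < 1e-6 * mp.f_max


class TestDeterminismAndConvergence:
    def test_bitwise_deterministic(self, mini_params):
        sp = StimProtocol(kind="const")
        t1 = simulate_cycle(sp, 0.0, mini_params, 0.10)
        t2 = simulate_cycle(sp, 0.0, mini_params, 0.10)
        np.testing.assert_array_equal(t1.y, t2.y)
        np.testing.assert_array_equal(t1.f_ce, t2.f_ce)
        assert t1.h1 == t2.h1

    def test_mini_grid_consistent_with_full_grid(self, params, mini_params):
        """Return apex from the coarse test grid is within 2 mm of the
        study-resolution apex."""
        sp = StimProtocol(kind="const")
        h_full = simulate_cycle(sp, 0.0, params, 0.108).h1
        h_mini = simulate_cycle(sp, 0.0, mini_params, 0.108).h1
        assert abs(h_full - h_mini) < 2e-3


class TestPeriodicOrbit:
    def test_fixed_point_is_periodic(self, mini_params):
        h_ref, traj, _ = find_periodic_orbit(
            StimProtocol(kind="const"), mini_params, 0.106)
        assert abs(traj.h1 - h_ref) < mini_params.sim.apex_tol

    def test_restart_at_fixed_point_converges_immediately(self, mini_params):
        h_ref, _, _ = find_periodic_orbit(
            StimProtocol(kind="const"), mini_params, 0.106)
        _, _, iters = find_periodic_orbit(
            StimProtocol(kind="const"), mini_params, h_ref)
        assert iters == 1

    def test_rising_needs_expected_touchdown(self, mini_params):
        with pytest.raises(ValueError):
            simulate_cycle(StimProtocol(kind="rising"), 0.0, mini_params,
                           0.05)


@pytest.fixture(scope="module")
def small_suite(mini_params):
    """Reference plus one step-up and one step-down per protocol."""
    out = {}
    for kind, h0 in (("const", 0.106), ("rising", 0.052)):
        h_ref, _, _ = find_periodic_orbit(StimProtocol(kind=kind),
                                          mini_params, h0)
        sp = _with_expected_td(StimProtocol(kind=kind), h_ref, 9.81)
        out[kind] = (h_ref, {dh: simulate_cycle(sp, dh, mini_params, h_ref)
                             for dh in (-0.025, 0.0, 0.05)})
    return out


class TestPerturbations:
    def test_const_stimulation_at_touchdown_unchanged(self, small_suite):
        _, trials = small_suite["const"]
        for tr in trials.values():
            i = tr.stance_slice().start
            assert tr.u[i] == pytest.approx(0.15)

    def test_rising_touchdown_postponed_by_step_down(self, small_suite):
        _, trials = small_suite["rising"]
        tds = [trials[dh].t_td for dh in (-0.025, 0.0, 0.05)]
        assert tds[0] < tds[1] < tds[2]

    def test_rising_stimulation_at_touchdown_grows_with_drop(
            self, small_suite):
        _, trials = small_suite["rising"]
        us = [trials[dh].u[trials[dh].stance_slice().start]
              for dh in (-0.025, 0.0, 0.05)]
        assert us[0] < us[1] < us[2]

    def test_rising_fibres_shorten_before_reference_touchdown(
            self, small_suite):
        _, trials = small_suite["rising"]
        tr = trials[0.0]
        i_pre = tr.index_before_touchdown()
        assert tr.v_ce[i_pre] < 0.0

    def test_apex_returns_toward_reference(self, small_suite):
        for kind in ("const", "rising"):
            h_ref, trials = small_suite[kind]
            for dh, tr in trials.items():
                if dh == 0.0:
                    continue
                assert abs(tr.h1 - h_ref) < abs(tr.h0 - h_ref)


class TestPinning:
    def test_pinned_flight_state_matches_targets(self):
        from preflex import leg
        p = pin_reference_touchdown(ModelParams(), u_flight=0.15,
                                    a_td=0.11, f_td=1260.0)
        lp, mp = p.leg, p.muscle
        phi_f = leg.knee_angle_from_height(lp.l_f, lp)
        l_mtu_f = leg.mtu_length_from_knee(phi_f, lp)
        l_ce, state = mtu.isometric_fixed_point(l_mtu_f, 0.15, mp)
        law = mtu.make_activation_law(mp)
        a = law.activity(state, l_ce)
        fb = mtu.solve_fibre_velocity(l_ce, l_mtu_f, 0.0, a, mp)
        assert a == pytest.approx(0.11, abs=1e-9)
        assert fb.f_ce == pytest.approx(1260.0, abs=1e-6)

    def test_defaults_already_pinned(self, params, pinned_params):
        assert params.muscle.act_gain == pytest.approx(
            pinned_params.muscle.act_gain, rel=1e-9)
        assert params.leg.l_mtu_ref == pytest.approx(
            pinned_params.leg.l_mtu_ref, rel=1e-9)
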