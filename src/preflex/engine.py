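"""Apex-to-apex hopping cycles: flight, stance, events, periodic orbits.

Each trial starts at the apex of flight with the model at the fixed-end
muscle equilibrium for the protocol's flight-time stimulation (the unique
history-free initial condition), falls onto the ground, goes through
stance, and is integrated back up to the next apex. Ground-height
perturbations shift the ground by ``dh`` relative to the reference trial:
positive dh = step-down = deeper drop. The stimulation timeline of the
'rising' protocol is anchored to the *expected* (reference) touch-down and
is identical in absolute time across perturbations.

Integration uses adaptive RK45 with a hard cap on the step size and event
location for touch-down (y falling through l_f), take-off (y rising
through l_f, or the MTU force falling through zero, whichever first) and
the final apex (v_y falling through zero).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from . import leg, mtu
from .params import ModelParams, StimProtocol
from .protocols import flight_stimulation_level, stimulation

log = logging.getLogger(__name__)


class SimulationError(RuntimeError):
    """A phase failed to terminate or an event could not be located."""


@dataclass
class Trajectory:
    """Uniform-grid record of one apex-to-apex hopping cycle.

    Event times are stored at solver precision; the sample grid has spacing
    ``dt_output`` within each phase, with the exact phase-boundary states
    included, so the stance segment starts exactly at touch-down.
    """

    protocol: str
    dh: float
    h0: float                      # m, drop height (start apex above l_f)
    h1: float                      # m, return apex above l_f
    t_td: float
    t_to: float
    t_apex_end: float
    t: np.ndarray = field(repr=False)
    phase: np.ndarray = field(repr=False)      # "flight" | "stance"
    y: np.ndarray = field(repr=False)
    v_y: np.ndarray = field(repr=False)
    phi: np.ndarray = field(repr=False)
    l_mtu: np.ndarray = field(repr=False)
    v_mtu: np.ndarray = field(repr=False)
    l_ce: np.ndarray = field(repr=False)
    v_ce: np.ndarray = field(repr=False)
    a: np.ndarray = field(repr=False)
    u: np.ndarray = field(repr=False)
    f_ce: np.ndarray = field(repr=False)
    f_mtu: np.ndarray = field(repr=False)
    f_leg: np.ndarray = field(repr=False)

    @property
    def stance_duration(self) -> float:
        return self.t_to - self.t_td

    @property
    def cycle_duration(self) -> float:
        return self.t_apex_end

    @property
    def hop_frequency(self) -> float:
        return 1.0 / self.t_apex_end

    def index_before_touchdown(self) -> int:
        """Index of the last sample strictly before the touch-down event."""
        idx = int(np.searchsorted(self.t, self.t_td, side="left")) - 1
        if idx < 0:
            raise ValueError("no pre-touch-down sample in trajectory")
        return idx

    def stance_slice(self) -> slice:
        i0 = int(np.searchsorted(self.t, self.t_td, side="left"))
        i1 = int(np.searchsorted(self.t, self.t_to, side="right"))
        return slice(i0, i1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t_s": self.t, "phase": self.phase, "y_m": self.y,
            "v_y_m_per_s": self.v_y, "phi_rad": self.phi,
            "l_mtu_m": self.l_mtu, "v_mtu_m_per_s": self.v_mtu,
            "l_ce_m": self.l_ce, "v_ce_m_per_s": self.v_ce,
            "a": self.a, "u": self.u, "f_ce_n": self.f_ce,
            "f_mtu_n": self.f_mtu, "f_leg_n": self.f_leg,
        })

    def meta(self) -> dict:
        return {
            "protocol": self.protocol, "dh_m": self.dh, "h0_m": self.h0,
            "h1_m": self.h1, "t_td_s": self.t_td, "t_to_s": self.t_to,
            "t_apex_end_s": self.t_apex_end,
            "stance_duration_s": self.stance_duration,
            "hop_frequency_hz": self.hop_frequency,
        }


def _phase_grid(t0: float, t1: float, dt: float) -> np.ndarray:
    """Uniform grid on [t0, t1] with spacing dt, endpoint included."""
    n = max(int(math.floor((t1 - t0) / dt + 1e-9)), 0)
    grid = t0 + dt * np.arange(n + 1)
    if t1 - grid[-1] > 1e-12:
        grid = np.append(grid, t1)
    else:
        grid[-1] = t1
    return grid


def simulate_cycle(protocol: StimProtocol, dh: float, params: ModelParams,
                   h_ref: float) -> Trajectory:
    """One apex-to-apex hopping cycle with ground perturbation ``dh``.

    The cycle starts at apex height ``l_f + h_ref + dh`` above the
    (perturbed) ground with zero vertical velocity and the muscle at its
    flight fixed point. Deterministic for a fixed configuration.
    """
    mp, lp, cfg = params.muscle, params.leg, params.sim
    law = mtu.make_activation_law(mp)
    if protocol.kind == "rising" and protocol.t_td_expected is None:
        raise ValueError(
            "rising protocol needs t_td_expected from the reference trial")

    phi_flight = leg.knee_angle_from_height(lp.l_f, lp)
    l_mtu_flight = leg.mtu_length_from_knee(phi_flight, lp)
    u_flight = flight_stimulation_level(protocol)
    l_ce0, act0 = mtu.isometric_fixed_point(l_mtu_flight, u_flight, mp)
    y0 = lp.l_f + h_ref + dh

    ivp_opts = dict(method="RK45", max_step=cfg.max_step,
                    atol=cfg.abs_tol, rtol=cfg.rel_tol, dense_output=True)

    # --- phase 1: flight (descent), knee locked ---------------------------
    def flight_rhs(t, s):
        dl, da = leg.flight_internal_dynamics(
            t, (s[2], s[3]), protocol, mp, l_mtu_flight, law)
        return (s[1], -lp.g, dl, da)

    def ev_touchdown(t, s):
        return s[0] - lp.l_f
    ev_touchdown.terminal = True
    ev_touchdown.direction = -1

    sol1 = solve_ivp(flight_rhs, (0.0, cfg.event_horizon),
                     (y0, 0.0, l_ce0, act0), events=ev_touchdown, **ivp_opts)
    if sol1.status != 1:
        raise SimulationError(
            f"touch-down not found within {cfg.event_horizon} s "
            f"(dh={dh}, protocol={protocol.kind})")
    t_td = float(sol1.t_events[0][0])
    s_td = sol1.y_events[0][0]

    # --- phase 2: stance --------------------------------------------------
    def stance_rhs(t, s):
        return leg.stance_derivatives(t, s, protocol, mp, lp, t_td, law)

    def ev_takeoff_y(t, s):
        return s[0] - lp.l_f
    ev_takeoff_y.terminal = True
    ev_takeoff_y.direction = 1

    def ev_takeoff_force(t, s):
        phi = leg.knee_angle_from_height(s[0], lp)
        l_m = leg.mtu_length_from_knee(phi, lp)
        v_m = leg.mtu_velocity_from_body(s[0], s[1], lp)
        a = law.activity(s[3], s[2])
        return mtu.solve_fibre_velocity(s[2], l_m, v_m, a, mp).f_mtu
    ev_takeoff_force.terminal = True
    ev_takeoff_force.direction = -1

    sol2 = solve_ivp(stance_rhs, (t_td, t_td + cfg.event_horizon), s_td,
                     events=[ev_takeoff_y, ev_takeoff_force], **ivp_opts)
    if sol2.status != 1:
        raise SimulationError(
            f"take-off not found within {cfg.event_horizon} s "
            f"(dh={dh}, protocol={protocol.kind})")
    # earliest satisfied take-off condition; ties resolve to the y-crossing
    cand = [(te[0], k) for k, te in enumerate(sol2.t_events) if te.size]
    t_to, which = min(cand)
    t_to = float(t_to)
    s_to = sol2.y_events[which][0]
    log.debug("stance %s dh=%+.3f: TD %.4f s, TO %.4f s (%s)",
              protocol.kind, dh, t_td, t_to,
              "y-crossing" if which == 0 else "force-zero")

    # --- phase 3: flight (ascent) to apex ---------------------------------
    if s_to[1] <= 0.0:
        # degenerate: take-off without upward velocity; apex is take-off
        sol3 = None
        t_apex = t_to
        s_apex = s_to
    else:
        def ev_apex(t, s):
            return s[1]
        ev_apex.terminal = True
        ev_apex.direction = -1

        sol3 = solve_ivp(_ascent_rhs(protocol, mp, lp, l_mtu_flight, law,
                                     t_td),
                         (t_to, t_to + cfg.event_horizon), s_to,
                         events=ev_apex, **ivp_opts)
        if sol3.status != 1:
            raise SimulationError(
                f"apex not found within {cfg.event_horizon} s "
                f"(dh={dh}, protocol={protocol.kind})")
        t_apex = float(sol3.t_events[0][0])
        s_apex = sol3.y_events[0][0]

    # --- sample the three phases on the output grid -----------------------
    segs = []
    grid1 = _phase_grid(0.0, t_td, cfg.dt_output)[:-1]  # TD sample -> stance
    segs.append(("flight", grid1, sol1.sol(grid1)))
    grid2 = _phase_grid(t_td, t_to, cfg.dt_output)
    segs.append(("stance", grid2, sol2.sol(grid2)))
    if sol3 is not None and t_apex > t_to:
        grid3 = _phase_grid(t_to, t_apex, cfg.dt_output)[1:]
        if grid3.size:
            segs.append(("flight", grid3, sol3.sol(grid3)))

    return _assemble(protocol, dh, h_ref, t_td, t_to, t_apex, s_apex,
                     segs, params, law, phi_flight, l_mtu_flight)


def _ascent_rhs(protocol, mp, lp, l_mtu_flight, law, t_td):
    """Flight RHS after touch-down (stimulation may reference t_td)."""
    def rhs(t, s):
        a = law.activity(s[3], s[2])
        fb = mtu.solve_fibre_velocity(s[2], l_mtu_flight, 0.0, a, mp)
        u = stimulation(t, t_td, protocol)
        return (s[1], -lp.g, fb.v_ce, law.rate(s[3], u, s[2]))
    return rhs


def _assemble(protocol, dh, h_ref, t_td, t_to, t_apex, s_apex, segs,
              params, law, phi_flight, l_mtu_flight) -> Trajectory:
    mp, lp = params.muscle, params.leg
    rows = {k: [] for k in ("t", "phase", "y", "v_y", "phi", "l_mtu",
                            "v_mtu", "l_ce", "v_ce", "a", "u", "f_ce",
                            "f_mtu", "f_leg")}
    for phase, grid, states in segs:
        y_s, vy_s, lce_s, act_s = states
        for i, t in enumerate(grid):
            y, v_y, l_ce, act = y_s[i], vy_s[i], lce_s[i], act_s[i]
            a = law.activity(act, l_ce)
            if phase == "stance":
                phi = leg.knee_angle_from_height(y, lp)
                l_m = leg.mtu_length_from_knee(phi, lp)
                v_m = leg.mtu_velocity_from_body(y, v_y, lp)
                u = stimulation(t, t_td, protocol)
            else:
                phi, l_m, v_m = phi_flight, l_mtu_flight, 0.0
                u = stimulation(t, t_td if t > t_td else None, protocol)
            fb = mtu.solve_fibre_velocity(l_ce, l_m, v_m, a, mp)
            f_leg = (leg.ground_reaction_force(fb.f_mtu, phi, lp)
                     if phase == "stance" else 0.0)
            rows["t"].append(t)
            rows["phase"].append(phase)
            rows["y"].append(y)
            rows["v_y"].append(v_y)
            rows["phi"].append(phi)
            rows["l_mtu"].append(l_m)
            rows["v_mtu"].append(v_m)
            rows["l_ce"].append(l_ce)
            rows["v_ce"].append(fb.v_ce)
            rows["a"].append(a)
            rows["u"].append(u)
            rows["f_ce"].append(fb.f_ce)
            rows["f_mtu"].append(fb.f_mtu)
            rows["f_leg"].append(f_leg)

    arrays = {k: (np.array(v) if k != "phase" else np.array(v, dtype=object))
              for k, v in rows.items()}
    return Trajectory(
        protocol=protocol.kind, dh=dh, h0=h_ref + dh,
        h1=float(s_apex[0]) - lp.l_f, t_td=t_td, t_to=t_to,
        t_apex_end=t_apex, **arrays)


# ----------------------------------------------------------------------
# reference-state pinning
# ----------------------------------------------------------------------

def pin_reference_touchdown(params: ModelParams, u_flight: float = 0.15,
                            a_td: float = 0.11,
                            f_td: float = 1260.0) -> ModelParams:
    """Fix the free geometry/gain so the constant-stimulation flight
    equilibrium lands exactly on the reference touch-down state.

    With constant flight stimulation the muscle reaches a fixed-end
    equilibrium before impact, so the touch-down activity and pre-impact
    fibre force are properties of that fixed point. Two free constants
    absorb the two constraints analytically:

    * the activation gain is set so the steady-state activity at the
      equilibrium fibre length equals ``a_td``;
    * the MTU reference length is set so the tendon carries ``f_td`` at
      that fibre length (isometric force balance).

    The equilibrium fibre length itself follows from the force-length
    bell: ``fl(l*) = f_td / (a_td * f_max)`` on the ascending limb.
    Only applies to the saturating activation law.
    """
    mp, lp = params.muscle, params.leg
    if mp.act_law != "saturating":
        raise ValueError("touch-down pinning requires the saturating "
                         "activation law")
    c = f_td / (a_td * mp.f_max)
    if not 0.0 < c < 1.0:
        raise ValueError(
            f"target force {f_td} N not reachable at activity {a_td}")
    lam = 1.0 - mp.fl_width * (-math.log(c)) ** (1.0 / mp.fl_exponent)
    if lam <= 0.2:
        raise ValueError(
            f"pinned fibre length {lam:.3f} l_opt unreasonably short; "
            "widen the force-length bell")
    l_ce = lam * mp.l_opt

    # activation gain: steady drive u_flight must yield activity a_td
    x = (a_td - mp.a_min) / (1.0 - a_td)
    gain = x ** (1.0 / mp.act_exponent) / (
        u_flight * lam ** mp.act_len_exponent)

    # MTU reference length: tendon strain carrying f_td
    nu_see = mp.du_see_nll / mp.du_see_l
    if f_td < mp.df_see0:
        eps = mp.du_see_nll * (f_td / mp.df_see0) ** (1.0 / nu_see)
    else:
        eps = mp.du_see_nll + mp.du_see_l * (f_td / mp.df_see0 - 1.0)
    phi_flight = 2.0 * math.asin(lp.l_f / (2.0 * lp.l_s))
    l_mtu_flight = l_ce + mp.l_see0 * (1.0 + eps)
    # phi_ref defaults to the flight angle, where l_mtu_ref is the MTU
    # length; translate if a different reference angle is configured
    l_mtu_ref = l_mtu_flight - lp.r_a * (lp.phi_ref - phi_flight)

    out = params.replace_muscle(act_gain=gain)
    return out.replace_leg(l_mtu_ref=l_mtu_ref)


# ----------------------------------------------------------------------
# periodic reference hopping
# ----------------------------------------------------------------------

@dataclass
class ReferenceCalibration:
    """Periodic-orbit observables and residuals against target values."""

    protocol: str
    h_ref: float                 # m, periodic apex height above l_f
    stance_duration: float       # s
    hop_frequency: float         # Hz
    a_td: float                  # activity at touch-down
    f_ce_td: float               # N, fibre force just before touch-down
    iterations: int
    residuals: dict = field(default_factory=dict)
    trajectory: Trajectory | None = None


def _with_expected_td(protocol: StimProtocol, h: float,
                      g: float) -> StimProtocol:
    if protocol.kind != "rising":
        return protocol
    return replace(protocol, t_td_expected=math.sqrt(2.0 * max(h, 1e-9) / g))


def find_periodic_orbit(protocol: StimProtocol, params: ModelParams,
                        h_init: float = 0.10, max_iter: int = 60,
                        ) -> tuple[float, Trajectory, int]:
    """Apex fixed point by fixed-point iteration h -> h1(h).

    For the rising protocol the expected touch-down time is re-derived from
    the current apex at every iterate, so at convergence the stimulation
    onset is self-consistently 54 ms before the actual touch-down.
    Converged when |h1 - h0| < ``sim.apex_tol``.
    """
    g = params.leg.g
    tol = params.sim.apex_tol
    h = h_init
    traj = None
    for it in range(1, max_iter + 1):
        sp = _with_expected_td(protocol, h, g)
        traj = simulate_cycle(sp, 0.0, params, h)
        log.info("orbit search %s: iter %d  h0=%.5f  h1=%.5f",
                 protocol.kind, it, h, traj.h1)
        if abs(traj.h1 - h) < tol:
            return h, traj, it
        h = traj.h1
        if h <= tol:
            raise SimulationError(
                f"apex collapsed to {h:.2g} m during orbit search "
                f"({protocol.kind}): no periodic hopping for these "
                "parameters")
    raise SimulationError(
        f"apex fixed point not converged after {max_iter} cycles "
        f"({protocol.kind}); last |h1-h0|={abs(traj.h1 - h):.2g} m")


def calibrate_reference(protocol: StimProtocol, targets: dict | None,
                        params: ModelParams, h_init: float = 0.10,
                        ) -> ReferenceCalibration:
    """Locate the periodic orbit and report residuals against targets.

    ``targets`` maps observable names (``h_ref``, ``stance_duration``,
    ``hop_frequency``, ``a_td``, ``f_ce_td``) to target values; residuals
    are (achieved - target). Only parameters the study leaves free may be
    adjusted beforehand; this routine itself only finds the orbit.
    """
    h_ref, traj, iters = find_periodic_orbit(protocol, params, h_init)
    i_pre = traj.index_before_touchdown()
    i_td = traj.stance_slice().start
    cal = ReferenceCalibration(
        protocol=protocol.kind, h_ref=h_ref,
        stance_duration=traj.stance_duration,
        hop_frequency=traj.hop_frequency,
        a_td=float(traj.a[i_td]),
        f_ce_td=float(traj.f_ce[i_pre]),
        iterations=iters, trajectory=traj)
    if targets:
        obs = {"h_ref": cal.h_ref, "stance_duration": cal.stance_duration,
               "hop_frequency": cal.hop_frequency, "a_td": cal.a_td,
               "f_ce_td": cal.f_ce_td}
        cal.residuals = {k: obs[k] - v for k, v in targets.items()
                         if k in obs}
    return cal


def run_perturbation_suite(protocol: StimProtocol, params: ModelParams,
                           h_ref: float) -> list[Trajectory]:
    """Reference plus all perturbed trials, sorted by dh.

    All trials share the calibrated expected touch-down (rising protocol).
    A failure in any single trial aborts the suite, naming the offending
    perturbation.
    """
    sp = _with_expected_td(protocol, h_ref, params.leg.g)
    out = []
    for dh in sorted(set(params.sim.perturbations) | {0.0}):
        try:
            out.append(simulate_cycle(sp, dh, params, h_ref))
        except Exception as exc:
            raise SimulationError(
                f"perturbation dh={dh:+.3f} m failed ({protocol.kind}): "
                f"{exc}") from exc
    return out
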