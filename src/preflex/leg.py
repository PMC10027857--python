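"""Two-segment leg: knee geometry, MTU coupling, and stance dynamics.

The hopper is a point mass m at the hip of a massless, symmetric
two-segment leg constrained to the vertical axis. With the inner knee
angle ``phi`` the closure relation is

    y = 2 * l_s * sin(phi / 2),

so ``phi = pi`` is the straight leg. Knee flexion (smaller phi) lengthens
the extensor MTU through a constant lever arm:

    l_MTU = l_mtu_ref + r_a * (phi_ref - phi),
    v_MTU = -r_a * dphi/dt.

The MTU force produces a knee torque ``T = r_a * F_MTU`` which maps to a
vertical ground reaction force by virtual work,

    F_leg = T / (l_s * cos(phi / 2)),

positive upward; it diverges as the leg straightens (phi -> pi), which is
why take-off always fires before full extension. In flight the knee is
locked at the flight leg length l_f and the body is ballistic, while the
muscle keeps contracting against its own tendon (fixed-end dynamics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import mtu
from .params import LegParams, MuscleParams, StimProtocol
from .protocols import stimulation


@dataclass
class BodyState:
    """Hip height, vertical velocity and contact phase."""

    y: float
    v_y: float
    phase: str  # "flight" | "stance"


def knee_angle_from_height(y: float, lp: LegParams) -> float:
    """Inner knee angle (rad) closing the leg at hip height y."""
    if y <= 0:
        raise ValueError(f"hip height must be positive, got {y}")
    if y > 2.0 * lp.l_s:
        raise ValueError(
            f"hip height {y} exceeds maximal leg length {2 * lp.l_s} "
            "(overextension)")
    return 2.0 * math.asin(y / (2.0 * lp.l_s))


def height_from_knee_angle(phi: float, lp: LegParams) -> float:
    """Hip height (m) at inner knee angle phi; inverse of the above."""
    return 2.0 * lp.l_s * math.sin(phi / 2.0)


def mtu_length_from_knee(phi: float, lp: LegParams) -> float:
    """Extensor MTU length (m); flexion (smaller phi) lengthens it."""
    return lp.l_mtu_ref + lp.r_a * (lp.phi_ref - phi)


def knee_rate_from_body(y: float, v_y: float, lp: LegParams) -> float:
    """dphi/dt from the vertical velocity via the closure relation."""
    phi = knee_angle_from_height(y, lp)
    return v_y / (lp.l_s * math.cos(phi / 2.0))


def mtu_velocity_from_body(y: float, v_y: float, lp: LegParams) -> float:
    """MTU lengthening rate (m/s) in stance; positive while descending."""
    return -lp.r_a * knee_rate_from_body(y, v_y, lp)


def ground_reaction_force(f_mtu: float, phi: float, lp: LegParams) -> float:
    """Vertical GRF (N) transmitted by the knee torque, positive upward."""
    if phi >= math.pi:
        raise ValueError(
            f"knee angle {phi} at or beyond full extension (singular)")
    return lp.r_a * f_mtu / (lp.l_s * math.cos(phi / 2.0))


def stance_derivatives(t: float, state, protocol: StimProtocol,
                       mp: MuscleParams, lp: LegParams, t_td: float,
                       law: mtu.ActivationLaw | None = None):
    """Time derivatives of (y, v_y, l_ce, act_state) during stance.

    Side-effect free. The fibre velocity comes from the four-element force
    equilibrium at the instantaneous MTU length and velocity; the vertical
    acceleration from the GRF of the resulting MTU force.
    """
    y, v_y, l_ce, act_state = state
    if law is None:
        law = mtu.make_activation_law(mp)
    phi = knee_angle_from_height(y, lp)
    l_mtu = mtu_length_from_knee(phi, lp)
    v_mtu = mtu_velocity_from_body(y, v_y, lp)
    a = law.activity(act_state, l_ce)
    fb = mtu.solve_fibre_velocity(l_ce, l_mtu, v_mtu, a, mp)
    f_leg = ground_reaction_force(fb.f_mtu, phi, lp)
    u = stimulation(t, t_td, protocol)
    return (v_y,
            (f_leg - lp.m * lp.g) / lp.m,
            fb.v_ce,
            law.rate(act_state, u, l_ce))


def flight_internal_dynamics(t: float, state, protocol: StimProtocol,
                             mp: MuscleParams, l_mtu_flight: float,
                             law: mtu.ActivationLaw | None = None):
    """Time derivatives of (l_ce, act_state) in flight (fixed-end).

    The knee is locked, so the MTU length is frozen at its flight value and
    v_MTU = 0; fibre and activation dynamics keep evolving under the
    protocol's flight-time stimulation. Touch-down time is unknown in
    flight: the 'const' protocol holds u = u_0 there by definition, the
    'rising' protocol is anchored to the expected touch-down.
    """
    l_ce, act_state = state
    if law is None:
        law = mtu.make_activation_law(mp)
    a = law.activity(act_state, l_ce)
    fb = mtu.solve_fibre_velocity(l_ce, l_mtu_flight, 0.0, a, mp)
    u = stimulation(t, None, protocol)
    return (fb.v_ce, law.rate(act_state, u, l_ce))


def event_touchdown(y: float, lp: LegParams) -> float:
    """Signed touch-down test: crosses zero as y falls through l_f."""
    return y - lp.l_f


def event_takeoff(y: float, f_leg: float, lp: LegParams) -> bool:
    """True once either take-off condition holds in stance."""
    return y > lp.l_f or f_leg <= 0.0
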