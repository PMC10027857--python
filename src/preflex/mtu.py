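"""Hill-type muscle-tendon unit: force laws, fibre-velocity equilibrium,
and activation dynamics.

The MTU has four elements. The contractile element (CE, the muscle fibres)
acts in parallel with a passive elastic element (PEE); that pair is in
series with a tendon-like elastic element (SEE) and a damper (SDE). At
every instant the elements satisfy the force equilibrium

    F_MTU = F_CE + F_PEE = F_SEE + F_SDE,

which implicitly determines the fibre velocity ``v_CE`` given the fibre
length, MTU length/velocity and activity. Sign convention: negative v_CE =
fibre shortening (concentric), positive = lengthening (eccentric).

CE force is separable: ``F_CE = a * fl(l_CE) * fv(v_CE) * f_max`` with a
bell-shaped force-length factor and a hyperbolic force-velocity factor
(classic concentric Hill hyperbola; saturating eccentric branch joined with
matching slope at v = 0 when ``s_ecc = 1``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .params import MuscleParams

log = logging.getLogger(__name__)

#: lengths are clamped above this to avoid singular passive expressions
MIN_LENGTH = 1e-6


@dataclass
class MTUState:
    """Internal muscle state: fibre length and activity."""

    l_ce: float
    a: float


@dataclass
class ForceBalance:
    """Element forces and the fibre velocity that balances them."""

    f_ce: float
    f_pee: float
    f_see: float
    f_sde: float
    f_mtu: float
    v_ce: float

    @property
    def residual(self) -> float:
        return (self.f_ce + self.f_pee) - (self.f_see + self.f_sde)


# ----------------------------------------------------------------------
# force laws
# ----------------------------------------------------------------------

def force_length_factor(l_ce: float, p: MuscleParams) -> float:
    """Bell-shaped active force-length factor, 1 at the optimal length.

    ``fl = exp(-|((l/l_opt) - 1) / fl_width| ** fl_exponent)``
    """
    if l_ce <= 0:
        raise ValueError(f"fibre length must be positive, got {l_ce}")
    lam = l_ce / p.l_opt
    return math.exp(-abs((lam - 1.0) / p.fl_width) ** p.fl_exponent)


def force_velocity_factor(v_ce: float, p: MuscleParams) -> float:
    """Normalized force-velocity factor, 1 at v = 0.

    Concentric (v <= 0): Hill hyperbola
        fv = (1 + a_rel) * b / (b - v) - a_rel,     b = b_rel * l_opt,
    zero at v = -v_max = -b / a_rel and clamped at 0 below.
    Eccentric (v > 0): saturating hyperbola
        fv = f_ecc - (f_ecc - 1) * c / (c + v),
    with c chosen so the slope at 0+ is ``s_ecc`` times the concentric
    slope at 0- (continuously differentiable for s_ecc = 1).
    """
    b = p.b_rel * p.l_opt
    if v_ce <= 0.0:
        if v_ce <= -p.v_max:
            return 0.0
        return (1.0 + p.a_rel) * b / (b - v_ce) - p.a_rel
    slope0 = (1.0 + p.a_rel) / b  # d(fv)/dv at v = 0-
    c = (p.f_ecc_plateau - 1.0) / (p.s_ecc * slope0)
    return p.f_ecc_plateau - (p.f_ecc_plateau - 1.0) * c / (c + v_ce)


def contractile_force(v_ce: float, l_ce: float, a: float,
                      p: MuscleParams) -> float:
    """CE force (N): activity x force-length x force-velocity x f_max."""
    if not (p.a_min - 1e-12 <= a <= p.a_max + 1e-12):
        raise ValueError(
            f"activity {a} outside bounds [{p.a_min}, {p.a_max}]")
    return a * force_length_factor(l_ce, p) * force_velocity_factor(v_ce, p) \
        * p.f_max


def parallel_elastic_force(l_ce: float, p: MuscleParams) -> float:
    """PEE force (N): engages above ``l_pee0 * l_opt``, polynomial beyond."""
    l_ce = max(l_ce, MIN_LENGTH)
    l_engage = p.l_pee0 * p.l_opt
    if l_ce <= l_engage:
        return 0.0
    return p.k_pee * p.f_max * ((l_ce - l_engage) / p.l_opt) ** p.n_pee


def series_elastic_force(l_see: float, p: MuscleParams) -> float:
    """SEE force (N): zero below slack, nonlinear toe, then linear."""
    eps = (l_see - p.l_see0) / p.l_see0
    if eps <= 0.0:
        return 0.0
    nu = p.du_see_nll / p.du_see_l  # exponent making the junction C1
    if eps < p.du_see_nll:
        return p.df_see0 * (eps / p.du_see_nll) ** nu
    return p.df_see0 * (1.0 + (eps - p.du_see_nll) / p.du_see_l)


def series_damper_coefficient(f_ce_pee: float, p: MuscleParams) -> float:
    """SDE coefficient (N s/m), force-dependent between r_sde and 1."""
    return p.d_sde_max * ((1.0 - p.r_sde) * f_ce_pee / p.f_max + p.r_sde)


def passive_and_serial_forces(l_ce: float, l_mtu: float, v_see: float,
                              f_ce_pee: float,
                              p: MuscleParams) -> tuple[float, float, float]:
    """(F_PEE, F_SEE, F_SDE) for the given lengths and serial velocity.

    ``f_ce_pee`` is the CE+PEE force the damper coefficient depends on.
    Elastic forces clamp to zero below engagement/slack; they are never
    negative.
    """
    l_ce = max(l_ce, MIN_LENGTH)
    f_pee = parallel_elastic_force(l_ce, p)
    f_see = series_elastic_force(l_mtu - l_ce, p)
    f_sde = series_damper_coefficient(f_ce_pee, p) * v_see
    return f_pee, f_see, f_sde


# ----------------------------------------------------------------------
# fibre-velocity equilibrium
# ----------------------------------------------------------------------

def _equilibrium_residual(v_ce: float, l_ce: float, l_mtu: float,
                          v_mtu: float, a: float, p: MuscleParams) -> float:
    f_ce = contractile_force(v_ce, l_ce, a, p)
    f_pee = parallel_elastic_force(l_ce, p)
    f_see = series_elastic_force(l_mtu - l_ce, p)
    d = series_damper_coefficient(f_ce + f_pee, p)
    f_sde = d * (v_mtu - v_ce)
    return (f_ce + f_pee) - (f_see + f_sde)


class EquilibriumError(RuntimeError):
    """No fibre velocity balances the element forces."""


def solve_fibre_velocity(l_ce: float, l_mtu: float, v_mtu: float, a: float,
                         p: MuscleParams) -> ForceBalance:
    """Fibre velocity satisfying the four-element force equilibrium.

    Brackets the root in ``[-2 v_max, +5 v_max]`` (expanded once on
    failure) and bisects with Brent's method; the residual of the returned
    balance is below ``1e-6 * f_max``. Deterministic: no initial guess.
    """
    if not (p.a_min - 1e-12 <= a <= p.a_max + 1e-12):
        raise ValueError(
            f"activity {a} outside bounds [{p.a_min}, {p.a_max}]")
    l_ce = max(l_ce, MIN_LENGTH)

    def res(v):
        return _equilibrium_residual(v, l_ce, l_mtu, v_mtu, a, p)

    lo, hi = -2.0 * p.v_max, 5.0 * p.v_max
    rlo, rhi = res(lo), res(hi)
    if rlo * rhi > 0.0:
        lo, hi = -8.0 * p.v_max, 30.0 * p.v_max  # expand once
        rlo, rhi = res(lo), res(hi)
        if rlo * rhi > 0.0:
            raise EquilibriumError(
                "no fibre-velocity root in bracket "
                f"[{lo:.3g}, {hi:.3g}] m/s: residuals ({rlo:.6g}, {rhi:.6g}) N "
                f"at l_ce={l_ce:.6g}, l_mtu={l_mtu:.6g}, v_mtu={v_mtu:.6g}, "
                f"a={a:.6g} (inconsistent parameters?)")
    v_ce = brentq(res, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)

    f_ce = contractile_force(v_ce, l_ce, a, p)
    f_pee = parallel_elastic_force(l_ce, p)
    f_see = series_elastic_force(l_mtu - l_ce, p)
    f_sde = series_damper_coefficient(f_ce + f_pee, p) * (v_mtu - v_ce)
    fb = ForceBalance(f_ce=f_ce, f_pee=f_pee, f_see=f_see, f_sde=f_sde,
                      f_mtu=f_see + f_sde, v_ce=v_ce)
    if abs(fb.residual) > 1e-6 * p.f_max:
        raise EquilibriumError(
            f"equilibrium residual {fb.residual:.3g} N exceeds tolerance at "
            f"l_ce={l_ce:.6g}, l_mtu={l_mtu:.6g}, v_mtu={v_mtu:.6g}, a={a:.6g}")
    return fb


# ----------------------------------------------------------------------
# activation dynamics
# ----------------------------------------------------------------------
#
# Two first-order strategies turn the stimulation u(t) into activity a(t),
# both with a fibre-length-dependent gain and output bounded in
# [a_min, a_max]:
#
# "linear" (plain lag): the ODE state is the activity itself,
#     da/dt = rho_l(l_ce) * (u_mapped - a) / tau,
# with u mapped affinely onto [a_min, a_max] and the rate clamped at the
# bounds. Its steady state equals the mapped stimulation.
#
# "saturating" (default): a calcium-like drive c follows
#     dc/dt = (u - c) / tau,
# and activity is a saturating Hill function of the drive scaled by a
# length gain,
#     a(c, l) = (a_min + x) / (1 + x),   x = (rho0 * (l/l_opt)^p * c)^nu.
# Its steady-state activity is a *nonlinear* function of u: sub-maximal
# stimulation produces sub-proportional activity (e.g. u = 0.15 holds
# a ~ 0.11), while the cubic saturation makes a rise much faster than the
# drive once u ramps up. Bounds [a_min, ~1) hold by construction.


def _length_gain_linear(l_ce: float, p: MuscleParams) -> float:
    """Rational length gain of the linear law, equal to 1 at l_opt."""
    lam = max(l_ce, MIN_LENGTH) / p.l_opt
    k = p.act_len_gain
    return k * lam / (1.0 + (k - 1.0) * lam)


def _clamp_u(u: float) -> float:
    if u < 0.0 or u > 1.0:
        log.warning("stimulation %.4g outside [0, 1]; clamping", u)
        return min(1.0, max(0.0, u))
    return u


def activation_rate(a: float, u: float, l_ce: float,
                    p: MuscleParams) -> float:
    """Rate da/dt (1/s) of the *linear* activation law.

    First-order lag toward the stimulation mapped onto the activity bounds,
    with a length-dependent gain equal to 1 at the optimal fibre length.
    The rate is clamped so integration never leaves [a_min, a_max].
    """
    if not (p.a_min - 1e-12 <= a <= p.a_max + 1e-12):
        raise ValueError(
            f"activity {a} outside bounds [{p.a_min}, {p.a_max}]")
    u = _clamp_u(u)
    u_mapped = p.a_min + (p.a_max - p.a_min) * u
    rate = _length_gain_linear(l_ce, p) * (u_mapped - a) / p.tau_act
    if a >= p.a_max and rate > 0.0:
        return 0.0
    if a <= p.a_min and rate < 0.0:
        return 0.0
    return rate


class ActivationLaw:
    """Strategy interface: ODE on an internal state, activity read-out."""

    def rate(self, state: float, u: float, l_ce: float) -> float:
        raise NotImplementedError

    def activity(self, state: float, l_ce: float) -> float:
        raise NotImplementedError

    def steady_state(self, u: float) -> float:
        """Fixed point of the internal state under constant stimulation."""
        raise NotImplementedError


class LinearActivation(ActivationLaw):
    """State = activity; plain first-order lag (see ``activation_rate``)."""

    def __init__(self, p: MuscleParams):
        self.p = p

    def rate(self, state, u, l_ce):
        return activation_rate(state, u, l_ce, self.p)

    def activity(self, state, l_ce):
        return min(self.p.a_max, max(self.p.a_min, state))

    def steady_state(self, u):
        u = _clamp_u(u)
        return self.p.a_min + (self.p.a_max - self.p.a_min) * u


class SaturatingActivation(ActivationLaw):
    """State = normalized drive c; activity saturates in the drive."""

    def __init__(self, p: MuscleParams):
        self.p = p

    def rate(self, state, u, l_ce):
        u = _clamp_u(u)
        rate = (u - state) / self.p.tau_act
        if state >= 1.0 and rate > 0.0:
            return 0.0
        if state <= 0.0 and rate < 0.0:
            return 0.0
        return rate

    def activity(self, state, l_ce):
        p = self.p
        lam = max(l_ce, MIN_LENGTH) / p.l_opt
        rho = p.act_gain * lam ** p.act_len_exponent
        x = max(rho * state, 0.0) ** p.act_exponent
        return (p.a_min + x) / (1.0 + x)

    def steady_state(self, u):
        return _clamp_u(u)

    def drive_for_activity(self, a: float, l_ce: float) -> float:
        """Inverse of ``activity`` at fixed fibre length (for calibration)."""
        p = self.p
        a = min(max(a, p.a_min), 1.0 - 1e-12)
        lam = max(l_ce, MIN_LENGTH) / p.l_opt
        rho = p.act_gain * lam ** p.act_len_exponent
        x = (a - p.a_min) / (1.0 - a)
        return x ** (1.0 / p.act_exponent) / rho


def make_activation_law(p: MuscleParams) -> ActivationLaw:
    if p.act_law == "linear":
        return LinearActivation(p)
    return SaturatingActivation(p)


# ----------------------------------------------------------------------
# isometric fixed point (fixed-end contraction at constant stimulation)
# ----------------------------------------------------------------------

def isometric_fixed_point(l_mtu: float, u: float,
                          p: MuscleParams) -> tuple[float, float]:
    """(l_ce, activation state) of the fixed-end equilibrium at constant u.

    With the MTU length frozen and stimulation constant, fibre length and
    activity relax to the state where the isometric CE+PEE force balances
    the SEE force at zero serial velocity; the activation state sits at its
    own fixed point. Used as the history-free initial condition in flight.
    """
    law = make_activation_law(p)
    state = law.steady_state(u)

    def res(l_ce):
        a = law.activity(state, l_ce)
        f_iso = a * force_length_factor(l_ce, p) * p.f_max
        return (f_iso + parallel_elastic_force(l_ce, p)
                - series_elastic_force(l_mtu - l_ce, p))

    lo = 0.2 * p.l_opt
    hi = min(1.55 * p.l_opt, l_mtu - MIN_LENGTH)
    if res(lo) * res(hi) > 0.0:
        raise EquilibriumError(
            f"no fixed-end equilibrium for l_mtu={l_mtu:.6g}, u={u:.4g}")
    l_ce = brentq(res, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    return l_ce, state
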