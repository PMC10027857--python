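"""Parameter containers for the muscle-tendon unit, leg, stimulation and solver.

All quantities are SI (m, s, kg, N, rad) unless noted. Defaults reproduce the
reference hopping conditions of the study: a single knee-extensor MTU driving
a two-segment leg of an 80 kg vertical hopper. Constants that the study pins
directly (body mass, gravity, leg geometry, maximum isometric force, optimal
fibre length, activation time constant, activity bounds, PEE engagement
length) are marked "pinned" below; the remaining shape constants of the
force-velocity, series-elastic, damper and activation laws were calibrated
once against the reference hopping observables and are documented in
docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class MuscleParams:
    """Constants of the four-element Hill-type muscle-tendon unit.

    The contractile element (CE) force is separable:
    ``F_CE = a * fl(l_CE) * fv(v_CE) * f_max`` with a bell-shaped
    force-length factor ``fl`` and a hyperbolic force-velocity factor ``fv``
    (concentric Hill hyperbola, saturating eccentric branch). A parallel
    elastic element (PEE) engages above ``l_pee0 * l_opt``; the series
    elastic element (SEE) has a nonlinear toe followed by a linear region;
    the series damping element (SDE) is linear in series-element velocity
    with a force-dependent coefficient.
    """

    # --- contractile element (pinned) ---
    f_max: float = 22_000.0       # N, maximum isometric force (pinned)
    l_opt: float = 0.1            # m, optimal fibre length (pinned)

    # --- force-velocity shape (calibrated) ---
    a_rel: float = 0.2            # -, concentric hyperbola curvature
    b_rel: float = 1.5            # 1/s, concentric hyperbola rate constant
    f_ecc_plateau: float = 1.09   # -, eccentric force asymptote / isometric
    s_ecc: float = 1.0            # -, eccentric/concentric slope ratio at v=0
                                  #    (1.0 keeps the law C1 at v=0)

    # --- force-length bell (calibrated) ---
    fl_width: float = 0.40        # -, bell half-width in units of l_opt
    fl_exponent: float = 1.5      # -, bell exponent

    # --- parallel elastic element ---
    l_pee0: float = 0.95          # -, engagement length / l_opt (pinned)
    k_pee: float = 2.0            # -, stiffness scale (x f_max per l_opt^n)
    n_pee: float = 2.5            # -, exponent

    # --- series elastic element (calibrated) ---
    l_see0: float = 0.40          # m, slack length
    du_see_nll: float = 0.082     # -, strain at end of nonlinear toe
    du_see_l: float = 0.0328      # -, linear-region strain per df_see0
    df_see0: float = 26_000.0     # N, force at end of toe region

    # --- series damping element (calibrated) ---
    d_sde_max: float = 24_000.0   # N s/m, maximum damper coefficient
    r_sde: float = 0.01           # -, force-independent coefficient fraction

    # --- activation dynamics ---
    tau_act: float = 0.0885       # s, activation time constant (pinned)
    a_min: float = 0.005          # -, minimum activity (pinned)
    a_max: float = 1.0            # -, maximum activity (pinned)
    act_law: str = "saturating"   # "saturating" (calcium-like, default)
                                  # or "linear" (plain first-order lag)
    act_gain: float = 6.0098058579  # -, saturation gain rho0 (saturating law)
    act_exponent: float = 3.0     # -, saturation exponent nu (saturating law)
    act_len_exponent: float = 1.7 # -, length-gain exponent p in (l/l_opt)^p
    act_len_gain: float = 3.0     # -, curvature k of the linear law's
                                  #    length gain k*lam/(1+(k-1)*lam)

    def __post_init__(self) -> None:
        _require(self.f_max > 0, "muscle.f_max must be positive")
        _require(self.l_opt > 0, "muscle.l_opt must be positive")
        _require(self.a_rel > 0 and self.b_rel > 0,
                 "muscle.a_rel and muscle.b_rel must be positive")
        _require(self.f_ecc_plateau > 1,
                 "muscle.f_ecc_plateau must exceed 1 (eccentric asymptote)")
        _require(self.s_ecc > 0, "muscle.s_ecc must be positive")
        _require(self.fl_width > 0 and self.fl_exponent > 0,
                 "muscle.fl_width and muscle.fl_exponent must be positive")
        _require(0 < self.l_pee0 < 1, "muscle.l_pee0 must lie in (0, 1)")
        _require(self.l_see0 > 0, "muscle.l_see0 must be positive")
        _require(self.du_see_nll > 0 and self.du_see_l > 0,
                 "muscle SEE strain constants must be positive")
        _require(self.df_see0 > 0, "muscle.df_see0 must be positive")
        _require(self.d_sde_max >= 0, "muscle.d_sde_max must be >= 0")
        _require(0 <= self.r_sde <= 1, "muscle.r_sde must lie in [0, 1]")
        _require(self.tau_act > 0, "muscle.tau_act must be positive")
        _require(0 < self.a_min < self.a_max <= 1,
                 "activity bounds must satisfy 0 < a_min < a_max <= 1")
        _require(self.act_law in ("saturating", "linear"),
                 "muscle.act_law must be 'saturating' or 'linear'")

    @property
    def v_max(self) -> float:
        """Maximal shortening speed (m/s): fv reaches 0 at v = -v_max."""
        return self.b_rel * self.l_opt / self.a_rel


@dataclass
class LegParams:
    """Two-segment leg with a point mass at the hip.

    The inner knee angle ``phi`` closes the geometry through
    ``y = 2 l_s sin(phi/2)``; knee flexion (smaller phi) lengthens the
    extensor MTU through a constant lever arm:
    ``l_MTU = l_mtu_ref + r_a * (phi_ref - phi)``.
    """

    m: float = 80.0               # kg, body mass (pinned)
    g: float = 9.81               # m/s^2 (pinned)
    l_f: float = 0.99             # m, flight leg length (pinned)
    l_s: float = 0.5              # m, segment length (pinned)
    r_a: float = 0.04             # m, muscle lever arm (pinned)
    phi_ref: float | None = None  # rad, reference knee angle (default: the
                                  #      flight/touch-down angle)
    l_mtu_ref: float = 0.4796765988  # m, MTU length at phi_ref (calibrated)

    def __post_init__(self) -> None:
        _require(self.m > 0, "leg.m must be positive")
        _require(self.g > 0, "leg.g must be positive")
        _require(self.l_s > 0, "leg.l_s must be positive")
        _require(0 < self.l_f <= 2 * self.l_s,
                 "leg.l_f must lie in (0, 2*l_s] (leg cannot overextend)")
        _require(self.r_a > 0, "leg.r_a must be positive")
        _require(self.l_mtu_ref > 0, "leg.l_mtu_ref must be positive")
        if self.phi_ref is None:
            self.phi_ref = 2.0 * math.asin(self.l_f / (2.0 * self.l_s))


@dataclass
class StimProtocol:
    """Open-loop ramp stimulation.

    ``kind='const'``: u is held at the prestimulation level ``u_0``
    throughout flight and the first ``delay`` seconds after the *actual*
    touch-down, then ramps at ``u_beta``.

    ``kind='rising'``: u is 0 until ``delay`` seconds before the *expected*
    touch-down time ``t_td_expected`` (the touch-down of the unperturbed
    reference trial), then ramps at ``u_beta`` regardless of the actual
    ground height. The ramp is never re-anchored to the actual touch-down.

    In both cases u is clamped to [0, 1].
    """

    kind: str = "const"           # "const" | "rising"
    u_0: float = 0.15             # -, prestimulation level (const only)
    u_beta: float = 10.0          # 1/s, ramp slope
    delay: float | None = None    # s, 0.030 for const / 0.054 for rising
    t_td_expected: float | None = None  # s, rising only

    def __post_init__(self) -> None:
        _require(self.kind in ("const", "rising"),
                 "stimulation.kind must be 'const' or 'rising'")
        if self.delay is None:
            self.delay = 0.030 if self.kind == "const" else 0.054
        _require(self.delay >= 0, "stimulation.delay must be >= 0")
        _require(self.u_beta >= 0, "stimulation.u_beta must be >= 0")
        _require(0 <= self.u_0 <= 1, "stimulation.u_0 must lie in [0, 1]")


#: Ground-height perturbations of the study (m). Positive = step-down
#: (deeper drop), negative = step-up.
STUDY_PERTURBATIONS: tuple[float, ...] = (
    -0.050, -0.025, 0.025, 0.050, 0.075, 0.100)


@dataclass
class SimConfig:
    """Integrator and output settings (adaptive RK45)."""

    max_step: float = 1e-4        # s, maximum integrator step
    abs_tol: float = 1e-8         # absolute error tolerance
    rel_tol: float = 1e-8         # relative error tolerance
    preflex_window: float = 0.030 # s, analysis window after touch-down
    dt_output: float = 1e-4       # s, output sampling interval
    perturbations: tuple[float, ...] = STUDY_PERTURBATIONS
    event_horizon: float = 5.0    # s, wall on event search per phase
    apex_tol: float = 1e-4        # m, periodic-orbit convergence tolerance

    def __post_init__(self) -> None:
        _require(self.max_step > 0, "sim.max_step must be positive")
        _require(self.abs_tol > 0 and self.rel_tol > 0,
                 "sim tolerances must be positive")
        _require(self.preflex_window > 0,
                 "sim.preflex_window must be positive")
        _require(self.dt_output > 0, "sim.dt_output must be positive")
        _require(self.event_horizon > 0, "sim.event_horizon must be positive")


@dataclass
class ModelParams:
    """Full parameter set: one muscle, one leg, solver settings."""

    muscle: MuscleParams = field(default_factory=MuscleParams)
    leg: LegParams = field(default_factory=LegParams)
    sim: SimConfig = field(default_factory=SimConfig)

    def replace_muscle(self, **kw) -> "ModelParams":
        return ModelParams(muscle=replace(self.muscle, **kw),
                           leg=self.leg, sim=self.sim)

    def replace_leg(self, **kw) -> "ModelParams":
        return ModelParams(muscle=self.muscle,
                           leg=replace(self.leg, **kw), sim=self.sim)


def param_dict(obj) -> dict:
    """Flat name -> value mapping of a parameter dataclass."""
    return {f.name: getattr(obj, f.name) for f in fields(obj)}
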