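"""Synthetic test inputs with analytically known force partitions.

The decomposition stage is tested independently of the hopping simulator
on fabricated trajectories whose force law is deliberately *not* the Hill
law but a simple separable product of polynomial factors,

    f(v, l, a) = g1(v) * g2(l) * g3(a),

sampled along polynomial ramps v(t), a(t) with l(t) the exact integral of
v(t) (kinematic consistency by construction). For such paths every
component path integral

    F_V = int g1'(v) g2(l) g3(a) dv,   etc.

is itself a polynomial in time, computed here exactly by polynomial
algebra (composition, multiplication, antidifferentiation) — a closed-form
oracle fully independent of the finite-difference/trapezoid numerics under
test. A pseudo-touch-down with a velocity jump (length and activity
continuous) emulates the instantaneous impact of the simulator.

``make_mini_config`` provides a coarse-but-faithful solver configuration
for fast end-to-end runs; all model constants are identical to the full
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial import Polynomial

from .engine import Trajectory
from .params import ModelParams, SimConfig


@dataclass
class AnalyticTrajectorySpec:
    """A fabricated stance path and separable force law.

    ``g1_v``, ``g2_l``, ``g3_a`` are polynomial coefficient sequences
    (ascending order) for the velocity, length and activity factors;
    ``v_coeffs`` / ``a_coeffs`` are polynomials in time-since-touch-down
    for the stance kinematics. Before touch-down the state is constant at
    (``v_pre``, ``l_0``, ``a_coeffs[0]``).
    """

    duration: float = 0.05            # s, stance length of the fixture
    dt: float = 1e-4                  # s, sample spacing
    n_pre: int = 5                    # pre-touch-down samples
    v_pre: float = 0.0                # m/s, flight fibre velocity
    l_0: float = 0.09                 # m, fibre length at touch-down
    v_coeffs: tuple = (0.3, -8.0)     # m/s, stance v(t') polynomial
    a_coeffs: tuple = (0.1, 3.0)      # -, stance a(t') polynomial
    g1_v: tuple = (1.0, 1.0)          # force factor g1(v)
    g2_l: tuple = (1.0,)              # force factor g2(l)
    g3_a: tuple = (0.0, 1.0)          # force factor g3(a)
    scale: float = 1000.0             # N, overall force scale
    a_bounds: tuple = (0.005, 1.0)

    def validate(self) -> None:
        pa = Polynomial(self.a_coeffs)
        t = np.linspace(0.0, self.duration, 101)
        a = pa(t)
        lo, hi = self.a_bounds
        if a.min() < lo - 1e-12 or a.max() > hi + 1e-12:
            raise ValueError(
                f"activity path leaves [{lo}, {hi}]: "
                f"range [{a.min():.4g}, {a.max():.4g}]")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")


@dataclass
class AnalyticComponents:
    """Closed-form component polynomials in time since touch-down."""

    f_v: Polynomial
    f_l: Polynomial
    f_a: Polynomial
    f_0: float
    jump_v: float                     # force jump assigned to F_V at impact

    def reconstruction(self, t_since_td: np.ndarray) -> np.ndarray:
        return (self.f_v(t_since_td) + self.f_l(t_since_td)
                + self.f_a(t_since_td) + self.f_0)


def make_analytic_trajectory(spec: AnalyticTrajectorySpec,
                             ) -> tuple[Trajectory, AnalyticComponents,
                                        callable]:
    """Build the fixture: (trajectory table, closed forms, force law).

    The returned callable ``f(v, l, a)`` is the separable force law; the
    closed forms satisfy ``F_V + F_L + F_A + F_0 = f(v(t), l(t), a(t))``
    identically (up to float roundoff).
    """
    spec.validate()
    g1 = Polynomial(np.asarray(spec.g1_v) * spec.scale)
    g2 = Polynomial(spec.g2_l)
    g3 = Polynomial(spec.g3_a)

    def f_law(v, l, a):
        return g1(v) * g2(l) * g3(a)

    pv = Polynomial(spec.v_coeffs)
    pl = pv.integ() + spec.l_0            # l(t') = l_0 + int v
    pa = Polynomial(spec.a_coeffs)

    # closed-form component integrands (polynomials in t'), integrated
    g1_of_v, g2_of_l, g3_of_a = g1(pv), g2(pl), g3(pa)
    int_v = (g1.deriv()(pv) * g2_of_l * g3_of_a * pv.deriv()).integ()
    int_l = (g1_of_v * g2.deriv()(pl) * g3_of_a * pv).integ()  # dl/dt = v
    int_a = (g1_of_v * g2_of_l * g3.deriv()(pa) * pa.deriv()).integ()

    a0 = float(pa(0.0))
    f_0 = float(f_law(spec.v_pre, spec.l_0, a0))
    jump_v = float(f_law(pv(0.0), spec.l_0, a0)) - f_0
    comps = AnalyticComponents(
        f_v=int_v - int_v(0.0) + jump_v,
        f_l=int_l - int_l(0.0),
        f_a=int_a - int_a(0.0),
        f_0=f_0, jump_v=jump_v)

    # assemble a trajectory table in the simulator's dialect
    t_td = spec.n_pre * spec.dt
    t_pre = spec.dt * np.arange(spec.n_pre)
    t_st = t_td + np.arange(int(round(spec.duration / spec.dt)) + 1) * spec.dt
    ts = t_st - t_td
    t = np.r_[t_pre, t_st]
    v = np.r_[np.full(spec.n_pre, spec.v_pre), pv(ts)]
    l = np.r_[np.full(spec.n_pre, spec.l_0), pl(ts)]
    a = np.r_[np.full(spec.n_pre, a0), pa(ts)]
    f = f_law(v, l, a)
    z = np.zeros_like(t)
    phase = np.array(["flight"] * spec.n_pre + ["stance"] * ts.size,
                     dtype=object)
    traj = Trajectory(
        protocol="fixture", dh=0.0, h0=0.0, h1=0.0,
        t_td=float(t_td), t_to=float(t_st[-1]), t_apex_end=float(t_st[-1]),
        t=t, phase=phase, y=z, v_y=z, phi=z, l_mtu=z, v_mtu=z,
        l_ce=l, v_ce=v, a=a, u=z, f_ce=f, f_mtu=f.copy(), f_leg=z)
    return traj, comps, f_law


def random_spec(seed: int, duration: float = 0.05,
                dt: float = 1e-4) -> AnalyticTrajectorySpec:
    """Deterministic randomized fixture; identical for identical seeds."""
    rng = np.random.default_rng(seed)
    v0 = rng.uniform(-0.5, 0.5)
    v1 = rng.uniform(-10.0, 10.0)
    v2 = rng.uniform(-100.0, 100.0)
    a0 = rng.uniform(0.05, 0.3)
    a1 = rng.uniform(0.0, (0.9 - a0) / duration)
    return AnalyticTrajectorySpec(
        duration=duration, dt=dt,
        v_pre=rng.uniform(-0.2, 0.2), l_0=rng.uniform(0.07, 0.11),
        v_coeffs=(v0, v1, v2),
        a_coeffs=(a0, a1),
        g1_v=(1.0, rng.uniform(0.2, 1.5), rng.uniform(0.0, 0.3)),
        g2_l=(1.0, rng.uniform(-2.0, 8.0)),
        g3_a=(rng.uniform(0.0, 0.05), 1.0, rng.uniform(0.0, 0.5)),
        scale=rng.uniform(500.0, 3000.0))


def make_mini_config(params: ModelParams | None = None) -> ModelParams:
    """Coarse solver settings for fast end-to-end test runs.

    Identical model constants; only the integrator step cap, tolerances and
    output sampling are relaxed (the dynamics are smooth within phases, so
    apex heights move by well under a millimetre).
    """
    base = params or ModelParams()
    mini_sim = replace(base.sim, max_step=2e-3, dt_output=5e-4,
                       abs_tol=1e-7, rel_tol=1e-7)
    return ModelParams(muscle=base.muscle, leg=base.leg, sim=mini_sim)
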