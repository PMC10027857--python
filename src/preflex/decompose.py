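"""Offline decomposition of muscle-fibre force along a trajectory.

The fibre force is a nonlinear function of the sampled state,
``F_CE(t) = f_CE(v_CE(t), l_CE(t), a(t))``. Writing its change since the
instant just before touch-down as a path integral and applying the chain
rule splits the force into additive components:

    F_CE = F_V + F_L + F_A + F_0
    F_V  = int df/dv_CE dv_CE     (force-velocity contribution)
    F_L  = int df/dl_CE dl_CE     (force-length contribution)
    F_A  = int df/da    da        (activity contribution)

where ``F_0`` is the fibre force at the last sample before touch-down and
each integral runs along the simulated trajectory. Touch-down is an
instantaneous impact: fibre length and activity are continuous across it
while the fibre velocity jumps, so the force jump at touch-down belongs
entirely to the force-velocity component and the integrations initialize
algebraically as

    F_L(t_TD) = F_A(t_TD) = 0,     F_V(t_TD) = F_CE(t_TD) - F_0.

Partial derivatives are central finite differences of the force law along
the trajectory samples; the integrals use the cumulative trapezoidal rule
on the output grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .engine import Trajectory
from .params import SimConfig

#: relative finite-difference steps (in units of v_max, l_opt, and 1)
FD_REL_STEP = 1e-6


@dataclass
class DecompositionResult:
    """Component force series on the trajectory grid from just before
    touch-down to ``t_x``; index 0 is the last flight sample."""

    t: np.ndarray = field(repr=False)
    f_ce: np.ndarray = field(repr=False)
    f_v: np.ndarray = field(repr=False)
    f_l: np.ndarray = field(repr=False)
    f_a: np.ndarray = field(repr=False)
    f_0: float
    t_td: float
    reconstruction_error: float

    def reconstruction(self) -> np.ndarray:
        return self.f_v + self.f_l + self.f_a + self.f_0


def partials_along_trajectory(f_ce: Callable[[float, float, float], float],
                              v_ce: float, l_ce: float, a: float,
                              scale_v: float = 1.0, scale_l: float = 0.1,
                              a_bounds: tuple[float, float] = (0.005, 1.0),
                              rel_step: float = FD_REL_STEP,
                              ) -> tuple[float, float, float]:
    """(df/dv, df/dl, df/da) of the force law at one trajectory sample.

    Central second-order differences with absolute steps
    ``rel_step * scale_v`` (velocity), ``rel_step * scale_l`` (length) and
    ``rel_step`` (activity); one-sided at the activity bounds.
    """
    hv = rel_step * scale_v
    hl = rel_step * scale_l
    ha = rel_step

    dfv = (f_ce(v_ce + hv, l_ce, a) - f_ce(v_ce - hv, l_ce, a)) / (2 * hv)
    dfl = (f_ce(v_ce, l_ce + hl, a) - f_ce(v_ce, l_ce - hl, a)) / (2 * hl)

    a_lo, a_hi = a_bounds
    if a - ha < a_lo:
        dfa = (f_ce(v_ce, l_ce, a + ha) - f_ce(v_ce, l_ce, a)) / ha
    elif a + ha > a_hi:
        dfa = (f_ce(v_ce, l_ce, a) - f_ce(v_ce, l_ce, a - ha)) / ha
    else:
        dfa = (f_ce(v_ce, l_ce, a + ha)
               - f_ce(v_ce, l_ce, a - ha)) / (2 * ha)
    for name, val in (("df/dv", dfv), ("df/dl", dfl), ("df/da", dfa)):
        if not math.isfinite(val):
            raise ValueError(
                f"non-finite {name} at v={v_ce}, l={l_ce}, a={a}")
    return dfv, dfl, dfa


def _cumtrapz_increments(partial: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid of ``partial`` against increments of ``x``."""
    inc = 0.5 * (partial[1:] + partial[:-1]) * np.diff(x)
    out = np.empty_like(x)
    out[0] = 0.0
    np.cumsum(inc, out=out[1:])
    return out


def decompose_force(traj: Trajectory,
                    f_ce: Callable[[float, float, float], float],
                    t_x: float | None = None,
                    cfg: SimConfig | None = None,
                    scale_v: float = 1.0, scale_l: float = 0.1,
                    a_bounds: tuple[float, float] = (0.005, 1.0),
                    ) -> DecompositionResult:
    """Partition the fibre force from just before touch-down to ``t_x``.

    ``t_x`` defaults to take-off and must lie within stance. The grid is
    [last flight sample, touch-down, stance samples <= t_x]; the force jump
    across the impact initializes the force-velocity component.
    """
    if t_x is None:
        t_x = traj.t_to
    if not (traj.t_td <= t_x <= traj.t_to + 1e-12):
        raise ValueError(
            f"t_x={t_x} outside stance [{traj.t_td}, {traj.t_to}]")

    i_pre = traj.index_before_touchdown()
    st = traj.stance_slice()
    i_end = int(np.searchsorted(traj.t, t_x + 1e-15, side="left"))
    i_end = min(max(i_end, st.start + 1), st.stop)
    idx = np.r_[i_pre, np.arange(st.start, i_end)]

    t = traj.t[idx]
    v = traj.v_ce[idx]
    l = traj.l_ce[idx]
    a = traj.a[idx]
    f = traj.f_ce[idx]
    f_0 = float(f[0])

    dfv = np.empty_like(t)
    dfl = np.empty_like(t)
    dfa = np.empty_like(t)
    for i in range(t.size):
        dfv[i], dfl[i], dfa[i] = partials_along_trajectory(
            f_ce, v[i], l[i], a[i], scale_v=scale_v, scale_l=scale_l,
            a_bounds=a_bounds)

    # the impact (sample 0 -> 1) is instantaneous in l and a: the whole
    # force jump is the force-velocity component, set algebraically
    f_v = _cumtrapz_increments(dfv, v)
    f_l = _cumtrapz_increments(dfl, l)
    f_a = _cumtrapz_increments(dfa, a)
    f_v[1:] += (f[1] - f_0) - f_v[1]
    f_l[1:] -= f_l[1]
    f_a[1:] -= f_a[1]

    recon = f_v + f_l + f_a + f_0
    err = float(np.max(np.abs(f - recon)))
    return DecompositionResult(t=t, f_ce=f, f_v=f_v, f_l=f_l, f_a=f_a,
                               f_0=f_0, t_td=traj.t_td,
                               reconstruction_error=err)


@dataclass
class ComponentWork:
    """Fibre work (J) over a window, split by force component.

    Sign convention: positive = energy absorbed by the fibres (lengthening
    against positive force). ``w_0`` is the work of the constant pre-impact
    force over the fibre length change.
    """

    w_ce: float
    w_v: float
    w_l: float
    w_a: float
    w_0: float
    window: tuple[float, float]

    @property
    def closure(self) -> float:
        """w_ce - (w_v + w_l + w_a + w_0); small iff the partition closed."""
        return self.w_ce - (self.w_v + self.w_l + self.w_a + self.w_0)


def component_work(decomp: DecompositionResult, traj: Trajectory,
                   window: tuple[float, float] | None = None,
                   ) -> ComponentWork:
    """Trapezoidal work integrals of each force component over ``window``.

    ``W_X = int F_X(t) v_CE(t) dt`` for X in {V, L, A} and for the total
    fibre force; ``W_0 = F_0 * (l_CE(end) - l_CE(start))``. The window
    defaults to the 30 ms preflex phase after touch-down and must lie
    within the decomposed range.
    """
    if window is None:
        window = (traj.t_td, traj.t_td + 0.030)
    t0, t1 = window
    if t1 > decomp.t[-1] + 1e-12 or t0 < decomp.t[0] - 1e-12:
        raise ValueError(
            f"work window ({t0}, {t1}) exceeds decomposed range "
            f"({decomp.t[0]}, {decomp.t[-1]})")
    # select stance samples in the window (the impact itself is
    # instantaneous and does no work, so the pre-impact sample never enters)
    sel = (decomp.t >= t0 - 1e-12) & (decomp.t <= t1 + 1e-12)

    i_traj = int(np.searchsorted(traj.t, decomp.t[sel][0] - 1e-15))
    n = int(np.count_nonzero(sel))
    v = traj.v_ce[i_traj:i_traj + n]
    l = traj.l_ce[i_traj:i_traj + n]
    t = decomp.t[sel]

    def wint(force):
        return float(np.trapezoid(force[sel] * v, t))

    return ComponentWork(
        w_ce=wint(decomp.f_ce),
        w_v=wint(decomp.f_v), w_l=wint(decomp.f_l), w_a=wint(decomp.f_a),
        w_0=decomp.f_0 * float(l[-1] - l[0]),
        window=(float(t[0]), float(t[-1])))
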