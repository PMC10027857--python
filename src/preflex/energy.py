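"""Study-level energy and stability analysis.

Combines simulated trials and their force decompositions into the
quantities the perturbation experiment is about: the change in fibre work
during the 30 ms preflex window relative to the reference trial, the
potential energy injected by each ground-height perturbation
(``dE_P = m g dh``), the fraction of that energy rejected by the fibres
within the preflex, workloop paths, touch-down summaries, and the
apex-return map with its stability classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decompose import ComponentWork, DecompositionResult
from .engine import Trajectory
from .params import LegParams


def potential_energy_change(dh: float, lp: LegParams) -> float:
    """Potential energy (J) added by a ground perturbation; m*g*dh.

    Positive for a step-down (deeper drop adds energy the hopper must
    reject), negative for a step-up.
    """
    return lp.m * lp.g * dh


@dataclass
class EnergySummary:
    """Preflex energy bookkeeping of one trial against the reference."""

    dh: float
    w_ce: float                  # J, fibre work over the preflex window
    dw_ce: float                 # J, perturbed minus reference
    dw_v: float
    dw_l: float
    dw_a: float
    dw_0: float
    de_p: float                  # J, m*g*dh
    rejection: float | None      # dw_ce / de_p, None at dh = 0
    rejection_abs: float | None  # |dw_ce| / |de_p| (magnitude form)


def preflex_energy_summary(trial: tuple[Trajectory, ComponentWork],
                           reference: tuple[Trajectory, ComponentWork],
                           lp: LegParams) -> EnergySummary:
    """Delta of preflex component works, perturbed minus reference.

    Each trial's works are integrated over its own preflex window
    (touch-down to touch-down + 30 ms). The rejection fraction is reported
    both signed and as a magnitude ratio.
    """
    traj, work = trial
    ref_traj, ref_work = reference
    if traj.protocol != ref_traj.protocol:
        raise ValueError(
            f"protocol mismatch: trial {traj.protocol!r} vs reference "
            f"{ref_traj.protocol!r}")
    dh = traj.dh
    de_p = potential_energy_change(dh, lp)
    dw_ce = work.w_ce - ref_work.w_ce
    return EnergySummary(
        dh=dh, w_ce=work.w_ce, dw_ce=dw_ce,
        dw_v=work.w_v - ref_work.w_v, dw_l=work.w_l - ref_work.w_l,
        dw_a=work.w_a - ref_work.w_a, dw_0=work.w_0 - ref_work.w_0,
        de_p=de_p,
        rejection=(dw_ce / de_p) if dh != 0.0 else None,
        rejection_abs=(abs(dw_ce) / abs(de_p)) if dh != 0.0 else None)


@dataclass
class Workloop:
    """Time-ordered fibre force vs fibre length path over stance.

    Marker indices point into the path arrays: touch-down, end of the
    preflex window, mid-stance (temporal midpoint) and take-off. The signed
    area enclosed by a closed loop equals the net fibre work by Green's
    theorem.
    """

    l_ce: np.ndarray = field(repr=False)
    f_ce: np.ndarray = field(repr=False)
    t: np.ndarray = field(repr=False)
    i_td: int
    i_preflex_end: int
    i_midstance: int
    i_to: int

    def preflex_segment_area(self) -> float:
        """Work absorbed along the preflex segment (trapezoid in l)."""
        s = slice(self.i_td, self.i_preflex_end + 1)
        return float(np.trapezoid(self.f_ce[s], self.l_ce[s]))


def workloop(traj: Trajectory, preflex_window: float = 0.030) -> Workloop:
    """Extract the stance workloop with its standard markers."""
    st = traj.stance_slice()
    t = traj.t[st]
    i_td = 0
    i_pf = int(np.searchsorted(t, traj.t_td + preflex_window, side="right"))
    i_pf = min(max(i_pf - 1, 0), t.size - 1)
    t_mid = 0.5 * (traj.t_td + traj.t_to)
    i_mid = int(np.clip(np.searchsorted(t, t_mid), 0, t.size - 1))
    return Workloop(l_ce=traj.l_ce[st], f_ce=traj.f_ce[st], t=t,
                    i_td=i_td, i_preflex_end=i_pf, i_midstance=i_mid,
                    i_to=t.size - 1)


@dataclass
class ApexReturnMap:
    """(drop height, return apex) pairs and local stability at the fixed
    point. ``|slope| < 1`` at the fixed point means perturbations decay
    over successive hopping cycles (asymptotically stable)."""

    h0: np.ndarray
    h1: np.ndarray
    fixed_point: float
    slope: float
    classification: str          # "stable" | "neutral" | "unstable"
    fixed_point_found: bool = True


def apex_return_map(trials: list[Trajectory],
                    slope_tol: float = 1e-6) -> ApexReturnMap:
    """Fit the apex map from one cycle per tested drop height.

    The fixed point is located by linear interpolation of the sign change
    of ``h1 - h0``; the local slope by central difference across the two
    entries bracketing it (one-sided at the ends).
    """
    if len(trials) < 3:
        raise ValueError("apex return map needs at least 3 trials")
    order = np.argsort([tr.h0 for tr in trials])
    h0 = np.array([trials[i].h0 for i in order])
    h1 = np.array([trials[i].h1 for i in order])
    diff = h1 - h0

    sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    if sign_change.size:
        i = int(sign_change[0])
        w = diff[i] / (diff[i] - diff[i + 1])
        fp = float(h0[i] + w * (h0[i + 1] - h0[i]))
        found = True
    else:
        i_ref = int(np.argmin(np.abs(diff)))
        fp = float(h0[i_ref])
        found = False

    # local slope of h1(h0) around the fixed point
    j = int(np.clip(np.searchsorted(h0, fp), 1, h0.size - 1))
    lo, hi = max(j - 1, 0), min(j + 1, h0.size - 1)
    slope = float((h1[hi] - h1[lo]) / (h0[hi] - h0[lo]))

    if abs(abs(slope) - 1.0) <= slope_tol:
        cls = "neutral"
    elif abs(slope) < 1.0:
        cls = "stable"
    else:
        cls = "unstable"
    return ApexReturnMap(h0=h0, h1=h1, fixed_point=fp, slope=slope,
                         classification=cls, fixed_point_found=found)


@dataclass
class TouchdownSummary:
    """Per-trial state at the touch-down instant (first stance sample)."""

    dh: np.ndarray
    v_ce: np.ndarray
    f_ce: np.ndarray
    f_v: np.ndarray
    f_0: np.ndarray
    a: np.ndarray
    u: np.ndarray


def touchdown_summary(trials: list[Trajectory],
                      decomps: list[DecompositionResult],
                      ) -> TouchdownSummary:
    """Tabulate touch-down conditions, one row per perturbation.

    The force-velocity component at touch-down is enforced to its algebraic
    value, ``F_V(t_TD) = F_CE(t_TD) - F_0`` (the impact force jump).
    """
    if len(trials) != len(decomps):
        raise ValueError("one decomposition per trial required")
    order = np.argsort([tr.dh for tr in trials])
    rows = {k: [] for k in ("dh", "v_ce", "f_ce", "f_v", "f_0", "a", "u")}
    for i in order:
        tr, dc = trials[i], decomps[i]
        i_td = tr.stance_slice().start
        f_td = float(tr.f_ce[i_td])
        rows["dh"].append(tr.dh)
        rows["v_ce"].append(float(tr.v_ce[i_td]))
        rows["f_ce"].append(f_td)
        rows["f_v"].append(f_td - dc.f_0)
        rows["f_0"].append(dc.f_0)
        rows["a"].append(float(tr.a[i_td]))
        rows["u"].append(float(tr.u[i_td]))
    return TouchdownSummary(**{k: np.array(v) for k, v in rows.items()})
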