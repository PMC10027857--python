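"""Open-loop stimulation protocols.

Two piecewise-linear ramp signals drive the muscle:

* ``const``: u is held at the prestimulation level u_0 throughout flight
  and for the first ``delay`` (30 ms) after the *actual* touch-down, then
  ramps at u_beta. Anchored to the touch-down event, so the preflex window
  always sees constant stimulation regardless of the perturbation.
* ``rising``: u is 0 until ``delay`` (54 ms) before the *expected*
  touch-down (the touch-down time of the unperturbed reference trial),
  then ramps at u_beta. Fixed in absolute time, never re-anchored: a
  perturbed (later or earlier) impact meets a different stimulation level.

Both signals are clamped to [0, 1], continuous, and non-decreasing after
onset.
"""

from __future__ import annotations

from .params import StimProtocol


def stimulation_const(t: float, t_td: float | None,
                      sp: StimProtocol) -> float:
    """Touch-down-anchored ramp: u_0 until t_td + delay, then rising.

    ``t_td=None`` means touch-down has not happened yet (flight), where the
    'otherwise' branch applies and u = u_0.
    """
    if t_td is None or t <= t_td + sp.delay:
        return sp.u_0
    return min(1.0, sp.u_0 + sp.u_beta * (t - t_td - sp.delay))


def stimulation_rising(t: float, sp: StimProtocol) -> float:
    """Expected-touch-down-anchored ramp: 0 until t*_td - delay."""
    if sp.t_td_expected is None:
        raise ValueError(
            "rising protocol needs t_td_expected (the reference trial's "
            "touch-down time); run or supply the reference first")
    t_on = sp.t_td_expected - sp.delay
    if t <= t_on:
        return 0.0
    return min(1.0, sp.u_beta * (t - t_on))


def stimulation(t: float, t_td: float | None, sp: StimProtocol) -> float:
    """Protocol dispatch; ``t_td`` is the actual touch-down time if known."""
    if sp.kind == "const":
        return stimulation_const(t, t_td, sp)
    return stimulation_rising(t, sp)


def flight_stimulation_level(sp: StimProtocol) -> float:
    """Stimulation far before touch-down (initial-condition fixed point)."""
    return sp.u_0 if sp.kind == "const" else 0.0
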