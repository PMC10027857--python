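# Methods

## Model overview

The package simulates vertical hopping of an 80 kg point mass on a
massless, symmetric two-segment leg (segment length 0.5 m) actuated by a
single knee-extensor muscle-tendon unit (MTU), and analyses how the
muscle fibres reject unexpected ground-height changes during the first
30 ms after impact — the *preflex* phase, before any neuronal feedback
can act.

### Leg mechanics

The inner knee angle `phi` closes the geometry through
`y = 2 l_s sin(phi/2)` (hip height `y`; `phi = pi` is a straight leg).
The extensor MTU wraps a constant lever arm `r_a = 0.04 m`, so knee
flexion lengthens it linearly, `l_MTU = l_mtu_ref + r_a (phi_ref - phi)`,
and the MTU force maps to a vertical ground-reaction force by virtual
work, `F_leg = r_a F_MTU / (l_s cos(phi/2))`. In flight the knee is
locked at leg length `l_f = 0.99 m` and the body is ballistic; the muscle
keeps contracting against its own tendon (fixed-end). Touch-down fires
when `y` falls through `l_f`; take-off when `y` rises back through `l_f`
or the MTU force reaches zero, whichever happens first (ties resolve to
the `y`-crossing). Each trial is one apex-to-apex cycle.

### Muscle-tendon unit

Four elements satisfy `F_MTU = F_CE + F_PEE = F_SEE + F_SDE` at every
instant:

* **CE** (fibres): separable law
  `F_CE = a * fl(l_CE) * fv(v_CE) * F_max`, `F_max = 22 kN`,
  `l_opt = 0.1 m`. `fl` is an exponential bell
  `exp(-|(l/l_opt - 1)/w|^nu)` with width `w = 0.40`, exponent 1.5.
  `fv` is the concentric Hill hyperbola
  `(1 + a_rel) b / (b - v) - a_rel` (`b = b_rel l_opt`,
  `a_rel = 0.2`, `b_rel = 1.5 1/s`) joined at `v = 0` with matching slope
  to a saturating eccentric branch with asymptote
  `f_ecc_plateau = 1.09` times isometric. The near-flat eccentric branch
  is deliberate: the reference results require the impact force
  adjustment to saturate within ~0.1 m/s of lengthening velocity.
* **PEE**: engages above `0.95 l_opt`, polynomial beyond. In every
  simulated trial the fibre stays below that length, so `F_CE = F_MTU`.
* **SEE** (tendon + aponeurosis): slack length 0.40 m, power-law toe up
  to strain 0.082 (force 26 kN at the knee of the curve, exponent
  `0.082/0.0328 = 2.5`), linear beyond. The operating range of the study
  lies inside the toe; its exponent controls how tendon compliance grows
  with load, which in turn sets how much of an impact is buffered
  elastically rather than absorbed by the fibres.
* **SDE**: serial damper with force-dependent coefficient
  `d = d_max ((1-r) F/F_max + r)`, `d_max = 24 kN s/m`, `r = 0.01`. It
  distributes the impact velocity between fibre and tendon and guarantees
  a well-posed fibre-velocity equilibrium.

The fibre velocity is the root of the four-element force balance,
bracketed in `[-2, +5] v_max` (one expansion to `[-8, +30] v_max`) and
solved with Brent's method to a residual below `1e-6 F_max`; no initial
guess enters, so results are reproducible bit for bit.

### Stimulation and activation

Two open-loop ramps drive the muscle (slope `u_beta = 10 1/s`, clamped to
[0, 1]). *Const*: `u = 0.15` through flight and the first 30 ms after the
actual touch-down, then rising. *Rising*: `u = 0` until 54 ms before the
*expected* (reference) touch-down, then rising — fixed in absolute time,
so a perturbed impact meets a different stimulation level.

Activation dynamics are first order with a saturating read-out: a
calcium-like drive follows `dc/dt = (u - c)/tau`, `tau = 88.5 ms`, and
activity is `a = (a_min + x)/(1 + x)` with
`x = (rho0 (l/l_opt)^p c)^3`, `p = 1.7`. The cubic saturation makes the
steady-state activity sub-proportional at low drive (u = 0.15 holds
a = 0.11) while activity rises much faster than the drive once the ramp
saturates, and it bounds activity in `[0.005, ~0.99]` by construction. A
plain first-order lag (`act_law = "linear"`) is available as an
alternative strategy; it cannot reproduce the 0.11 touch-down activity at
u = 0.15 and is not the default.

### Force decomposition (the core method)

Along a simulated trajectory the fibre-force change since the last
instant before touch-down is a path integral; the chain rule splits it
into additive components,

    F_CE = F_V + F_L + F_A + F_0,
    F_V = ∫ (∂f/∂v) dv,  F_L = ∫ (∂f/∂l) dl,  F_A = ∫ (∂f/∂a) da,

with `F_0` the force at the last flight sample. The impact is
instantaneous (length and activity continuous, velocity jumping), so the
touch-down force jump initializes `F_V` algebraically and
`F_L(t_TD) = F_A(t_TD) = 0`. Partials are central finite differences
(relative step 1e-6 of `v_max`, `l_opt`, and 1; one-sided at the activity
bounds); integrals use the cumulative trapezoid on the 0.1 ms output
grid. Component works are `W_X = ∫ F_X v_CE dt` over the preflex window,
with `W_0 = F_0 Δl_CE` reported separately rather than folded into the
three mechanism components; positive work means energy absorbed by the
fibres. This convention makes the work partition exact whenever the force
partition is; the reconstruction error (max deviation of the component
sum from `F_CE`) is stored with every decomposition and stays far below
1% of peak stance force at the default sampling.

### Numerical settings

Adaptive RK45 with maximum step 1e-4 s and absolute/relative tolerances
1e-8; events located by the integrator's root finder; output resampled
from the dense solution at 0.1 ms with exact phase-boundary samples, so
the stance segment starts exactly at touch-down. Periodic hopping is the
fixed point of the apex-return map, found by fixed-point iteration to
|h1 - h0| < 1e-4 m; for the rising protocol the expected touch-down time
is re-derived from the current apex each iterate so the converged orbit
is self-consistent. Degenerate inputs: lengths are clamped above 1e-6 m
in the passive laws; stimulation outside [0, 1] is clamped with a logged
warning; a take-off without upward velocity ends the cycle at take-off.

## Calibration

The study pins `m, g, l_f, l_s, r_a, F_max, l_opt, tau`, the activity
bounds, the PEE engagement length, the stimulation constants
(`u_0 = 0.15`, `u_beta = 10`, delays 30/54 ms) and the reference
touch-down state of the const protocol (`a = 0.11`, `F_CE = 1260 N`).
The last two are absorbed analytically: with constant flight stimulation
the muscle sits at its fixed-end equilibrium before impact, so the
activation gain `rho0` and the MTU reference length `l_mtu_ref` are
solved in closed form from `fl(l*) = 1260/(0.11 F_max)` and the tendon
strain carrying 1260 N (`engine.pin_reference_touchdown`).

The remaining shape constants (`a_rel`, `b_rel`, `f_ecc_plateau`, SEE toe
shape and scale, `d_sde_max`, activation length exponent) are not
published for this configuration. They were calibrated once, offline,
with deterministic Nelder-Mead on the squared relative residuals of the
reference observables (apex heights, stance durations, pre-impact forces)
and then frozen as the package defaults; they are this package's own
parameter choices, not published values. Within this structural class the
calibration could not reproduce the rising protocol's 179 N pre-impact
force together with the other observables: the pre-impact force is the
concentric equilibrium at the pinned touch-down activity, and lowering it
to 179 N needs a concentric branch so slow that the const protocol's
push-off (and with it the 10.6 cm reference apex) collapses. Models whose
force-velocity curvature varies with activation can decouple the two
regimes; such rescaling is out of scope here, and the achieved value
(~515 N) is reported as-is.

## Synthetic fixtures

The decomposition is tested independently of the simulator on fabricated
trajectories: polynomial ramps `v(t)`, `a(t)` with `l(t)` the exact
integral of `v`, under a deliberately non-Hill separable force law
`g1(v) g2(l) g3(a)` with polynomial factors. Every component path
integral is then itself a polynomial, computed exactly by polynomial
algebra (composition and antidifferentiation) — a closed-form oracle
fully independent of the finite-difference/trapezoid numerics under test.
The fixtures emulate the sampled-trajectory *interface* (including the
impact velocity jump), not hopping physics: passing them shows the
decomposition numerics are correct, not that the simulator is realistic.
Realism is checked separately against the reference observables above.

## Problem sizes and runtimes

Default test runs use a coarsened solver grid (max step 2 ms, output
0.5 ms, tolerances 1e-7) that moves apex heights by well under a
millimetre; acceptance-level checks and `scripts/acceptance.py` run at
full study resolution (both protocols, seven trials each, ~1-2 minutes on
one CPU). The full `preflex reproduce` pipeline, including all file
output, stays within a few minutes.

## Known limitations

* The eccentric branch is almost flat, so the impact force band of the
  const protocol is nearly degenerate (~1.37 kN across all
  perturbations) instead of spanning 1.15-1.35 kN.
* The rising protocol's pre-impact force level is ~3x the reference
  value (see Calibration); quantities that build on it at large
  step-downs (impact forces beyond +5 cm) run correspondingly high,
  while the energy partition and rejection fractions stay within ~11%.
* Constant `a_rel`/`b_rel`: no activation- or length-dependence of the
  force-velocity curvature.
* Single muscle, vertical-only, rigid ground, massless leg; no reflexes
  or feedback; one hopping cycle per trial (the apex map composes
  cycles).
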