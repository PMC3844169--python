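# Methods

## Scope and model structure

`fontansim` is a closed-loop, zero-dimensional (lumped-parameter) model of
a single-ventricle circulation typical of a 3–4-year-old, 17 kg child
after the second (bidirectional Glenn, BCPA) or third (total
cavopulmonary connection, TCPC) stage of the Fontan pathway.  The model's
purpose is narrow and explicit: the *transient* hemodynamic consequence of
converting a BCPA into a TCPC, i.e. the instant after the IVC is re-routed
and before any neuro-humoral regulation or chronic adaptation acts.  No
baroreflex, venous-tone control, or volume retention is modelled; the two
configurations share every parameter value and the same total stressed
blood volume, and differ in exactly one circuit edge (the IVC outlet:
right atrium vs. pulmonary trunk node).

The circuit comprises 16 compliant vascular compartments (aorta; upper and
lower body arterioles/capillaries/veins; SVC; IVC; pulmonary trunk node;
left and right pulmonary arterial/capillary/venous beds), 21 flow segments
(19 vessels including the atrial septal defect, plus mitral and aortic
valves), and 3 cardiac chambers (RA, LA, LV; the single functional
ventricle is labelled LV).  State vector: 16 pressures + 21 flows + 3
volumes = 40 ODE states, plus two discrete valve modes.

Mass conservation at a compliant node: dP/dt = (ΣQ_in − ΣQ_out)/C.
Momentum conservation on a segment: dQ/dt = (P_up − R·Q − P_down)/L.
Vessels carry no valves; retrograde flow is allowed everywhere except
through the two cardiac valves (the Glenn-configuration IVC in fact shows
substantial retrograde flow, which is a model output, not an input).

## External pressures

Intrathoracic pressure P_it = −3.5 mmHg loads the thoracic compartments
(aorta, SVC, IVC, pulmonary trunk/arteries/capillaries/veins); the
extrathoracic systemic beds see ambient 0 mmHg.  The heart feels
P_pc + P_it (pericardial plus intrathoracic, −0.5 mmHg net).  Stored
pressures are absolute luminal values; compartment stressed volume is
C·(P − P_ext).  Both P_it and P_pc are constant (no respiratory
oscillation).

## Heart

Each chamber obeys the time-varying elastance law
P = E(t)·V + S·dV/dt with E(t) = E_s·e(t) + E_d, zero unstressed volume,
and wall viscoelasticity proportional to instantaneous pressure,
S = k_S·P with k_S = 5×10⁻⁴ s/mL for all chambers.  Because S depends on
P the law is implicit; it has the exact closed-form solution
P = E(t)·V/(1 − k_S·dV/dt), which is used directly (no inner iteration).
The denominator is clamped at 0.5 as a numerical guard; at physiological
filling/ejection rates (|dV/dt| ≲ 300 mL/s) the correction is ≲ 15% and
the clamp is never reached.

The ventricular activation e(t) is the standard two-cosine waveform:
raised-cosine rise over the contraction period T_vcp = 0.246 s, fall over
the relaxation period T_vrp = 0.147 s, zero for the rest of the
T_0 = 0.67 s cycle (heart rate ≈ 90 bpm).  No atrial activation shape is
prescribed by the source material for this model family, so the atria use
the same two-cosine shape with contraction and relaxation each lasting
0.09·T_0, timed so that atrial relaxation completes exactly at ventricular
contraction onset (atrial kick in late diastole, atria silent throughout
ventricular systole).  The atrial timing fractions are a design choice;
cycle-averaged outputs are second-order sensitive to them because the
atrial elastances are small (E_ras = 0.26, E_las = 0.5 mmHg/mL) compared
with the ventricle (E_lvs = 6.64 mmHg/mL).

## Valves

Open valves follow ΔP = R_v·Q + B_v·Q|Q| + L_v·dQ/dt (viscous, Bernoulli
and inertial terms).  Mode logic, evaluated once per time step at the step
boundary:

* open-forward → closed: gradient reversed (ΔP < 0) *and* forward jet
  decayed (Q ≤ ε_Q = 10⁻³ mL/s); flow projected to exactly 0.
* closed → open-forward: ΔP > 0.
* closed → regurgitant (leaky mitral valve only, A_reg > 0): ΔP < 0.
* regurgitant → open-forward: ΔP > 0 and the retrograde jet has decayed,
  Q ≥ −ε_Q.  The decay test is one-sided on purpose: with a finite step
  the decelerating jet crosses zero between step boundaries (typical
  per-step change ~0.2 mL/s), so a two-sided |Q| ≤ ε_Q window would
  essentially never be sampled and the valve would stay trapped in
  regurgitant mode through diastole.

Regurgitant constants derive from the effective orifice area A_reg and the
instantaneous left-atrial volume (spherical-equivalent cross-section
A_la = π·(3V_la/4π)^{2/3}):

    B_reg = ρ/2·(1/A_reg − 1/A_la)²,
    L_reg = 2ρ√π·(1/√A_reg − 1/√A_la),

computed in CGS (ρ = 1.06 g/cm³) and converted with
1 mmHg = 1333.22 dyn/cm², refreshed every time step as the atrium fills
and empties.  Two notes on these expressions.  First, the inertance is
sometimes quoted in the literature of this model family as
2πρ(1/A_reg − 1/A_la), which is dimensionally inconsistent for an
inertance (pressure·time²/volume requires ρ/√A scaling); the √A form used
here has the correct dimensions, the same monotonicity, and only sets the
inertial timescale of the regurgitant jet, to which cycle-averaged outputs
are insensitive.  Second, a consistency check on the unit convention:
inverting B = ρ/(2·1333.22·A²) at the tabulated *forward* mitral Bernoulli
constant B_mv = 8×10⁻⁵ mmHg·s²/mL² implies an effective forward orifice of
2.23 cm², a plausible pediatric mitral area — supporting both the ρ and
the conversion factor.  The regurgitant viscous term reuses the forward
R_mv (negligible next to B_reg).  The aortic valve is always competent.

## Parameters

All constants live in a single immutable, name-addressable registry
(`parameters.ParameterSet`): chamber elastances, timing, viscoelastic
factors, valve constants, and the full R/L/C table of the vascular network
(units mmHg, mL, s throughout).  The registry values describe the 17 kg
reference patient; the compliance scaling laws C_sys = 2.1·weight and
C_pul = 0.408·weight (mL/mmHg) are carried as validation metadata only —
individual compartment constants are not rescaled with weight.

Sweep support scales exactly one of four targets by a factor in
[0.5, 2.5]: `R_art_l` (lower-body arteriolar resistance), `E_lvs`
(ventricular systolic elastance), `E_lvd` (ventricular diastolic
stiffness), or `R_pul`.  "Pulmonary vascular resistance" is implemented as
a common multiplier on *every* pulmonary resistive element (both trunk
branches and the arterial/capillary/venous segments of both lungs), since
it is a single physiological property; the trunk branches contribute only
1×10⁻³ mmHg·s/mL each, so their inclusion is numerically irrelevant.

**Total stressed volume V_tot** is the one closing parameter that no table
provides: it fixes the operating point of the closed loop.  It is
calibrated by bisection (tolerance 0.1 mmHg) so that the converged Glenn
mean aortic pressure equals 72.1 mmHg, giving V_tot = 370.9 mL, which is
stored as the registry default and frozen for every sweep and for the TCPC
run.  Mean arterial pressure is monotone in V_tot (verified by scan), so
bisection is robust; the default bracket is 200–1200 mL with automatic
expansion.  A crude volume audit at the operating point (ΣC·P_tm across
compartments plus chamber volumes) lands in the 350–450 mL range,
consistent with the calibrated value.

## Numerics

* Fixed-step classical RK4, dt = 10⁻⁴ s (6700 steps per cycle).  Halving
  dt changes converged cycle means by < 2×10⁻⁷ relative (tested), far
  inside the 10⁻³ tolerance asserted in the suite.
* Valve modes are held constant within a step and updated at step
  boundaries; no sub-step event location.  The resulting valve-timing
  error is ≤ dt ≈ 0.015% of the cycle.
* Initial conditions: chamber volumes start at coarse physiological
  guesses (RA = LA = 8 mL, LV = 30 mL) and the remaining stressed volume
  is distributed over the compartments at one uniform transmural pressure,
  so the initial total equals V_tot exactly; all flows start at zero and
  both valves closed.  Only the limit cycle matters; the convergence
  criterion guards against initialization dependence.
* Total blood volume is a linear invariant of the RHS (every flow enters
  one node and leaves another), so RK4 preserves it to round-off; the
  suite asserts drift < 0.1% and observes ~10⁻¹³ relative.
* Convergence to the periodic steady state: cycle means of all 40 states
  are averaged over 6-beat blocks and the run stops when the maximum
  relative block-to-block change falls below the tolerance (floored
  denominators keep near-zero flows, e.g. the TCPC septal flow, from
  stalling the test).  Block averaging exists because valve switching is
  quantized to the step: at some regurgitation severities the limit set is
  a tiny period-2/3 orbit in the cycle means (relative amplitude ~10⁻⁴)
  that consecutive-beat comparison can never resolve below, while block
  means cancel it and still detect genuine drift.  Default tolerance
  10⁻⁴; the calibration loop, the experiment drivers and the
  reproduction script use 10⁻⁶ so the slow venous-pooling mode (time
  constant of tens of beats) is fully settled.  Typical convergence: 35–60
  cycles from cold start, < 1 s per run on one CPU (the stepping kernel is
  numba-compiled; the pure-Python reference right-hand side, against which
  the kernel is tested to machine precision, integrates the same
  equations through the object model).
* Everything is deterministic: identical inputs give bit-identical
  trajectories, and the test suite asserts it.

## Experiments and reported quantities

`summarize` reduces a converged run to cycle averages over the final beat:
mP_svc, mP_ivc ("central venous pressure" is sampled at the IVC
compartment, not the right atrium), mP_pa (pulmonary trunk node), mP_la
(reconstructed from the LA volume waveform through the elastance law),
mP_art (aortic compartment); SV = max V_lv − min V_lv, EDV = max V_lv,
EF = 100·SV/EDV; CO = mean aortic-valve flow; mQ_pul = mean total
pulmonary venous return; regurgitation fraction = retrograde/forward
transmitral volume per beat.

Perioperative changes are 100·(X_TCPC − X_Glenn)/X_Glenn for
X ∈ {mQ_pul, mP_ivc}, with both runs sharing one parameter set and the
frozen V_tot.  The full sweep grids are 50–250% in 10% steps (21 points
per target) and A_reg from 0.01 to 0.21 cm² (11 evenly spaced points; the
grid spacing is a package choice, only the endpoints being prescribed).
The test suite exercises reduced 3–4-point grids of the same ranges to
keep the default run short; the full grids are available through the
library and CLI.

Waveform morphology features (used for the Glenn-vs-TCPC IVC comparison:
biphasic with retrograde flow before completion, single-peaked without
retrograde flow after) count local maxima with prominence above 5% of the
waveform range over one cycle, scanning two concatenated cycles so a peak
at the cycle wrap is neither lost nor double-counted.  The prominence
threshold is a package choice for an inherently qualitative feature.

## What the model does and does not show

Passing the baseline checks means the reconstructed network reproduces the
reference operating points of both configurations within ±10% (observed:
within ~2% for the Glenn column, within ~6% for the TCPC column) and all
the qualitative completion effects: higher transpulmonary flow, markedly
higher IVC pressure, lower cardiac output and arterial pressure, loss of
IVC flow pulsatility and retrograde flow.  It does *not* validate
post-operative reality beyond the acute instant — real patients
vasoconstrict, retain volume and remodel, none of which is modelled — and
the absolute post-TCPC output/pressure are accordingly pessimistic.

One reconstruction-specific caveat: the magnitude of the regurgitant jet
at a given orifice area depends on the unit convention adopted for the
orifice formulas, which the source material leaves ambiguous (see the
valve section).  Under the dimensionally coherent convention used here,
the 0.01–0.21 cm² grid spans regurgitation fractions of roughly 0.06–0.61,
and severe regurgitation raises the perioperative pulmonary-flow
improvement by substantially more than the ~3 percentage points reported
for this experiment in the source study — the direction (improvement, and
attenuation of the venous-pressure rise) agrees, the magnitude only agrees
at matched low severity (regurgitation fraction ≲ 0.17).  The
corresponding bound in the acceptance suite is deliberately left failing
rather than recalibrated, since the severity mapping cannot be pinned down
from the available material.

## Key defaults

| quantity | value | meaning |
|---|---|---|
| T_0 | 0.67 s | cardiac cycle |
| dt | 10⁻⁴ s | RK4 step (6700/cycle) |
| P_it / P_pc | −3.5 / 3 mmHg | intrathoracic / pericardial pressure |
| ρ | 1.06 g/cm³ | blood density (orifice formulas) |
| V_tot | 370.9 mL | calibrated total stressed volume |
| ε_Q | 10⁻³ mL/s | valve jet-decay threshold |
| steady-state tol | 10⁻⁴ (default), 10⁻⁶ (experiments) | block-mean relative change |
| max cycles | 400 (default), 800 (experiments) | non-convergence flagged |
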