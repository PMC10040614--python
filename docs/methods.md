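# Methods

`cardiomef` is a desk-scale, fully coupled 0D model of canine biventricular
electromechanics built to study acute mechanoelectric feedback (MEF): how
stretch-activated channels (SACs) and the length- and velocity-dependence of
active tension shape the heartbeat, and what they do under left bundle
branch block (LBBB) and cardiac resynchronization therapy (CRT). This note
documents the model, its assumptions, the calibration, the numerical
choices, and — importantly — what the 0D surrogate can and cannot
reproduce of the 3D physiology it stands in for.

## Cellular electrophysiology

Ventricular myocytes follow the Ten Tusscher–Panfilov 2006 human
formulation (19 states; epicardial variant by default, endo/mid
conductances available). Constants and initial conditions are the standard
published/CellML values; the model is used unchanged for dog, as the study
this package reconstructs did. External currents (stimulus, SAC) enter the
membrane balance as an affine function of voltage, `i_ext = a + b·V_m`,
which represents a rectangular stimulus plus an ohmic stretch-activated
current exactly; the external charge is carried on the potassium balance,
the usual convention for long-run stability.

Tissue propagation is out of scope: activation is a prescribed per-patch
schedule. The tissue "foot" current that precedes local activation in a
propagating wave is approximated by a rectangular 2 ms stimulus at roughly
twice diastolic threshold (−26 A/F). Baseline activation is simultaneous at
the atrioventricular (AV) delay, mirroring simultaneous endocardial
activation by the His–Purkinje system; the intramural 75 ms QRS of the
reference 3D model collapses to zero in 0D.

* Integration: Rush–Larsen exponential updates for the 12 Hodgkin–Huxley
  gates (saturation-safe by construction), forward Euler for concentrations
  and voltage, fixed dt = 0.02 ms. The fixed-step trace agrees with an
  adaptive LSODA solve of the same right-hand side to < 1 mV.
* Depolarization time: first upward 0 mV crossing (linear interpolation);
  repolarization: 90 % return from peak toward the pre-stimulus potential.
  The reference study does not state its thresholds; these are the
  package's definitions.

## Stretch-activated channels and trigger calibration

`I_SAC = G (V_m − E_SAC) / (1 + K e^{−α(λ−1)})` with E_SAC = −20 mV,
K = 100, α = 3 (published values of the cited formulation; configurable).
Only `G` is calibrated: bisection (relative tolerance 3·10⁻⁴) finds the
smallest conductance for which a sustained stretch step at the trigger
level (default 10 %), applied for one full cycle to an end-diastolic
paced cell, elicits an action potential (peak V_m > 0 mV), while one
scan step (1 %) below stays under −40 mV. Lower trigger levels therefore
calibrate to larger conductances.

A consequence worth knowing: a cell held near its trigger under a *slowly
rising* stretch accommodates — the tonic SAC current depolarizes it to
about −65 mV, sodium channels inactivate, and no action potential fires
even though a step to the same stretch from rest would fire. This shapes
the organ-level SAC results below.

## Active tension

The three-state cross-bridge scheme of the cited human tension model:
blocked troponin B, unattached-unblocked U = 1 − B − S − W, pre-powerstroke
W, force-generating S, with calcium-bound troponin CaTRPN and distortions
ζ_s, ζ_w. Tension is
`Ta = h(λ) · T_ref/r_s · ((ζ_s + 1) S + ζ_w W)`, floored at zero, with
`h(λ) = max(0, 1 + β₀(min(λ,1.2) + min(λ,0.87) − 1.87))` and calcium
half-activation `[Ca]_T50 = [Ca]_T50^ref + β₁(min(λ,1.2) − 1)`. β₁ is
*negative* (stretch sensitizes the filaments — the cellular basis of the
Frank–Starling response); β₀ = 2.3. The distortion ODEs
`dζ/dt = A_eff λ̇ − c ζ` carry the velocity dependence (A_eff = 10).
Coupling to electrophysiology is strictly one-way: calcium is read from the
ionic model; there is no troponin feedback on ionic calcium.

MEF ablations: `velocity_dependence=False` sets A_eff = 0 (the "Ta(λ,0)"
configuration); additionally `length_dependence=False` sets β₀ = β₁ = 0
("Ta(1,0)"). Because removing the distortion terms raises generated
tension, these configurations use a retuned `T_ref` chosen so peak LV
pressure is again comparable to baseline — the same criterion the
reference study applied. For this package's calibration that value is
**105 kPa** (the study's own retuned value, 70 kPa, belongs to its
unavailable supplementary calibration and would collapse peak pressure to
~80 mmHg here).

Canine calibration: the published human values are retained except
k_uw/k_ws (cross-bridge cycling, ×1.5) and [Ca]_T50^ref (×1.4), which set
the twitch time-to-peak and relaxation; the human twitch is too slow and
too sustained for a dog at 100 beats/min and would stretch the ejection
phase far past the measured 139 ms. T_ref = 120 kPa (published value)
survives organ-level calibration unchanged.

## Wall mechanics

Each ventricle is an independent thin-wall sphere tiled by patches
(default 8 LV free wall + 4 septal on the LV sphere; 6 RV). Given a cavity
volume V, the midwall radius follows from V + half the wall volume; patch
areas {A_i} partition the midwall area such that the membrane tension

    T_i = k_t · σ_i(λ_i) · h_i,   λ_i = sqrt(A_i / A_ref,i),  h_i = V_wall,i / A_i

is equal across patches, and P = 2 T / r (Laplace). σ is the sum of the
passive fiber stress (exponential orthotropic energy reduced to the fiber
axis under incompressible uniaxial kinematics; C = 6.8 kPa calibrated,
b_ff = 8, b_ss = b_nn = 6), the active tension, and a viscous stress
η λ̇ with η = 0.8 kPa·s (within measured myocardial viscosity).

`k_t` = 0.285 is the *tension transmission* factor: the fraction of fiber
Cauchy stress transmitted into each in-plane membrane direction. Fibers
dispersed in-plane transmit at most half their axial stress per direction;
the calibrated value also absorbs the 3D effects a sphere lacks (transmural
fiber rotation, shear). It is the main pressure-scale calibration constant
and keeps the model's peak fiber tensions (~60–75 kPa) and peak pressures
(~110 mmHg) simultaneously physiological.

Reference areas are prescribed from an end-diastolic calibration state
(LV 59.1 mL, RV 74.5 mL at fiber stretch 1.10); there is no unloading
step. Fiber stretch is the in-plane isotropic area stretch — sheet/normal
structure enters only through the uniaxial reduction, and the 40 %
transverse active stress of 3D models has no meaning on a membrane.

The equal-tension partition is solved by damped Newton on the arrowhead
system (areas + common tension; area conservation is exact, tension
equalization to 10⁻¹⁰ relative). The solver evaluates the distortions at
their end-of-step values implied by each trial stretch rate (exact
exponential update), so the physical velocity dependence also stabilizes
inter-patch redistribution under dyssynchronous activation; the viscous
term covers the velocity-ablated configurations.

## Circulation and coupling

A reduced closed loop (the full reference circulation model's 26 ODEs are
collapsed to 12): volumes of systemic/pulmonary arteries and veins, both
atria and both ventricles, plus four valve flows. Vascular beds are linear
compliances; atria are time-varying elastances (RA at beat onset, LA 40 ms
later, 180 ms twitches so the atrial kick peaks at the 130 ms AV delay);
valves are inertial Bernoulli diodes whose resistance blends geometrically
between open and closed values over a 0.75 mmHg window, with a series
characteristic resistance at the two outflow valves standing in for the
arterial tube impedance. The semi-implicit valve update solves the step
equation exactly (a scalar quadratic), so closed-valve stiffness cannot
destabilize the integration. Total blood volume is conserved to rounding
because every flow enters one volume and leaves another.

Coupling: within each 1 ms mechanics step the loop is integrated in five
substeps against a linearization P ≈ P₀ + dP/dV·(V − V₀) of each
ventricle (slope from the equilibrium solve), and the linearization is
refreshed at the end-of-step volumes until the pressure residual falls
below 10⁻⁶ (≤ 50 iterations). The wall then advances: stretch and stretch
rate (backward difference) → SAC conductance and stimulus per patch → 50
electrophysiology substeps → 10 tension substeps at the recorded calcium.
Timesteps: EP 0.02 ms, tension 0.1 ms, mechanics/circulation 1 ms
(staggered); halving the mechanics step changes stroke volume by < 0.5 %.

## Protocols

* **Baseline**: 600 ms cycle, beats repeat until SV/EDV/EDP of both
  ventricles change < 1 % beat-to-beat (the package's steady-state
  definition) or 10 beats. The shipped initial state is the converged
  baseline, so the default run settles in a few beats.
* **Ablation matrix**: {±SAC} × {Ta(λ,λ̇), Ta(λ,0), Ta(1,0)}, the latter
  two with the retuned T_ref.
* **SAC sweep**: recalibrate G at each trigger level, run to steady state,
  report the earliest pre-stimulus depolarization over the whole run and
  the final-beat hemodynamics.
* **LBBB**: acute — exactly 2 beats from the converged baseline state. RV
  patches keep the AV delay; septal (42–84 ms) and LV free-wall
  (84–126 ms) delays are scaled so depolarization completes ≈ 138 ms after
  the sinus stimulus, the reported LBBB QRS duration.
* **CRT**: acute — 2 beats from the LBBB state; LV-lateral-epicardial and
  RV-apical patches paced at a 120 ms AV delay, the rest reached by the
  same slow myocardial propagation with conduction distances halved by the
  two sites (0.5 × the LBBB delays).
* **Activation-dispersion fixture**: uniform per-patch activation jitter
  (± configured half-width, seeded) supplies the heterogeneity a 0D model
  lacks, so the *direction* of MEF effects on stretch/tension dispersion is
  testable; 3D geometric heterogeneity itself is not reproducible.

All experiments are pure functions of their configuration; there is no
hidden randomness (the seed only feeds the optional jitter draws).

## Calibration summary

Tuned once against the canine baseline targets (LV SV 18.8 mL, PP
111.2 mmHg, EDP 12.7 mmHg, EDV 59.1 mL, IVC 68 ms, ejection 139 ms) and
then frozen: k_t = 0.285, C = 6.8 kPa, tension kinetics as above,
R_sys = 2850, R_pul = 360, R_char,sys = 100 mmHg·ms/mL, C_sa = 0.55
mL/mmHg, atrial elastances 0.25–0.50 (LA) and 0.12–0.30 (RA) mmHg/mL,
total blood volume via the shipped initial volumes. The default run lands
at SV 18.6, PP 113.3, EDP 12.2, EDV 58.5, IVC 61, ejection 139.

## What the synthetic world does and does not establish

The generators and fixtures emulate what a 3D electromechanics pipeline
feeds its cell models — stretch waveforms, calcium transients, activation
schedules — under idealized, spatially coarse conditions. A green test
establishes that the *mechanisms* behave and interact as in the reference
physiology at matched global hemodynamics; it does not establish 3D stress
or strain fields, transmural gradients, or wave propagation.

Known limitations found and kept (not patched over):

* **High operating stretch.** The sphere shortens less per ejected
  milliliter than 3D fibers do; systolic fiber stretch stays ≥ 1.0 instead
  of dipping to ~0.9. The length factor h(λ) therefore matters more here,
  and the fully ablated Ta(1,0) configuration is weaker relative to
  Ta(λ,0) than in 3D — at the shared retuned T_ref its peak pressure is
  ~80 mmHg, not ~110.
* **Stretch-IQR saturation.** Under dispersed activation the tension
  heterogeneity ordering (largest with full MEF, smallest with none)
  reproduces, and stretch dispersion grows when velocity dependence is
  removed; but the additional growth from removing length dependence does
  not appear — the weakened Ta(1,0) ventricle dilates in the closed loop,
  every patch's stretch floor rises, and the interquartile range of patch
  maxima compresses even though systolic stretch heterogeneity grows.
* **SAC accommodation.** Because every patch sits at λ ≈ 1.03–1.10
  through diastole, the calibrated SAC current tonically depolarizes the
  myocytes (to ≈ −65 mV before the stimulus — the reference study's
  supplementary cellular traces show the same rise). Under slow coupled
  stretch ramps this suppresses self-excitation at steady state: premature
  depolarization appears on the first (unadapted) beat with monotonically
  longer lead times below the 7 % trigger (13–90 ms), but does not persist,
  and lowering the trigger to 5 % under LBBB does not restore stroke
  volume the way the 3D model's stretch hot spots allow. The tonic current
  also makes the ±SAC hemodynamic difference ~2 % rather than < 1 %.
* **Acute CRT gain** (+1.6 mL vs ~1.3) is sensitive to the CRT propagation
  map, which 0D cannot derive from lead positions; the default is the
  two-site halved-distance construction, fixed a priori.
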