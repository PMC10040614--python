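# cardiomef

Closed-loop 0D cardiac electromechanics with mechanoelectric feedback (MEF).

`cardiomef` simulates the beating canine ventricles at desk scale to study
how the mechanisms by which mechanics feeds back on electrophysiology and
force generation — stretch-activated channels (SACs), length-dependent
tension (the cellular Frank–Starling effect), and shortening-velocity-
dependent tension — shape cardiac output, and what they do under left bundle
branch block (LBBB) and cardiac resynchronization therapy (CRT). It is aimed
at cardiac-modeling researchers who want the coupled physiology of a 3D
finite-element electromechanics pipeline in a seconds-per-beat surrogate.

## The model

* **Myocyte electrophysiology** — the Ten Tusscher–Panfilov human ventricular
  ionic model (19 states), integrated with Rush–Larsen exponential gate
  updates at dt = 0.02 ms, with an injection port for external currents.
* **Stretch-activated current** — the Kohl–Sachs sigmoid channel
  `I_SAC = G (V_m − E_SAC) / (1 + K e^{−α(λ−1)})`, with `G` calibrated by
  bisection so that a sustained stretch at a configurable *trigger level*
  (10 % by default) elicits an action potential in an isolated paced cell
  while one percent less does not.
* **Active tension** — a three-state cross-bridge model with
  troponin–calcium regulation, distortion (velocity) dynamics and length
  dependence:
  `Ta(λ, λ̇) = h(λ) · T_ref/r_s · ((ζ_s + 1) S + ζ_w W)`,
  `dζ_{s,w}/dt = A_eff λ̇ − c_{s,w} ζ_{s,w}`,
  `[Ca]_T50 = [Ca]_T50^ref + β₁ (min(λ, 1.2) − 1)`.
  MEF toggles set `A_eff = 0` (no velocity dependence) and/or
  `β₀ = β₁ = 0` (no length dependence).
* **Ventricular walls** — each ventricle is a thin-wall sphere tiled by
  patches (12 LV incl. 4 septal, 6 RV). A cavity volume fixes the midwall
  area; patch areas partition it such that membrane tension (passive
  exponential-orthotropic fiber stress + active tension, times wall
  thickness) is equal across patches; Laplace's law returns cavity pressure.
  Per-patch stretch drives the SACs and the tension model — the closed MEF
  loop.
* **Circulation** — a reduced 12-ODE closed loop (8 compartment volumes +
  4 valve flows): linear vascular compliances, time-varying-elastance atria
  (right atrium at beat onset, 40 ms inter-atrial delay), inertial
  Bernoulli-diode valves, strongly coupled to both ventricles by fixed-point
  sub-iteration each 1 ms mechanics step.

The default configuration is calibrated to a ~20 kg dog at 100 beats/min
(600 ms cycle, 130 ms AV delay): LV stroke volume ≈ 18.8 mL, peak pressure
≈ 111 mmHg, end-diastolic volume/pressure ≈ 59 mL / 12.7 mmHg. Experiment
pipelines reproduce the MEF ablation matrix ({±SAC} × {Ta(λ,λ̇), Ta(λ,0),
Ta(1,0)}), the SAC trigger-level sweep, and acute LBBB/CRT protocols.
See `docs/methods.md` for assumptions, calibration and known limitations.

## Worked example

```
$ cardiomef run-baseline --out out
LV: SV=18.61 mL PP=113.3 mmHg EDV=58.5 mL EDP=12.19 mmHg IVC=61 ms ejection=139 ms (converged=True)
```

The baseline heart is paced to a steady state in ≤ 10 beats: an LV stroke
volume of 18.6 mL ejected against a 113 mmHg peak pressure from an
end-diastolic volume of 58.5 mL, with a 61 ms isovolumetric-contraction
phase and a 139 ms ejection phase — canine physiology at 100 beats/min.
`out/` receives per-beat metrics, hemodynamic traces, per-patch
stretch/tension/voltage traces (CSV) and a run manifest (JSON).

The same library calls are available in Python:

```python
from cardiomef import protocols as pr

base = pr.run_to_steady_state()          # calibrates SACs, runs <= 10 beats
lbbb = pr.lbbb_protocol(base)            # 2 acute beats, LBBB activation map
crt  = pr.crt_protocol(lbbb)             # 2 acute beats, biventricular pacing
for r in (base, lbbb, crt):
    print(round(r.final["lv"].SV, 1))
# 18.6 / 16.2 / 17.8  (mL)
```

Other CLI subcommands: `run-ablation`, `run-sac-sweep`, `run-lbbb`,
`run-crt`, `calibrate` (all take `--config`, `--out`, `--seed`,
`--log-level`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the study's headline quantities from scratch — the single-cell
stretch trigger after SAC calibration, the calibrated baseline LV
hemodynamics (stroke volume, peak pressure, end-diastolic pressure and
volume, isovolumetric-contraction and ejection durations), and the acute
LBBB / LBBB-with-5 %-SAC-trigger / CRT stroke volumes — by pacing the cell
model, calibrating the stretch-activated conductance, and running the
closed-loop protocols, and writes them as JSON.
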