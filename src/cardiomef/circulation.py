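"""Reduced closed-loop lumped circulation strongly coupled to the two
thin-wall ventricles.

Eight volume states (systemic/pulmonary arteries and veins, both atria, both
ventricles) and four valve flow states (mitral, aortic, tricuspid,
pulmonary) form a 12-ODE closed loop: linear compliances for the vascular
beds, time-varying-elastance atria, and Bernoulli-resistance valves with
inertance and smooth (tanh) open/closed switching. Ventricular pressures come
from the wall-equilibrium solve; within a mechanics step the two systems are
sub-iterated to a fixed point on the ventricular pressure.

Units: mL, ms, mmHg; flows mL/ms; resistances mmHg*ms/mL (Bernoulli:
mmHg*ms^2/mL^2); compliances mL/mmHg; inertances mmHg*ms^2/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .wall import Ventricle0D, SolverError, MECH_DT

__all__ = [
    "ValveLaw",
    "AtriumParams",
    "CircParams",
    "CircState",
    "valve_flow_derivative",
    "atrial_activation",
    "atrial_pressure",
    "circulation_derivatives",
    "step_system",
]


@dataclass(frozen=True)
class ValveLaw:
    """Diode with inertia: dq/dt = (dP - R_eff q |q|) / L, R_eff blending
    smoothly between open and closed values over a pressure window."""

    R_open: float        # mmHg ms^2/mL^2
    R_closed: float = 1e9
    L: float = 300.0     # mmHg ms^2/mL
    width: float = 0.75  # mmHg, tanh blending window

    def __post_init__(self) -> None:
        if self.R_closed <= self.R_open:
            raise ValueError("closed resistance must exceed open resistance")
        if min(self.R_open, self.L, self.width) <= 0:
            raise ValueError("valve parameters must be positive")

    def r_eff(self, dP: float) -> float:
        # geometric blending: with R_closed ~ 1e9 a linear mix would leave a
        # large closed-branch contribution far into the open regime
        s = 0.5 * (1.0 + math.tanh(dP / self.width))
        return math.exp(s * math.log(self.R_open)
                        + (1.0 - s) * math.log(self.R_closed))


@dataclass(frozen=True)
class AtriumParams:
    E_min: float         # mmHg/mL
    E_max: float
    V_us: float          # mL, unstressed volume
    t_act: float         # ms from beat onset
    duration: float = 150.0  # ms, twitch duration

    def __post_init__(self) -> None:
        if min(self.E_min, self.E_max, self.duration) <= 0:
            raise ValueError("elastances and duration must be positive")
        if self.E_max < self.E_min:
            raise ValueError("E_max must be >= E_min")


@dataclass(frozen=True)
class CircParams:
    """Closed-loop parameters, tuned for a ~20 kg dog at 100 beats/min."""

    R_sys: float = 2850.0
    R_pul: float = 360.0
    R_sv: float = 30.0       # systemic veins -> RA
    R_pv: float = 25.0       # pulmonary veins -> LA
    R_char_sys: float = 100.0  # aortic characteristic (proximal) resistance
    R_char_pul: float = 25.0   # pulmonary artery characteristic resistance
    C_sa: float = 0.55
    C_pa: float = 1.2
    C_sv: float = 35.0
    C_pv: float = 10.0
    V_us_sa: float = 35.0
    V_us_pa: float = 20.0
    V_us_sv: float = 300.0
    V_us_pv: float = 60.0
    la: AtriumParams = field(default_factory=lambda: AtriumParams(
        E_min=0.25, E_max=0.50, V_us=8.0, t_act=40.0, duration=180.0))
    ra: AtriumParams = field(default_factory=lambda: AtriumParams(
        E_min=0.12, E_max=0.30, V_us=25.0, t_act=0.0, duration=180.0))
    mitral: ValveLaw = field(default_factory=lambda: ValveLaw(R_open=10.0, L=150.0))
    aortic: ValveLaw = field(default_factory=lambda: ValveLaw(R_open=25.0, L=300.0))
    tricuspid: ValveLaw = field(default_factory=lambda: ValveLaw(R_open=10.0, L=150.0))
    pulmonary: ValveLaw = field(default_factory=lambda: ValveLaw(R_open=12.0, L=200.0))

    def __post_init__(self) -> None:
        for name in ("R_sys", "R_pul", "R_sv", "R_pv",
                     "C_sa", "C_pa", "C_sv", "C_pv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CircState:
    """Compartment volumes (mL) and valve flows (mL/ms)."""

    # defaults: converged baseline state (so <= 10 beats reach steady state)
    V_sa: float = 81.73
    V_sv: float = 385.27
    V_pa: float = 42.99
    V_pv: float = 164.58
    V_la: float = 44.57
    V_ra: float = 34.29
    V_lv: float = 48.44
    V_rv: float = 54.29
    q_mv: float = 0.05
    q_av: float = 0.0
    q_tv: float = 0.03
    q_pv: float = 0.0

    VOLUMES = ("V_sa", "V_sv", "V_pa", "V_pv", "V_la", "V_ra", "V_lv", "V_rv")
    FLOWS = ("q_mv", "q_av", "q_tv", "q_pv")

    def __post_init__(self) -> None:
        for name in self.VOLUMES:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def total_volume(self) -> float:
        return sum(getattr(self, n) for n in self.VOLUMES)

    def copy(self) -> "CircState":
        return replace(self)


# ------------------------------------------------------------------- pieces
def valve_flow_derivative(q: float, dP: float, law: ValveLaw) -> float:
    """dq/dt (mL/ms^2) of the inertial diode at flow ``q`` and pressure drop
    ``dP`` (upstream minus downstream)."""
    if not (math.isfinite(q) and math.isfinite(dP)):
        raise ValueError("non-finite valve inputs")
    return (dP - law.r_eff(dP) * q * abs(q)) / law.L


def _valve_step(q: float, dP: float, law: ValveLaw, dt: float,
                r_lin: float = 0.0) -> float:
    """Semi-implicit update: solves q' = q + dt*(dP - r_lin q' - R q'|q'|)/L
    exactly (scalar quadratic), unconditionally stable for stiff closed
    valves. ``r_lin`` is a series (characteristic) resistance."""
    R = law.r_eff(dP)
    c = law.L * q + dt * dP
    if c == 0.0:
        return 0.0
    a = R * dt
    b = law.L + r_lin * dt
    # cancellation-free root of a q^2 + b q - |c| = 0
    mag = 2.0 * abs(c) / (b + math.sqrt(b * b + 4.0 * a * abs(c)))
    return math.copysign(mag, c)


def atrial_activation(t: float, atrium: AtriumParams, cycle_length: float) -> float:
    """Smooth single-peak activation a(t) in [0, 1], periodic."""
    th = (t - atrium.t_act) % cycle_length
    if th >= atrium.duration:
        return 0.0
    return 0.5 * (1.0 - math.cos(2.0 * math.pi * th / atrium.duration))


def atrial_pressure(V: float, t: float, atrium: AtriumParams,
                    cycle_length: float = 600.0) -> float:
    """Time-varying elastance P = E(t) (V - V_us), E sweeping E_min..E_max."""
    if V <= 0:
        raise ValueError("atrial volume must be positive")
    a = atrial_activation(t, atrium, cycle_length)
    e = atrium.E_min + (atrium.E_max - atrium.E_min) * a
    return e * (V - atrium.V_us)


def _pressures(s: CircState, p: CircParams, t: float, cycle_length: float,
               P_lv: float, P_rv: float) -> dict:
    return {
        "sa": (s.V_sa - p.V_us_sa) / p.C_sa,
        "sv": (s.V_sv - p.V_us_sv) / p.C_sv,
        "pa": (s.V_pa - p.V_us_pa) / p.C_pa,
        "pv": (s.V_pv - p.V_us_pv) / p.C_pv,
        "la": atrial_pressure(s.V_la, t, p.la, cycle_length),
        "ra": atrial_pressure(s.V_ra, t, p.ra, cycle_length),
        "lv": P_lv,
        "rv": P_rv,
    }


def circulation_derivatives(s: CircState, P_lv: float, P_rv: float,
                            p: CircParams, t: float = 0.0,
                            cycle_length: float = 600.0) -> dict:
    """Full derivative of the 12-state loop (volumes: signed flow sums;
    valve flows: inertial diode law). Closed loop: volume derivatives sum to
    zero exactly by construction."""
    pr = _pressures(s, p, t, cycle_length, P_lv, P_rv)
    q_sys = (pr["sa"] - pr["sv"]) / p.R_sys
    q_vr = (pr["sv"] - pr["ra"]) / p.R_sv
    q_pul = (pr["pa"] - pr["pv"]) / p.R_pul
    q_pvr = (pr["pv"] - pr["la"]) / p.R_pv
    return {
        "V_sa": s.q_av - q_sys,
        "V_sv": q_sys - q_vr,
        "V_ra": q_vr - s.q_tv,
        "V_rv": s.q_tv - s.q_pv,
        "V_pa": s.q_pv - q_pul,
        "V_pv": q_pul - q_pvr,
        "V_la": q_pvr - s.q_mv,
        "V_lv": s.q_mv - s.q_av,
        "q_mv": valve_flow_derivative(s.q_mv, pr["la"] - pr["lv"], p.mitral),
        "q_av": valve_flow_derivative(
            s.q_av, pr["lv"] - pr["sa"] - p.R_char_sys * s.q_av, p.aortic),
        "q_tv": valve_flow_derivative(s.q_tv, pr["ra"] - pr["rv"], p.tricuspid),
        "q_pv": valve_flow_derivative(
            s.q_pv, pr["rv"] - pr["pa"] - p.R_char_pul * s.q_pv, p.pulmonary),
    }


def _integrate_sub(s: CircState, p: CircParams, t0: float, dt: float,
                   n_sub: int, cycle_length: float,
                   lin_lv: tuple, lin_rv: tuple) -> CircState:
    """Advance the loop ``n_sub`` substeps with ventricular pressures from
    the linearizations ``lin = (P0, E, V0)``; conservative volume updates."""
    s = s.copy()
    h = dt / n_sub
    for k in range(n_sub):
        t = t0 + k * h
        P_lv = lin_lv[0] + lin_lv[1] * (s.V_lv - lin_lv[2])
        P_rv = lin_rv[0] + lin_rv[1] * (s.V_rv - lin_rv[2])
        pr = _pressures(s, p, t, cycle_length, P_lv, P_rv)
        q_sys = (pr["sa"] - pr["sv"]) / p.R_sys
        q_vr = (pr["sv"] - pr["ra"]) / p.R_sv
        q_pul = (pr["pa"] - pr["pv"]) / p.R_pul
        q_pvr = (pr["pv"] - pr["la"]) / p.R_pv
        s.q_mv = _valve_step(s.q_mv, pr["la"] - pr["lv"], p.mitral, h)
        s.q_av = _valve_step(s.q_av, pr["lv"] - pr["sa"], p.aortic, h,
                             r_lin=p.R_char_sys)
        s.q_tv = _valve_step(s.q_tv, pr["ra"] - pr["rv"], p.tricuspid, h)
        s.q_pv = _valve_step(s.q_pv, pr["rv"] - pr["pa"], p.pulmonary, h,
                             r_lin=p.R_char_pul)
        s.V_sa += h * (s.q_av - q_sys)
        s.V_sv += h * (q_sys - q_vr)
        s.V_ra += h * (q_vr - s.q_tv)
        s.V_rv += h * (s.q_tv - s.q_pv)
        s.V_pa += h * (s.q_pv - q_pul)
        s.V_pv += h * (q_pul - q_pvr)
        s.V_la += h * (q_pvr - s.q_mv)
        s.V_lv += h * (s.q_mv - s.q_av)
    return s


def step_system(circ: CircState, ventricles: tuple[Ventricle0D, Ventricle0D],
                params: CircParams, t: float, dt: float = MECH_DT, *,
                cycle_length: float = 600.0, n_sub: int = 5,
                tol: float = 1e-6, max_iter: int = 50,
                stim_amp: float = -26.0, stim_dur: float = 2.0,
                t_in_beat: Optional[float] = None) -> CircState:
    """Advance the coupled circulation + walls one mechanics step.

    Fixed-point sub-iteration between the cavity-pressure (wall equilibrium)
    and the flow integration: the ventricular P(V) relation is linearized
    about the latest equilibrium solve, the loop is integrated over the
    step, and the linearization is refreshed at the end-of-step volumes
    until the relative pressure residual falls below ``tol``.
    """
    lv, rv = ventricles
    tb = t if t_in_beat is None else t_in_beat
    lin_lv = (lv.P, lv.dPdV, lv.V)
    lin_rv = (rv.P, rv.dPdV, rv.V)
    for it in range(max_iter):
        trial = _integrate_sub(circ, params, tb, dt, n_sub, cycle_length,
                               lin_lv, lin_rv)
        _, _, P_lv, dPdV_lv = lv.equilibrium(trial.V_lv, dt_visc=dt)
        _, _, P_rv, dPdV_rv = rv.equilibrium(trial.V_rv, dt_visc=dt)
        res = max(
            abs(P_lv - (lin_lv[0] + lin_lv[1] * (trial.V_lv - lin_lv[2])))
            / max(abs(P_lv), 1.0),
            abs(P_rv - (lin_rv[0] + lin_rv[1] * (trial.V_rv - lin_rv[2])))
            / max(abs(P_rv), 1.0),
        )
        if res < tol:
            break
        lin_lv = (P_lv, dPdV_lv, trial.V_lv)
        lin_rv = (P_rv, dPdV_rv, trial.V_rv)
    else:
        raise SolverError(
            f"pressure-flow fixed point did not converge (residual {res:.2e})",
            residual=res)
    # commit: full MEF wall update at the accepted end-of-step volumes
    lv.advance(trial.V_lv, tb, dt, stim_amp=stim_amp, stim_dur=stim_dur)
    rv.advance(trial.V_rv, tb, dt, stim_amp=stim_amp, stim_dur=stim_dur)
    return trial
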