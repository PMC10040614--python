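"""Stretch-activated channel (SAC) current and its trigger-level calibration.

The current follows the Kohl-Sachs sigmoidal conductance model

    I_SAC = G * (Vm - E_SAC) / (1 + K * exp(-alpha * (lambda - 1)))

added to the myocyte's membrane current balance. ``G`` is the only parameter
touched by calibration: it is rescaled by bisection until a sustained stretch
step at exactly the requested trigger level elicits a full action potential in
a paced-to-steady-state cell, while one scan step below does not depolarize
the cell past -40 mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .ionic import CellParams, CellState, pace_to_steady_state, simulate_beats

__all__ = [
    "SACParams",
    "TriggerLevel",
    "CalibrationError",
    "CalibrationResult",
    "i_sac",
    "sac_conductance",
    "calibrate_sac",
]


@dataclass(frozen=True)
class SACParams:
    """Sigmoid stretch-activated current parameters.

    ``G`` in A/F per mV (equivalently nS/pF), ``E_SAC`` in mV. ``K`` and
    ``alpha`` shape the stretch sigmoid; defaults follow the cited
    formulation's published values, with ``G`` the calibration target.
    """

    G: float = 1.0
    E_SAC: float = -20.0
    K: float = 100.0
    alpha: float = 3.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.G < 0:
            raise ValueError("G must be >= 0")
        if self.K <= 0 or self.alpha <= 0:
            raise ValueError("K and alpha must be > 0")


@dataclass(frozen=True)
class TriggerLevel:
    """Stretch fraction at which a sustained stretch must elicit an AP."""

    value: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 < self.value <= 0.2:
            raise ValueError("trigger level must lie in (0, 0.2]")


def sac_conductance(lam: float, params: SACParams) -> float:
    """Effective ohmic conductance G / (1 + K e^{-alpha (lambda-1)}) (A/F/mV).

    The SAC current is linear in Vm at fixed stretch, so the coupled solver
    passes this conductance to the ionic kernel as an affine external current.
    """
    if np.any(np.asarray(lam) <= 0):
        raise ValueError("stretch ratio must be > 0")
    if not params.enabled:
        return np.zeros_like(np.asarray(lam, dtype=float)) if np.ndim(lam) else 0.0
    return params.G / (1.0 + params.K * np.exp(-params.alpha * (np.asarray(lam) - 1.0)))


def i_sac(Vm, lam, params: SACParams):
    """Stretch-activated current density (A/F); 0 when disabled."""
    g = sac_conductance(lam, params)
    return g * (np.asarray(Vm) - params.E_SAC)


class CalibrationError(RuntimeError):
    def __init__(self, message: str, history=None):
        super().__init__(message)
        self.history = history or []


@dataclass
class CalibrationResult:
    params: SACParams
    scale: float
    trigger: float
    history: list  # (scale, stretch, fired, peak_vm) evaluations


def _stretch_response(scale: float, lam: float, cell: CellParams,
                      base: SACParams, state: CellState,
                      cycle_length: float) -> float:
    """Peak Vm over one cycle of sustained stretch, no stimulus."""
    g = scale * base.G / (1.0 + base.K * math.exp(-base.alpha * (lam - 1.0)))
    _, vm, _, _ = simulate_beats(
        state, cell, cycle_length=cycle_length, n_beats=1,
        stim=None, i_sac_affine=(-g * base.E_SAC, g), record_dt=1.0,
    )
    return float(vm.max())


def calibrate_sac(trigger: TriggerLevel | float, cell: CellParams,
                  base: Optional[SACParams] = None, scan_step: float = 0.01,
                  *, cycle_length: float = 600.0, rel_tol: float = 3e-4,
                  paced_state: Optional[CellState] = None) -> CalibrationResult:
    """Rescale ``G`` so that a sustained stretch at the trigger level fires an
    action potential (peak Vm > 0 mV) and one scan step below stays
    subthreshold (peak Vm < -40 mV).

    A "sustained stretch" is a step from lambda = 1 to the target held for one
    full cycle, applied to the end-diastolic paced state.
    """
    trig = trigger.value if isinstance(trigger, TriggerLevel) else float(trigger)
    trig = TriggerLevel(trig).value
    if scan_step > 0.01:
        raise ValueError("scan step must be <= 0.01")
    if base is None:
        base = SACParams()
    if paced_state is None:
        paced_state = pace_to_steady_state(cell, cycle_length=cycle_length,
                                           n_beats_max=100, tol=1e-3).state
    lam_fire = 1.0 + trig
    lam_sub = 1.0 + trig - scan_step
    history: list = []

    def fires(scale: float, lam: float) -> tuple[bool, float]:
        peak = _stretch_response(scale, lam, cell, base, paced_state, cycle_length)
        fired = peak > 0.0
        history.append((scale, lam, fired, peak))
        return fired, peak

    # bracket the minimal firing scale at the trigger stretch
    lo, hi = 1e-3, 1e-3
    fired = False
    for _ in range(25):
        hi *= 4.0
        fired, _ = fires(hi, lam_fire)
        if fired:
            break
        lo = hi
    if not fired:
        raise CalibrationError(
            f"no conductance scale up to {hi:g} fires at stretch {lam_fire:.3f}",
            history)
    while (hi - lo) / hi > rel_tol:
        mid = math.sqrt(lo * hi)
        if fires(mid, lam_fire)[0]:
            hi = mid
        else:
            lo = mid
    scale = hi  # smallest scale found that fires at the trigger level
    sub_fired, sub_peak = fires(scale, lam_sub)
    if sub_fired or sub_peak > -40.0:
        raise CalibrationError(
            f"calibrated scale {scale:g} depolarizes to {sub_peak:.1f} mV at "
            f"stretch {lam_sub:.3f}; trigger separation of {scan_step} "
            "not achievable", history)
    return CalibrationResult(replace(base, G=base.G * scale), scale, trig, history)
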