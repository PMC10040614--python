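"""Quantitative observables of a simulated beat: pressure-volume loop
features, phase durations, depolarization/repolarization summaries, and
per-patch stretch/tension statistics.

End-diastole and end-systole are defined by valve events (inflow-valve
closure and outflow-valve closure) rather than volume extrema: the two
coincide in clean beats, and valve events stay well defined under
SAC-induced premature activity. Quartiles use linear interpolation between
order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ValveEvents",
    "BeatMetrics",
    "find_valve_events",
    "pv_features",
    "patch_statistics",
    "activation_summary",
]

FLOW_THRESHOLD = 1e-4  # mL/ms, open/closed discrimination on valve flow


@dataclass
class ValveEvents:
    inflow_close: Optional[float] = None
    outflow_open: Optional[float] = None
    outflow_close: Optional[float] = None


@dataclass
class BeatMetrics:
    """Hemodynamic features of one beat of one ventricle; None marks a
    quantity whose defining valve event was absent (flagged, not fabricated)."""

    PP: Optional[float] = None        # peak pressure, mmHg
    EDV: Optional[float] = None       # mL
    ESV: Optional[float] = None       # mL
    SV: Optional[float] = None        # mL
    EDP: Optional[float] = None       # mmHg
    max_dPdt: Optional[float] = None  # mmHg/ms
    ivc_duration: Optional[float] = None   # ms
    ejection_duration: Optional[float] = None  # ms
    events: ValveEvents = field(default_factory=ValveEvents)


def _crossings(q: np.ndarray, thr: float, upward: bool) -> np.ndarray:
    if upward:
        idx = np.nonzero((q[:-1] < thr) & (q[1:] >= thr))[0]
    else:
        idx = np.nonzero((q[:-1] >= thr) & (q[1:] < thr))[0]
    return idx


def find_valve_events(times: np.ndarray, q_inflow: np.ndarray,
                      q_outflow: np.ndarray,
                      thr: float = FLOW_THRESHOLD) -> ValveEvents:
    """Valve open/close times from flow-threshold crossings within the beat.

    Inflow closure: the last downward crossing of the inflow flow before the
    outflow valve opens (or the last in the beat if it never opens). Outflow
    closure: the last downward crossing after opening (robust to brief flow
    flutter at ejection onset under dyssynchronous activation).
    """
    times = np.asarray(times)
    ev = ValveEvents()
    up_out = _crossings(np.asarray(q_outflow), thr, True)
    dn_out = _crossings(np.asarray(q_outflow), thr, False)
    if up_out.size:
        ev.outflow_open = float(times[up_out[0] + 1])
        later = dn_out[dn_out > up_out[0]]
        if later.size:
            ev.outflow_close = float(times[later[-1] + 1])
    dn_in = _crossings(np.asarray(q_inflow), thr, False)
    if dn_in.size:
        if ev.outflow_open is not None:
            before = dn_in[times[dn_in + 1] <= ev.outflow_open]
            if before.size:
                ev.inflow_close = float(times[before[-1] + 1])
        else:
            ev.inflow_close = float(times[dn_in[-1] + 1])
    return ev


def _at(times: np.ndarray, y: np.ndarray, t: float) -> float:
    return float(np.interp(t, times, y))


def pv_features(times: np.ndarray, P: np.ndarray, V: np.ndarray,
                events: ValveEvents) -> BeatMetrics:
    """Hemodynamic beat metrics from uniformly sampled P(t), V(t) and valve
    events. max dP/dt uses central differences; features whose defining
    event is missing are left None."""
    times = np.asarray(times, dtype=float)
    P = np.asarray(P, dtype=float)
    V = np.asarray(V, dtype=float)
    if times.size < 3 or P.shape != times.shape or V.shape != times.shape:
        raise ValueError("need uniformly sampled P and V traces (>= 3 samples)")
    m = BeatMetrics(events=events)
    m.PP = float(P.max())
    m.max_dPdt = float(np.max(np.gradient(P, times)))
    if events.inflow_close is not None:
        m.EDV = _at(times, V, events.inflow_close)
        m.EDP = _at(times, P, events.inflow_close)
    if events.outflow_close is not None:
        m.ESV = _at(times, V, events.outflow_close)
    if m.EDV is not None and m.ESV is not None:
        m.SV = m.EDV - m.ESV
    if events.inflow_close is not None and events.outflow_open is not None:
        m.ivc_duration = events.outflow_open - events.inflow_close
    if events.outflow_open is not None and events.outflow_close is not None:
        m.ejection_duration = events.outflow_close - events.outflow_open
    return m


def patch_statistics(per_patch_maxima: np.ndarray) -> dict:
    """Median and [Q1, Q3] across patches of per-patch beat maxima.

    Quartiles are linearly interpolated order statistics; with fewer than 3
    patches the quartiles are flagged undefined (None)."""
    x = np.asarray(per_patch_maxima, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("need a 1-D array of per-patch maxima")
    out = {"median": float(np.median(x)), "q1": None, "q3": None,
           "iqr": None, "n": int(x.size)}
    if x.size >= 3:
        q1, q3 = np.percentile(x, [25.0, 75.0])
        out.update(q1=float(q1), q3=float(q3), iqr=float(q3 - q1))
    return out


def activation_summary(t_dep: np.ndarray, stim_times: np.ndarray) -> dict:
    """Premature-depolarization lead time and activation spread.

    lead_time = max(0, max_i(stimulus_i - t_dep_i)) over patches that
    depolarized; spread = max(t_dep) - min(t_dep). Patches with no detected
    depolarization (NaN/None) are ignored."""
    t_dep = np.asarray(
        [np.nan if v is None else v for v in np.atleast_1d(t_dep)], dtype=float)
    stim = np.asarray(stim_times, dtype=float)
    if stim.shape != t_dep.shape:
        raise ValueError("t_dep and stim_times must have equal length")
    ok = np.isfinite(t_dep)
    if not np.any(ok):
        return {"lead_time": 0.0, "spread": None, "n_activated": 0}
    lead = float(max(0.0, np.max(stim[ok] - t_dep[ok])))
    spread = float(t_dep[ok].max() - t_dep[ok].min())
    return {"lead_time": lead, "spread": spread,
            "n_activated": int(ok.sum())}
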