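"""Ventricular myocyte electrophysiology (Ten Tusscher / Panfilov 2006 human
ventricular formulation) with an injection port for external currents
(stimulus, stretch-activated channels) and action-potential trace analysis.

The cell state is held as a flat float64 vector (layout in
:mod:`cardiomef._kernel`); :class:`CellState` is a thin, validated view used
at API boundaries. All currents are densities in A/F, potentials in mV,
concentrations in mM, time in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np

from . import _kernel as K

__all__ = [
    "CellType",
    "CellParams",
    "CellState",
    "StimulusSpec",
    "PacingResult",
    "cell_derivatives",
    "step_cell",
    "pace_to_steady_state",
    "detect_activation_time",
    "detect_repolarization_time",
    "simulate_beats",
]

EP_DT = 0.02  # ms, fixed electrophysiology substep (stiff upstroke)

STATE_NAMES = (
    "Vm", "m", "h", "j", "d", "f", "f2", "fCass", "r", "s",
    "Xr1", "Xr2", "Xs", "Rbar", "Cai", "CaSR", "CaSS", "Nai", "Ki",
)
GATE_NAMES = STATE_NAMES[K.S_M:K.S_XS + 1]
CONCENTRATION_NAMES = STATE_NAMES[K.S_CAI:]

# published initial conditions (epicardial variant, 1 Hz steady pacing)
_Y0 = np.array([
    -85.23,      # Vm
    1.72e-3,     # m
    0.7444,      # h
    0.7045,      # j
    3.373e-5,    # d
    0.7888,      # f
    0.9755,      # f2
    0.9953,      # fCass
    2.42e-8,     # r
    0.999998,    # s
    6.21e-3,     # Xr1
    0.4712,      # Xr2
    9.5e-3,      # Xs
    0.9073,      # Rbar
    1.26e-4,     # Cai
    3.64,        # CaSR
    3.6e-4,      # CaSS
    8.604,       # Nai
    136.89,      # Ki
])


class CellType(str, Enum):
    ENDO = "endo"
    MID = "mid"
    EPI = "epi"


@dataclass(frozen=True)
class CellParams:
    """Per-cell-type channel conductances (nS/pF) and fixed constants."""

    cell_type: CellType = CellType.EPI
    g_Na: float = 14.838
    g_K1: float = 5.405
    g_to: float = 0.294          # 0.073 for endo
    g_Kr: float = 0.153
    g_Ks: float = 0.392          # 0.098 for mid
    g_CaL: float = 3.98e-5
    g_bNa: float = 2.9e-4
    g_bCa: float = 5.92e-4
    g_pCa: float = 0.1238
    g_pK: float = 0.0146
    P_NaK: float = 2.724
    k_NaCa: float = 1000.0
    K_o: float = 5.4
    Na_o: float = 140.0
    Ca_o: float = 2.0
    Cm: float = 0.185            # uF, scales concentration balances

    def __post_init__(self) -> None:
        for name in ("g_Na", "g_K1", "g_to", "g_Kr", "g_Ks", "g_CaL", "g_bNa",
                     "g_bCa", "g_pCa", "g_pK", "P_NaK", "k_NaCa"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if self.Cm <= 0:
            raise ValueError("Cm must be positive")
        CellType(self.cell_type)

    @classmethod
    def for_cell_type(cls, cell_type: CellType | str) -> "CellParams":
        ct = CellType(cell_type)
        if ct is CellType.ENDO:
            return cls(cell_type=ct, g_to=0.073)
        if ct is CellType.MID:
            return cls(cell_type=ct, g_Ks=0.098)
        return cls(cell_type=ct)

    def to_array(self) -> np.ndarray:
        p = np.empty(K.N_PARAM)
        p[K.P_GNA] = self.g_Na
        p[K.P_GK1] = self.g_K1
        p[K.P_GTO] = self.g_to
        p[K.P_GKR] = self.g_Kr
        p[K.P_GKS] = self.g_Ks
        p[K.P_GCAL] = self.g_CaL
        p[K.P_GBNA] = self.g_bNa
        p[K.P_GBCA] = self.g_bCa
        p[K.P_GPCA] = self.g_pCa
        p[K.P_GPK] = self.g_pK
        p[K.P_PNAK] = self.P_NaK
        p[K.P_KNACA] = self.k_NaCa
        p[K.P_KO] = self.K_o
        p[K.P_NAO] = self.Na_o
        p[K.P_CAO] = self.Ca_o
        p[K.P_SENDO] = 1.0 if CellType(self.cell_type) is CellType.ENDO else 0.0
        p[K.P_CM] = self.Cm
        return p


@dataclass
class CellState:
    """Validated view of the flat state vector."""

    y: np.ndarray = field(default_factory=lambda: _Y0.copy())

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (K.N_STATE,):
            raise ValueError(f"state vector must have length {K.N_STATE}")

    @property
    def Vm(self) -> float:
        return float(self.y[K.S_V])

    @property
    def Cai(self) -> float:
        return float(self.y[K.S_CAI])

    @property
    def gates(self) -> dict:
        return {n: float(v) for n, v in
                zip(GATE_NAMES, self.y[K.S_M:K.S_XS + 1])}

    @property
    def concentrations(self) -> dict:
        return {n: float(v) for n, v in
                zip(CONCENTRATION_NAMES, self.y[K.S_CAI:])}

    def validate(self) -> None:
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite cell state component")
        g = self.y[K.S_M:K.S_XS + 1]
        if np.any(g < 0) or np.any(g > 1):
            raise ValueError("gating variable outside [0, 1]")
        if np.any(self.y[K.S_CAI:] <= 0):
            raise ValueError("non-positive concentration")

    def copy(self) -> "CellState":
        return CellState(self.y.copy())

    @classmethod
    def initial(cls) -> "CellState":
        return cls(_Y0.copy())


@dataclass(frozen=True)
class StimulusSpec:
    """Rectangular (default) transmembrane stimulus, depolarizing when
    amplitude < 0 (A/F). The foot-shaped tissue current of the source model is
    approximated by a 2 ms rectangle at roughly twice diastolic threshold."""

    onset: float = 0.0
    duration: float = 2.0
    amplitude: float = -26.0
    shape: str = "rectangular"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be > 0")
        if self.onset < 0:
            raise ValueError("stimulus onset must be >= 0")
        if self.shape not in ("rectangular", "foot-like"):
            raise ValueError(f"unknown stimulus shape {self.shape!r}")


def cell_derivatives(state: CellState, params: CellParams,
                     i_external: float = 0.0) -> np.ndarray:
    """Time derivative of the full state; ``i_external`` (A/F) is added to the
    membrane current balance (dVm/dt = -(I_ion + i_external))."""
    if not np.all(np.isfinite(state.y)):
        raise ValueError("non-finite cell state component")
    dy = np.empty(K.N_STATE)
    xinf = np.empty(K.N_STATE)
    xtau = np.empty(K.N_STATE)
    K.rhs(state.y, params.to_array(), float(i_external), 0.0, dy, xinf, xtau)
    return dy


def step_cell(state: CellState, params: CellParams, i_external: float = 0.0,
              dt: float = EP_DT) -> CellState:
    """Advance one Rush-Larsen/Euler step of size ``dt`` (ms)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    y = state.y.copy().reshape(1, -1)
    a = np.array([float(i_external)])
    b = np.zeros(1)
    dummy = np.empty((1, 1))
    K.advance(y, params.to_array(), dt, 1, a, b, 0, dummy, dummy)
    return CellState(y[0])


def simulate_beats(state: CellState, params: CellParams, *,
                   cycle_length: float = 600.0, n_beats: int = 1,
                   stim: Optional[StimulusSpec] = None, dt: float = EP_DT,
                   i_sac_affine: tuple[float, float] = (0.0, 0.0),
                   record_dt: float = 1.0):
    """Paced single-cell simulation.

    ``i_sac_affine = (a, b)`` adds a constant ohmic external current
    ``a + b*Vm`` throughout (used for sustained-stretch protocols).
    ``stim=None`` runs unstimulated. Returns ``(times, vm, cai, final_state)``
    with traces sampled every ``record_dt`` ms (t=0 sample included).
    """
    p = params.to_array()
    y = state.y.copy().reshape(1, -1)
    rec_every = max(1, int(round(record_dt / dt)))
    steps_total = int(round(cycle_length / dt)) * n_beats
    n_rec = steps_total // rec_every
    rec_v = np.empty((n_rec, 1))
    rec_cai = np.empty((n_rec, 1))
    sa, sb = i_sac_affine
    a0 = np.array([sa])
    b = np.array([sb])
    k = 0
    for _ in range(n_beats):
        if stim is None:
            segs = ((cycle_length, a0),)
        else:
            a1 = np.array([sa + stim.amplitude])
            segs = (
                (stim.onset, a0),
                (stim.duration, a1),
                (cycle_length - stim.onset - stim.duration, a0),
            )
        for span, a in segs:
            n = int(round(span / dt))
            if n <= 0:
                continue
            kk = K.advance(y, p, dt, n, a, b, rec_every,
                           rec_v[k:], rec_cai[k:])
            k += kk
    times = np.arange(1, k + 1) * (rec_every * dt)
    times = np.concatenate(([0.0], times))
    vm = np.concatenate(([state.Vm], rec_v[:k, 0]))
    cai = np.concatenate(([state.Cai], rec_cai[:k, 0]))
    return times, vm, cai, CellState(y[0])


@dataclass
class PacingResult:
    state: CellState
    converged: bool
    n_beats: int
    criterion: str          # "tolerance" | "max_beats" | "no_beats"
    last_delta: float


def pace_to_steady_state(params: CellParams, cycle_length: float = 600.0,
                         n_beats_max: int = 200, tol: float = 1e-4,
                         stim: Optional[StimulusSpec] = None,
                         state: Optional[CellState] = None) -> PacingResult:
    """Pace an isolated, unstretched cell until the beat-to-beat state change
    (relative L-inf norm at end diastole) falls below ``tol``.

    Non-convergence within ``n_beats_max`` is reported via the ``converged``
    flag, not raised.
    """
    if cycle_length <= 0:
        raise ValueError("cycle_length must be > 0")
    if stim is None:
        stim = StimulusSpec(onset=10.0)
    cur = (state or CellState.initial()).copy()
    if n_beats_max <= 0:
        return PacingResult(cur, False, 0, "no_beats", np.inf)
    # floor avoids the norm being dominated by gates that are ~0 in diastole
    scale = np.maximum(np.abs(_Y0), 0.01)
    delta = np.inf
    for beat in range(1, n_beats_max + 1):
        _, _, _, nxt = simulate_beats(cur, params, cycle_length=cycle_length,
                                      n_beats=1, stim=stim, record_dt=cycle_length)
        delta = float(np.max(np.abs(nxt.y - cur.y) / scale))
        cur = nxt
        if delta < tol:
            return PacingResult(cur, True, beat, "tolerance", delta)
    return PacingResult(cur, False, n_beats_max, "max_beats", delta)


def detect_activation_time(vm: np.ndarray, dt: float,
                           threshold: float = 0.0,
                           t0: float = 0.0) -> Optional[float]:
    """First upward crossing of ``threshold`` (linear interpolation between
    uniformly sampled points), or None if never crossed."""
    vm = np.asarray(vm, dtype=float)
    if vm.size == 0:
        raise ValueError("empty trace")
    below = vm[:-1] < threshold
    above = vm[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    frac = (threshold - vm[i]) / (vm[i + 1] - vm[i])
    return t0 + (i + frac) * dt


def detect_repolarization_time(vm: np.ndarray, dt: float,
                               level: float = 0.9,
                               t0: float = 0.0) -> Optional[float]:
    """Time of ``level`` (default 90%) repolarization.

    The repolarization potential is ``V_peak - level * (V_peak - V_dia)``
    where ``V_dia`` is the pre-upstroke (first-sample) potential; the first
    downward crossing after the AP peak is returned, linearly interpolated.
    None when no activation was detected. ``level`` may alternatively be an
    absolute potential in mV (any value <= -20 is taken as mV).
    """
    vm = np.asarray(vm, dtype=float)
    if vm.size == 0:
        raise ValueError("empty trace")
    if detect_activation_time(vm, dt, threshold=0.0) is None:
        return None
    ipk = int(np.argmax(vm))
    vdia = float(vm[0])
    vpk = float(vm[ipk])
    if level <= -20.0:
        vrep = float(level)
    else:
        vrep = vpk - level * (vpk - vdia)
    seg = vm[ipk:]
    above = seg[:-1] > vrep
    below = seg[1:] <= vrep
    idx = np.nonzero(above & below)[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    frac = (seg[i] - vrep) / (seg[i] - seg[i + 1])
    return t0 + (ipk + i + frac) * dt


def apd(vm: np.ndarray, dt: float, level: float = 0.9) -> Optional[float]:
    """Action potential duration at the given repolarization fraction."""
    t_act = detect_activation_time(vm, dt)
    if t_act is None:
        return None
    t_rep = detect_repolarization_time(vm, dt, level=level)
    if t_rep is None:
        return None
    return t_rep - t_act
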