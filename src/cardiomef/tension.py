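"""Active tension from a three-state cross-bridge model with troponin-calcium
regulation, length dependence (Frank-Starling) and shortening-velocity
dependence (Land et al. human formulation).

State variables: post-powerstroke fraction S, pre-powerstroke fraction W,
blocked-troponin fraction B, calcium-bound troponin fraction CaTRPN, and the
cross-bridge distortions zeta_s, zeta_w. Generated tension:

    Ta(lambda, lambda_dot) = h(lambda) * Tref/rs * ((zeta_s + 1) S + zeta_w W)

with h the length factor and the distortions driven by A_eff * lambda_dot.
Mechanoelectric-feedback toggles remove the velocity term (A_eff -> 0) and/or
the length terms (beta0 = beta1 = 0).

Calcium is read from the ionic model (one-way coupling); concentrations here
are in mM to match it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "LandParams",
    "LandState",
    "MEFToggles",
    "length_factor",
    "ca50",
    "land_derivatives",
    "active_tension",
    "land_steady_state",
    "isometric_twitch",
    "TENSION_DT",
]

TENSION_DT = 0.1  # ms, tension ODE substep

# state vector layout for the array-based integrator
L_S, L_W, L_B, L_CATRPN, L_ZS, L_ZW = range(6)
N_LAND = 6


@dataclass(frozen=True)
class MEFToggles:
    """Which mechanoelectric feedback mechanisms are active."""

    velocity_dependence: bool = True
    length_dependence: bool = True
    sac_enabled: bool = True

    @property
    def label(self) -> str:
        base = ("Ta_lv" if self.velocity_dependence and self.length_dependence
                else "Ta_l0" if self.length_dependence
                else "Ta_10")
        return base + ("+sac" if self.sac_enabled else "-sac")


@dataclass(frozen=True)
class LandParams:
    """Cross-bridge and troponin parameters (rates in 1/ms, tension in kPa,
    calcium in mM). Defaults are the cited model's human values; ``Tref`` is
    retuned at the organ level."""

    Tref: float = 120.0          # kPa, maximal active tension at resting length
    rs: float = 0.25             # steady-state duty ratio
    rw: float = 0.5
    k_uw: float = 0.182
    k_ws: float = 0.012
    k_u: float = 0.04
    n_Tm: float = 2.4
    Trpn50: float = 0.35
    k_TRPN: float = 0.1
    n_TRPN: float = 2.0
    Ca50_ref: float = 8.05e-4    # mM ([Ca]T50ref)
    beta0: float = 2.3
    beta1: float = -2.4e-3       # mM per unit stretch (negative: sensitization)
    gamma_s: float = 0.0085
    gamma_w: float = 0.615
    phi: float = 2.23
    Tot_A: float = 25.0

    def __post_init__(self) -> None:
        for name in ("Tref", "rs", "rw", "k_uw", "k_ws", "k_u", "k_TRPN",
                     "phi", "Ca50_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_TRPN < 1:
            raise ValueError("n_TRPN must be >= 1")
        if self.beta0 < 0:
            raise ValueError("beta0 must be >= 0")

    # derived transition rates of the three-state scheme
    @property
    def k_wu(self) -> float:
        return self.k_uw * (1.0 / self.rw - 1.0) - self.k_ws

    @property
    def k_su(self) -> float:
        return self.k_ws * self.rw * (1.0 / self.rs - 1.0)

    @property
    def A_eff(self) -> float:
        """Velocity-dependence coefficient (same for both distortions)."""
        return self.Tot_A * self.rs / ((1.0 - self.rs) * self.rw + self.rs)

    @property
    def c_w(self) -> float:
        return self.phi * self.k_uw * ((1.0 - self.rs) * (1.0 - self.rw)) / (
            (1.0 - self.rs) * self.rw)

    @property
    def c_s(self) -> float:
        return self.phi * self.k_ws * ((1.0 - self.rs) * self.rw) / self.rs

    @property
    def k_b(self) -> float:
        return self.k_u * self.Trpn50 ** self.n_Tm / (
            1.0 - self.rs - (1.0 - self.rs) * self.rw)


@dataclass
class LandState:
    S: float = 0.0
    W: float = 0.0
    B: float = 1.0
    CaTRPN: float = 1e-4
    zeta_s: float = 0.0
    zeta_w: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("S", "W", "B", "CaTRPN"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.S + self.W + self.B > 1.0 + 1e-9:
            raise ValueError("S + W + B must not exceed 1")

    def to_array(self) -> np.ndarray:
        return np.array([self.S, self.W, self.B, self.CaTRPN,
                         self.zeta_s, self.zeta_w])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "LandState":
        return cls(*[float(v) for v in y])


def length_factor(lam, beta0: float):
    """Length-dependent tension factor h(lambda) with both clamps and floor:
    h = max(0, 1 + beta0*(min(lam,1.2) + min(min(lam,1.2),0.87) - 1.87))."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch ratio must be > 0")
    lc = np.minimum(lam, 1.2)
    h = 1.0 + beta0 * (lc + np.minimum(lc, 0.87) - 1.87)
    out = np.maximum(0.0, h)
    return float(out) if out.ndim == 0 else out


def ca50(lam, beta1: float, Ca50_ref: float):
    """Half-activation calcium (same units as Ca50_ref), with the 1.2 clamp."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch ratio must be > 0")
    out = Ca50_ref + beta1 * (np.minimum(lam, 1.2) - 1.0)
    return float(out) if out.ndim == 0 else out


def _effective(params: LandParams, toggles: MEFToggles):
    a_eff = params.A_eff if toggles.velocity_dependence else 0.0
    b0 = params.beta0 if toggles.length_dependence else 0.0
    b1 = params.beta1 if toggles.length_dependence else 0.0
    return a_eff, b0, b1


def land_rhs(y: np.ndarray, lam, lam_dot, cai, params: LandParams,
             toggles: MEFToggles) -> np.ndarray:
    """Vectorized derivative of the 6-state tension model.

    ``y`` has shape (..., 6); ``lam``, ``lam_dot``, ``cai`` broadcast against
    the leading dimensions.
    """
    a_eff, _, b1 = _effective(params, toggles)
    S, W, B, catrpn, zs, zw = (y[..., i] for i in range(N_LAND))
    U = 1.0 - B - S - W
    catrpn = np.clip(catrpn, 1e-8, 1.0)

    gamma_su = params.gamma_s * np.where(
        zs > 0.0, zs, np.where(zs < -1.0, -zs - 1.0, 0.0))
    gamma_wu = params.gamma_w * np.abs(zw)

    dS = params.k_ws * W - params.k_su * S - gamma_su * S
    dW = params.k_uw * U - params.k_wu * W - params.k_ws * W - gamma_wu * W

    ca50v = params.Ca50_ref + b1 * (np.minimum(lam, 1.2) - 1.0)
    dcatrpn = params.k_TRPN * (
        (cai / ca50v) ** params.n_TRPN * (1.0 - catrpn) - catrpn)

    half = params.n_Tm / 2.0
    dB = (params.k_b * U * np.minimum(catrpn ** (-half), 100.0)
          - params.k_u * catrpn ** half * B)

    dzs = a_eff * lam_dot - params.c_s * zs
    dzw = a_eff * lam_dot - params.c_w * zw
    return np.stack([dS, dW, dB, dcatrpn, dzs, dzw], axis=-1)


def land_derivatives(state: LandState, lam: float, lam_dot: float, cai: float,
                     params: LandParams,
                     toggles: Optional[MEFToggles] = None) -> LandState:
    """Scalar-API derivative; returns a LandState-shaped derivative record."""
    if toggles is None:
        toggles = MEFToggles()
    vals = [lam, lam_dot, cai, state.S, state.W, state.B, state.CaTRPN,
            state.zeta_s, state.zeta_w]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite tension-model input")
    if cai <= 0:
        raise ValueError("Cai must be > 0")
    dy = land_rhs(state.to_array(), lam, lam_dot, cai, params, toggles)
    out = LandState.__new__(LandState)  # derivative record: skip validation
    out.S, out.W, out.B, out.CaTRPN, out.zeta_s, out.zeta_w = (
        float(v) for v in dy)
    return out


def land_step(y: np.ndarray, lam, lam_dot, cai, params: LandParams,
              toggles: MEFToggles, dt: float) -> np.ndarray:
    """One explicit substep; distortions use the exact exponential update of
    their linear ODE, fractions are clipped to [0, 1]."""
    a_eff, _, _ = _effective(params, toggles)
    dy = land_rhs(y, lam, lam_dot, cai, params, toggles)
    out = y + dt * dy
    # exact update for d zeta/dt = a - c zeta
    for idx, c in ((L_ZS, params.c_s), (L_ZW, params.c_w)):
        zinf = a_eff * np.asarray(lam_dot) / c
        out[..., idx] = zinf + (y[..., idx] - zinf) * np.exp(-c * dt)
    out[..., L_S:L_CATRPN + 1] = np.clip(out[..., L_S:L_CATRPN + 1], 0.0, 1.0)
    return out


def active_tension(state, lam, params: LandParams,
                   toggles: Optional[MEFToggles] = None):
    """Active tension Ta (kPa) = h(lambda) * Tref/rs * ((zeta_s+1) S + zeta_w W),
    floored at zero. ``state`` may be a LandState or an (..., 6) array."""
    if toggles is None:
        toggles = MEFToggles()
    _, b0, _ = _effective(params, toggles)
    y = state.to_array() if isinstance(state, LandState) else np.asarray(state)
    h = length_factor(lam, b0)
    ta = h * (params.Tref / params.rs) * (
        (y[..., L_ZS] + 1.0) * y[..., L_S] + y[..., L_ZW] * y[..., L_W])
    out = np.maximum(0.0, ta)
    return float(out) if np.ndim(out) == 0 else out


def tension_scalar(y: np.ndarray, params: LandParams) -> np.ndarray:
    """Length-independent part Tref/rs * ((zeta_s+1) S + zeta_w W) (kPa);
    multiplied by h(lambda) inside the wall equilibrium solve."""
    return (params.Tref / params.rs) * (
        (y[..., L_ZS] + 1.0) * y[..., L_S] + y[..., L_ZW] * y[..., L_W])


def land_steady_state(cai: float, lam: float, params: LandParams,
                      toggles: Optional[MEFToggles] = None) -> LandState:
    """Resting fixed point at constant calcium and stretch (zero velocity),
    with negligible cross-bridge occupancy (diastolic initialization)."""
    if toggles is None:
        toggles = MEFToggles()
    _, _, b1 = _effective(params, toggles)
    ca50v = params.Ca50_ref + b1 * (min(lam, 1.2) - 1.0)
    r = (cai / ca50v) ** params.n_TRPN
    catrpn = max(r / (1.0 + r), 1e-8)
    half = params.n_Tm / 2.0
    q = (params.k_b * min(catrpn ** (-half), 100.0)
         / (params.k_u * catrpn ** half))
    B = q / (1.0 + q)
    return LandState(S=0.0, W=0.0, B=B, CaTRPN=catrpn, zeta_s=0.0, zeta_w=0.0)


@dataclass
class TwitchResult:
    times: np.ndarray
    tension: np.ndarray
    peak: float
    time_to_peak: float
    state: LandState


def isometric_twitch(params: LandParams, toggles: MEFToggles,
                     times: np.ndarray, cai: np.ndarray,
                     lam: float = 1.0) -> TwitchResult:
    """Integrate one twitch at fixed length (lambda_dot = 0) under the given
    calcium transient; returns the tension trace with peak markers."""
    times = np.asarray(times, dtype=float)
    cai = np.asarray(cai, dtype=float)
    if times.shape != cai.shape or times.size < 2:
        raise ValueError("times and cai must be equal-length (>= 2) series")
    y = land_steady_state(float(cai[0]), lam, params, toggles).to_array()
    ta = np.empty_like(times)
    ta[0] = active_tension(y, lam, params, toggles)
    for i in range(1, times.size):
        dt_i = times[i] - times[i - 1]
        n_sub = max(1, int(round(dt_i / TENSION_DT)))
        h = dt_i / n_sub
        for _ in range(n_sub):
            y = land_step(y, lam, 0.0, cai[i], params, toggles, h)
        ta[i] = active_tension(y, lam, params, toggles)
    ipk = int(np.argmax(ta))
    return TwitchResult(times, ta, float(ta[ipk]), float(times[ipk]),
                        LandState.from_array(y))
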