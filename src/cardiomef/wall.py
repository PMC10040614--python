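"""Passive fiber stress and the multi-patch thin-wall ventricle surrogate.

Passive stress is the fiber-axis reduction of an orthotropic exponential
(Fung-type) strain energy under incompressible uniaxial kinematics
(transverse stretch lambda^(-1/2), zero shear, zero transverse traction).

Each ventricle is an independent thin-wall sphere tiled by patches. A cavity
volume V determines the midwall area A_m (midwall enclosed volume = cavity
volume + half the wall volume); the patch areas {A_i} partition A_m such
that the membrane tension T_i = sigma_i(lambda_i) * h_i is equal across
patches (sigma = passive + active Cauchy fiber stress, h_i = V_wall_i / A_i
the incompressible wall thickness, lambda_i = sqrt(A_i / A_ref_i) the
in-plane fiber stretch). The cavity pressure follows Laplace's law
P = 2 T / r. This is the desk-scale stand-in for a 3D FEM wall: it keeps
per-region stretch/tension heterogeneity but has no direct LV-RV coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernel as K
from . import tension as tn
from .ionic import CellParams
from .sac import SACParams

__all__ = [
    "PassiveParams",
    "Patch",
    "Ventricle0D",
    "SolverError",
    "passive_fiber_stress",
    "patch_equilibrium",
    "cavity_pressure",
    "advance_wall",
    "KPA_TO_MMHG",
    "MECH_DT",
]

KPA_TO_MMHG = 7.50062
MECH_DT = 1.0  # ms, mechanics/circulation step


class SolverError(RuntimeError):
    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class PassiveParams:
    """Exponential orthotropic material, fiber-axis reduction.

    ``C`` (kPa) scales the energy; the ``b_*`` exponents weight the squared
    Green-Lagrange strains. Shear terms never enter the uniaxial reduction
    but are kept for configuration completeness, as is the (inactive)
    incompressibility factor ``k_incomp`` (J = 1 is enforced kinematically).
    """

    C: float = 0.88
    b_ff: float = 8.0
    b_ss: float = 6.0
    b_nn: float = 6.0
    b_fs: float = 12.0
    b_fn: float = 3.0
    b_sn: float = 3.0
    k_incomp: float = 50.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if min(self.b_ff, self.b_ss, self.b_nn,
               self.b_fs, self.b_fn, self.b_sn) < 0:
            raise ValueError("exponent coefficients must be >= 0")
        if self.k_incomp <= 0:
            raise ValueError("k_incomp must be > 0")


def passive_energy_uniaxial(lam, params: PassiveParams):
    """Strain energy Psi (kPa) along the incompressible uniaxial path."""
    lam = np.asarray(lam, dtype=float)
    e_ff = 0.5 * (lam ** 2 - 1.0)
    e_tt = 0.5 * (1.0 / lam - 1.0)
    q = params.b_ff * e_ff ** 2 + (params.b_ss + params.b_nn) * e_tt ** 2
    return 0.5 * params.C * (np.exp(q) - 1.0)


def passive_fiber_stress(lam, params: PassiveParams):
    """Cauchy fiber stress (kPa) at stretch ``lam`` (analytic derivative
    sigma = lambda * dPsi/dlambda; zero at the reference state)."""
    lam_a = np.asarray(lam, dtype=float)
    if np.any(lam_a <= 0.5) or np.any(lam_a >= 2.0):
        raise ValueError("stretch outside the admissible range (0.5, 2)")
    e_ff = 0.5 * (lam_a ** 2 - 1.0)
    e_tt = 0.5 * (1.0 / lam_a - 1.0)
    btt = params.b_ss + params.b_nn
    q = params.b_ff * e_ff ** 2 + btt * e_tt ** 2
    dq = 2.0 * params.b_ff * e_ff * lam_a - btt * e_tt / lam_a ** 2
    out = lam_a * 0.5 * params.C * np.exp(q) * dq
    return float(out) if out.ndim == 0 else out


@dataclass
class Patch:
    """One wall region of the thin-wall surrogate."""

    pid: int
    wall: str                    # "lv-free" | "septum" | "rv-free"
    A_ref: float                 # cm^2, reference midwall area
    V_wall: float                # mL, wall volume
    t_act: float                 # ms, activation time within the beat
    lam: float = 1.0
    lam_dot: float = 0.0

    def __post_init__(self) -> None:
        if self.A_ref <= 0 or self.V_wall <= 0:
            raise ValueError("A_ref and V_wall must be > 0")
        if self.wall not in ("lv-free", "septum", "rv-free"):
            raise ValueError(f"unknown wall assignment {self.wall!r}")
        if self.lam <= 0:
            raise ValueError("stretch must be > 0")


class Ventricle0D:
    """Thin-wall spherical ventricle made of tension-equilibrated patches.

    Holds the per-patch electrophysiological and tension states as arrays
    for vectorized stepping; ``patches`` carries the static description.
    """

    def __init__(self, name: str, patches: list[Patch],
                 passive: PassiveParams, land: tn.LandParams,
                 toggles: tn.MEFToggles, cell: CellParams,
                 sac: SACParams, cell_state0: np.ndarray,
                 V0: float = 0.0, tension_transmission: float = 0.5):
        if not patches:
            raise ValueError("a ventricle needs at least one patch")
        self.name = name
        self.patches = patches
        self.passive = passive
        self.land = land
        self.toggles = toggles
        self.cell = cell
        self.sac = sac
        self.V0 = float(V0)
        # fraction of fiber Cauchy stress transmitted into each in-plane
        # membrane direction: 0.5 for fibers isotropically dispersed in-plane
        # (a single aligned fiber family would give 1). Keeps cavity pressure
        # consistent with physiological fiber-stress magnitudes.
        self.tension_transmission = float(tension_transmission)
        # viscous fiber stress eta * d(lambda)/dt (kPa*ms = Pa*s): physical
        # tissue viscosity; also damps inter-patch area redistribution in
        # configurations with the velocity dependence ablated, where the
        # cross-bridge distortions no longer stabilize the partition
        self.viscosity = 800.0
        n = len(patches)
        self.A_ref = np.array([p.A_ref for p in patches])
        self.V_wall = np.array([p.V_wall for p in patches])
        self.t_act = np.array([p.t_act for p in patches])
        self.lam = np.ones(n)
        self.lam_dot = np.zeros(n)
        self.A = self.A_ref.copy()
        self.cell_states = np.tile(np.asarray(cell_state0, dtype=float), (n, 1))
        cai0 = float(self.cell_states[0, K.S_CAI])
        self.land_states = np.tile(
            tn.land_steady_state(cai0, 1.0, land, toggles).to_array(), (n, 1))
        self._cell_p = cell.to_array()
        self.tau = 0.0           # common membrane tension, kPa*cm
        self.P = 0.0             # cavity pressure, mmHg
        self.dPdV = 0.0          # mmHg/mL, from the last equilibrium solve
        self.V = float(np.sum(self.A_ref) / (4.0 * np.pi))  # placeholder

    # -- geometry ---------------------------------------------------------
    @property
    def n_patches(self) -> int:
        return len(self.patches)

    @property
    def wall_volume(self) -> float:
        return float(self.V_wall.sum())

    def midwall_radius(self, V: float) -> float:
        vm = V + 0.5 * self.wall_volume
        return (3.0 * vm / (4.0 * np.pi)) ** (1.0 / 3.0)

    def midwall_area(self, V: float) -> float:
        return 4.0 * np.pi * self.midwall_radius(V) ** 2

    # -- mechanics --------------------------------------------------------
    def tension_scalars(self) -> np.ndarray:
        """Length-independent active tension per patch (kPa)."""
        return tn.tension_scalar(self.land_states, self.land)

    def _sigma(self, lam: np.ndarray, ta_scalar: np.ndarray) -> np.ndarray:
        # clipped evaluation: Newton iterates may transiently overshoot the
        # admissible stretch band; the converged solution is bounds-checked
        lam = np.clip(lam, 0.55, 1.9)
        b0 = self.land.beta0 if self.toggles.length_dependence else 0.0
        h = tn.length_factor(lam, b0)
        return passive_fiber_stress(lam, self.passive) + np.maximum(
            0.0, h * ta_scalar)

    def _make_sigma_dyn(self, dt_visc: Optional[float]):
        """Velocity-consistent total-stress evaluator sigma(lam).

        The cross-bridge distortions are advanced to their end-of-step values
        implied by the trial stretch rate (exact exponential update of their
        linear ODEs), so the equilibrium solve sees the same velocity
        feedback the tension substeps will apply. This makes shortening
        velocity act as an in-step stabilizer of the area partition (it is
        also what physically damps inter-patch redistribution). A small
        viscous fiber stress eta*d(lambda)/dt covers configurations with the
        velocity dependence ablated.
        """
        ls = self.land_states
        S_, W_ = ls[:, tn.L_S], ls[:, tn.L_W]
        zs, zw = ls[:, tn.L_ZS], ls[:, tn.L_ZW]
        p = self.land
        lam_prev = self.lam
        vel_on = self.toggles.velocity_dependence and dt_visc is not None
        visc = self.viscosity / dt_visc if dt_visc else 0.0
        if vel_on:
            es = np.exp(-p.c_s * dt_visc)
            ew = np.exp(-p.c_w * dt_visc)

        def sigma(lam: np.ndarray) -> np.ndarray:
            if vel_on:
                ld = (lam - lam_prev) / dt_visc
                zse = zs * es + (p.A_eff * ld / p.c_s) * (1.0 - es)
                zwe = zw * ew + (p.A_eff * ld / p.c_w) * (1.0 - ew)
            else:
                zse, zwe = zs, zw
            scalar = (p.Tref / p.rs) * ((zse + 1.0) * S_ + zwe * W_)
            return (self._sigma(lam, scalar)
                    + visc * (lam - lam_prev))

        return sigma

    def equilibrium(self, V: float, *, update: bool = False,
                    tol: float = 1e-10, max_iter: int = 50,
                    dt_visc: Optional[float] = MECH_DT):
        """Solve the equal-tension area partition at cavity volume ``V``.

        Returns (lam, tau, P_mmHg, dPdV). With ``update=True`` the solution
        is stored on the ventricle (areas, stretches, pressure). The viscous
        fiber stress uses the stretch change from the stored state over
        ``dt_visc``; ``dt_visc=None`` solves the purely static problem.
        """
        if V <= self.V0:
            raise ValueError(f"cavity volume {V} must exceed dead volume {self.V0}")
        r = self.midwall_radius(V)
        A_m = 4.0 * np.pi * r ** 2
        sigma_dyn = self._make_sigma_dyn(dt_visc)
        n = self.n_patches
        A = self.A.copy() * (A_m / self.A.sum())
        tau = float(self.tau)
        scale = max(abs(tau), 1e-2)
        ok = False
        k_t = self.tension_transmission
        for it in range(max_iter):
            lam = np.sqrt(A / self.A_ref)
            T = k_t * sigma_dyn(lam) * self.V_wall / A
            F = T - tau
            res_area = abs(A.sum() - A_m) / A_m
            scale = max(abs(tau), float(np.abs(T).max()), 1e-2)
            if np.abs(F).max() / scale < tol and res_area < 1e-12:
                ok = True
                break
            # dT/dA by relative finite difference (robust across h-clamps)
            dA = 1e-7 * A
            lam2 = np.sqrt((A + dA) / self.A_ref)
            T2 = k_t * sigma_dyn(lam2) * self.V_wall / (A + dA)
            dTdA = (T2 - T) / dA
            dTdA = np.where(np.abs(dTdA) < 1e-12, 1e-12, dTdA)
            # solve the arrowhead system: dTdA_i * delta_i - d tau = -F_i,
            # sum delta_i = A_m - sum A_i
            inv = 1.0 / dTdA
            dtau = (A_m - A.sum() + np.sum(F * inv)) / np.sum(inv)
            delta = (dtau - F) * inv
            # damped update keeping areas positive and steps bounded
            step = 1.0
            lim = np.max(np.abs(delta) / (0.3 * A))
            if lim > 1.0:
                step = 1.0 / lim
            while np.any(A + step * delta <= 0.2 * A) and step > 1e-4:
                step *= 0.5
            A = A + step * delta
            tau = tau + step * dtau
        if not ok:
            raise SolverError(
                f"{self.name}: patch equilibrium did not converge in "
                f"{max_iter} iterations (residual {np.abs(F).max() / scale:.2e})",
                residual=float(np.abs(F).max() / scale))
        if lam.min() <= 0.55 or lam.max() >= 1.9:
            raise SolverError(
                f"{self.name}: converged patch stretch outside the admissible "
                f"band: [{lam.min():.3f}, {lam.max():.3f}]")
        P = 2.0 * tau / r * KPA_TO_MMHG
        dtau_dAm = 1.0 / np.sum(1.0 / dTdA) if it > 0 else 0.0
        if it == 0:  # converged immediately; recompute sensitivity
            dA = 1e-7 * A
            lam2 = np.sqrt((A + dA) / self.A_ref)
            T2 = k_t * sigma_dyn(lam2) * self.V_wall / (A + dA)
            dTdA = (T2 - T) / dA
            dTdA = np.where(np.abs(dTdA) < 1e-12, 1e-12, dTdA)
            dtau_dAm = 1.0 / np.sum(1.0 / dTdA)
        vm = V + 0.5 * self.wall_volume
        dr_dV = r / (3.0 * vm)
        dA_dV = 2.0 * A.sum() / (3.0 * vm)
        dPdV = (2.0 * dtau_dAm * dA_dV / r
                - 2.0 * tau / r ** 2 * dr_dV) * KPA_TO_MMHG
        if update:
            self.A = A
            self.tau = tau
            self.P = P
            self.dPdV = dPdV
            self.V = V
        return lam, tau, P, dPdV

    # -- coupled update ---------------------------------------------------
    def advance(self, V_new: float, t: float, dt: float = MECH_DT,
                stim_amp: float = -26.0, stim_dur: float = 2.0) -> float:
        """Advance the wall one mechanics step to cavity volume ``V_new``.

        Order (staggered coupling): equilibrium solve -> lambda, lambda_dot
        (backward difference) -> SAC current + stimulus injected into each
        patch's myocyte -> EP substeps -> tension ODE substeps at the new
        calcium -> pressure for the next step. Returns P (mmHg).
        """
        prev_lam = self.lam.copy()
        lam, tau, P, dPdV = self.equilibrium(V_new, update=True, dt_visc=dt)
        self.lam = lam
        self.lam_dot = (lam - prev_lam) / dt

        # external currents: ohmic SAC + rectangular stimulus
        n = self.n_patches
        if self.sac.enabled and self.toggles.sac_enabled:
            g = self.sac.G / (1.0 + self.sac.K
                              * np.exp(-self.sac.alpha * (lam - 1.0)))
        else:
            g = np.zeros(n)
        a = -g * self.sac.E_SAC
        stim_on = (t >= self.t_act) & (t < self.t_act + stim_dur)
        a = a + np.where(stim_on, stim_amp, 0.0)

        # EP substeps (dt_ep), recording Cai every tension substep
        from .ionic import EP_DT
        n_ep = int(round(dt / EP_DT))
        rec_every = int(round(tn.TENSION_DT / EP_DT))
        n_rec = n_ep // rec_every
        rec_v = np.empty((n_rec, n))
        rec_cai = np.empty((n_rec, n))
        K.advance(self.cell_states, self._cell_p, EP_DT, n_ep, a, g,
                  rec_every, rec_v, rec_cai)

        # tension substeps at the new stretch / stretch rate
        y = self.land_states
        for k in range(n_rec):
            y = tn.land_step(y, lam, self.lam_dot, rec_cai[k], self.land,
                             self.toggles, tn.TENSION_DT)
        self.land_states = y
        return P

    # -- observables ------------------------------------------------------
    def vm(self) -> np.ndarray:
        return self.cell_states[:, K.S_V].copy()

    def cai(self) -> np.ndarray:
        return self.cell_states[:, K.S_CAI].copy()

    def active_tension_now(self) -> np.ndarray:
        return tn.active_tension(self.land_states, self.lam, self.land,
                                 self.toggles)


# ---------------------------------------------------------------- module API
def patch_equilibrium(ventricle: Ventricle0D, V: float):
    """Per-patch stretches and the common membrane tension at volume ``V``
    (static solve: no viscous or velocity contribution)."""
    lam, tau, _, _ = ventricle.equilibrium(V, dt_visc=None)
    return lam, tau


def cavity_pressure(ventricle: Ventricle0D, V: float, T_m: float) -> float:
    """Laplace pressure P = 2 T_m / r (T_m in kPa*cm, r from V), in mmHg."""
    if V <= ventricle.V0:
        raise ValueError("V must exceed the dead volume")
    return 2.0 * T_m / ventricle.midwall_radius(V) * KPA_TO_MMHG


def advance_wall(ventricle: Ventricle0D, V_new: float, t: float,
                 dt: float = MECH_DT, **kw) -> float:
    return ventricle.advance(V_new, t, dt, **kw)
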