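"""Low-level numerical kernel for the ventricular myocyte model.

The full ionic right-hand side and the Rush-Larsen stepping loop live here,
compiled with numba. State vectors are flat float64 arrays; the index layout
is shared with :mod:`cardiomef.ionic` through the ``S_*`` / ``P_*`` constants.

External (non-ionic) current is passed as an affine function of the membrane
potential, ``i_ext = a + b * Vm`` (A/F), which represents a rectangular
stimulus (``b = 0``) and/or an ohmic stretch-activated current
(``b = G_eff``, ``a -= G_eff * E_rev``) exactly, without re-evaluating the
stretch sigmoid inside the inner loop.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------- state layout
S_V = 0
S_M = 1
S_H = 2
S_J = 3
S_D = 4
S_F = 5
S_F2 = 6
S_FCASS = 7
S_R = 8
S_S = 9
S_XR1 = 10
S_XR2 = 11
S_XS = 12
S_RBAR = 13  # ryanodine-receptor adaptation variable (not HH-form)
S_CAI = 14
S_CASR = 15
S_CASS = 16
S_NAI = 17
S_KI = 18
N_STATE = 19

GATE_SLICE = slice(S_M, S_XS + 1)  # Hodgkin-Huxley gates, Rush-Larsen updated

# ---------------------------------------------------------------- param layout
P_GNA = 0
P_GK1 = 1
P_GTO = 2
P_GKR = 3
P_GKS = 4
P_GCAL = 5
P_GBNA = 6
P_GBCA = 7
P_GPCA = 8
P_GPK = 9
P_PNAK = 10
P_KNACA = 11
P_KO = 12
P_NAO = 13
P_CAO = 14
P_SENDO = 15  # 1.0 -> endocardial s-gate kinetics
P_CM = 16  # membrane capacitance (uF), scales concentration balances
N_PARAM = 17

# physical constants and cell geometry (fixed across cell types)
_RGAS = 8314.472
_TEMP = 310.0
_FARADAY = 96485.3415
_RTOF = _RGAS * _TEMP / _FARADAY
_VC = 0.016404
_VSR = 0.001094
_VSS = 0.00005468


@njit(cache=True)
def rhs(y, p, ext_a, ext_b, dy, xinf, xtau):
    """Full ionic right-hand side for one cell.

    Fills ``dy`` (d(state)/dt), and ``xinf``/``xtau`` (steady state and time
    constant for the 12 HH gates, indices S_M..S_XS) for Rush-Larsen updates.
    Returns the total membrane current (A/F) including the external term.
    """
    V = y[S_V]
    m = y[S_M]
    h = y[S_H]
    j = y[S_J]
    d = y[S_D]
    f = y[S_F]
    f2 = y[S_F2]
    fcass = y[S_FCASS]
    r = y[S_R]
    s = y[S_S]
    xr1 = y[S_XR1]
    xr2 = y[S_XR2]
    xs = y[S_XS]
    rbar = y[S_RBAR]
    cai = y[S_CAI]
    casr = y[S_CASR]
    cass = y[S_CASS]
    nai = y[S_NAI]
    ki = y[S_KI]

    ko = p[P_KO]
    nao = p[P_NAO]
    cao = p[P_CAO]
    cm = p[P_CM]

    ena = _RTOF * math.log(nao / nai)
    ek = _RTOF * math.log(ko / ki)
    eks = _RTOF * math.log((ko + 0.03 * nao) / (ki + 0.03 * nai))
    eca = 0.5 * _RTOF * math.log(cao / cai)

    # fast sodium current
    ina = p[P_GNA] * m * m * m * h * j * (V - ena)
    minf = 1.0 / (1.0 + math.exp((-56.86 - V) / 9.03))
    minf = minf * minf
    am = 1.0 / (1.0 + math.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + math.exp((V + 35.0) / 5.0)) + 0.1 / (
        1.0 + math.exp((V - 50.0) / 200.0)
    )
    xinf[S_M] = minf
    xtau[S_M] = am * bm

    hinf = 1.0 / (1.0 + math.exp((V + 71.55) / 7.43))
    hinf = hinf * hinf
    if V < -40.0:
        ah = 0.057 * math.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * V) + 310000.0 * math.exp(0.3485 * V)
    else:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp((V + 10.66) / -11.1)))
    xinf[S_H] = hinf
    xtau[S_H] = 1.0 / (ah + bh)

    if V < -40.0:
        aj = (
            (-25428.0 * math.exp(0.2444 * V) - 6.948e-6 * math.exp(-0.04391 * V))
            * (V + 37.78)
            / (1.0 + math.exp(0.311 * (V + 79.23)))
        )
        bj = 0.02424 * math.exp(-0.01052 * V) / (
            1.0 + math.exp(-0.1378 * (V + 40.14))
        )
    else:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    xinf[S_J] = hinf
    xtau[S_J] = 1.0 / (aj + bj)

    # L-type calcium current (GHK-like driving term, singularity handled)
    x = 2.0 * (V - 15.0) / _RTOF
    if abs(x) < 1e-5:
        drive = (0.25 * cass * (1.0 + x) - cao) * _RTOF * 0.5 * (1.0 - 0.5 * x)
    else:
        drive = (0.25 * cass * math.exp(x) - cao) * (V - 15.0) / (math.exp(x) - 1.0)
    # 4 F^2/(R T) = 4 F / _RTOF
    ical = p[P_GCAL] * d * f * f2 * fcass * 4.0 * (_FARADAY / _RTOF) * drive
    dinf = 1.0 / (1.0 + math.exp((-8.0 - V) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + math.exp((50.0 - V) / 20.0))
    xinf[S_D] = dinf
    xtau[S_D] = ad * bd + gd

    xinf[S_F] = 1.0 / (1.0 + math.exp((V + 20.0) / 7.0))
    xtau[S_F] = (
        1102.5 * math.exp(-((V + 27.0) ** 2) / 225.0)
        + 200.0 / (1.0 + math.exp((13.0 - V) / 10.0))
        + 180.0 / (1.0 + math.exp((V + 30.0) / 10.0))
        + 20.0
    )
    xinf[S_F2] = 0.67 / (1.0 + math.exp((V + 35.0) / 7.0)) + 0.33
    xtau[S_F2] = (
        562.0 * math.exp(-((V + 27.0) ** 2) / 240.0)
        + 31.0 / (1.0 + math.exp((25.0 - V) / 10.0))
        + 80.0 / (1.0 + math.exp((V + 30.0) / 10.0))
    )
    fc = 1.0 / (1.0 + (cass / 0.05) * (cass / 0.05))
    xinf[S_FCASS] = 0.6 * fc + 0.4
    xtau[S_FCASS] = 80.0 * fc + 2.0

    # transient outward current
    ito = p[P_GTO] * r * s * (V - ek)
    xinf[S_R] = 1.0 / (1.0 + math.exp((20.0 - V) / 6.0))
    xtau[S_R] = 9.5 * math.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8
    if p[P_SENDO] > 0.5:
        xinf[S_S] = 1.0 / (1.0 + math.exp((V + 28.0) / 5.0))
        xtau[S_S] = 1000.0 * math.exp(-((V + 67.0) ** 2) / 1000.0) + 8.0
    else:
        xinf[S_S] = 1.0 / (1.0 + math.exp((V + 20.0) / 5.0))
        xtau[S_S] = (
            85.0 * math.exp(-((V + 45.0) ** 2) / 320.0)
            + 5.0 / (1.0 + math.exp((V - 20.0) / 5.0))
            + 3.0
        )

    # rapid delayed rectifier
    ikr = p[P_GKR] * math.sqrt(ko / 5.4) * xr1 * xr2 * (V - ek)
    xinf[S_XR1] = 1.0 / (1.0 + math.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((V + 30.0) / 11.5))
    xtau[S_XR1] = axr1 * bxr1
    xinf[S_XR2] = 1.0 / (1.0 + math.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((V - 60.0) / 20.0))
    xtau[S_XR2] = axr2 * bxr2

    # slow delayed rectifier
    iks = p[P_GKS] * xs * xs * (V - eks)
    xinf[S_XS] = 1.0 / (1.0 + math.exp((-5.0 - V) / 14.0))
    axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((V - 35.0) / 15.0))
    xtau[S_XS] = axs * bxs + 80.0

    # inward rectifier
    ak1 = 0.1 / (1.0 + math.exp(0.06 * (V - ek - 200.0)))
    bk1 = (
        3.0 * math.exp(0.0002 * (V - ek + 100.0)) + math.exp(0.1 * (V - ek - 10.0))
    ) / (1.0 + math.exp(-0.5 * (V - ek)))
    ik1 = p[P_GK1] * math.sqrt(ko / 5.4) * ak1 / (ak1 + bk1) * (V - ek)

    # Na/Ca exchanger and Na/K pump
    evf = math.exp(0.35 * V / _RTOF)
    evf1 = math.exp((0.35 - 1.0) * V / _RTOF)
    inaca = (
        p[P_KNACA]
        * (evf * nai ** 3 * cao - evf1 * nao ** 3 * cai * 2.5)
        / (
            (87.5 ** 3 + nao ** 3)
            * (1.38 + cao)
            * (1.0 + 0.1 * evf1)
        )
    )
    inak = (
        p[P_PNAK]
        * ko
        * nai
        / (
            (ko + 1.0)
            * (nai + 40.0)
            * (1.0 + 0.1245 * math.exp(-0.1 * V / _RTOF) + 0.0353 * math.exp(-V / _RTOF))
        )
    )

    ipca = p[P_GPCA] * cai / (cai + 0.0005)
    ipk = p[P_GPK] * (V - ek) / (1.0 + math.exp((25.0 - V) / 5.98))
    ibna = p[P_GBNA] * (V - ena)
    ibca = p[P_GBCA] * (V - eca)

    i_ext = ext_a + ext_b * V
    itot = (
        ik1 + ito + ikr + iks + ical + inak + ina + ibna + inaca + ibca + ipk + ipca
    )
    dy[S_V] = -(itot + i_ext)

    # SR calcium release (Shannon-type RyR with CaSR-dependent gain)
    kcasr = 2.5 - 1.5 / (1.0 + (1.5 / casr) * (1.5 / casr))
    k1 = 0.15 / kcasr
    k2 = 0.045 * kcasr
    o_rel = k1 * cass * cass * rbar / (0.06 + k1 * cass * cass)
    dy[S_RBAR] = -k2 * cass * rbar + 0.005 * (1.0 - rbar)
    irel = 0.102 * o_rel * (casr - cass)
    iup = 0.006375 / (1.0 + (0.00025 / cai) * (0.00025 / cai))
    ileak = 0.00036 * (casr - cai)
    ixfer = 0.0038 * (cass - cai)

    bufc = 1.0 / (1.0 + 0.2 * 0.001 / ((cai + 0.001) * (cai + 0.001)))
    dy[S_CAI] = bufc * (
        (ileak - iup) * _VSR / _VC
        + ixfer
        - (ibca + ipca - 2.0 * inaca) * cm / (2.0 * _VC * _FARADAY)
    )
    bufsr = 1.0 / (1.0 + 10.0 * 0.3 / ((casr + 0.3) * (casr + 0.3)))
    dy[S_CASR] = bufsr * (iup - irel - ileak)
    bufss = 1.0 / (1.0 + 0.4 * 0.00025 / ((cass + 0.00025) * (cass + 0.00025)))
    dy[S_CASS] = bufss * (
        -ical * cm / (2.0 * _VSS * _FARADAY)
        + irel * _VSR / _VSS
        - ixfer * _VC / _VSS
    )

    dy[S_NAI] = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * cm / (_VC * _FARADAY)
    # external current carried on the potassium balance (charge conservation,
    # same convention as the published model's stimulus handling)
    dy[S_KI] = -(ik1 + ito + ikr + iks - 2.0 * inak + ipk + i_ext) * cm / (
        _VC * _FARADAY
    )

    # gate derivatives in HH form (also used by the derivative API)
    for g in range(S_M, S_XS + 1):
        dy[g] = (xinf[g] - y[g]) / xtau[g]

    return itot + i_ext


@njit(cache=True)
def advance(states, p, dt, n_steps, ext_a, ext_b, rec_every, rec_v, rec_cai):
    """Advance all cells ``n_steps`` of size ``dt`` (Rush-Larsen / Euler).

    ``states``: (n_cells, N_STATE), modified in place.
    ``ext_a``, ``ext_b``: per-cell affine external current, constant over the call.
    If ``rec_every > 0``, Vm and Cai are recorded every ``rec_every`` steps
    (starting after that many steps) into ``rec_v``/``rec_cai``.
    """
    n_cells = states.shape[0]
    dy = np.empty(N_STATE)
    xinf = np.empty(N_STATE)
    xtau = np.empty(N_STATE)
    k = 0
    for step in range(n_steps):
        for c in range(n_cells):
            y = states[c]
            rhs(y, p, ext_a[c], ext_b[c], dy, xinf, xtau)
            y[S_V] += dt * dy[S_V]
            for g in range(S_M, S_XS + 1):
                # exponential (saturation-safe) gate update
                y[g] = xinf[g] + (y[g] - xinf[g]) * math.exp(-dt / xtau[g])
            y[S_RBAR] += dt * dy[S_RBAR]
            for i in range(S_CAI, N_STATE):
                y[i] += dt * dy[i]
        if rec_every > 0 and (step + 1) % rec_every == 0:
            for c in range(n_cells):
                rec_v[k, c] = states[c, S_V]
                rec_cai[k, c] = states[c, S_CAI]
            k += 1
    return k
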