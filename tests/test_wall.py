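"""Passive material and the multi-patch thin-wall equilibrium solver."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import brentq

from cardiomef.ionic import CellParams
from cardiomef.sac import SACParams
from cardiomef.tension import LandParams, MEFToggles
from cardiomef.wall import (KPA_TO_MMHG, PassiveParams, Patch, SolverError,
                            Ventricle0D, cavity_pressure,
                            passive_energy_uniaxial, passive_fiber_stress,
                            patch_equilibrium)

PAS = PassiveParams(C=0.88, b_ff=8.0, b_ss=6.0, b_nn=6.0)


def make_vent(paced, patches, passive=PAS, k_t=1.0, toggles=None):
    return Ventricle0D(
        "LV", patches, passive, LandParams(), toggles or MEFToggles(),
        CellParams.for_cell_type("epi"), SACParams(enabled=False),
        paced.state.y, tension_transmission=k_t)


class TestPassiveStress:
    def test_reference_state_is_stress_free(self):
        assert passive_fiber_stress(1.0, PAS) == pytest.approx(0.0, abs=1e-14)

    def test_monotone_in_tension_range(self):
        s11 = passive_fiber_stress(1.1, PAS)
        s12 = passive_fiber_stress(1.2, PAS)
        assert s12 > s11 > 0.0

    def test_matches_energy_finite_difference(self):
        """sigma = lambda dPsi/dlambda along the uniaxial path."""
        for lam in (0.9, 1.05, 1.1, 1.3):
            h = 1e-6
            dpsi = (passive_energy_uniaxial(lam + h, PAS)
                    - passive_energy_uniaxial(lam - h, PAS)) / (2 * h)
            assert passive_fiber_stress(lam, PAS) == pytest.approx(
                lam * dpsi, rel=1e-6)

    def test_range_guard(self):
        with pytest.raises(ValueError):
            passive_fiber_stress(0.4, PAS)
        with pytest.raises(ValueError):
            passive_fiber_stress(2.5, PAS)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            PassiveParams(C=0.0)
        with pytest.raises(ValueError):
            PassiveParams(b_ff=-1.0)


class TestEquilibrium:
    def test_identical_patches_share_stretch(self, paced):
        patches = [Patch(i, "lv-free", A_ref=25.0, V_wall=20.0, t_act=130.0)
                   for i in range(4)]
        v = make_vent(paced, patches)
        lam, tau = patch_equilibrium(v, 60.0)
        expected = np.sqrt(v.midwall_area(60.0) / 100.0)
        np.testing.assert_allclose(lam, expected, rtol=1e-10)

    def test_two_patch_solution_matches_scalar_root_finder(self, paced):
        """Independent oracle: reduce the 2-patch partition to a scalar
        root-finding problem in the first patch area."""
        patches = [Patch(0, "lv-free", A_ref=50.0, V_wall=40.0, t_act=130.0),
                   Patch(1, "lv-free", A_ref=55.0, V_wall=40.0, t_act=130.0)]
        v = make_vent(paced, patches)
        V = 55.0
        A_m = v.midwall_area(V)

        def tension(A, pid):
            lam = np.sqrt(A / patches[pid].A_ref)
            return (passive_fiber_stress(lam, PAS)
                    * patches[pid].V_wall / A)

        f = lambda a1: tension(a1, 0) - tension(A_m - a1, 1)
        # bracket restricted so both stretches stay in the admissible band
        lo = 0.6 ** 2 * 50.0
        hi = A_m - 0.6 ** 2 * 55.0
        a1 = brentq(f, lo, hi, xtol=1e-13, rtol=1e-15)
        lam, tau = patch_equilibrium(v, V)
        assert lam[0] == pytest.approx(np.sqrt(a1 / 50.0), rel=1e-8)
        assert lam[1] == pytest.approx(np.sqrt((A_m - a1) / 55.0), rel=1e-8)

    def test_thicker_patch_is_stretched_less(self, paced):
        patches = [Patch(0, "lv-free", A_ref=50.0, V_wall=30.0, t_act=130.0),
                   Patch(1, "lv-free", A_ref=50.0, V_wall=60.0, t_act=130.0)]
        v = make_vent(paced, patches)
        lam, _ = patch_equilibrium(v, 60.0)
        assert lam[1] < lam[0]

    def test_area_conservation_and_tension_equalization(self, paced):
        rng = np.random.default_rng(3)
        areas = 20.0 + 10.0 * rng.random(6)
        patches = [Patch(i, "lv-free", A_ref=float(a),
                         V_wall=float(0.8 * a), t_act=130.0)
                   for i, a in enumerate(areas)]
        v = make_vent(paced, patches)
        for V in (40.0, 55.0, 80.0):
            lam, tau, _, _ = v.equilibrium(V, dt_visc=None)
            A = lam ** 2 * v.A_ref
            assert abs(A.sum() - v.midwall_area(V)) / v.midwall_area(V) < 1e-12
            T = (v.tension_transmission
                 * passive_fiber_stress(lam, PAS) * v.V_wall / A)
            assert np.max(np.abs(T - tau)) / max(abs(tau), 1e-9) < 1e-8

    def test_single_patch_equals_closed_form_sphere(self, paced):
        p = [Patch(0, "lv-free", A_ref=90.0, V_wall=80.0, t_act=130.0)]
        v = make_vent(paced, p, k_t=0.5)
        V = 58.0
        lam, tau, P, _ = v.equilibrium(V, dt_visc=None)
        r = v.midwall_radius(V)
        A_m = v.midwall_area(V)
        lam_ref = np.sqrt(A_m / 90.0)
        sigma = passive_fiber_stress(lam_ref, PAS)
        T = 0.5 * sigma * 80.0 / A_m
        assert lam[0] == pytest.approx(lam_ref, rel=1e-12)
        assert P == pytest.approx(2.0 * T / r * KPA_TO_MMHG, rel=1e-9)

    def test_volume_below_dead_volume_rejected(self, paced):
        p = [Patch(0, "lv-free", A_ref=90.0, V_wall=80.0, t_act=130.0)]
        v = make_vent(paced, p)
        with pytest.raises(ValueError):
            v.equilibrium(-1.0)


class TestCavityPressure:
    def test_zero_tension_gives_zero_pressure(self, paced):
        p = [Patch(0, "lv-free", A_ref=90.0, V_wall=80.0, t_act=130.0)]
        v = make_vent(paced, p)
        assert cavity_pressure(v, 50.0, 0.0) == 0.0

    def test_linearity_in_tension(self, paced):
        p = [Patch(0, "lv-free", A_ref=90.0, V_wall=80.0, t_act=130.0)]
        v = make_vent(paced, p)
        assert cavity_pressure(v, 50.0, 10.0) * 2 == pytest.approx(
            cavity_pressure(v, 50.0, 20.0))

    def test_hand_value_at_r2cm(self, paced):
        # wall volume 0 -> midwall radius = cavity radius; V for r = 2 cm
        p = [Patch(0, "lv-free", A_ref=90.0, V_wall=1e-9, t_act=130.0)]
        v = make_vent(paced, p)
        V = 4.0 / 3.0 * np.pi * 8.0
        # P = 2 * 30 kPa cm / 2 cm = 30 kPa = 225.02 mmHg
        assert cavity_pressure(v, V, 30.0) == pytest.approx(
            30.0 * KPA_TO_MMHG, rel=1e-9)


class TestAdvance:
    def test_symmetric_patches_stay_bitwise_identical(self, paced):
        patches = [Patch(i, "lv-free", A_ref=25.0, V_wall=20.0, t_act=30.0)
                   for i in range(4)]
        v = make_vent(paced, patches, k_t=0.4)
        v.equilibrium(60.0, update=True, dt_visc=None)
        v.lam = np.sqrt(v.A / v.A_ref)
        for i in range(80):
            v.advance(60.0, float(i), 1.0)
        for col in (v.cell_states, v.land_states):
            assert np.all(col == col[0])

    def test_isovolumetric_stretch_rate_vanishes(self, paced):
        patches = [Patch(i, "lv-free", A_ref=25.0 + i, V_wall=20.0,
                         t_act=1e9) for i in range(3)]
        v = make_vent(paced, patches, k_t=0.4)
        v.equilibrium(60.0, update=True, dt_visc=None)
        v.lam = np.sqrt(v.A / v.A_ref)
        v.advance(60.0, 0.0, 1.0)
        v.advance(60.0, 1.0, 1.0)
        assert np.max(np.abs(v.lam_dot)) < 1e-4


def test_patch_validation():
    with pytest.raises(ValueError):
        Patch(0, "lv-free", A_ref=-1.0, V_wall=1.0, t_act=0.0)
    with pytest.raises(ValueError):
        Patch(0, "outer-wall", A_ref=1.0, V_wall=1.0, t_act=0.0)
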