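"""Cross-bridge active-tension model: length factor, calcium sensitivity,
distortion dynamics, twitches and the MEF toggles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cardiomef import tension as tn
from cardiomef.drivers import CalciumTransientSpec, make_calcium
from cardiomef.tension import (LandParams, LandState, MEFToggles,
                               active_tension, ca50, isometric_twitch,
                               land_derivatives, land_step, land_steady_state,
                               length_factor)

P = LandParams()
ON = MEFToggles()


class TestLengthFactor:
    def test_unity_at_resting_length(self):
        for b0 in (0.0, 1.0, 2.3):
            assert length_factor(1.0, b0) == pytest.approx(1.0)

    def test_worked_value(self):
        assert length_factor(1.1, 2.0) == pytest.approx(1.2)

    def test_upper_clamp_and_floor(self):
        assert length_factor(1.3, 2.0) == length_factor(1.2, 2.0)
        assert length_factor(0.5, 2.0) == 0.0

    @given(st.floats(0.6, 1.4))
    def test_continuity_across_clamps(self, lam):
        eps = 1e-7
        a = length_factor(lam - eps, 2.3)
        b = length_factor(lam + eps, 2.3)
        assert abs(a - b) < 1e-5


class TestCa50:
    def test_reference_at_unit_stretch(self):
        assert ca50(1.0, -2.4e-3, 8.05e-4) == pytest.approx(8.05e-4)

    def test_worked_value_with_clamp(self):
        assert ca50(1.25, 1.5, 0.8) == pytest.approx(1.1)

    def test_no_length_dependence(self):
        for lam in (0.9, 1.0, 1.15):
            assert ca50(lam, 0.0, 0.8) == 0.8


class TestDerivatives:
    def test_distortion_decays_exponentially_without_velocity(self):
        s = LandState(zeta_s=0.5, zeta_w=-0.2)
        d = land_derivatives(s, 1.0, 0.0, 1e-4, P, ON)
        assert d.zeta_s == pytest.approx(-P.c_s * 0.5)
        assert d.zeta_w == pytest.approx(P.c_w * 0.2)

    def test_distortion_steady_state_under_constant_velocity(self):
        v = 2e-3
        y = LandState().to_array()
        for _ in range(4000):
            y = land_step(y, 1.0, v, 1e-4, P, ON, 0.1)
        assert y[tn.L_ZS] == pytest.approx(P.A_eff * v / P.c_s, rel=1e-6)
        assert y[tn.L_ZW] == pytest.approx(P.A_eff * v / P.c_w, rel=1e-6)

    def test_troponin_derivative_bounded(self):
        hi = LandState(CaTRPN=1.0)
        lo = LandState(CaTRPN=1e-8)
        assert land_derivatives(hi, 1.0, 0.0, 1e-3, P, ON).CaTRPN < 0
        assert land_derivatives(lo, 1.0, 0.0, 1e-3, P, ON).CaTRPN > 0

    def test_velocity_toggle_zeroes_distortion_drive(self):
        tog = MEFToggles(velocity_dependence=False)
        d = land_derivatives(LandState(), 1.0, 5e-3, 1e-4, P, tog)
        assert d.zeta_s == 0.0 and d.zeta_w == 0.0

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            land_derivatives(LandState(), np.nan, 0.0, 1e-4, P, ON)
        with pytest.raises(ValueError):
            land_derivatives(LandState(), 1.0, 0.0, -1e-4, P, ON)


class TestActiveTension:
    def test_zero_without_crossbridges(self):
        assert active_tension(LandState(S=0.0, W=0.0), 1.1, P, ON) == 0.0

    def test_distortion_free_reduction(self):
        s = LandState(S=0.3, W=0.0, B=0.5)
        expected = length_factor(1.05, P.beta0) * (P.Tref / P.rs) * 0.3
        assert active_tension(s, 1.05, P, ON) == pytest.approx(expected)

    def test_tref_override_is_configuration(self):
        import dataclasses
        p70 = dataclasses.replace(P, Tref=70.0)
        assert p70.Tref == 70.0
        s = LandState(S=0.3, B=0.5)
        tog = MEFToggles(velocity_dependence=False)
        assert active_tension(s, 1.0, p70, tog) == pytest.approx(
            70.0 / P.rs * 0.3)

    def test_nonnegative_and_length_toggle(self):
        s = LandState(S=0.2, W=0.1, B=0.5, zeta_s=-2.0, zeta_w=-3.0)
        assert active_tension(s, 1.1, P, ON) >= 0.0
        tog = MEFToggles(length_dependence=False)
        # with length dependence off, stretch does not enter
        assert active_tension(s, 0.8, P, tog) == active_tension(s, 1.2, P, tog)


class TestTwitch:
    def test_diastolic_calcium_gives_no_twitch(self):
        t = np.arange(0.0, 600.0, 1.0)
        cai = np.full_like(t, 1e-4)
        tw = isometric_twitch(P, ON, t, cai, lam=1.0)
        assert tw.peak < 0.01 * P.Tref

    def test_determinism(self, calcium_transient):
        t, cai = calcium_transient
        a = isometric_twitch(P, ON, t, cai, lam=1.0)
        b = isometric_twitch(P, ON, t, cai, lam=1.0)
        np.testing.assert_array_equal(a.tension, b.tension)

    def test_frank_starling_at_cell_level(self, calcium_transient):
        t, cai = calcium_transient
        pk10 = isometric_twitch(P, ON, t, cai, lam=1.0).peak
        pk11 = isometric_twitch(P, ON, t, cai, lam=1.1).peak
        assert pk11 > pk10

    def test_removing_velocity_dependence_raises_shortening_tension(self):
        """Under a shortening protocol, the distortion terms depress tension;
        with A_eff = 0 the same protocol produces a larger peak."""
        from cardiomef.drivers import StretchProtocol, make_stretch
        t, cai = make_calcium(CalciumTransientSpec(), 1.0)
        # shortening protocol: steady shortening through the twitch
        prot = StretchProtocol(kind="ramp", baseline=1.1, rate=-2e-4,
                               onset=0.0, duration=600.0)
        _, lam, dlam = make_stretch(prot, 1.0)
        peaks = {}
        for vd in (True, False):
            tog = MEFToggles(velocity_dependence=vd)
            y = land_steady_state(cai[0], lam[0], P, tog).to_array()
            ta = []
            for i in range(1, len(t)):
                for _ in range(10):
                    y = land_step(y, lam[i], dlam[i], cai[i], P, tog, 0.1)
                ta.append(active_tension(y, lam[i], P, tog))
            peaks[vd] = max(ta)
        assert peaks[False] > peaks[True]

    def test_no_mef_tension_is_stretch_history_independent(self,
                                                           calcium_transient):
        t, cai = calcium_transient
        tog = MEFToggles(velocity_dependence=False, length_dependence=False)
        tw_a = isometric_twitch(P, tog, t, cai, lam=1.0)
        tw_b = isometric_twitch(P, tog, t, cai, lam=1.15)
        np.testing.assert_allclose(tw_a.tension, tw_b.tension, rtol=1e-12)

    def test_state_fractions_remain_admissible(self, calcium_transient):
        t, cai = calcium_transient
        y = land_steady_state(cai[0], 1.0, P, ON).to_array()
        for i in range(1, len(t)):
            for _ in range(10):
                y = land_step(y, 1.0, 0.0, cai[i], P, ON, 0.1)
            frac = y[[tn.L_S, tn.L_W, tn.L_B, tn.L_CATRPN]]
            assert np.all(frac >= 0.0) and np.all(frac <= 1.0)
            assert y[tn.L_S] + y[tn.L_W] + y[tn.L_B] <= 1.0 + 1e-9


def test_land_state_validation():
    with pytest.raises(ValueError):
        LandState(S=0.6, W=0.6, B=0.2)
    with pytest.raises(ValueError):
        LandState(CaTRPN=1.5)


def test_params_validation():
    with pytest.raises(ValueError):
        LandParams(Tref=-1.0)
    with pytest.raises(ValueError):
        LandParams(beta0=-0.1)
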