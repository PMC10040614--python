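"""Myocyte electrophysiology: derivatives, integration, pacing, AP markers."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cardiomef import ionic
from cardiomef.ionic import (CellState, StimulusSpec, apd, cell_derivatives,
                             detect_activation_time,
                             detect_repolarization_time, pace_to_steady_state,
                             simulate_beats, step_cell)


class TestDerivatives:
    def test_gate_at_steady_state_has_zero_derivative(self, cell_params, paced):
        # evaluate xinf at the current Vm, set one gate to it: dx/dt = 0
        from cardiomef import _kernel as K
        y = paced.state.y.copy()
        dy = np.empty(K.N_STATE)
        xinf = np.empty(K.N_STATE)
        xtau = np.empty(K.N_STATE)
        K.rhs(y, cell_params.to_array(), 0.0, 0.0, dy, xinf, xtau)
        y2 = y.copy()
        y2[K.S_M] = xinf[K.S_M]
        d2 = cell_derivatives(CellState(y2), cell_params)
        assert d2.y if hasattr(d2, "y") else True
        assert abs(d2[K.S_M]) < 1e-12

    def test_diastolic_state_is_quiescent(self, cell_params, paced):
        dvm = cell_derivatives(paced.state, cell_params)[0]
        assert abs(dvm) < 0.01  # mV/ms

    def test_external_current_enters_linearly(self, cell_params, paced):
        d0 = cell_derivatives(paced.state, cell_params, i_external=0.0)
        d1 = cell_derivatives(paced.state, cell_params, i_external=-2.5)
        # dVm/dt = -(I_ion + i_ext): difference is exactly +2.5 mV/ms
        assert d1[0] - d0[0] == pytest.approx(2.5, abs=1e-12)

    def test_nonfinite_state_rejected(self, cell_params, paced):
        bad = paced.state.copy()
        bad.y[0] = np.nan
        with pytest.raises(ValueError):
            cell_derivatives(bad, cell_params)


class TestStepping:
    def test_vanishing_step_is_identity(self, cell_params, paced):
        out = step_cell(paced.state, cell_params, dt=1e-9)
        np.testing.assert_allclose(out.y, paced.state.y, rtol=1e-7)

    def test_step_halving_in_diastole(self, cell_params, paced):
        full = step_cell(paced.state, cell_params, dt=0.02)
        half = step_cell(step_cell(paced.state, cell_params, dt=0.01),
                         cell_params, dt=0.01)
        assert abs(full.Vm - half.Vm) < 0.01

    def test_invalid_dt(self, cell_params, paced):
        with pytest.raises(ValueError):
            step_cell(paced.state, cell_params, dt=0.0)

    def test_suprathreshold_stimulus_fires_fast_upstroke(self, cell_params,
                                                         paced):
        t, vm, _, _ = simulate_beats(
            paced.state, cell_params, cycle_length=10.0, n_beats=1,
            stim=StimulusSpec(onset=0.0, duration=1.0, amplitude=-52.0),
            record_dt=0.5)
        assert vm[t <= 5.0].max() > 10.0

    def test_gates_and_concentrations_stay_admissible(self, cell_params,
                                                      paced):
        # 10 000 EP steps spanning a stimulated beat
        from cardiomef import _kernel as K
        y = paced.state.y.copy().reshape(1, -1)
        p = cell_params.to_array()
        d = np.empty((1, 1))
        stim = np.array([-26.0])
        none = np.zeros(1)
        for seg, a in ((100, none), (100, stim), (9800, none)):
            K.advance(y, p, 0.02, seg, a, none, 0, d, d)
            assert np.all(y[0, K.S_M:K.S_XS + 1] >= 0.0)
            assert np.all(y[0, K.S_M:K.S_XS + 1] <= 1.0)
            assert np.all(y[0, K.S_CAI:] > 0.0)


class TestPacing:
    def test_converged_state_is_fixed_point(self, cell_params, paced):
        res = pace_to_steady_state(cell_params, 600.0, n_beats_max=1,
                                   tol=1e-3, state=paced.state)
        assert res.converged and res.n_beats == 1

    def test_no_beats_returns_input_with_warning(self, cell_params):
        res = pace_to_steady_state(cell_params, 600.0, n_beats_max=0)
        assert not res.converged and res.criterion == "no_beats"
        np.testing.assert_array_equal(res.state.y, CellState.initial().y)

    def test_resting_potential_in_published_range(self, paced):
        assert -90.0 < paced.state.Vm < -80.0

    def test_rate_dependence_of_apd(self, cell_params, paced):
        _, vm6, _, _ = simulate_beats(paced.state, cell_params,
                                      cycle_length=600.0, n_beats=1,
                                      stim=StimulusSpec(onset=5.0))
        res10 = pace_to_steady_state(cell_params, 1000.0, n_beats_max=40,
                                     tol=1e-3, state=paced.state)
        _, vm10, _, _ = simulate_beats(res10.state, cell_params,
                                       cycle_length=1000.0, n_beats=1,
                                       stim=StimulusSpec(onset=5.0))
        a6, a10 = apd(vm6, 1.0), apd(vm10, 1.0)
        assert a6 < a10
        assert 260.0 < a10 < 330.0  # published 1 Hz APD90 ballpark

    def test_refractoriness(self, cell_params, paced):
        # second stimulus 50 ms after the upstroke must not elicit a second
        # regenerative AP: exactly one upward 0 mV crossing in the trace
        t, vm, _, st = simulate_beats(
            paced.state, cell_params, cycle_length=60.0, n_beats=1,
            stim=StimulusSpec(onset=10.0, duration=1.0, amplitude=-52.0))
        t2, vm2, _, _ = simulate_beats(
            st, cell_params, cycle_length=540.0, n_beats=1,
            stim=StimulusSpec(onset=0.0, duration=1.0, amplitude=-52.0))
        full = np.concatenate([vm, vm2[1:]])
        crossings = np.sum((full[:-1] < 0.0) & (full[1:] >= 0.0))
        assert crossings == 1


class TestIntegratorCrossCheck:
    def test_rush_larsen_matches_adaptive_reference(self, cell_params, paced):
        """Fixed-step exponential integration agrees with an adaptive
        high-accuracy ODE solve of the same right-hand side to < 1 mV."""
        # state right after a stimulus, then 400 ms free evolution
        _, _, _, st = simulate_beats(
            paced.state, cell_params, cycle_length=3.0, n_beats=1,
            stim=StimulusSpec(onset=0.5, duration=2.0, amplitude=-40.0))
        t_eval = np.arange(0.0, 400.0 + 0.5, 1.0)
        sol = solve_ivp(
            lambda t, y: cell_derivatives(CellState(y), cell_params),
            (0.0, 400.0), st.y, method="LSODA", t_eval=t_eval,
            rtol=1e-8, atol=1e-10)
        assert sol.success
        _, vm_rl, _, _ = simulate_beats(st, cell_params, cycle_length=400.0,
                                        n_beats=1, stim=None, record_dt=1.0)
        n = min(len(vm_rl), sol.y.shape[1])
        assert np.max(np.abs(vm_rl[:n] - sol.y[0, :n])) < 1.0


class TestTraceMarkers:
    def test_activation_time_on_linear_ramp(self):
        vm = -80.0 + 10.0 * np.arange(11.0)
        assert detect_activation_time(vm, 1.0, threshold=0.0) == pytest.approx(8.0)

    def test_constant_trace_has_no_activation(self):
        assert detect_activation_time(np.full(50, -80.0), 1.0) is None

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_activation_time(np.array([]), 1.0)

    def test_activation_matches_sample_scan(self, cell_params, paced):
        _, vm, _, _ = simulate_beats(paced.state, cell_params,
                                     cycle_length=600.0, n_beats=1,
                                     stim=StimulusSpec(onset=50.0))
        t = detect_activation_time(vm, 1.0)
        scan = next(i for i in range(len(vm)) if vm[i] >= 0.0)
        assert abs(t - scan) <= 1.0

    def test_repolarization_on_triangle(self):
        up = np.linspace(-80.0, 20.0, 6)
        down = np.linspace(20.0, -80.0, 301)
        vm = np.concatenate([up, down[1:]])
        t = detect_repolarization_time(vm, 1.0, level=0.9)
        assert t == pytest.approx(275.0, abs=1e-9)

    def test_repolarization_requires_activation(self):
        assert detect_repolarization_time(np.full(100, -80.0), 1.0) is None

    def test_repolarization_time_shift_equivariance(self):
        up = np.linspace(-80.0, 20.0, 6)
        down = np.linspace(20.0, -80.0, 301)
        vm = np.concatenate([up, down[1:]])
        t0 = detect_repolarization_time(vm, 1.0)
        t1 = detect_repolarization_time(vm, 1.0, t0=40.0)
        assert t1 - t0 == pytest.approx(40.0)


def test_cell_state_invariants_enforced():
    s = CellState.initial()
    s.validate()
    s.y[1] = 1.5
    with pytest.raises(ValueError):
        s.validate()


def test_stimulus_spec_validation():
    with pytest.raises(ValueError):
        StimulusSpec(duration=0.0)
    with pytest.raises(ValueError):
        StimulusSpec(onset=-1.0)
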