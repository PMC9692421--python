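"""Circuit dynamics: primitives, sub-step updates, composition, rhythm."""

import numpy as np
import pytest
from scipy.optimize import fsolve

import wormnav.network as net
from wormnav import _kernels as K
from wormnav.cpg import TOSC, measure_period
from wormnav.network import (CircuitState, initial_state, joint_angle,
                             muscle_output, proprioceptive_current,
                             run_open_loop, sigmoid, step_circuit, step_cpg,
                             step_head_muscles, step_smb, step_smdv,
                             step_vnc_units)
from wormnav.params import CPGParams


class TestSigmoid:
    def test_symmetry_point(self):
        assert sigmoid(0.0) == 0.5

    def test_saturation(self):
        assert sigmoid(50.0) == pytest.approx(1.0, abs=1e-12)
        assert sigmoid(-50.0) == pytest.approx(0.0, abs=1e-12)

    def test_logistic_symmetry_identity(self):
        assert sigmoid(2.0) + sigmoid(-2.0) == pytest.approx(1.0, abs=1e-15)

    def test_strictly_increasing(self):
        x = np.linspace(-8, 8, 201)
        assert np.all(np.diff(sigmoid(x)) > 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            sigmoid(float("inf"))


class TestMuscleOutput:
    def test_bias_cancellation_gives_half(self):
        assert muscle_output(3.2, -3.2) == pytest.approx(0.5)

    def test_large_negative_bias_saturates_low(self):
        assert muscle_output(0.0, -5.0) < 0.01

    def test_monotone_in_activation(self):
        outs = [muscle_output(a, -2.0) for a in np.linspace(-3, 3, 50)]
        assert np.all(np.diff(outs) > 0)


class TestJointAngle:
    def test_equal_outputs_give_zero(self):
        assert joint_angle(0.4, 0.4, 2.0) == 0.0

    def test_arithmetic(self):
        assert joint_angle(0.8, 0.2, 1.0) == pytest.approx(0.6)

    def test_antisymmetry(self):
        assert joint_angle(0.7, 0.3, 1.5) == -joint_angle(0.3, 0.7, 1.5)


class TestStepCPG:
    def test_uncoupled_neurons_relax_to_rest(self, params):
        p = params.replace(cpg=CPGParams(tau=[0.5, 0.5, 0.5], w=np.zeros((3, 3)),
                                         e_rest=[1.0, -2.0, 3.0], bias=[0, 0, 0]))
        s = initial_state(p)
        s.v_cpg = np.array([5.0, 5.0, 5.0])
        for _ in range(200):  # 2 s = 4 time constants
            s = step_cpg(s, p, 0.01)
        e_rest = np.array([1.0, -2.0, 3.0])
        expected = e_rest + (5.0 - e_rest) * np.exp(-4.0)
        assert np.allclose(s.v_cpg, expected, atol=2e-2)

    def test_zero_dt_is_identity(self, params):
        s = initial_state(params)
        s.v_cpg = np.array([0.3, -0.7, 1.1])
        s2 = step_cpg(s, params, 0.0)
        assert np.allclose(s2.v_cpg, s.v_cpg)

    def test_only_cpg_voltages_change(self, params):
        s = initial_state(params)
        s2 = step_cpg(s, params, 0.01)
        assert np.allclose(s2.theta, s.theta)
        assert s2.v_smbd == s.v_smbd and s2.a_dm0 == s.a_dm0

    def test_fixed_point_is_step_invariant(self, params):
        # solve V* = e_rest + W f(V* + b) and verify the Euler step holds it
        rng = np.random.default_rng(11)
        w = rng.uniform(-2, 2, (3, 3))
        np.fill_diagonal(w, 0.0)
        cp = CPGParams(tau=[0.3, 0.7, 1.1], w=w,
                       e_rest=rng.uniform(-2, 2, 3), bias=rng.uniform(-1, 1, 3))

        def resid(v):
            return v - (cp.e_rest + cp.w @ (1 / (1 + np.exp(-(v + cp.bias)))))

        v_star = fsolve(resid, np.zeros(3), xtol=1e-14)
        assert np.linalg.norm(resid(v_star)) < 1e-12
        p = params.replace(cpg=cp)
        s = initial_state(p)
        s.v_cpg = v_star.copy()
        s2 = step_cpg(s, p, 0.01)
        assert np.linalg.norm(s2.v_cpg - v_star) < 1e-12

    def test_nonfinite_state_rejected(self, params):
        s = initial_state(params)
        s.v_cpg[0] = np.nan
        with pytest.raises(ValueError):
            step_cpg(s, params, 0.01)


class TestStepSMB:
    def test_zero_input_relaxes_to_rest(self, params):
        s = initial_state(params)
        s.v_cpg[:] = 0.0
        s.v_smbd, s.v_smbv = 4.0, -3.0
        for _ in range(2000):
            s = step_smb(s, params, 0.0, 0.0, 0.01)
        er = params.head.e_smb_rest
        assert s.v_smbd == pytest.approx(er, abs=1e-6)
        assert s.v_smbv == pytest.approx(er, abs=1e-6)

    def test_c3_drive_is_antisymmetric(self, params):
        s = initial_state(params)
        s.v_cpg[2] = 2.5
        s2 = step_smb(s, params, 0.0, 0.0, 0.01)
        er = params.head.e_smb_rest
        assert (s2.v_smbd - s.v_smbd) - (er - s.v_smbd) * 0 == pytest.approx(
            -(s2.v_smbv - s.v_smbv), rel=1e-9)

    def test_aser_input_shifts_both_up(self, params):
        # excitatory ASER input raises both SMB voltages vs the silent case
        base = initial_state(params)
        a = step_smb(base, params, 0.0, 0.0, 0.01)
        b = step_smb(base, params, 0.0, 3.0, 0.01)
        assert b.v_smbd > a.v_smbd and b.v_smbv > a.v_smbv

    def test_asel_input_shifts_both_down(self, params):
        base = initial_state(params)
        a = step_smb(base, params, 0.0, 0.0, 0.01)
        b = step_smb(base, params, 3.0, 0.0, 0.01)
        assert b.v_smbd < a.v_smbd and b.v_smbv < a.v_smbv


class TestStepSMDV:
    def test_silent_without_aser(self, params):
        s = initial_state(params)
        for _ in range(5000):
            s = step_smdv(s, params, 0.0, 0.01)
        assert s.v_smdv == pytest.approx(params.head.e_smdv_rest, abs=1e-9)

    def test_bounded_by_synaptic_reversal(self, params):
        s = initial_state(params)
        for _ in range(20000):
            s = step_smdv(s, params, 1e6, 0.01)
        assert s.v_smdv < params.head.e_smdv_aser
        assert s.v_smdv > 0.5 * params.head.e_smdv_aser  # saturating response

    def test_steady_state_monotone_in_aser(self, params):
        def steady(v_aser):
            s = initial_state(params)
            for _ in range(8000):
                s = step_smdv(s, params, v_aser, 0.01)
            return s.v_smdv

        levels = [steady(v) for v in np.linspace(0, 15, 12)]
        assert np.all(np.diff(levels) >= -1e-12)


class TestHeadMuscles:
    def test_steady_state_tracks_weighted_voltage(self, params):
        s = initial_state(params)
        s.v_smbd = 1.7
        s.v_smbv = 0.0
        s.v_smdv = 0.0
        for _ in range(5000):
            s = step_head_muscles(s, params, 0.01)
        assert s.a_dm0 == pytest.approx(params.head.w_m0_smb * 1.7, rel=1e-6)

    def test_smdv_adds_linearly_to_vm0(self, params):
        def steady(v_smdv):
            s = initial_state(params)
            s.v_smbv = 0.8
            s.v_smdv = v_smdv
            for _ in range(5000):
                s = step_head_muscles(s, params, 0.01)
            return s.a_vm0

        base, driven = steady(0.0), steady(2.0)
        assert driven - base == pytest.approx(params.head.w_m0_smdv * 2.0, rel=1e-6)


class TestProprioception:
    def test_zero_angles_give_half_gated_current(self, params):
        v = 1.3
        expect = sum(params.vnc.w_shape[j] * 0.5 * (v - params.vnc.e_shape[j])
                     for j in range(2))
        got = proprioceptive_current(v, 0.0, 0.0, params, "dorsal")
        assert got == pytest.approx(expect, rel=1e-12)

    def test_ventral_is_dorsal_with_negated_angles(self, params, rng):
        for _ in range(10):
            v, th_o, th_a = rng.uniform(-2, 2, 3)
            d = proprioceptive_current(v, -th_o, -th_a, params, "dorsal")
            vtr = proprioceptive_current(v, th_o, th_a, params, "ventral")
            assert vtr == pytest.approx(d, rel=1e-12)


class TestVNCUnits:
    def test_frozen_straight_body_units_converge_identically(self, params):
        s = initial_state(params)
        for _ in range(5000):
            vec = s.to_vector()
            # freeze all joints at zero each tick: identical inputs for all units
            _, _, _, _, _, vnc, _ = K.pack_params(params)
            K.step_vnc_units(vec, vnc, 0.01)
            vec[K.I_TH:K.I_TH + 11] = 0.0
            s = CircuitState.from_vector(vec)
        assert np.ptp(s.v_db) < 1e-9 and np.ptp(s.v_vb) < 1e-9
        assert np.ptp(s.a_dm) < 1e-9 and np.ptp(s.a_vm) < 1e-9

    def test_unloaded_units_relax_to_conductance_equilibrium(self, params):
        # with w_shape = 0 the B neurons are pure leaks toward e_b_rest
        import copy
        p = copy.deepcopy(params)
        p.vnc.w_shape[:] = 0.0
        s = initial_state(p)
        s.v_db[:] = 3.0
        for _ in range(2000):
            s = step_vnc_units(s, p, 0.01)
        assert np.allclose(s.v_db, p.vnc.e_b_rest, atol=1e-6)


class TestStepCircuit:
    def test_deterministic_bitwise(self, params):
        s1 = initial_state(params)
        s2 = initial_state(params)
        for _ in range(500):
            s1 = step_circuit(s1, params, 0.1, 0.2, 0.01)
            s2 = step_circuit(s2, params, 0.1, 0.2, 0.01)
        assert np.array_equal(s1.to_vector(), s2.to_vector())

    def test_muscle_outputs_stay_in_open_unit_interval(self, params):
        df, _ = run_open_loop(params, 30.0)
        assert ((df["o_dm0"] > 0) & (df["o_dm0"] < 1)).all()
        assert ((df["o_vm0"] > 0) & (df["o_vm0"] < 1)).all()


class TestRhythm:
    """Behaviour of the full circuit with the shipped default parameters."""

    @pytest.fixture(scope="class")
    def trace(self, params):
        df, _ = run_open_loop(params, 60.0)
        return df[df["t"] >= 20.0].reset_index(drop=True)

    def test_theta1_periodic_with_tosc_and_zero_mean(self, trace, params):
        th1 = trace["theta1"].to_numpy()
        period = measure_period(th1, params.sim.dt)
        assert period == pytest.approx(TOSC, abs=0.15)
        amp = 0.5 * (th1.max() - th1.min())
        assert abs(th1.mean()) < 0.01 * amp

    def test_smb_antiphase(self, trace, params):
        vd = trace["v_smbd"].to_numpy()
        vv = trace["v_smbv"].to_numpy()
        n_half = int(round(TOSC / 2 / params.sim.dt))
        a = vd[:-n_half] - vd.mean()
        b = vv[n_half:] - vv.mean()
        corr = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        assert corr > 0.99

    def test_wave_propagates_with_preserved_waveform(self, trace):
        # every joint oscillates; the last joint nearly synchronises with
        # the first (10 lags of ~Tosc/10 add up to one full cycle)
        th = trace[[f"theta{i}" for i in range(1, 12)]].to_numpy()
        amps = 0.5 * (th.max(axis=0) - th.min(axis=0))
        assert np.all(amps > 0.3 * amps[0])

    def test_boundedness_over_long_run(self, params):
        df, state = run_open_loop(params, 100.0, record_stride=10)
        vec = state.to_vector()
        assert np.all(np.isfinite(vec))
        volts = df[["v_smbd", "v_smbv", "v_smdv"]].to_numpy()
        assert np.max(np.abs(volts)) < 100.0  # 10x the parameter range

    def test_step_halving_converges(self, params):
        # Euler is order 1.  The limit-cycle period shifts by O(dt), so the
        # raw trace difference is dominated by accumulated phase drift; the
        # convergence check therefore compares period, amplitude, and the
        # phase-aligned waveform.
        from wormnav.metrics import pair_lag
        traces = {}
        for dt in (0.01, 0.005, 0.0025):
            df, _ = run_open_loop(params, 40.0, dt=dt,
                                  record_stride=int(round(0.01 / dt)))
            traces[dt] = df["theta1"].to_numpy()[2000:]
        p = {dt: measure_period(x, 0.01) for dt, x in traces.items()}
        # period error shrinks linearly with dt (first-order convergence)
        e1 = p[0.01] - p[0.005]
        e2 = p[0.005] - p[0.0025]
        assert abs(e1) < 0.01 * p[0.01]
        assert 1.3 < e1 / e2 < 3.0
        # amplitude error also shrinks linearly with dt
        amp = {dt: x.max() - x.min() for dt, x in traces.items()}
        a1 = amp[0.01] - amp[0.005]
        a2 = amp[0.005] - amp[0.0025]
        assert abs(a1) < 0.05 * amp[0.01]
        assert 1.3 < a1 / a2 < 3.0
        # waveform agreement, phase-drift-free: one full cycle from each
        # trace, resampled onto a common phase grid

        def cycle_by_phase(x, n_pts=400):
            up = np.nonzero((x[:-1] < 0) & (x[1:] >= 0))[0]
            i0, i1 = up[-2], up[-1]
            return np.interp(np.linspace(0, 1, n_pts, endpoint=False),
                             np.linspace(0, 1, i1 - i0, endpoint=False),
                             x[i0:i1])

        wa = cycle_by_phase(traces[0.01])
        wb = cycle_by_phase(traces[0.005])
        rms_diff = np.sqrt(np.mean((wa - wb) ** 2))
        assert rms_diff < 0.05 * np.sqrt(np.mean(wa ** 2))
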