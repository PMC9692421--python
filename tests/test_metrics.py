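"""Trajectory metrics on constructed fixtures and circuit-driven scans."""

import numpy as np
import pandas as pd
import pytest

from wormnav.cpg import TOSC
from wormnav.environment import Scenario
from wormnav.metrics import (compute_cycle_stats, compute_ssr, pair_lag,
                             phase_lag, phase_response_scan,
                             strategy_quantification)

DT = 0.01


def synthetic_trajectory(duration, turn_rate=0.0, speed=0.25, psi0=0.0):
    """Unicycle trajectory with sinusoidal theta1 plus a constant turn rate."""
    t = np.arange(0, duration, DT)
    theta1 = 0.9 * np.sin(2 * np.pi * t / TOSC)
    psi = psi0 + np.cumsum(theta1 + turn_rate) * DT
    x = np.concatenate(([0.0], np.cumsum(speed * DT * np.cos(psi))))[:-1]
    y = np.concatenate(([0.0], np.cumsum(speed * DT * np.sin(psi))))[:-1]
    return pd.DataFrame({"t": t, "x": x, "y": y, "theta1": theta1})


@pytest.fixture
def far_scenario():
    # nearly flat field so gradient terms do not matter for kinematic checks
    return Scenario(peak_xy=(1000.0, 0.0), c_max=50.0, sigma=400.0)


class TestCycleStats:
    def test_straight_trajectory_has_zero_bias(self, far_scenario):
        stats = compute_cycle_stats(synthetic_trajectory(48.0), far_scenario)
        bias = stats["turning_bias"].dropna()
        assert len(bias) >= 8
        assert np.all(np.abs(np.degrees(bias)) < 0.5)

    def test_constant_turn_rate_gives_r_tosc_bias(self, far_scenario):
        r = 0.05  # rad/s
        stats = compute_cycle_stats(synthetic_trajectory(40.0, turn_rate=r),
                                    far_scenario)
        bias = stats["turning_bias"].dropna()
        assert np.allclose(bias, r * TOSC, atol=0.01)

    def test_bias_additivity_over_cycles(self, far_scenario):
        stats = compute_cycle_stats(synthetic_trajectory(60.0, turn_rate=0.03),
                                    far_scenario)
        d = stats["translation_dir"].to_numpy()
        total = d[-1] - d[0]
        assert np.nansum(stats["turning_bias"]) == pytest.approx(total, abs=1e-6)

    def test_short_trajectory_rejected(self, far_scenario):
        with pytest.raises(ValueError):
            compute_cycle_stats(synthetic_trajectory(6.0), far_scenario)

    def test_normal_gradient_sign(self):
        # peak to the left of travel: the normal (90 deg CCW of +x travel)
        # points at the peak, so the normal gradient is positive
        sc = Scenario(peak_xy=(5.0, 30.0), c_max=50.0, sigma=20.0)
        stats = compute_cycle_stats(synthetic_trajectory(20.0), sc)
        assert np.all(stats["normal_grad"] > 0)


class TestSSR:
    def test_straight_run_is_unity(self):
        assert compute_ssr(80.0, 20.0, 0.25) == pytest.approx(1.0)

    def test_longer_path_scales(self):
        assert compute_ssr(96.0, 20.0, 0.25) == pytest.approx(1.2)

    def test_non_arrival_rejected(self):
        with pytest.raises(ValueError):
            compute_ssr(float("nan"), 20.0, 0.25)


class TestPhaseLag:
    def test_identical_traces_lag_zero(self):
        t = np.arange(0, 30, DT)
        x = np.sin(2 * np.pi * t / TOSC)
        assert pair_lag(x, x, DT, max_lag=2.0) == 0.0

    def test_constructed_shift_recovered(self):
        t = np.arange(0, 30, DT)
        x = np.sin(2 * np.pi * t / TOSC)
        y = np.sin(2 * np.pi * (t - 0.4) / TOSC)
        assert pair_lag(x, y, DT, max_lag=2.0) == pytest.approx(0.40, abs=0.01)

    def test_kymogram_ladder(self):
        t = np.arange(0, 40, DT)
        th = np.stack([np.sin(2 * np.pi * (t - 0.4 * i) / TOSC)
                       for i in range(11)], axis=1)
        lags = phase_lag(th, DT)
        assert lags.shape == (10,)
        assert np.allclose(lags, 0.4, atol=0.03)

    def test_flat_trace_rejected(self):
        th = np.zeros((4000, 11))
        with pytest.raises(ValueError):
            phase_lag(th, DT)


class TestPhaseResponse:
    """Gating structure of the klinotaxis circuit (default parameters).

    The scans run with the SMDV (klinokinesis) pathway severed so that the
    measured steering is the state-dependent gating alone, as in the
    dedicated analysis of that circuit.
    """

    @pytest.fixture(scope="class")
    def scans(self, params):
        from wormnav.simulate import apply_ablation
        taxis = apply_ablation(params, "klinotaxis_only")
        up = phase_response_scan(taxis, "up", n_phases=12)
        down = phase_response_scan(taxis, "down", n_phases=12)
        return up, down

    def test_zero_step_gives_zero_response(self, params):
        scan = phase_response_scan(params, "up", step_size=0.0, n_phases=4)
        assert np.allclose(scan["response"], 0.0, atol=1e-12)

    def test_sensory_dependence_up_down_opposite(self, scans):
        # feature f2: up and down steps at the same phase steer oppositely
        up, down = scans
        strong = np.abs(up["response"]) > 0.3 * np.abs(up["response"]).max()
        assert np.all(np.sign(up.loc[strong, "response"])
                      == -np.sign(down.loc[strong, "response"]))

    def test_state_dependence_half_cycle_opposite(self, scans):
        # feature f1: the same step half a cycle later steers the other way
        up, _ = scans
        r = up["response"].to_numpy()
        n = len(r)
        opposite = np.roll(r, n // 2)
        strong = np.abs(r) > 0.3 * np.abs(r).max()
        assert np.all(np.sign(r[strong]) == -np.sign(opposite[strong]))

    def test_zero_perpendicular_phases_steer_weakly(self, params):
        # at the two phases of extremal sweep angle the perpendicular
        # velocity component vanishes and steering is minimal; a finer grid
        # resolves the response zeros
        from wormnav.simulate import apply_ablation
        taxis = apply_ablation(params, "klinotaxis_only")
        scan = phase_response_scan(taxis, "up", n_phases=24)
        r = np.abs(scan["response"].to_numpy())
        assert r.min() < 0.1 * r.max()


class TestStrategyQuantification:
    def test_binned_tables_and_correlations(self, rng):
        # synthetic cycle stats: klinotaxis bias proportional to the normal
        # gradient; klinokinesis bias negative on negative temporal gradient
        n = 600
        ng = rng.uniform(-2, 2, n)
        taxis = pd.DataFrame({
            "turning_bias": 0.05 * ng + 0.005 * rng.standard_normal(n),
            "normal_grad": ng, "temporal_grad": rng.uniform(-1, 1, n)})
        tg = rng.uniform(-3, 3, n)
        kin = pd.DataFrame({
            "turning_bias": np.where(tg < 0, 0.12 * tg, 0.0)
            + 0.003 * rng.standard_normal(n),
            "normal_grad": rng.uniform(-1, 1, n), "temporal_grad": tg})
        out = strategy_quantification({"klinotaxis": taxis, "klinokinesis": kin})
        assert out["correlation"]["klinotaxis"] > 0.9
        table = out["tables"]["klinokinesis"]
        pos = table[table["bin_center"] > 0.1]["mean_bias"].dropna()
        neg = table[table["bin_center"] < -0.1]["mean_bias"].dropna()
        assert np.all(np.abs(np.degrees(pos)) < 1.0)
        assert np.all(neg < 0)
        # sharper strategy has the larger steering amplitude here
        assert out["max_abs_bias"]["klinokinesis"] > out["max_abs_bias"]["klinotaxis"]

    def test_normalisation_is_sign_preserving(self, rng):
        g = rng.uniform(-5, 5, 300)
        df = pd.DataFrame({"turning_bias": np.sign(g) * 0.1,
                           "normal_grad": g, "temporal_grad": g})
        out = strategy_quantification({"klinotaxis": df})
        table = out["tables"]["klinotaxis"]
        mid = table[np.abs(table["bin_center"]) > 0.05].dropna()
        assert np.all(np.sign(mid["mean_bias"]) == np.sign(mid["bin_center"]))
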