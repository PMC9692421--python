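"""Kinematic and behavioural analyses of trajectories and circuit traces.

Implements the cycle-level trajectory statistics (translation direction,
turning bias, normal and temporal concentration gradients), the search-time
ratio (SSR), kymogram phase lags, the phase-response scan that exposes the
state-dependent gating, and the strategy quantification relating turning
bias to gradients for the two chemotaxis strategies.

Conventions: one locomotion cycle runs between consecutive upward zero
crossings of the Joint-1 angle; the translation direction of a cycle is the
direction of its net head displacement; the normal direction is 90 degrees
counterclockwise from it; the turning bias is the signed angle between the
translation directions of consecutive cycles (CCW positive, wrapped to
(-pi, pi]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _stats

from . import _kernels as K
from .cpg import TOSC
from .environment import Scenario, gradient_at
from .params import ModelParams

__all__ = [
    "compute_cycle_stats",
    "compute_ssr",
    "phase_lag",
    "pair_lag",
    "phase_response_scan",
    "strategy_quantification",
]


def _wrap_angle(a: np.ndarray | float):
    """Wrap to (-pi, pi]."""
    return -(np.mod(-np.asarray(a) + np.pi, 2 * np.pi) - np.pi)


def _upward_crossings(x: np.ndarray) -> np.ndarray:
    """Indices i where x crosses 0 upward between samples i and i+1."""
    return np.nonzero((x[:-1] < 0) & (x[1:] >= 0))[0]


def compute_cycle_stats(trajectory: pd.DataFrame, scenario: Scenario,
                        tosc: float = TOSC) -> pd.DataFrame:
    """Per-cycle trajectory statistics.

    ``trajectory`` needs columns t, x, y, theta1 (and optionally c; the
    concentration is re-evaluated from the scenario field along the path).
    Cycle boundaries are the upward zero crossings of theta1.  Returns one
    row per full cycle with translation_dir (rad), turning_bias (rad, NaN
    for the first cycle), normal_grad (mM/mm) and temporal_grad (mM/s).
    """
    t = trajectory["t"].to_numpy()
    xy = trajectory[["x", "y"]].to_numpy()
    th1 = trajectory["theta1"].to_numpy()
    if t[-1] - t[0] < 2 * tosc:
        raise ValueError("trajectory must cover at least 2 locomotion cycles")
    bounds = _upward_crossings(th1)
    if bounds.size < 3:
        raise ValueError("fewer than 2 full cycles between theta1 zero crossings")
    conc = None
    if "c" in trajectory:
        conc = trajectory["c"].to_numpy()
    rows = []
    for k in range(bounds.size - 1):
        i0, i1 = bounds[k], bounds[k + 1]
        disp = xy[i1] - xy[i0]
        tdir = float(np.arctan2(disp[1], disp[0]))
        ndir = np.array([-np.sin(tdir), np.cos(tdir)])  # 90 deg CCW
        grads = gradient_at(scenario, xy[i0:i1 + 1])
        ngrad = float(np.mean(grads @ ndir))
        if conc is not None:
            dc = conc[i1] - conc[i0]
        else:
            from .environment import concentration_at
            dc = concentration_at(scenario, xy[i1]) - concentration_at(scenario, xy[i0])
        tgrad = float(dc / (t[i1] - t[i0]))
        rows.append({"cycle_index": k, "t_start": t[i0], "t_end": t[i1],
                     "translation_dir": tdir, "normal_grad": ngrad,
                     "temporal_grad": tgrad})
    df = pd.DataFrame(rows)
    # turning bias: angle from each cycle's direction to the next one,
    # attributed to the later cycle
    bias = _wrap_angle(np.diff(df["translation_dir"].to_numpy()))
    df["turning_bias"] = np.concatenate(([np.nan], bias))
    return df


def compute_ssr(arrival_time: float, initial_distance: float,
                speed: float) -> float:
    """Search-time ratio: arrival time over the straight-line travel time."""
    if initial_distance <= 0 or speed <= 0:
        raise ValueError("initial_distance and speed must be > 0")
    if not np.isfinite(arrival_time):
        raise ValueError("SSR is undefined for a non-arrived episode")
    return float(arrival_time / (initial_distance / speed))


def pair_lag(a: np.ndarray, b: np.ndarray, dt: float,
             max_lag: float) -> float:
    """Lag of ``b`` relative to ``a`` (s) from the cross-correlation argmax,
    searched in [-max_lag, max_lag]."""
    a = np.asarray(a, dtype=float) - np.mean(a)
    b = np.asarray(b, dtype=float) - np.mean(b)
    if np.std(a) < 1e-12 or np.std(b) < 1e-12:
        raise ValueError("non-oscillating trace")
    corr = _signal.correlate(b, a, mode="full")
    lags = _signal.correlation_lags(b.size, a.size, mode="full")
    sel = np.abs(lags * dt) <= max_lag
    k = np.argmax(corr[sel])
    return float(lags[sel][k] * dt)


def phase_lag(theta_traces: np.ndarray | pd.DataFrame, dt: float,
              tosc: float = TOSC) -> np.ndarray:
    """Per-pair propagation lag (s) of each joint relative to its anterior
    neighbour, from post-transient kymogram traces of shape (n_t, 11)."""
    th = np.asarray(theta_traces, dtype=float)
    if th.ndim != 2 or th.shape[1] < 2:
        raise ValueError("expected an (n_t, n_joints) trace array")
    if th.shape[0] * dt < 5 * tosc:
        raise ValueError("need at least 5 cycles of post-transient traces")
    # propagation lag is positive and below half a cycle
    return np.array([pair_lag(th[:, i], th[:, i + 1], dt, tosc / 2.0)
                     for i in range(th.shape[1] - 1)])


def phase_response_scan(params: ModelParams, step_sign: str = "up",
                        step_size: float | None = None, n_phases: int = 16,
                        baseline_c: float = 25.0, settle: float = 60.0,
                        adaptive: bool = True) -> pd.DataFrame:
    """Cumulative DM0-VM0 output change caused by a concentration step
    applied at each locomotion phase.

    The circuit runs to steady oscillation at constant concentration; phase 0
    is the upward zero crossing of theta1.  At each of ``n_phases`` evenly
    spaced phases the full state (circuit + sensors) is cloned, the
    concentration is stepped up or down by ``step_size`` and held, and both
    the perturbed and unperturbed clones integrate for half a cycle.  The
    reported response is integral of [(O_DM0^pert - O_DM0^ref) -
    (O_VM0^pert - O_VM0^ref)] dt -- the net steering command injected by the
    stimulus.  Default step size is 0.5/a (mid-range of the sensor tanh).
    """
    if step_sign not in ("up", "down"):
        raise ValueError("step_sign must be 'up' or 'down'")
    dt = params.sim.dt
    step = step_size if step_size is not None else 0.5 / params.ase.a
    if step == 0.0:
        pass  # a zero step is allowed and yields zero responses
    tau, w, e_rest, bias, head, vnc, ase = K.pack_params(params)
    state = K.init_state_vector(params)
    ase_state, buf = K.init_ase_state(params, baseline_c)

    def advance(circ, sen, b, c_trace, stride=0, rec=None):
        if rec is None:
            rec = np.zeros((c_trace.size // max(stride, 1) + 2, K.NREC))
        n = K.run_sensed_circuit(circ, sen, b, tau, w, e_rest, bias, head,
                                 vnc, ase, c_trace, dt, adaptive, rec, stride)
        return rec[:n]

    n_settle = int(round(settle / dt))
    advance(state, ase_state, buf, np.full(n_settle, baseline_c))
    # locate the next upward zero crossing of theta1 = start of the phase grid
    n_cycle = int(round(TOSC / dt))
    probe = advance(state.copy(), ase_state.copy(), buf.copy(),
                    np.full(2 * n_cycle, baseline_c), stride=1)
    th1 = probe[:, 4]
    ups = _upward_crossings(th1)
    if ups.size == 0:
        raise ValueError("circuit is not oscillating; cannot define phases")
    advance(state, ase_state, buf, np.full(int(ups[0]) + 1, baseline_c))

    # snapshots at the requested phases within one cycle
    phase_ticks = [int(round(k * n_cycle / n_phases)) for k in range(n_phases)]
    snaps = []
    pos = 0
    for tick in phase_ticks:
        if tick > pos:
            advance(state, ase_state, buf, np.full(tick - pos, baseline_c))
            pos = tick
        snaps.append((state.copy(), ase_state.copy(), buf.copy()))

    stepped_c = baseline_c + step if step_sign == "up" else baseline_c - step
    n_half = n_cycle // 2
    c_ref = np.full(n_half, baseline_c)
    c_pert = np.full(n_half, stepped_c)
    responses = []
    for circ, sen, b in snaps:
        ref = advance(circ.copy(), sen.copy(), b.copy(), c_ref, stride=1)
        pert = advance(circ.copy(), sen.copy(), b.copy(), c_pert, stride=1)
        d_od = pert[:, 20] - ref[:, 20]
        d_ov = pert[:, 21] - ref[:, 21]
        responses.append(float(np.sum(d_od - d_ov) * dt))
    phases = 2.0 * np.pi * np.arange(n_phases) / n_phases
    return pd.DataFrame({"phase": phases, "response": responses})


def strategy_quantification(cycle_stats: dict[str, pd.DataFrame],
                            n_bins: int = 20) -> dict:
    """Binned turning-bias-versus-gradient tables for the two strategies.

    ``cycle_stats`` maps strategy names to cycle-statistics tables from
    :func:`compute_cycle_stats` pooled over episodes: ``"klinotaxis"`` is
    analysed against the normal gradient, ``"klinokinesis"`` against the
    temporal gradient.  Gradients are normalised to [-1, 1] by their maximum
    absolute value (sign- and zero-preserving).  Returns per-strategy binned
    tables (empty bins flagged with NaN mean and n = 0), Pearson correlations
    on the cycle-level points, and the maximum |mean bias| per strategy.
    """
    out: dict = {"tables": {}, "correlation": {}, "max_abs_bias": {}}
    grad_col = {"klinotaxis": "normal_grad", "klinokinesis": "temporal_grad"}
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    for name, df in cycle_stats.items():
        col = grad_col[name]
        d = df.dropna(subset=["turning_bias", col])
        g = d[col].to_numpy()
        bias = d["turning_bias"].to_numpy()
        scale = np.max(np.abs(g))
        gn = g / scale if scale > 0 else g
        idx = np.clip(np.digitize(gn, edges) - 1, 0, n_bins - 1)
        mean_bias = np.full(n_bins, np.nan)
        counts = np.zeros(n_bins, dtype=int)
        for b in range(n_bins):
            sel = idx == b
            counts[b] = int(sel.sum())
            if counts[b]:
                mean_bias[b] = float(bias[sel].mean())
        table = pd.DataFrame({"bin_center": centers, "mean_bias": mean_bias,
                              "n": counts})
        out["tables"][name] = table
        r, _p = _stats.pearsonr(gn, bias) if len(d) > 2 else (np.nan, np.nan)
        out["correlation"][name] = float(r)
        valid = table["mean_bias"].dropna()
        out["max_abs_bias"][name] = float(valid.abs().max()) if len(valid) else np.nan
    return out
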