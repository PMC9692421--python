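"""Diagnostics and a small search harness for hand-tuning circuit parameters.

The head, VNC and sensor parameters are not evolved; they are tuned so the
circuit satisfies the model's behavioural invariants:

* SMBD/SMBV oscillate in antiphase and Joint 1 is periodic with zero mean;
* each VNC unit reproduces its anterior joint's waveform with a lag close to
  Tosc/10, so Joint 11 is nearly synchronised with Joint 1 and the body
  carries one full spatial wave (wavelength/body length close to v*Tosc/L);
* with zero sensory input the model travels straight;
* the phase-response structure of the gating (state and sensory dependence)
  has the right sign pattern.

:func:`rhythm_diagnostics` measures all of this from a single zero-input
run.  :func:`random_search` is the generic scorer loop used to produce the
shipped defaults.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from .cpg import TOSC, measure_period
from .kinematics import measure_wavelength, reconstruct_body
from .metrics import pair_lag, phase_lag
from .network import run_open_loop
from .params import ModelParams

__all__ = ["rhythm_diagnostics", "random_search", "set_param"]


def rhythm_diagnostics(params: ModelParams, duration: float = 60.0,
                       skip: float = 20.0) -> dict:
    """Zero-sensory-input rhythm, wave-propagation and straightness measures.

    Returns a dict with the Joint-1 period and amplitude, the SMBD/SMBV
    antiphase correlation, per-unit propagation lags, the Joint-11 versus
    Joint-1 residual lag, the amplitude ratio along the body, the net turn
    per cycle (deg), the heading oscillation amplitude (rad) and the
    wavelength/body-length ratio of the reconstructed body.
    """
    dt = params.sim.dt
    df, _ = run_open_loop(params, duration)
    post = df[df["t"] >= skip].reset_index(drop=True)
    th = post[[f"theta{i}" for i in range(1, 12)]].to_numpy()
    out: dict = {}
    th1 = th[:, 0]
    out["theta1_amplitude"] = 0.5 * (th1.max() - th1.min())
    out["theta1_mean"] = float(th1.mean())
    try:
        out["period"] = measure_period(th1, dt)
    except ValueError:
        out["period"] = np.nan
        out["antiphase_corr"] = np.nan
        return out
    # antiphase: corr of v_smbd(t) with v_smbv shifted by half a period
    n_half = int(round(out["period"] / 2 / dt))
    vd = post["v_smbd"].to_numpy()
    vv = post["v_smbv"].to_numpy()
    a = vd[:-n_half] - vd.mean()
    b = vv[n_half:] - vv.mean()
    out["antiphase_corr"] = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
    try:
        lags = phase_lag(th, dt)
        out["unit_lags"] = lags
        out["mean_unit_lag"] = float(np.mean(lags))
        out["joint11_vs_joint1_lag"] = pair_lag(th[:, 0], th[:, 10], dt,
                                                max_lag=out["period"] / 2)
    except ValueError:
        out["unit_lags"] = None
        out["mean_unit_lag"] = np.nan
        out["joint11_vs_joint1_lag"] = np.nan
    amps = 0.5 * (th.max(axis=0) - th.min(axis=0))
    out["amplitude_ratio_11_1"] = float(amps[10] / amps[0]) if amps[0] > 0 else np.nan
    out["joint_amplitudes"] = amps
    # integrate the heading from theta1 over whole cycles
    psi = np.cumsum(th1) * dt / params.body.steer_tau
    n_cyc = int(round(out["period"] / dt))
    k_cycles = psi.size // n_cyc
    if k_cycles >= 2:
        cycle_means = [psi[i * n_cyc:(i + 1) * n_cyc].mean() for i in range(k_cycles)]
        out["net_turn_per_cycle_deg"] = float(np.degrees(np.mean(np.diff(cycle_means))))
    else:
        out["net_turn_per_cycle_deg"] = np.nan
    out["heading_amplitude"] = 0.5 * float(psi[-k_cycles * n_cyc:].max()
                                           - psi[-k_cycles * n_cyc:].min()) \
        if k_cycles >= 1 else np.nan
    # integrate the trajectory, reconstruct the body at several phases of the
    # final cycle and average the wavelength measure over them
    psi_w = np.cumsum(th1) * dt / params.body.steer_tau
    steps = params.body.speed * dt * np.stack([np.cos(psi_w), np.sin(psi_w)], axis=1)
    traj = np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    ratios = []
    for off in range(0, n_cyc, max(1, n_cyc // 8)):
        i = th1.size - 1 - off
        if i - 2 * n_cyc < 0:
            break
        disp = traj[i] - traj[i - 2 * n_cyc]
        tdir = float(np.arctan2(disp[1], disp[0]))
        nodes = reconstruct_body(traj[i], psi_w[i], th[i], params.body)
        try:
            ratios.append(measure_wavelength(nodes, tdir, params.body))
        except ValueError:
            continue
    out["wavelength_ratio"] = float(np.mean(ratios)) if ratios else np.nan
    return out


def set_param(params: ModelParams, path: str, value) -> ModelParams:
    """Return a copy of ``params`` with one dotted field replaced, e.g.
    ``set_param(p, "vnc.tau_b", 0.25)`` or ``"vnc.w_shape[1]"``."""
    out = params.copy()
    section, _, fieldname = path.partition(".")
    target = getattr(out, section)
    if "[" in fieldname:
        name, idx = fieldname[:-1].split("[")
        getattr(target, name)[int(idx)] = value
    else:
        # bypass dataclass validation only on intermediate tuning copies
        object.__setattr__(target, fieldname, value)
    return out


def random_search(base: ModelParams, space: dict[str, tuple[float, float]],
                  score: Callable[[ModelParams], float], n_iter: int,
                  rng: np.random.Generator) -> tuple[ModelParams, float, list]:
    """Uniform random search over dotted-parameter boxes; maximises ``score``.

    Returns (best params, best score, [(score, {path: value}), ...] log).
    """
    best_p, best_s = base, score(base)
    log = [(best_s, {})]
    for _ in range(n_iter):
        draw = {path: rng.uniform(lo, hi) for path, (lo, hi) in space.items()}
        p = base
        for path, value in draw.items():
            p = set_param(p, path, value)
        try:
            s = score(p)
        except (ValueError, FloatingPointError):
            continue
        log.append((s, draw))
        if s > best_s:
            best_p, best_s = p, s
    return best_p, best_s, log
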