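"""Adaptive conductance-based ASEL/ASER chemosensors.

A single concentration sample stream from the head tip is converted into two
voltage channels: ASEL (the ON cell) depolarises on concentration increases,
ASER (the OFF cell) on decreases.  On the preferred sign of dC the synaptic
conductance is set instantaneously to

    g = g_max * tanh(a * |dC| / (1 + b * C_N)),

where C_N is the mean |dC| over the last ``window_n`` seconds; otherwise the
conductance decays exponentially with time constant ``tau_g``.  The divisive
C_N term adapts the sensitivity to the recently experienced gradient
amplitude, letting the same circuit operate across peak concentrations that
span more than an order of magnitude.  The non-adaptive variant drops the
divisor (g = g_max * tanh(a * |dC|)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .params import ASEParams

__all__ = ["ASEState", "update_cn", "update_conductance", "step_ase_voltage", "sense"]


@dataclass
class ASEState:
    """Sensor voltages, conductances and the sliding |dC| window."""

    v_asel: float
    v_aser: float
    g_asel: float
    g_aser: float
    last_c: float
    history: np.ndarray      # ring buffer of |dC|, window_n / sample_dt slots
    buf_pos: int = 0
    buf_sum: float = 0.0

    @classmethod
    def at_rest(cls, p: ASEParams, c0: float = 0.0) -> "ASEState":
        return cls(v_asel=p.e_ase_rest, v_aser=p.e_ase_rest,
                   g_asel=0.0, g_aser=0.0, last_c=c0,
                   history=np.zeros(p.window_samples))


def update_cn(state: ASEState, new_abs_dc: float) -> float:
    """Push |dC| into the ring buffer and return the windowed mean C_N.

    The buffer starts as zeros, so C_N ramps in linearly over the first
    ``window_n`` seconds; the current sample is included in the window.
    """
    state.buf_sum += new_abs_dc - state.history[state.buf_pos]
    state.history[state.buf_pos] = new_abs_dc
    state.buf_pos = (state.buf_pos + 1) % state.history.size
    return max(state.buf_sum, 0.0) / state.history.size


def update_conductance(state: ASEState, dc: float, c_n: float, p: ASEParams,
                       dt: float, which: str, adaptive: bool = True) -> None:
    """Set (preferred sign) or decay (otherwise) one neuron's conductance."""
    if which not in ("ASEL", "ASER"):
        raise ValueError("which must be 'ASEL' or 'ASER'")
    preferred = dc > 0 if which == "ASEL" else dc < 0
    attr = "g_asel" if which == "ASEL" else "g_aser"
    if preferred:
        drive = p.a * abs(dc) / (1.0 + p.b * c_n) if adaptive else p.a * abs(dc)
        setattr(state, attr, p.g_max * np.tanh(drive))
    else:
        g = getattr(state, attr)
        setattr(state, attr, g + dt * (-g / p.tau_g))


def step_ase_voltage(state: ASEState, p: ASEParams, dt: float, which: str) -> None:
    """Euler step of one neuron's conductance-based voltage equation."""
    if which not in ("ASEL", "ASER"):
        raise ValueError("which must be 'ASEL' or 'ASER'")
    attr_v = "v_asel" if which == "ASEL" else "v_aser"
    g = state.g_asel if which == "ASEL" else state.g_aser
    v = getattr(state, attr_v)
    dv = (-(v - p.e_ase_rest) - g * (v - p.e_ase_ext)) / p.tau_ase
    setattr(state, attr_v, v + dt * dv)


def sense(state: ASEState, c_now: float, p: ASEParams, dt: float | None = None,
          adaptive: bool = True) -> tuple[float, float]:
    """Process one concentration sample; returns (v_asel, v_aser).

    Computes dC from the previous sample, updates the adaptation window
    (adaptive mode only -- in non-adaptive mode the window is bypassed but
    still maintained for trace comparability), both conductances and both
    voltages, via the same compiled kernel the episode loop uses.
    """
    if not np.isfinite(c_now):
        raise ValueError("concentration must be finite")
    dt = p.sample_dt if dt is None else dt
    vec = np.array([state.v_asel, state.v_aser, state.g_asel, state.g_aser,
                    state.last_c, state.buf_sum, float(state.buf_pos)])
    ase_arr = np.array([p.tau_ase, p.e_ase_rest, p.e_ase_ext, p.g_max,
                        p.tau_g, p.a, p.b])
    K.step_sensor(vec, state.history, c_now, ase_arr, dt, adaptive)
    (state.v_asel, state.v_aser, state.g_asel, state.g_aser,
     state.last_c, state.buf_sum) = map(float, vec[:6])
    state.buf_pos = int(vec[6])
    return state.v_asel, state.v_aser
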