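"""Head circuit and ventral-nerve-cord dynamics.

The network is a chain of leaky-integrator neurons and first-order muscle
activations updated by forward Euler.  One tick applies, in fixed order:

1. CPG (three coupled neurons, C3 is the rhythmic output),
2. SMBD/SMBV head motoneurons (antiphase copies of C3 plus sensory input),
3. SMDV (the thresholded, saturating klinokinesis interneuron),
4. DM0/VM0 head muscles and the Joint-1 angle,
5. the ten identical VNC units, which read their own and the anterior joint
   angle through proprioceptive conductances and produce Joints 2-11.

All functions are pure: they take a :class:`CircuitState` and return a new
one.  The math itself is shared with the fast simulation loops via
:mod:`wormnav._kernels`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as K
from .params import ModelParams

__all__ = [
    "CircuitState",
    "sigmoid",
    "muscle_output",
    "joint_angle",
    "proprioceptive_current",
    "step_cpg",
    "step_smb",
    "step_smdv",
    "step_head_muscles",
    "step_vnc_units",
    "step_circuit",
    "initial_state",
    "run_open_loop",
]


def sigmoid(x):
    """Logistic nonlinearity 1 / (1 + exp(-x)), the f(.) of every synapse."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("sigmoid input must be finite")
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                   np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    return float(out) if out.ndim == 0 else out


def muscle_output(activation: float, bias: float) -> float:
    """Muscle output f(A + b); the strongly negative bias used by the head
    muscles parks the output near 0, creating the gating half-cycles."""
    return float(K.sigmoid(activation + bias))


def joint_angle(o_dorsal: float, o_ventral: float, omega: float) -> float:
    """theta = omega * (O_D - O_V); positive = anterior rod rotates CCW (left)."""
    return omega * (o_dorsal - o_ventral)


@dataclass
class CircuitState:
    """All neuron voltages, muscle activations and joint angles at one instant."""

    v_cpg: np.ndarray       # (3,) mV
    v_smbd: float
    v_smbv: float
    v_smdv: float
    a_dm0: float
    a_vm0: float
    v_db: np.ndarray        # (10,) mV
    v_vb: np.ndarray        # (10,) mV
    a_dm: np.ndarray        # (10,)
    a_vm: np.ndarray        # (10,)
    theta: np.ndarray       # (11,) rad, theta[0] = Joint 1

    def to_vector(self) -> np.ndarray:
        s = np.empty(K.NSTATE, dtype=np.float64)
        s[K.I_CPG:K.I_CPG + 3] = self.v_cpg
        s[K.I_SMBD] = self.v_smbd
        s[K.I_SMBV] = self.v_smbv
        s[K.I_SMDV] = self.v_smdv
        s[K.I_ADM0] = self.a_dm0
        s[K.I_AVM0] = self.a_vm0
        s[K.I_VDB:K.I_VDB + 10] = self.v_db
        s[K.I_VVB:K.I_VVB + 10] = self.v_vb
        s[K.I_ADM:K.I_ADM + 10] = self.a_dm
        s[K.I_AVM:K.I_AVM + 10] = self.a_vm
        s[K.I_TH:K.I_TH + 11] = self.theta
        return s

    @classmethod
    def from_vector(cls, s: np.ndarray) -> "CircuitState":
        return cls(
            v_cpg=s[K.I_CPG:K.I_CPG + 3].copy(),
            v_smbd=float(s[K.I_SMBD]),
            v_smbv=float(s[K.I_SMBV]),
            v_smdv=float(s[K.I_SMDV]),
            a_dm0=float(s[K.I_ADM0]),
            a_vm0=float(s[K.I_AVM0]),
            v_db=s[K.I_VDB:K.I_VDB + 10].copy(),
            v_vb=s[K.I_VVB:K.I_VVB + 10].copy(),
            a_dm=s[K.I_ADM:K.I_ADM + 10].copy(),
            a_vm=s[K.I_AVM:K.I_AVM + 10].copy(),
            theta=s[K.I_TH:K.I_TH + 11].copy(),
        )

    def validate(self) -> None:
        if not np.all(np.isfinite(self.to_vector())):
            raise ValueError("circuit state contains non-finite values")


def initial_state(params: ModelParams) -> CircuitState:
    """Voltages at their resting potentials, activations 0, straight body."""
    return CircuitState.from_vector(K.init_state_vector(params))


def _apply(state: CircuitState, fn, *args) -> CircuitState:
    state.validate()
    vec = state.to_vector()
    fn(vec, *args)
    return CircuitState.from_vector(vec)


def step_cpg(state: CircuitState, params: ModelParams, dt: float) -> CircuitState:
    """Forward-Euler update of the three CPG voltages; everything else unchanged."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    c = params.cpg
    return _apply(state, K.step_cpg, c.tau, c.w, c.e_rest, c.bias, dt)


def step_smb(state: CircuitState, params: ModelParams,
             v_asel: float, v_aser: float, dt: float) -> CircuitState:
    """SMBD gets +w*C3, SMBV gets -w*C3; both share the same sensory input."""
    head, = _head(params)
    return _apply(state, K.step_smb, head, v_asel, v_aser, dt)


def step_smdv(state: CircuitState, params: ModelParams,
              v_aser: float, dt: float) -> CircuitState:
    """Conductance-based SMDV update; silent at v_aser = 0, saturating above
    threshold (the klinokinesis logic function)."""
    head, = _head(params)
    return _apply(state, K.step_smdv, head, v_aser, dt)


def step_head_muscles(state: CircuitState, params: ModelParams, dt: float) -> CircuitState:
    """DM0 driven by SMBD; VM0 by SMBV plus the raw SMDV voltage."""
    head, = _head(params)
    return _apply(state, K.step_head_muscles, head, dt)


def step_vnc_units(state: CircuitState, params: ModelParams, dt: float) -> CircuitState:
    """Update all ten VNC units and recompute Joints 2-11."""
    _, _, _, _, _, vnc, _ = K.pack_params(params)
    return _apply(state, K.step_vnc_units, vnc, dt)


def proprioceptive_current(v: float, theta_own: float, theta_anterior: float,
                           params: ModelParams, side: str = "dorsal") -> float:
    """Shape-feedback current of one B-type neuron.

    The ventral expression is the dorsal one with both joint angles negated.
    """
    if side not in ("dorsal", "ventral"):
        raise ValueError("side must be 'dorsal' or 'ventral'")
    _, _, _, _, _, vnc, _ = K.pack_params(params)
    return float(K.proprioceptive_current(v, theta_own, theta_anterior, vnc,
                                          side == "ventral"))


def step_circuit(state: CircuitState, params: ModelParams,
                 v_asel: float, v_aser: float, dt: float) -> CircuitState:
    """One full network tick (all sub-steps in the fixed composition order)."""
    tau, w, e_rest, bias, head, vnc, _ = K.pack_params(params)
    return _apply(state, K.step_circuit, tau, w, e_rest, bias, head, vnc,
                  v_asel, v_aser, dt)


def _head(params: ModelParams):
    _, _, _, _, head, _, _ = K.pack_params(params)
    return (head,)


def run_open_loop(params: ModelParams, duration: float,
                  state: CircuitState | None = None,
                  v_asel: np.ndarray | float = 0.0,
                  v_aser: np.ndarray | float = 0.0,
                  dt: float | None = None,
                  record_stride: int = 1) -> tuple[pd.DataFrame, CircuitState]:
    """Integrate the circuit for ``duration`` seconds with prescribed sensory
    voltages (scalars are broadcast) and no body.

    Returns a tidy trace table and the final state.  This is the workhorse
    behind rhythm diagnostics, the tuning harness, and the phase-response
    protocol in :mod:`wormnav.metrics`.
    """
    dt = params.sim.dt if dt is None else dt
    n = int(round(duration / dt))
    va = np.broadcast_to(np.asarray(v_asel, dtype=float), (n,)).copy() \
        if np.ndim(v_asel) == 0 else np.asarray(v_asel, dtype=float)
    vr = np.broadcast_to(np.asarray(v_aser, dtype=float), (n,)).copy() \
        if np.ndim(v_aser) == 0 else np.asarray(v_aser, dtype=float)
    if va.size != n or vr.size != n:
        raise ValueError("sensory traces must have duration/dt samples")
    tau, w, e_rest, bias, head, vnc, _ = K.pack_params(params)
    vec = (state or initial_state(params)).to_vector()
    rec = np.zeros((n // max(record_stride, 1) + 2, K.NREC))
    nrec = K.run_circuit(vec, tau, w, e_rest, bias, head, vnc, va, vr, dt,
                         rec, record_stride)
    df = pd.DataFrame(rec[:nrec], columns=K.REC_COLUMNS)
    return df, CircuitState.from_vector(vec)
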