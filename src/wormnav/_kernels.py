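"""Numba-compiled numerical core.

Everything here operates on flat float64 arrays so that the per-tick update
and the closed-loop episode integration can run inside ``@njit`` loops.  The
public modules (:mod:`wormnav.network`, :mod:`wormnav.simulate`, ...) wrap
these kernels behind typed dataclasses; the math lives only here.

State vector layout (``NSTATE`` floats)::

    0:3    v_cpg[3]        CPG neuron voltages, mV
    3      v_smbd          4  v_smbv        5  v_smdv
    6      a_dm0           7  a_vm0         head muscle activations
    8:18   v_db[10]        18:28 v_vb[10]   B-type motoneuron voltages
    28:38  a_dm[10]        38:48 a_vm[10]   VNC muscle activations
    48:59  theta[11]       joint angles, rad (theta[0] = Joint 1)

Sensor state vector (``NASE`` floats)::

    0 v_asel  1 v_aser  2 g_asel  3 g_aser  4 last_c  5 buf_sum  6 buf_pos

The |dC| window ring buffer is passed separately.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------- layout

I_CPG = 0
I_SMBD = 3
I_SMBV = 4
I_SMDV = 5
I_ADM0 = 6
I_AVM0 = 7
I_VDB = 8
I_VVB = 18
I_ADM = 28
I_AVM = 38
I_TH = 48
N_UNITS = 10
NSTATE = 59

# head parameter array indices
H_TAU_SMB = 0
H_E_SMB_REST = 1
H_W_SMBD_C3 = 2
H_W_SMB_ASEL = 3
H_W_SMB_ASER = 4
H_TAU_A0 = 5
H_W_M0_SMB = 6
H_W_M0_SMDV = 7
H_B0M = 8
H_OMEGA0 = 9
H_TAU_SMDV = 10
H_E_SMDV_REST = 11
H_W_SMDV_ASER = 12
H_E_SMDV_ASER = 13
H_B_SMDV = 14
NHEAD = 15

# vnc parameter array indices
V_TAU_B = 0
V_E_B_REST = 1
V_W0 = 2
V_W1 = 3
V_E0 = 4
V_E1 = 5
V_P0 = 6
V_P1 = 7
V_TAU_AM = 8
V_W_AM_B = 9
V_B1M = 10
V_OMEGA1 = 11
NVNC = 12

# sensor parameter array indices
A_TAU = 0
A_E_REST = 1
A_E_EXT = 2
A_GMAX = 3
A_TAU_G = 4
A_A = 5
A_B = 6
NASEP = 7

# sensor state indices
S_VASEL = 0
S_VASER = 1
S_GASEL = 2
S_GASER = 3
S_LASTC = 4
S_BUFSUM = 5
S_BUFPOS = 6
NASE = 7

# trajectory record columns
REC_COLUMNS = (
    ["t", "x", "y", "psi"]
    + [f"theta{i}" for i in range(1, 12)]
    + ["v_smbd", "v_smbv", "v_smdv", "a_dm0", "a_vm0",
       "o_dm0", "o_vm0",
       "v_asel", "v_aser", "g_asel", "g_aser", "c", "c_n"]
)
NREC = len(REC_COLUMNS)


# ---------------------------------------------------------------- packing

def pack_params(params):
    """Flatten a :class:`wormnav.params.ModelParams` into kernel arrays."""
    h = params.head
    head = np.array(
        [h.tau_smb, h.e_smb_rest, h.w_smbd_c3, h.w_smb_asel, h.w_smb_aser,
         h.tau_a0, h.w_m0_smb, h.w_m0_smdv, h.b0m, h.omega0,
         h.tau_smdv, h.e_smdv_rest, h.w_smdv_aser, h.e_smdv_aser, h.b_smdv],
        dtype=np.float64,
    )
    v = params.vnc
    vnc = np.array(
        [v.tau_b, v.e_b_rest, v.w_shape[0], v.w_shape[1],
         v.e_shape[0], v.e_shape[1], v.p[0], v.p[1],
         v.tau_am, v.w_am_b, v.b1m, v.omega1],
        dtype=np.float64,
    )
    a = params.ase
    ase = np.array(
        [a.tau_ase, a.e_ase_rest, a.e_ase_ext, a.g_max, a.tau_g, a.a, a.b],
        dtype=np.float64,
    )
    c = params.cpg
    return (
        np.ascontiguousarray(c.tau), np.ascontiguousarray(c.w),
        np.ascontiguousarray(c.e_rest), np.ascontiguousarray(c.bias),
        head, vnc, ase,
    )


def init_state_vector(params) -> np.ndarray:
    """All voltages at rest, activations zero, straight body."""
    s = np.zeros(NSTATE, dtype=np.float64)
    s[I_CPG:I_CPG + 3] = params.cpg.e_rest
    s[I_SMBD] = params.head.e_smb_rest
    s[I_SMBV] = params.head.e_smb_rest
    s[I_SMDV] = params.head.e_smdv_rest
    s[I_VDB:I_VDB + N_UNITS] = params.vnc.e_b_rest
    s[I_VVB:I_VVB + N_UNITS] = params.vnc.e_b_rest
    return s


def init_ase_state(params, c0: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    st = np.zeros(NASE, dtype=np.float64)
    st[S_VASEL] = params.ase.e_ase_rest
    st[S_VASER] = params.ase.e_ase_rest
    st[S_LASTC] = c0
    buf = np.zeros(params.ase.window_samples, dtype=np.float64)
    return st, buf


# ---------------------------------------------------------------- primitives

@njit(cache=True)
def sigmoid(x: float) -> float:
    """Logistic 1 / (1 + exp(-x)); numerically symmetric around 0."""
    if x >= 0.0:
        z = np.exp(-x)
        return 1.0 / (1.0 + z)
    z = np.exp(x)
    return z / (1.0 + z)


@njit(cache=True)
def fn_norm(x: float, x0: float) -> float:
    """Unit-peak normalisation (x/x0)*exp(1 - x/x0); 0 for x0 <= 0, clamped at 0."""
    if x0 <= 0.0:
        return 0.0
    r = x / x0
    val = r * np.exp(1.0 - r)
    return val if val > 0.0 else 0.0


@njit(cache=True)
def gauss_field(x, y, px, py, cmax, sigma):
    dx = x - px
    dy = y - py
    return cmax * np.exp(-(dx * dx + dy * dy) / (2.0 * sigma * sigma))


# ---------------------------------------------------------------- sub-steps
#
# Each sub-step is forward Euler and mutates the state vector in place, using
# the values written earlier in the same tick (composition order is fixed in
# step_circuit).

@njit(cache=True)
def step_cpg(state, tau, w, e_rest, bias, dt):
    v0 = state[I_CPG]
    v1 = state[I_CPG + 1]
    v2 = state[I_CPG + 2]
    f0 = sigmoid(v0 + bias[0])
    f1 = sigmoid(v1 + bias[1])
    f2 = sigmoid(v2 + bias[2])
    i0 = w[0, 1] * f1 + w[0, 2] * f2
    i1 = w[1, 0] * f0 + w[1, 2] * f2
    i2 = w[2, 0] * f0 + w[2, 1] * f1
    state[I_CPG] = v0 + dt * (-(v0 - e_rest[0]) + i0) / tau[0]
    state[I_CPG + 1] = v1 + dt * (-(v1 - e_rest[1]) + i1) / tau[1]
    state[I_CPG + 2] = v2 + dt * (-(v2 - e_rest[2]) + i2) / tau[2]


@njit(cache=True)
def step_smb(state, head, v_asel, v_aser, dt):
    vc3 = state[I_CPG + 2]
    sens = head[H_W_SMB_ASEL] * v_asel + head[H_W_SMB_ASER] * v_aser
    er = head[H_E_SMB_REST]
    tau = head[H_TAU_SMB]
    wd = head[H_W_SMBD_C3]
    vd = state[I_SMBD]
    vv = state[I_SMBV]
    state[I_SMBD] = vd + dt * (-(vd - er) + wd * vc3 + sens) / tau
    state[I_SMBV] = vv + dt * (-(vv - er) - wd * vc3 + sens) / tau


@njit(cache=True)
def step_smdv(state, head, v_aser, dt):
    # conductance gate: baseline-subtracted logistic, exactly 0 at rest
    gate = sigmoid(v_aser + head[H_B_SMDV]) - sigmoid(head[H_B_SMDV])
    g = head[H_W_SMDV_ASER] * gate
    v = state[I_SMDV]
    dv = (-(v - head[H_E_SMDV_REST]) - g * (v - head[H_E_SMDV_ASER])) / head[H_TAU_SMDV]
    state[I_SMDV] = v + dt * dv


@njit(cache=True)
def step_head_muscles(state, head, dt):
    tau = head[H_TAU_A0]
    ad = state[I_ADM0]
    av = state[I_AVM0]
    state[I_ADM0] = ad + dt * (-ad + head[H_W_M0_SMB] * state[I_SMBD]) / tau
    state[I_AVM0] = av + dt * (-av + head[H_W_M0_SMB] * state[I_SMBV]
                               + head[H_W_M0_SMDV] * state[I_SMDV]) / tau


@njit(cache=True)
def update_theta1(state, head):
    od = sigmoid(state[I_ADM0] + head[H_B0M])
    ov = sigmoid(state[I_AVM0] + head[H_B0M])
    state[I_TH] = head[H_OMEGA0] * (od - ov)


@njit(cache=True)
def proprioceptive_current(v, th_own, th_ant, vnc, ventral):
    """Shape-feedback current of one B-type neuron (Ohmic, conductance form)."""
    s = -1.0 if ventral else 1.0
    g0 = vnc[V_W0] * sigmoid(s * vnc[V_P0] * th_own)
    g1 = vnc[V_W1] * sigmoid(s * vnc[V_P1] * th_ant)
    return g0 * (v - vnc[V_E0]) + g1 * (v - vnc[V_E1])


@njit(cache=True)
def step_vnc_units(state, vnc, dt):
    # Pass 1: all B-neuron voltages from the current joint angles
    # (theta[0] already updated this tick, theta[1:] from the previous tick).
    for i in range(N_UNITS):
        th_own = state[I_TH + i + 1]
        th_ant = state[I_TH + i]
        vdb = state[I_VDB + i]
        vvb = state[I_VVB + i]
        idb = proprioceptive_current(vdb, th_own, th_ant, vnc, False)
        ivb = proprioceptive_current(vvb, th_own, th_ant, vnc, True)
        state[I_VDB + i] = vdb + dt * (-(vdb - vnc[V_E_B_REST]) - idb) / vnc[V_TAU_B]
        state[I_VVB + i] = vvb + dt * (-(vvb - vnc[V_E_B_REST]) - ivb) / vnc[V_TAU_B]
    # Pass 2: muscle activations from the fresh voltages, then joint angles.
    for i in range(N_UNITS):
        ad = state[I_ADM + i]
        av = state[I_AVM + i]
        ad += dt * (-ad + vnc[V_W_AM_B] * state[I_VDB + i]) / vnc[V_TAU_AM]
        av += dt * (-av + vnc[V_W_AM_B] * state[I_VVB + i]) / vnc[V_TAU_AM]
        state[I_ADM + i] = ad
        state[I_AVM + i] = av
        od = sigmoid(ad + vnc[V_B1M])
        ov = sigmoid(av + vnc[V_B1M])
        state[I_TH + i + 1] = vnc[V_OMEGA1] * (od - ov)


@njit(cache=True)
def step_circuit(state, tau, w, e_rest, bias, head, vnc, v_asel, v_aser, dt):
    """One full network tick: CPG -> SMB -> SMDV -> head muscles -> theta1 -> VNC."""
    step_cpg(state, tau, w, e_rest, bias, dt)
    step_smb(state, head, v_asel, v_aser, dt)
    step_smdv(state, head, v_aser, dt)
    step_head_muscles(state, head, dt)
    update_theta1(state, head)
    step_vnc_units(state, vnc, dt)


# ---------------------------------------------------------------- sensors

@njit(cache=True)
def step_sensor(ase_state, buf, c_now, ase, dt, adaptive):
    """One sensory sample: dC, windowed mean |dC|, conductances, voltages.

    Returns the windowed mean C_N (for tracing)."""
    dc = c_now - ase_state[S_LASTC]
    ase_state[S_LASTC] = c_now
    adc = abs(dc)
    # ring-buffer windowed mean of |dC| (current sample included)
    pos = int(ase_state[S_BUFPOS])
    ase_state[S_BUFSUM] += adc - buf[pos]
    buf[pos] = adc
    pos += 1
    if pos >= buf.size:
        pos = 0
    ase_state[S_BUFPOS] = pos
    cn = ase_state[S_BUFSUM] / buf.size
    if cn < 0.0:
        cn = 0.0  # guard against float drift of the running sum
    # conductances: set on the preferred sign of dC, decay otherwise
    if adaptive:
        drive = ase[A_A] * adc / (1.0 + ase[A_B] * cn)
    else:
        drive = ase[A_A] * adc
    if dc > 0.0:
        ase_state[S_GASEL] = ase[A_GMAX] * np.tanh(drive)
        ase_state[S_GASER] += dt * (-ase_state[S_GASER] / ase[A_TAU_G])
    elif dc < 0.0:
        ase_state[S_GASER] = ase[A_GMAX] * np.tanh(drive)
        ase_state[S_GASEL] += dt * (-ase_state[S_GASEL] / ase[A_TAU_G])
    else:
        ase_state[S_GASEL] += dt * (-ase_state[S_GASEL] / ase[A_TAU_G])
        ase_state[S_GASER] += dt * (-ase_state[S_GASER] / ase[A_TAU_G])
    # conductance-based voltage update
    for k in range(2):
        v = ase_state[S_VASEL + k]
        g = ase_state[S_GASEL + k]
        dv = (-(v - ase[A_E_REST]) - g * (v - ase[A_E_EXT])) / ase[A_TAU]
        ase_state[S_VASEL + k] = v + dt * dv
    return cn


# ---------------------------------------------------------------- loops

@njit(cache=True)
def run_circuit(state, tau, w, e_rest, bias, head, vnc,
                v_asel_trace, v_aser_trace, dt, rec, rec_stride):
    """Drive the circuit with prescribed sensory voltage traces.

    ``rec`` has shape (n_rows, NREC); rows are written every ``rec_stride``
    ticks (kinematic columns stay 0 -- this loop has no body).  Returns the
    number of rows written.
    """
    n = v_asel_trace.size
    nrec = 0
    for k in range(n):
        step_circuit(state, tau, w, e_rest, bias, head, vnc,
                     v_asel_trace[k], v_aser_trace[k], dt)
        if rec_stride > 0 and k % rec_stride == 0:
            _write_row(rec, nrec, (k + 1) * dt, 0.0, 0.0, 0.0, state, head,
                       v_asel_trace[k], v_aser_trace[k], 0.0, 0.0, 0.0, 0.0)
            nrec += 1
    return nrec


@njit(cache=True)
def run_sensed_circuit(state, ase_state, buf, tau, w, e_rest, bias, head, vnc,
                       ase, c_trace, dt, adaptive, rec, rec_stride):
    """Drive the circuit with a prescribed concentration trace through the
    ASEL/ASER sensors (no body motion).  Returns rows written."""
    n = c_trace.size
    nrec = 0
    for k in range(n):
        cn = step_sensor(ase_state, buf, c_trace[k], ase, dt, adaptive)
        va = ase_state[S_VASEL]
        vr = ase_state[S_VASER]
        step_circuit(state, tau, w, e_rest, bias, head, vnc, va, vr, dt)
        if rec_stride > 0 and k % rec_stride == 0:
            _write_row(rec, nrec, (k + 1) * dt, 0.0, 0.0, 0.0, state, head,
                       va, vr, ase_state[S_GASEL], ase_state[S_GASER],
                       c_trace[k], cn)
            nrec += 1
    return nrec


@njit(cache=True)
def _write_row(rec, row, t, x, y, psi, state, head,
               v_asel, v_aser, g_asel, g_aser, c, cn):
    rec[row, 0] = t
    rec[row, 1] = x
    rec[row, 2] = y
    rec[row, 3] = psi
    for j in range(11):
        rec[row, 4 + j] = state[I_TH + j]
    rec[row, 15] = state[I_SMBD]
    rec[row, 16] = state[I_SMBV]
    rec[row, 17] = state[I_SMDV]
    rec[row, 18] = state[I_ADM0]
    rec[row, 19] = state[I_AVM0]
    rec[row, 20] = sigmoid(state[I_ADM0] + head[H_B0M])
    rec[row, 21] = sigmoid(state[I_AVM0] + head[H_B0M])
    rec[row, 22] = v_asel
    rec[row, 23] = v_aser
    rec[row, 24] = g_asel
    rec[row, 25] = g_aser
    rec[row, 26] = c
    rec[row, 27] = cn


@njit(cache=True)
def run_episode(state, ase_state, buf, tau, w, e_rest, bias, head, vnc, ase,
                speed, steer_tau,
                px, py, cmax, sigma,
                x0, y0, psi0,
                dt, warmup_steps, max_steps, adaptive, arrival_radius,
                rec, rec_stride):
    """Closed-loop episode: sense at the head tip -> circuit -> steer -> move.

    The circuit warms up in place (zero sensory input, body frozen); motion
    and sensing start at t = 0.  Returns (arrived, arrival_time, min_dist,
    n_rows); arrival_time is NaN when the peak was not reached."""
    for _ in range(warmup_steps):
        step_circuit(state, tau, w, e_rest, bias, head, vnc, 0.0, 0.0, dt)
    x = x0
    y = y0
    psi = psi0
    ase_state[S_LASTC] = gauss_field(x, y, px, py, cmax, sigma)
    r2 = arrival_radius * arrival_radius
    min_d2 = (x - px) ** 2 + (y - py) ** 2
    arrived = False
    arrival_time = np.nan
    nrec = 0
    for k in range(max_steps):
        c = gauss_field(x, y, px, py, cmax, sigma)
        cn = step_sensor(ase_state, buf, c, ase, dt, adaptive)
        va = ase_state[S_VASEL]
        vr = ase_state[S_VASER]
        step_circuit(state, tau, w, e_rest, bias, head, vnc, va, vr, dt)
        psi += (state[I_TH] / steer_tau) * dt
        x += speed * dt * np.cos(psi)
        y += speed * dt * np.sin(psi)
        d2 = (x - px) ** 2 + (y - py) ** 2
        if d2 < min_d2:
            min_d2 = d2
        if rec_stride > 0 and k % rec_stride == 0:
            _write_row(rec, nrec, (k + 1) * dt, x, y, psi, state, head,
                       va, vr, ase_state[S_GASEL], ase_state[S_GASER], c, cn)
            nrec += 1
        if d2 <= r2:
            arrived = True
            arrival_time = (k + 1) * dt
            break
    return arrived, arrival_time, np.sqrt(min_d2), nrec


# ---------------------------------------------------------------- CPG-only

@njit(cache=True)
def cpg_trace(tau, w, e_rest, bias, dt, n_steps):
    """Simulate the isolated CPG from rest; returns the C3 voltage trace."""
    v0 = e_rest[0]
    v1 = e_rest[1]
    v2 = e_rest[2]
    out = np.empty(n_steps, dtype=np.float64)
    for k in range(n_steps):
        f0 = sigmoid(v0 + bias[0])
        f1 = sigmoid(v1 + bias[1])
        f2 = sigmoid(v2 + bias[2])
        n0 = v0 + dt * (-(v0 - e_rest[0]) + w[0, 1] * f1 + w[0, 2] * f2) / tau[0]
        n1 = v1 + dt * (-(v1 - e_rest[1]) + w[1, 0] * f0 + w[1, 2] * f2) / tau[1]
        n2 = v2 + dt * (-(v2 - e_rest[2]) + w[2, 0] * f0 + w[2, 1] * f1) / tau[2]
        v0 = n0
        v1 = n1
        v2 = n2
        out[k] = v2
    return out


@njit(cache=True)
def fitness_from_trace(trace, tosc, dt):
    """Oscillation fitness (F, F1, F2, F3) of a voltage trace.

    F1 rewards zero mean, F2 equal positive/negative amplitudes, F3 a mean
    |dV/dt| matching that of a sinusoid of period ``tosc`` (4*max/tosc);
    components are clamped at 0 and F is their product."""
    n = trace.size
    mean = 0.0
    vmax = trace[0]
    vmin = trace[0]
    for i in range(n):
        v = trace[i]
        mean += v
        if v > vmax:
            vmax = v
        if v < vmin:
            vmin = v
    mean /= n
    slope_sum = 0.0
    for i in range(1, n):
        slope_sum += abs(trace[i] - trace[i - 1])
    mean_slope = slope_sum / ((n - 1) * dt)
    f1 = 1.0 - abs(mean)
    if f1 < 0.0:
        f1 = 0.0
    f2 = fn_norm(vmax if vmax > 0.0 else 0.0, -vmin)
    x0 = 4.0 * vmax / tosc
    f3 = fn_norm(mean_slope, x0)
    return f1 * f2 * f3, f1, f2, f3


@njit(cache=True)
def cpg_fitness(tau, w, e_rest, bias, dt, skip, horizon, tosc):
    """Simulate the CPG and score the post-transient C3 trace."""
    n_skip = int(round(skip / dt))
    n_total = n_skip + int(round(horizon / dt))
    trace = cpg_trace(tau, w, e_rest, bias, dt, n_total)
    return fitness_from_trace(trace[n_skip:], tosc, dt)
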