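# Methods

This note documents the model as implemented: its equations, the parameter
choices that matter, the numerical decisions, what the synthetic benchmark
does and does not emulate, and the known limitations.

## Circuit equations and integration

All neurons are leaky integrators and all muscles first-order activation
filters, advanced by forward Euler at dt = 0.01 s. One tick applies, in
fixed order: CPG → SMB motoneurons → SMDV → head muscles → Joint 1 → the
ten VNC units → Joints 2–11. Sub-steps use values already written in the
same tick (Gauss–Seidel style); the order is part of the model definition
and is exercised by the determinism tests. The synaptic nonlinearity is the
logistic `f(x) = 1/(1+e^-x)` throughout, matching the (0, 1) muscle-output
range the gating mechanism depends on.

Forward Euler at dt = 0.01 s carries a measurable first-order bias on the
limit cycle: the free-running period is ~0.7% long and the Joint-1
amplitude ~3.5% large relative to the dt → 0 limit. The convergence test
asserts exactly this first-order behaviour (errors halve from dt = 0.01 to
0.005 to 0.0025) plus phase-aligned waveform agreement, rather than raw
trace agreement, because the period error accumulates as phase drift over
multiple cycles.

## CPG evolution

The 15 CPG parameters are evolved by a steady-state GA: population 500 in
[-1, 1]^15, two random parents per event, two-point crossover, per-gene
Gaussian mutation (s.d. 0.2, clamped), unconditional replacement of the
worse parent; one "generation" is defined as 500 replacement events, and a
round stops at 300 generations or when the best fitness exceeds 0.98.
Because 3 time constants + 3 resting potentials + 3 biases leave exactly 6
weights, the connectivity is the six directed off-diagonal connections
among C1–C3 (no self-loops) — the minimal reading of "three interconnected
neurons" consistent with the 15-parameter count.

The fitness `F = F1·F2·F3` is evaluated on the C3 trace over a 16 s window
after an 8 s transient: `F1 = 1 - |mean|`, `F2 = fN(max, -min)`,
`F3 = fN(mean|dV/dt|, 4·max/Tosc)` with `fN(x, x0) = (x/x0)·e^(1-x/x0)`,
negative values clamped to zero. F is maximised by any pure sinusoid of
period Tosc = 4 s regardless of amplitude — but it is nearly flat in the
period near the optimum (a 10% period error costs well under 1% of F), so
a single run pins the period only to within roughly ±0.5 s. `evolve()`
therefore treats the GA output as a pool: every distinct champion and
population leader of a round is re-simulated over 200 s, damped solutions
are discarded (final-five-cycle amplitude must be ≥ 0.9× that of cycles
5–10), and among the sustained oscillators the one with the
zero-crossing period closest to 4 s is kept; up to eight rounds run from one
seeded stream, stopping early once the period is within 0.1 s. Selecting
the final individual against the oscillation goal from multiple evolved
solutions is part of the procedure, not a post-hoc filter.

## Hand-tuned parameters and the tuning harness

Everything outside the CPG (head circuit, VNC unit, sensors, steering
gains) is hand-tuned; the repository ships one default parameter file
(`wormnav/data/default_params.yaml`) and the harness that produced it
(`wormnav.tuning`: `rhythm_diagnostics`, `random_search`, plus
Nelder–Mead refinement on the diagnostic scores). The tuning objectives
are the model's behavioural invariants:

* SMBD/SMBV antiphase correlation > 0.99 at half-period shift;
* zero-input straightness: |net turn| < 0.5°/cycle (the default achieves
  0.002°/cycle — this also required a final local polish of the CPG genes
  against the full head-circuit straightness, since a residual C3 mean of
  even 0.05 mV otherwise bends the path by degrees per cycle);
* per-unit propagation lag 0.40 ± 0.05 s, uniform along the body, with
  Joint 11 synchronised to Joint 1 within 0.1 s;
* wavelength/body length 0.83 ± 0.03;
* the gating phase-response sign structure (state dependence, sensory
  dependence, near-zero steering at zero-perpendicular phases);
* benchmark arrival rate 1.0 and the search-time-ratio ordering of the
  three variants.

Key tuned values and why:

* `steer_tau = 0.4 s = l/v`. The heading rule is
  `psi_dot = theta1/steer_tau`; with steer_tau equal to the rod transit
  time, theta1 equals the heading first-difference `psi(t) - psi(t - l/v)`,
  which is exactly the condition for the reconstructed body to lie along
  the recent trajectory as a travelling wave. All eleven joints then share
  one amplitude, and wavelength/L = v·Tosc/L emerges without further
  tuning. (A net theta1 asymmetry integrates into a permanent heading
  change, so the cumulative dorsal–ventral output difference is the
  steering measure, as in the phase-response analysis.)
* `b0m = -2.5`, `omega0 = 0.869`: the head-muscle outputs alternately
  saturate near zero for half of each cycle (the gating), and the Joint-1
  amplitude of 0.51 rad gives a heading sweep of ±0.75 rad. The sweep
  amplitude is a real trade-off: it costs forward progress (the net
  advance per cycle is J0(0.75) ≈ 0.86 of the path length) but provides
  the transverse concentration sampling klinotaxis needs; shrinking it
  below ~0.6 rad degrades steering faster than it saves path.
* VNC unit (`tau_b ≈ tau_am ≈ 0.5 s`, anterior-drive and self-feedback
  conductances): tuned so each unit reproduces its anterior joint's
  waveform at unit gain with a 0.40 s lag; ten lags then span one cycle.
* Sensors (`a = 600, b = 4800 1/mM`, window N = 10 s, `tau_ase = 0.5 s`,
  `tau_g = 0.3 s`, `g_max = 2`, `E_ext = 15 mV`): with b·C_N >> 1 the
  drive becomes `(a/b)·|dC|/C_N`, i.e. scale-free in the gradient — the
  property that lets one parameter set cover 50–1400 mM peaks. The ratio
  a/b = 0.125 keeps the tanh in its linear range, which matters: a
  saturated ON-cell response is constant over the cycle, and a constant
  ASEL input suppresses the swing without steering. With strong
  saturation the model can trap itself on a logarithmic spiral (any
  heading with a positive radial component sustains ASEL, which kills the
  very sweep that would correct the heading); the linearised drive plus
  the asymmetric SMB weights below eliminate this trap.
* `w_smb_asel = -0.3`, `w_smb_aser = +0.6`: ASEL inhibits, ASER excites
  both SMB neurons (the sensory-dependence sign requirement). The
  asymmetry keeps the ASER-driven "enlarge the swing when things get
  worse" reflex strong while limiting the ASEL-driven swing reduction to
  a level that shortens the path without extinguishing the oscillation.
* SMDV gate (`b_smdv = -2`, `w_smdv_aser = 2`, `E_smdv_aser = 20 mV`,
  `tau_smdv = 0.35 s`, `w_m0_smdv = 0.5`): the ASER→SMDV synapse uses the
  baseline-subtracted logistic `f(v_aser + b_smdv) - f(b_smdv)`, which is
  exactly zero at rest and saturating above threshold — a thresholded
  logic function. The printed form without the bias would leave SMDV
  half-activated at rest, contradicting the intended silent-at-rest
  behaviour; the added threshold bias is the one extra head parameter this
  implementation introduces. The threshold ignores the ASER blips that
  normal sweeping produces and responds to the sustained depolarisation of
  genuinely falling concentration; `tau_smdv` sets how crisply the turn
  starts and stops.

## Sensing details

dC is the difference between consecutive 0.01 s samples (the sampling
interval equals the integration step). C_N is the arithmetic mean of |dC|
over a ring buffer spanning the last 10 s, zero-prefilled, with the current
sample included; a window of 2.5 undulation cycles averages over the sweep
while still tracking scenario-scale changes. In non-adaptive mode the
divisor is dropped (`g = g_max·tanh(a·|dC|)`) and the coefficient `a` is
set per run (15, 30 or 45 in the benchmark comparisons). The sensor
resting potential is 0 mV and the synaptic reversal +15 mV; the voltage
equation depolarises toward the reversal while the conductance is open and
relaxes to rest otherwise.

## Episodes, benchmark, and metrics

An episode warms the circuit up for 10 s in place (zero sensory input,
body frozen) so the rhythm is established and the dC history starts clean;
motion and sensing begin at t = 0 from the configured pose. Note that the
configured heading is the *instantaneous* heading; the mean travel
direction differs from it by up to the sweep amplitude depending on the
rhythm phase at onset. Per tick: sample the field at the head tip → sensor
update → circuit tick → heading and position update → arrival test
(distance to peak ≤ 1 mm). The timeout is 10× the straight-line travel
time. Episodes contain no randomness.

The benchmark suite is 10 scenarios (peak at the origin, peak
concentration linearly spaced 50–1400 mM, σ = 15 mm fixed) × 4 start
positions ((20, −10), (−20, 10), (15, 15), (−15, −15) mm — symmetric
placements 21–23 mm out, where the field still has a usable gradient) ×
10 evenly spaced headings. σ is not printed in the study conditions; 15 mm
makes the start positions sit near the gradient maximum of the shallowest
scenario. Only the peak concentration varies across scenarios.

SSR = arrival time / (initial straight-line distance / v), pooled over
arrived episodes; arrival rate is the arrived fraction. Cycle statistics
cut the trajectory at upward zero crossings of theta1; the turning bias is
the signed angle between consecutive cycles' net-displacement directions;
the normal gradient is the field gradient component 90° CCW of the
translation direction, averaged along the cycle's path. For the
strategy-quantification tables, gradients are normalised to [-1, 1] by
their maximum absolute value (sign- and zero-preserving, so "positive
gradient bins" are genuinely positive gradients) and binned into 20
equal-width bins; correlations are Pearson on cycle-level points.

The undulation wavelength is measured from a body snapshot as the spacing
of alternate zero crossings of the nodes' lateral offsets (perpendicular
to the translation direction), with the crossings located in arc length
along the body. The projection of the body onto the translation axis is
compressed by the factor J0(sweep amplitude) < 1, so a projected-axis
measure could never reach the travelling-wave value v·Tosc/L; the
arc-length measure is invariant to that compression. Because a single
snapshot's crossing count fluctuates over the cycle, the reported ratio
averages snapshots across one cycle.

The phase-response protocol (for the gating analysis) runs the circuit to
steady oscillation at constant concentration, clones the full state at
evenly spaced phases (phase 0 = upward zero crossing of theta1), steps the
concentration up or down in the clone, integrates both clones for half a
cycle, and reports the integral of the perturbed-minus-reference
dorsal-minus-ventral head-muscle output — the net steering command the
stimulus injected. The scans are run on the circuit with the SMDV pathway
severed, so they measure the gating mechanism alone.

## Ablations and variants

Strategy ablations act on parameters: klinotaxis-only zeroes `w_m0_smdv`
(severing SMDV→VM0), klinokinesis-only zeroes `w_smb_asel` and
`w_smb_aser` (severing the sensory gating of SMB). Which weights to zero
is an implementation choice; these are the minimal cuts that disable one
strategy without touching the shared rhythm machinery.

## What the benchmark does and does not show

The environment is a static, noise-free, single-peak Gaussian field and
the body is kinematic. Passing the suite shows that the circuit-level
mechanisms (rhythm generation, proprioceptive propagation, adaptive
single-point sensing, gated steering) compose into robust, near-shortest-
path search across a 28-fold gradient range, and that each strategy
contributes what the ablations say it contributes. It does not demonstrate
robustness to sensor noise, turbulent or time-varying fields, multi-peak
landscapes, or ground mechanics (friction, slip) — a physical body will
not track the commanded wave exactly. Ω-turn-like shapes appear
qualitatively during sharp klinokinesis turns but are not quantified.

## Problem sizes used

The shipped test-and-acceptance workloads use: 100 s rhythm runs for the
locomotion diagnostics; the full 400-episode suite per variant for arrival
and SSR statistics (the subset checks use 80–120 episodes); a reduced
120-episode recorded set for the cycle-level strategy tables; and one full
GA run (≤ 6 rounds internally) for the evolved-period check.

## Known limitations

* The steady-state GA with unconditional replacement (as specified)
  converges slowly and its fitness is period-flat near the optimum; the
  period of the returned oscillator is guaranteed only through the
  multi-round stable-candidate selection, and rare seeds may exhaust all
  rounds and return a period up to a few hundred ms off the goal.
* The straightness of zero-input travel depends on a CPG whose waveform
  was polished against the full head circuit; substituting a freshly
  evolved CPG into the default head parameters will generally travel in a
  wide arc until re-polished (`wormnav.tuning`).
* Sensor adaptation normalises to the *ratio* |dC|/C_N, so a constant
  gradient never fully adapts away; sustained ASEL activity mildly
  suppresses the swing on long straight climbs. This is by design (it
  shortens paths) but means the model is not a general-purpose adapting
  sensor front end.
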