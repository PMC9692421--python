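# wormnav

A neural-network autonomous-search model with undulatory locomotion,
inspired by the chemotaxis of *Caenorhabditis elegans*.

## The problem and who this is for

Small gradient-seeking robots (chemical-leak location, radiation survey)
usually carry a single scalar sensor, which rules out directly measuring a
spatial gradient. *C. elegans* solves the same problem: it senses salt at a
single point on its head, yet climbs concentration gradients along paths
close to the steepest ascent, by combining two strategies —
**klinokinesis** (sharp corrective turns whenever the concentration sampled
along the path is falling) and **klinotaxis** (gradual steering toward the
higher side, extracted from the concentration oscillation its own sinusoidal
gait produces). `wormnav` is a complete, deterministic simulation of such a
model for researchers in bio-inspired navigation and computational
neuroscience: a 12-rod kinematic body driven by a small neural circuit, with
benchmarking and trajectory-analysis tools around it.

## The model

* **CPG.** Three coupled leaky-integrator neurons,
  `tau_i dV_i/dt = -(V_i - E_i^rest) + sum_j w_ij f(V_j + b_j)` with logistic
  `f`. The 15 free parameters (3 time constants, 6 off-diagonal weights,
  3 resting potentials, 3 biases) are evolved by a steady-state GA
  (population 500, two-point crossover, Gaussian mutation s.d. 0.2) so that
  the output neuron C3 oscillates sinusoidally with period Tosc = 4 s. The
  fitness `F = F1·F2·F3` rewards zero mean, symmetric amplitudes, and a mean
  |dV/dt| equal to that of a sinusoid of the target period; damped solutions
  are rejected by a long-horizon re-check.
* **Head circuit.** C3 drives the SMBD/SMBV motoneurons in antiphase; they
  drive the DM0/VM0 head muscles, whose output difference through a
  saturating nonlinearity sets the Joint-1 angle. A strongly negative
  muscle bias parks each output near zero for half of every cycle — the
  **state-dependent gating** that makes the response to a sensory input
  depend on the locomotion phase.
* **Wave propagation.** Ten identical ventral-nerve-cord units (a DB/VB
  neuron pair plus a DM/VM muscle pair each) read their own and the anterior
  joint angle through proprioceptive conductances and reproduce the
  anterior waveform with a Tosc/10 = 0.4 s lag, so Joints 2–11 carry the
  head's bending wave tail-ward and the body always holds one full spatial
  wave (wavelength/body length ≈ v·Tosc/L = 0.83).
* **Chemosensors.** ASEL (ON) and ASER (OFF) are conductance-based neurons
  driven by `g = g_max · tanh(a·|dC| / (1 + b·C_N))` on their preferred sign
  of dC, where `C_N` is the mean |dC| over the last 10 s. The divisive
  adaptation makes the response depend on the *relative* gradient, so one
  parameter set works across peak concentrations from 50 to 1400 mM.
* **Steering.** Klinotaxis: ASEL inhibits and ASER excites both SMB
  neurons; through the gating this steers the model toward the higher side
  every cycle. Klinokinesis: ASER drives the SMDV interneuron through a
  thresholded saturating gate; SMDV adds to VM0 and produces a sustained
  right turn while the sampled concentration keeps falling.
* **Body.** Kinematic, not dynamic: the head tip moves at constant
  v = 0.25 mm/s along a heading whose rate is the commanded Joint-1 bend;
  the 13 node positions follow by chaining 0.1 mm rods through the 11 joint
  angles.

Everything is integrated with forward Euler at dt = 0.01 s and is fully
deterministic given a configuration.

## A worked example

```bash
python examples/03_single_search_episode.py
```

prints (abridged):

```
arrived      : True
arrival time : 95.7 s
shortest time: 89.4 s
SSR          : 1.069

trajectory (every 20 s):
  t=   0.0 s  pos=( +20.00,  -10.00) mm  dist to peak= 22.36 mm
  t=  20.0 s  pos=( +16.32,   -6.90) mm  dist to peak= 17.72 mm
  t=  40.0 s  pos=( +12.46,   -4.15) mm  dist to peak= 13.14 mm
  t=  60.0 s  pos=(  +8.37,   -1.80) mm  dist to peak=  8.56 mm
  t=  80.0 s  pos=(  +4.06,   +0.05) mm  dist to peak=  4.07 mm
```

The model starts 22.4 mm from the peak, initially heading *away* from it,
reorients within a few undulation cycles and reaches the 1 mm arrival zone
in 95.7 s — a search-time ratio (SSR, search time over straight-line time)
of 1.07, i.e. a path within 7% of the unreachable straight-line optimum.
The other scripts in `examples/` evolve the CPG, verify the locomotor
rhythm, benchmark the three steering variants, and map the sensor's
adaptive response surface.

There is also a thin CLI: `wormnav evolve-cpg`, `wormnav run`,
`wormnav benchmark`, `wormnav analyze` (see `wormnav --help`).

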