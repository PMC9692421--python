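cpg:
  tau:
  - 0.530862
  - 1.940133
  - 1.722861
  w:
  - - 0.0
    - -10.0
    - 10.0
  - - -8.925873
    - 0.0
    - -8.844229
  - - -4.350513
    - 9.978277
    - 0.0
  e_rest:
  - 4.542936
  - 1.327054
  - -4.88872
  bias:
  - -1.583793
  - 8.791314
  - -0.230869
head:
  tau_smb: 0.05
  e_smb_rest: 0.0
  w_smbd_c3: 2.127032
  w_smb_asel: -0.3
  w_smb_aser: 0.6
  tau_a0: 0.2
  w_m0_smb: 1.0
  w_m0_smdv: 0.5
  b0m: -2.5
  omega0: 0.869
  tau_smdv: 0.35
  e_smdv_rest: 0.0
  w_smdv_aser: 2.0
  e_smdv_aser: 20.0
  b_smdv: -2.0
vnc:
  tau_b: 0.50174
  e_b_rest: 0.0
  w_shape:
  - 0.83487
  - 1.76012
  e_shape:
  - -5.2869
  - 10.55915
  p:
  - 4.98925
  - 6.7402
  tau_am: 0.49467
  w_am_b: 0.98326
  b1m: -5.01248
  omega1: 2.13057
ase:
  tau_ase: 0.5
  e_ase_rest: 0.0
  e_ase_ext: 15.0
  g_max: 2.0
  tau_g: 0.3
  a: 600.0
  b: 4800.0
  window_n: 10.0
  sample_dt: 0.01
body:
  rod_length: 0.1
  n_rods: 12
  speed: 0.25
  steer_tau: 0.4
sim:
  dt: 0.01
  warmup: 10.0
  arrival_radius: 1.0
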