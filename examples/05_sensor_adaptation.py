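"""Adaptive response surface of the ASEL chemosensor.

Probes the ON-cell with single concentration up-steps of varying size dC
after preloading its adaptation window with different recent-gradient
levels C_N, and prints the peak voltage surface: the response grows with
dC and shrinks with C_N, which is what lets one parameter set operate
across peak concentrations from 50 to 1400 mM.
"""

import numpy as np

from wormnav import default_params
from wormnav.sensing import ASEState, sense

p = default_params().ase
dcs = [0.002, 0.005, 0.01, 0.02, 0.05]
cns = [0.0, 0.002, 0.01, 0.05]

print("ASEL peak voltage (mV); rows = dC (mM), cols = C_N (mM)")
print("  dC \\ C_N " + "".join(f"{cn:>9.3f}" for cn in cns))
for dc in dcs:
    peaks = []
    for cn in cns:
        st = ASEState.at_rest(p, c0=10.0)
        st.history[:] = cn
        st.buf_sum = cn * st.history.size
        peak = 0.0
        for _ in range(150):
            va, _ = sense(st, 10.0 + dc, p)
            peak = max(peak, va)
        peaks.append(peak)
    print(f"  {dc:8.3f} " + "".join(f"{v:9.3f}" for v in peaks))
print("\nEach column is monotone in dC; each row decreases with C_N:")
print("high sensitivity after quiet stretches, damped after steep ones.")
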