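"""Correlation shaping: how input rate redistributes pair correlation over timescales.

Computes the linear-response windowed spike-count correlation rho_T for the
two balanced states at fixed input correlation c = 0.1 and prints the
high/low ratio curve — the signature of correlation shaping: synchrony
(small windows) is enhanced by the high state while long-timescale
correlation is suppressed, with a single crossing of 1.
"""

import numpy as np

from corrshape import (
    canonical_states,
    default_windows,
    effective_params,
    rho_T_theory,
    shaping_ratio,
    spectral_response,
)

c_in = 0.1
low, high = canonical_states()
curves = {}
for st in (low, high):
    eff = effective_params(st.neuron, st.drive)
    spec = spectral_response(eff, st.neuron)
    curves[st.label] = rho_T_theory(spec, eff.sigma, c_in, default_windows())

ratio = shaping_ratio(curves["low"], curves["high"])
print(f"input correlation c = {c_in}")
print("T (ms)   rho_low   rho_high   high/low")
for T, rl, rh, r in zip(ratio.windows, curves["low"].rho, curves["high"].rho, ratio.ratio):
    print(f"{T:7.1f}  {rl:8.4f}  {rh:8.4f}  {r:8.3f}")
print(f"\nThe ratio decreases with window size and crosses 1 once, at "
      f"T = {ratio.crossings[0]:.1f} ms: the high-rate state favors spike")
print("synchrony over firing-rate co-variation at identical input correlation")
print("and identical 15 Hz output rate — correlation shaping.")
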