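"""The low and high balanced input states of a conductance-driven LIF neuron.

Builds the two canonical states (excitation 1.50 vs 6.16 kHz, inhibition
balanced so both fire at 15 Hz), prints the derived diffusion parameters,
and verifies the Fokker-Planck statistics against a stochastic simulation.
"""

import numpy as np

from corrshape import (
    canonical_states,
    effective_params,
    isi_moments,
    steady_state_rate,
    simulate_pair_diffusion,
    summarize,
)

low, high = canonical_states()
print("state   nu_E    nu_I    g_tot  tau_eff  V_inf   sigma   rate    CV")
for st in (low, high):
    eff = effective_params(st.neuron, st.drive)
    r0 = steady_state_rate(eff, st.neuron)
    _, cv = isi_moments(eff, st.neuron)
    print(
        f"{st.label:5s} {st.drive.nu_E:6.2f} {st.drive.nu_I:7.2f} "
        f"{eff.g_tot:7.1f} {eff.tau_eff:7.2f} {eff.V_inf:7.2f} "
        f"{eff.sigma:6.3f} {r0:6.2f} {cv:6.3f}"
    )

print("\nRaising the balanced input rate speeds the membrane (smaller tau_eff)")
print("and increases the current noise (sigma) while the equilibrium potential")
print("and the 15 Hz output rate barely move: the classic high-conductance shift.")

res = simulate_pair_diffusion(low, c=0.0, duration=60_000.0, seed=1)
s = summarize(res.trains[0])
print(f"\n60 s Euler-Maruyama check (low state): rate = {s['rate']:.2f} Hz, "
      f"ISI CV = {s['cv_isi']:.3f}  (theory: 15.00 Hz, 0.729)")
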