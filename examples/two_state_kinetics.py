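"""Two-state kinetics: energies, rates, lifetimes, and simulated dwells.

Builds the Arrhenius two-state model for a nucleosome-like landscape
(delta_G = 1.5 kBT, barrier 9 kBT), prints the derived rates and lifetimes,
inverts measured lifetimes back to energies, and checks a simulated state
trajectory against the analytic dwell times.
"""

import numpy as np

from alexfret import (
    TwoStateModel,
    energies_from_lifetimes,
    simulate_state_trajectory,
)

model = TwoStateModel.from_barrier(9.0, 1.5)
print(f"G_barrier = 9 kBT, delta_G = 1.5 kBT, ks = {model.ks:.0e} /s")
print(f"  k12 = {model.k12:7.1f} /s   k21 = {model.k21:7.1f} /s")
print(f"  tau1 = {model.tau1*1e3:5.2f} ms  tau2 = {model.tau2*1e3:5.2f} ms")
print(f"  K = {model.K:.2f} (occupancy of state 1: {model.occupancy1:.3f})")
print(f"  relaxation time tau_K = {model.tau_K*1e3:.3f} ms")

# invert experimentally measured lifetimes back to the energy landscape
gb, dg = energies_from_lifetimes(20.3e-3, 4.4e-3)
print(f"\nmeasured tau = (20.3, 4.4) ms  ->  G_barrier = {gb:.2f} kBT, "
      f"delta_G = {dg:.2f} kBT")

# a long trajectory reproduces the analytic dwell times
rng = np.random.default_rng(0)
traj = simulate_state_trajectory(model, 60.0, rng=rng)
d1, d2 = traj.dwell_times()
print(f"\n60 s trajectory: {traj.switch_steps.size} transitions")
print(f"  mean dwell state 1: {d1.mean()*1e3:.2f} ms (analytic "
      f"{model.tau1*1e3:.2f} ms)")
print(f"  mean dwell state 2: {d2.mean()*1e3:.2f} ms (analytic "
      f"{model.tau2*1e3:.2f} ms)")
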