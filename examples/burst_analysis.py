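"""Burst analysis of a contaminated sample: E-S populations and corrections.

Simulates the realistic scenario — 20 % donor-only and 20 % acceptor-only
(bleached) molecules, a small fast contaminant, and 10 % spectral leakage —
then detects bursts, estimates the leakage from the single-labeled
populations, and fits the FRET histogram of the double-labeled selection.
"""

from alexfret import (
    corrected_es,
    estimate_corrections,
    find_bursts,
    fit_fret_histogram,
    mixed_population_config,
    select_bursts,
    simulate_experiment,
)

cfg = mixed_population_config(duration=60.0, seed=2)
stream = simulate_experiment(cfg)
bursts = find_bursts(stream)
print(f"{len(bursts)} bursts in {cfg.duration:.0f} s")

alpha_hat, delta_hat = estimate_corrections(bursts)
print(f"leakage estimated from donor-only bursts: alpha = {alpha_hat:.3f} "
      f"(simulated 0.100)")
bursts = corrected_es(bursts, alpha_hat, 1.0, delta_hat)

valid = bursts[bursts["valid"]]
print(f"donor-only (S>0.9):    {(valid['S_raw'] > 0.9).sum():4d} bursts")
print(f"acceptor-only (S<0.1): {(valid['S_raw'] < 0.1).sum():4d} bursts")

selected = select_bursts(bursts, s_range=cfg.s_range)
print(f"double-labeled selection (0.2<S<0.8): {len(selected)} bursts")

pop = fit_fret_histogram(selected).sorted_by_mean()
print("\nFRET populations of the double-labeled selection:")
for mu, sig, w in zip(pop.means, pop.sigmas, pop.weights):
    print(f"  E = {mu:5.2f} +/- {sig:4.2f}  weight {w:.2f}")
print(f"populations overlap (case I constraints needed): {pop.overlap}")
print("(simulated FRET states: 0.8 and 0.1, slow exchange -> resolved)")
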