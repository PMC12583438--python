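"""Purified FCS: diffusion time and size of the double-labeled population.

In the contaminated scenario the raw correlation mixes contributions from
bleached molecules and a fast impurity.  Selecting double-labeled bursts
(0.2 < S < 0.8), keeping photons within 1 ms of them, and correcting for
the gate's own autocorrelation recovers the diffusion time of the labeled
species; the pinhole-aware conversion returns its hydrodynamic radius.
"""

from alexfret import mixed_population_config, simulate_experiment
from alexfret.pipeline import burst_stage, subpopulation_radius

cfg = mixed_population_config(duration=120.0, seed=11)  # R = 10 nm input
stream = simulate_experiment(cfg)
bursts = burst_stage(stream, cfg)
print(f"{len(stream)} photons, {len(bursts)} bursts, "
      f"alpha_hat = {bursts.attrs['alpha_hat']:.3f}")

res = subpopulation_radius(stream, cfg, e_range=(0.0, 1.0), bursts=bursts)
print(f"\ndouble-labeled selection: {res['n_bursts']} bursts")
print(f"fitted tau_D = {res['tau_D']*1e3:.2f} +/- {res['tau_D_err']*1e3:.2f} ms")
print(f"hydrodynamic radius = {res['radius']*1e9:.1f} +/- "
      f"{res['radius_err']*1e9:.1f} nm (input 10 nm)")
print("(the pinhole truncates the detection profile, shortening the "
      "apparent diffusion time by ~22%; radius_from_fit corrects for it)")
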