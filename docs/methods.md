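# Methods

`alexfret` simulates single-pair FRET measurements with alternating laser
excitation (ALEX) at the level of individual detected photons, and analyzes
the resulting time-tag streams with the combined burst / purified-FCS /
correlation-fitting workflow.  This note records the models, the numerical
choices, and what the synthetic data do and do not capture.

## Conformational kinetics

A molecule switches between two conformational states on a free-energy
landscape parametrized by the energy difference ΔG (state 1 lower) and the
barrier ΔG† seen from state 2, both in kBT.  Arrhenius kinetics with attempt
rate ks (default 1e6 s⁻¹) give

    k12 = ks·exp(−(ΔG + ΔG†)),   k21 = ks·exp(−ΔG†),

so K = k21/k12 = exp(ΔG) exactly, τ1 = 1/k12, τ2 = 1/k21, and the kinetic
relaxation time is τ_K = 1/(k12+k21).  `energies_from_lifetimes` is the
exact closed-form inverse.

State trajectories are discrete-time Markov chains on a grid of `dt_state`
(100 ns by default, 10 µs for G_barrier > 3 kBT, matching the regime where
lifetimes are milliseconds or longer).  The per-step switch probability is
taken from the exact two-state propagator

    P12(δt) = k12/(k12+k21)·(1 − e^−(k12+k21)δt),

the matrix exponential of the rate matrix, which satisfies the semigroup
property and accounts for arbitrarily many intermediate transitions.  A
"literal" first-order mode P12 = k12·δt·e^(−k12·δt) is provided for
comparison; the two agree to first order in k·δt, the regime all default
configurations operate in.  Because switching is a Bernoulli trial per step,
dwell lengths are geometric and are sampled directly (cost scales with the
number of transitions, not steps); trajectories are stored as transition
event lists.

## Diffusion and geometry

Radii map to diffusion coefficients by Stokes–Einstein, D = kBT/(6πηR),
with T = 293.15 K and η = 1.0 mPa·s (water at ~20 °C) by default — the
temperature is a convention choice; both are configurable.  Each coordinate
of a molecule receives an independent zero-mean Gaussian increment of
standard deviation L = √(2Dδt) per step, so the 3D mean-squared displacement
is 6Dτ, and 6(f1·D1+f2·D2)τ for a two-state switcher (state at the start of
a step sets its D).  Molecules live in a periodic box of volume
V = N/(c·N_A) with side lengths r0 × r0 × a·r0, r0 = (V/a)^(1/3), sharing
the axial aspect a of the detection volume.  Note r0 is the full side
length: that is the only reading under which the volume formula and the
printed r0 = 2.75 µm at N = 5, c = 50 pM are mutually consistent.  Initial
positions are uniform.

## Optics and photon generation

The excitation/detection profile is a 3D Gaussian with lateral waist
ω_xy = λ/(2·NA) (λ = 514 nm, NA = 1.2 → ω_xy = 214 nm), axial extent
a·ω_xy (a = 8), truncated by the confocal pinhole at lateral radius
d_pinhole/(2M) = 417 nm.  ALEX alternates 400 ns donor and acceptor pulses
with 100 ns gaps (1 µs period).  Per-channel expected rates for a molecule
with FRET efficiency E at relative profile intensity g:

    D514 = I0_D (1−E) g,  A514 = I0_D (E + α(1−E) + δ) g,  A632 = I0_A g,

with spectral leakage α adding donor emission into the acceptor channel
without depleting the donor channel, and direct excitation δ of the
acceptor under 514 nm (defaults α = 0, δ = 0, β = 1; the simulation
defaults I0_D = 150 kHz, I0_A = 100 kHz).  This additive-leakage reading is
the one under which the standard burst corrections invert the simulation
exactly.  Background (default 1 kHz per detection channel, an APD
dark-count scale) is emitted only while a laser is gated, so every photon
carries an unambiguous excitation label.

Photons are Bernoulli trials per 100 ns base step with probability
min(I·δt, 1), at most one per channel and step (I·δt ≈ 0.01–0.015 at the
defaults).  The engine advances positions on a coarser grid (default 10 µs,
an integer number of ALEX periods) and treats the profile intensity as
constant within a coarse step — the r.m.s. move per 10 µs is ~35 nm against
the 214 nm waist.  Photon counts per (coarse step, channel) are drawn
binomially over the laser-on 100 ns slots and placed uniformly, which is
exactly the per-slot Bernoulli model.  Steps with g < ~1e-3 (outside the
pinhole or several axial widths away, ~96 % of all steps at 50 pM) are
skipped.  The residual coarse-step approximation biases fitted diffusion
times by roughly −3 % at δt = 10 µs (measured against δt = 2 µs runs).
Immobilized molecules under continuous donor excitation use an exact
dwell-segment path with no coarse grid.

## Burst analysis

Bursts are maximal runs of ≥ 25 photons (all four channels pooled) with
inter-photon gaps strictly below 200 µs.  Raw FRET efficiency and
stoichiometry are E = A514/(A514+D514), S = (A514+D514)/(A514+D514+A632);
corrections follow the standard ALEX algebra and exactly invert the
simulator's leakage model in expectation.  α and δ are estimated from the
data via the single-point estimators α̂ = Ē_DO/(1−Ē_DO) (donor-only
bursts, S > 0.9) and δ̂ = S̄_AO/(1−S̄_AO) (acceptor-only, S < 0.1).  These
are biased upward by a few points when dim, background-contaminated bursts
enter the calibration populations (measured α̂ ≈ 0.12 for true α = 0.10 in
the contaminated scenario) — a realistic imperfection of the single-point
method, not corrected for.

With the default intensities the double-labeled population sits at
S = I0_D(1+α(1−E))/(I0_D(1+α(1−E))+I0_A) ≈ 0.60, not 0.5; S = 0.5 requires
matched detected rates (I0_A equal to the donor-excited rate).  The FRET
histogram of selected bursts is fitted by least squares with a normal
mixture (bin width 0.02), initialized from quantiles; the component count
is chosen parsimoniously (a component must reduce the residual by ≥ 30 %
and stay non-degenerate; weights < 0.05 are pruned).  Populations whose
extreme components satisfy E_high − σ_high < E_low + σ_low are flagged as
overlapping — the case-I fitting regime.

## Correlation analysis

The correlator counts photon pairs into log-spaced lag bins (default 12
points per decade, 1 µs–10 s, snapped to the 100 ns lattice) directly from
the time tags:

    C(τ_bin) = P_bin·T² / (N_A·N_B·Δ_bin·(T−τ̄)) − 1,

with P the forward pair count, Δ the number of lattice offsets in the bin
and T−τ̄ the edge-corrected overlap.  Zero-lag self pairs never enter (the
grid starts above zero).  Errors: the measurement is split into 10 equal
segments and the per-lag standard deviation across segments, divided by
√10, is used as σ_C; fits are weighted 1/σ_C.  ALEX gating imprints 1 µs
oscillations on single-channel correlations below ~0.1 ms; single-curve
fits therefore exclude lags below 2 µs by default (20 µs for the gated
diffusion fits below), and the divided method cancels them.

The model family for donor-excitation channels is

    C_pair(τ) = C0 · C_diff,pair(τ) · [1 ± A_pair e^(−τ/τ_K)],

with C_diff(τ) = (1+τ/τ_D)⁻¹(1+τ/(a²τ_D))^(−1/2), a FRET-brightness
weighted two-component mixture (weights (1−E_i)², E_i², E_i(1−E_i) for
D×D, A×A, D×A) when the states diffuse differently, and exchange
amplitudes carrying α and β; at α = 0, β = 1 they satisfy
A_DA² = A_DD·A_AA.  Conformational exchange raises the autocorrelations
and lowers the cross-correlation.

### Purified FCS

Photons within t_purify (default 1 ms) of any selected burst are kept;
windows merge when overlapping.  The gated stream keeps the full time axis
and full-duration mean normalization — and the gated correlation is then
divided by the gate autocorrelation factor ⟨w(t)w(t+τ)⟩/⟨w⟩², computed
exactly from the merged window intervals.  Without this factor the ~4 ms
windows imprint their own decay and fitted diffusion times come out ~30 %
low; with it, purified and ungated diffusion times agree.  Amplitudes of
gated curves remain distorted by burst-selection conditioning and are not
interpreted; fits use the shape.

A residual systematic remains for sparse selections (e.g., a minority FRET
population): windows then cluster on single-molecule episodes, and
conditioned recurrences of the same molecule add a slow shoulder
(~5–50 ms) that biases the fitted τ_D of the minority population upward by
~20–30 % even at 15 min.  This is reflected in the quoted uncertainties of
the sub-population analysis and is a known limitation.

### Diffusion times, radii, and the pinhole

Sub-population diffusion fits correlate the pooled donor-excitation
photons (D514+A514) of the purified selection: pooled brightness
∝ (1+α(1−E)) is nearly FRET-independent, so a pure diffusion model applies
and conformational exchange drops out.  Fits use lags 20 µs–10 ms (about
5× the diffusion time).

The simulated profile exp(−r²/2ω_xy²) has 1/e² radius 2ω_xy, so the
Gaussian-profile diffusion time is τ_D = ω_xy²/D.  The pinhole truncation
at 417 nm ≈ 0.97·(2ω_xy) makes the measured decay faster: the package
computes the exact lateral correlation decay of the truncated profile from
its power spectrum and calibrates the factor κ = τ_fit/(ω_xy²/D) ≈ 0.78
once per geometry.  `radius_from_fit` inverts with this factor:
D = κ·ω_xy²/τ_fit, R = kBT/(6πηD).  The truncated-profile prediction for
R = 10 nm is τ_fit ≈ 1.67 ms (vs 2.14 ms untruncated), and simulated
round trips recover the input radius within the fit error.  A "literal"
convention (τ_D = ω_xy²/4D, no truncation) is available for comparison
with conventions that define ω as the 1/e² radius.

### Lifetime extraction

Two methods recover τ_K from purified curves of the double-labeled
selection, with constraints chosen by the burst-histogram overlap flag:

* **Divided:** fit C_A×A/C_D×A.  In case I (merged populations, shared
  τ_D) diffusion cancels exactly and the ratio decays from
  (1+A_AA)/(1−A_DA) to 1 with time constant τ_K; only the combination
  f1·f2·(E1−E2)² is identifiable besides τ_K (K and ΔE individually carry
  large uncertainties), consistent with the constraint
  f1E1+f2E2 = E_overlap.  In case II, E1, E2, K and the two diffusion
  times are fixed from burst analysis and only τ_K is free; the diffusion
  ratio uses the FRET-weighted mixture.  Lags where C_D×A ≤ 0 are masked.
* **Global:** simultaneous weighted fit of D×D, A×A and D×A with shared
  kinetic parameters, per-curve amplitude, and (case I) per-curve τ_D; a
  two-curve variant omits D×D.

Rates derive from (K, τ_K) as k12 = (1−f1)/τ_K, k21 = f1/τ_K with
f1 = K/(1+K).  Immobilized traces skip diffusion entirely and fit
C(τ) = offset + A·e^(−τ/τ_K).

## Problem sizes in the test suite

Analytic checks are instantaneous.  Stochastic checks run the full
photon-level pipeline with fixed seeds at sizes chosen to finish on a
single CPU while keeping the statistical claims meaningful: immobilized
traces of 20 s (the protocol range is 10–60 s); the contaminated-sample
diffusion recovery at 2 min; the sub-population size comparison at the
full 15-minute measurement length for the slow-exchange case (the minority
population's diffusion time is episode-limited and genuinely needs the
statistics) and 5 min for the fast-exchange bias check.

## What the synthetic data do not capture

Triplet blinking and other photophysics, detector dead time and
afterpulsing, TCSPC micro-times, polarization, flow, hydrodynamic
interactions, and more than two conformational states are all outside the
model.  Passing tests therefore demonstrate the internal consistency of
the analysis chain under the stated generative model — shot noise,
diffusion, ALEX gating, leakage, background, bleached populations and
contaminants — not robustness to photophysical artifacts absent from it.
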