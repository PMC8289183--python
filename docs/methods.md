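# Methods

## The system

Ultrasmall gold nanoparticles (uGNPs, ~3–15 nm cores) are made by reducing
tetrachloroaurate (AuCl₄⁻, "precursor") with tannic acid (TA) and sodium
citrate (NaCit) in a carbonate-buffered medium, then growing the resulting
seeds in repeated rounds: extract part of the colloid, replace it with fresh
citrate solution, dose more Au(III) stock. This package models the
desk-scale side of that process — the reaction kinetics, the colorimetric
readout used to measure them, the selectivity argument that links kinetics
to final size, and the mass bookkeeping of the growth rounds.

## Kinetic mechanism

The precursor is consumed by three parallel routes, each first order in
precursor:

| route | rate law | product |
|---|---|---|
| TA reduction | r_ta = k_ta · c_Au · c_TA^l | Au⁰ |
| citrate reduction | r_cit = k_cit · c_Au · c_CtH₂⁻ | Au⁰ |
| passivation | r_pass = k_pass · c_Au · c_OH⁻ | AuCl₃(OH)⁻ |

TA reacts through its ten phenolic groups, each donating two electrons on
oxidation to the quinone; with three electrons per Au(III)→Au(0), TA is
consumed at 3/20 mol per mol Au reduced via the TA route. The citrate route
is carried by the singly-deprotonated-twice anion CtH₂⁻ (the species
reported active in citrate-only syntheses); we charge it 3/2 mol per mol Au
(two electrons per citrate oxidised to dicarboxyacetone). [OH⁻] is held
constant — the medium is buffered — and the model is isothermal (the
synthesis runs at a fixed 80 °C after pre-boil), so temperature never
enters.

An immediate consequence of the 3/20 stoichiometry worth stating: at the
seed recipe (0.125 mM Au, 0.1 mM TA), full reduction of all the gold can
consume at most 0.15 × 0.125 = 0.019 mM TA. TA therefore *plateaus* at
about 81 % of its initial value rather than depleting; "TA is used up fast"
means it reaches that plateau on the time scale of the initial colour jump,
which the calibrated defaults reproduce (TA route carries >99 % of the
reduction; the TA plateau is reached no later than 99 % precursor
conversion).

### Parameters

| parameter | default | units | provenance |
|---|---|---|---|
| l (TA order) | 1.1 | – | printed (log–log initial-rate regression) |
| au_order_ta | 1 | – | assumed (simple mass action) |
| k_ta | 2.5 × 10³ | (mol/L)^(−1.1)/s | calibrated |
| k_cit | 2.0 | L/mol/s | calibrated |
| k_pass | 1.0 × 10⁴ | L/mol/s | calibrated |
| pH | 6.0 | – | exposed parameter (see below) |
| pKa₁–₃ | 3.13 / 4.76 / 6.40 | – | citric-acid literature values |

k_ta, k_cit, k_pass are **calibrated, not measured**: no numeric rate
constants exist for this chemistry at our disposal. They were chosen once so
that (a) the precursor half-life is a few seconds and the TA route carries
essentially all of the reduction (the "initial jump"), and (b) sweeping the
NaCit/Au ratio from 6 to 25 at fixed TA moves the precursor profile by
under 0.1 % of total gold — the two qualitative signatures the mechanism
must show. The config records provenance per parameter (`printed` /
`calibrated` / `assumed`).

The working pH of the 6 mM K₂CO₃ medium is not independently known, so it
is an input, not a derived quantity. The default 6.0 is a typical citrate
synthesis medium; there CtH₂⁻ is ~4 % of total citrate (87 µM of 2.2 mM)
and [OH⁻] = 10⁻⁸ M. Both the reactive-citrate concentration and the
passivation rate inherit their pH dependence through this single knob; no
carbonate equilibrium or activity corrections are modelled.

### Numerics

`scipy.integrate.solve_ivp` with LSODA, rtol 1e-10, atol 1e-14. Negative
concentrations are prevented by tolerance, never by clipping; the simulator
raises (carrying the last good state) if gold conservation drifts beyond
1e-7 relative, and the test suite asserts ≤1e-9 along every trajectory. A
sixth auxiliary state integrates the gold reduced via the TA route only, so
the 3/20 TA:Au ratio can be verified pointwise (≤1e-6 relative). The
independent cross-check is a from-scratch fixed-step RK4 integrator in the
test suite (step 1 ms, 60 s horizon, agreement ≤1e-4 of total gold).

Rate-constant fitting is bounded least squares (`scipy.optimize.least_squares`,
TRF) on residuals over the precursor, reduced-gold and TA profiles,
normalised by initial total gold; positive coefficients are optimised in
log10 space, the order l linearly in [0.01, 5]. On noiseless traces the fit
recovers (k_ta, l) within 1 %; with 2 % multiplicative noise on 50 traces,
l is recovered within ±0.1.

## Colorimetry

The reaction progression proxy is the red fraction: the per-pixel mean of
R/(R+G+B) over a frame (pixels summing to zero are excluded; a
channel-mean variant is exposed as an option since either reading of "red
component fraction" is defensible). The curve is normalised between its
first-frame value and a plateau estimated from the last 5 frames.

The initial reduction rate is the straight-line slope of normalised
progress over the initial window — by default the points within the first
10 % of the dynamic range — times the initial precursor concentration
(progress 1 ⇔ full conversion). A linear fit over a window of a decaying
rate is biased low by roughly half the window width, so validation against
the kinetic oracle uses the documented `window_fraction` override at 2 %
(bias ~1 %, inside the 2 % tolerance); the 10 % default is kept for noisy
real-world curves where a wider window is the right trade.

The reaction order in TA is the OLS slope of log₁₀(rate) vs log₁₀(c_TA).
On the noiseless default-law decade grid this returns l = 1.1 to machine
precision; through the full synthetic pipeline (simulate → render frames →
red fraction → initial slope) it returns ~1.14, the residual being the
finite-window and quantisation bias.

## Selectivity and final size

With all routes first order in precursor, the ratio of reduction to
passivation is independent of the precursor concentration. Evaluated at
quasi-equilibrium (≈ initial recipe) concentrations:

σ = (k_ta·c_TA,0^l + k_cit·c_CtH₂⁻,0) / (k_pass·c_OH⁻,0)

The reduced fraction of any dose is σ/(1+σ); the rest passivates. With g
mol Au dosed per mol Au already in the seeds and no secondary nucleation,
mass conservation over spheres gives

d_final = d_seed · (1 + g·σ/(1+σ))^{1/3}

which is the seed diameter exactly at zero dose and obeys cube-root mass
scaling (8× gold per particle ⇒ 2× diameter). A denominator below 1e-300
raises an explicit infinite-selectivity error rather than returning inf.
Quasi-equilibrium concentrations default to the recipe's initial values;
`SelectivityInputs.from_trace` samples them from a simulated trajectory at
a chosen time instead.

What this model does **not** contain: nucleation. At the calibrated
defaults σ ≈ 10³, so σ/(1+σ) saturates and predicted size is dose-limited —
the high-TA plateau. The "large particles at very low reductant" regime of
real one-pot syntheses arises from sparse nucleation (fewer seeds sharing
the gold), which a fixed-seed-count growth model deliberately excludes.

## Growth-round bookkeeping

Volumes in mL, concentrations mol/L, diameters nm (TEM-equivalent cores;
`hydrodynamic_diameter` adds the ~1 nm DLS offset for reporting).
Constants: M_Au = 196.97 g/mol, ρ_Au = 19.3 g/cm³.

N = c_Au·M_Au/(ρ_Au·(π/6)d³) particles per mL; S = N·π·d² nm²/mL.

Each round retains (V−v_extract)/V of particles and gold (extraction
removes both proportionally), restores volume with citrate solution, and
doses 20 mM stock to the round's cumulative Au target; the dose volume is
tracked exactly in the balance (no "negligible volume" shortcut), so gold
and particle-number balances close to 1e-9 relative by construction and by
test. All dosed gold deposits uniformly across particles (100 % yield, per
the theoretical-size convention; a `reduction_yield` multiplier is exposed
for sensitivity analysis), and d grows by the cube root of gold per
particle. `plan_dosing` inverts this in closed form: given a diameter
ladder it returns per-round targets whose forward replay reproduces the
ladder to ≤1e-6 nm (observed: ~1e-15).

Two readings of the dosing table deliberately left visible: treating its
concentrations as *cumulative* per-round targets, seven rounds from a 3 nm
seed end at a theoretical 13.1 nm, short of the 15 nm nominal label — the
nominal ladder tracks measured sizes, not pure bookkeeping. The round
report prints both columns side by side rather than reconciling them.

Dilution factors equalise total surface area: DF_i = S_i/min_j S_j, so the
sample with the least area (the largest particles, 15 nm, under the
reference concentrations and nominal diameters) is the DF = 1.00 reference.
DF values for the other samples depend on measured diameters and are
reported as computed from the nominal ones, not asserted against any
external table.

## Synthetic data

The generators exist so every stage is testable without laboratory input,
and they emulate structure, not physics:

- **Traces**: exact ODE solutions plus per-column multiplicative or
  additive Gaussian noise (clipped at zero), bit-reproducible by seed.
  Real absorbance data would have correlated, heteroscedastic errors.
- **Frames**: uniform colour interpolated between palette endpoints by the
  progress value; channel noise is applied before uint8 quantisation and
  clipped to 0–255 (which biases extremes inward — documented, not
  corrected). The default palette endpoints share a channel sum, making
  the red fraction affine in progress (exact round trips); unequal sums
  give the curved monotone response of a real colloid. No plasmon
  rendering, no spatial structure, no flask/background.
- **Sizes**: normal or moment-matched lognormal draws at a stated mean/sd;
  no shape anisotropy, no aggregates, no measurement truncation.

Passing round-trip tests therefore demonstrates the *analysis* stages are
self-consistent at realistic noise levels, not that the instrument models
are faithful.

## Problem sizes

Defaults used by the tests and drivers: 120–300 s horizons at 0.25–0.5 s
output spacing; 8-point decade grids for order fitting; 50 noisy traces for
stochastic parameter recovery; 10⁴–2×10⁴ draws for size-distribution
checks. These are the package's chosen study conditions; all are config- or
argument-overridable.
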