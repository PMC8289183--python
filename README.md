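# ugnp — process model for seeded-growth gold nanoparticle synthesis

`ugnp` is a Python package for the process engineering behind ultrasmall
gold nanoparticle (uGNP, ~3–15 nm) synthesis by the tannic acid (TA) +
sodium citrate method. It is aimed at nanomaterials chemists who want to
reason quantitatively about a seeded-growth protocol before (or instead of)
running it: how fast the Au(III) precursor is reduced and by what, how much
of a dose ends up on the particles, what core diameter each growth round
should produce, and how to dose to hit a target size ladder.

The model, in brief:

- **Kinetics.** AuCl₄⁻ is consumed by three parallel mass-action routes —
  TA reduction (rate k_ta·c_Au·c_TA^l with l = 1.1), citrate reduction via
  the CtH₂⁻ anion (k_cit·c_Au·c_CtH₂⁻), and passivation to AuCl₃(OH)⁻
  (k_pass·c_Au·c_OH⁻). TA is consumed at 3/20 mol per mol Au it reduces
  (ten phenols × two electrons per TA; three electrons per Au). Citrate
  speciation over CtH₃/CtH₂⁻/CtH²⁻/Ct³⁻ follows the standard triprotic
  closed form.
- **Selectivity and size.** With first-order precursor dependence
  everywhere, σ = (k_ta·c_TA,0^l + k_cit·c_CtH₂⁻,0)/(k_pass·c_OH⁻,0) is
  the reduction:passivation ratio; a fraction σ/(1+σ) of dosed gold grows
  the seeds and d_final = d_seed·(1 + g·σ/(1+σ))^{1/3} for g mol Au dosed
  per mol seed gold.
- **Process bookkeeping.** Particle numbers N = c_Au·M_Au/(ρ_Au·(π/6)d³),
  surface areas S = N·π·d², exact volume-tracked mass balances over
  extract/replace/dose rounds, surface-area-equalising dilution factors,
  and closed-form inverse dosing design.
- **Colorimetry.** Reaction progression from RGB frames as the mean red
  fraction R/(R+G+B), initial rates from the initial slope of normalised
  progress, reaction orders from log–log regression.
- **Synthetic data.** Seeded generators for noisy kinetic traces,
  reaction-video frame series and TEM-style size samples, so the whole
  pipeline is testable offline.

See `docs/methods.md` for assumptions, parameter provenance and limitations
(notably: rate coefficients are calibrated, not measured, and there is no
nucleation model).

## Worked example

```python
import numpy as np
from ugnp import (ColloidState, RateParameters, default_recipe,
                  simulate_recipe, simulate_reduction, plan_dosing)
from ugnp.config import RunConfig

config = RunConfig()                       # seed recipe + calibrated kinetics
state = config.initial_reaction_state()    # 0.125 mM Au, 0.1 mM TA, pH 6

trace = simulate_reduction(state, config.rates.to_parameters(),
                           np.linspace(0, 300, 601))
print(f"precursor half-life {trace.t[np.argmax(trace.c_reduced > state.c_precursor/2)]:.1f} s,"
      f" TA remaining {trace.c_ta[-1]/state.c_ta:.0%}")

seed = ColloidState.from_concentration(1.25e-4, 3.0, 25.0)
for st in simulate_recipe(default_recipe(), seed):
    print(f"round -> {st.d_core:.2f} nm at {st.c_au_total*1e3:.3f} mM Au")
```

prints

```
precursor half-life 7.5 s, TA remaining 81%
round -> 3.78 nm at 0.150 mM Au
round -> 4.73 nm at 0.175 mM Au
round -> 5.86 nm at 0.200 mM Au
round -> 7.22 nm at 0.225 mM Au
round -> 8.84 nm at 0.250 mM Au
round -> 10.79 nm at 0.275 mM Au
round -> 13.11 nm at 0.300 mM Au
```

i.e. the precursor is half-reduced in ~7.5 s while TA levels off at 81 % of
its initial value (the 3/20 stoichiometry caps how much TA the available
gold can consume), and the reference seven-round recipe grows a 3 nm seed
to a theoretical 13.1 nm core. `plan_dosing([4, 5, 6, ...], seed)` inverts
the bookkeeping, returning the cumulative Au target of each round needed to
hit an exact nanometre ladder.

## Analysis drivers and CLI

`analysis/01_speciation.py` … `05_growth_recipe.py` are thin narrative
drivers over the library — speciation curves, the kinetics run and
NaCit-invariance sweep, reaction-order extraction (direct and through the
synthetic colorimetric pipeline), selectivity/size grids, and the
growth/dilution/dosing tables — each writing CSVs under `results/`. The
same stages are scriptable via the `ugnp` command (`ugnp simulate`,
`ugnp fit-order`, `ugnp plan --targets 4,5,6`, `ugnp dilution`, …; exit
codes 0/2/3 for ok/validation/numerical failure).

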