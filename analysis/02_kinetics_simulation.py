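#!/usr/bin/env python
"""Simulate the reduction mechanism at seed-recipe conditions.

Integrates the three-route mechanism (TA reduction, citrate reduction,
passivation) from the seed conditions, then repeats the run across NaCit/Au
ratios 6-25 at fixed TA to check that the precursor profile is insensitive
to citrate — the signature of TA-dominated reduction.  Writes the base
trace and a sweep summary under results/.
"""

from dataclasses import replace

import numpy as np
import pandas as pd

from ugnp.config import RunConfig
from ugnp.io import write_table, write_trace
from ugnp.kinetics import simulate_reduction
from ugnp.speciation import speciate_citrate

config = RunConfig()
params = config.rates.to_parameters()
state = config.initial_reaction_state()
t = np.linspace(0.0, 300.0, 601)

trace = simulate_reduction(state, params, t)
write_trace(trace, "results/kinetic_trace.csv",
            {"config_hash": config.config_hash(), "rate_provenance": config.rates.provenance})

total0 = state.total_gold
conv = 1.0 - trace.c_precursor / total0
t_half = t[np.argmax(conv >= 0.5)]
ta_floor = trace.c_ta[-1] / state.c_ta
print(f"Base run (TA {state.c_ta*1e3:.2f} mM, Au {total0*1e3:.3f} mM):")
print(f"  precursor half-life           {t_half:6.1f} s")
print(f"  final conversion              {conv[-1]*100:6.2f} %")
print(f"  passivated fraction           {trace.c_passivated[-1]/total0*100:6.3f} %")
print(f"  TA remaining at plateau       {ta_floor*100:6.1f} %  "
      "(electron stoichiometry caps TA use at 3/20 of the gold)")
print(f"  TA-route share of reduction   {trace.c_reduced_ta[-1]/trace.c_reduced[-1]*100:6.1f} %")

# NaCit/Au sweep at fixed TA: the precursor profile should barely move
rows = []
base_profile = None
for ratio in (6, 10, 15, 20, 25):
    c_cit_total = ratio * total0
    c_reactive = speciate_citrate(c_cit_total, config.speciation.pH).c_CtH2_minus
    sweep = simulate_reduction(replace(state, c_cit_reactive=c_reactive), params, t)
    profile = sweep.c_precursor / total0
    if base_profile is None:
        base_profile = profile
    rows.append({
        "nacit_au_ratio": ratio,
        "c_cit_reactive_M": c_reactive,
        "t_half_s": t[np.argmax(1 - profile >= 0.5)],
        "max_abs_dev_from_ratio6": float(np.abs(profile - base_profile).max()),
    })
sweep_df = pd.DataFrame(rows)
write_table(sweep_df, "results/nacit_sweep.csv", {"config_hash": config.config_hash()})

max_dev = sweep_df["max_abs_dev_from_ratio6"].max()
print(f"\nNaCit/Au sweep 6-25 at fixed TA: precursor profiles deviate by at most")
print(f"  {max_dev*100:.2f} % of total gold from the ratio-6 profile — citrate barely")
print("  perturbs the precursor decay, consistent with a TA-dominated mechanism.")
print("Wrote results/kinetic_trace.csv, results/nacit_sweep.csv")
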