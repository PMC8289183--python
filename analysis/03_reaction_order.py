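#!/usr/bin/env python
"""Reaction order in TA from colorimetric-style initial rates.

Two routes to the same number: (i) evaluate the TA rate law directly on a
noiseless decade grid of TA concentrations; (ii) simulate each condition,
render the conversion as a synthetic frame series, extract the progress
curve by red-fraction analysis and estimate the initial rate from its
initial slope.  Both initial-rate sets are regressed log-log against the TA
concentration.  Writes results/initial_rates.csv and prints both slopes.
"""

from dataclasses import replace

import numpy as np
import pandas as pd

from ugnp.colorimetry import estimate_initial_rate, fit_reaction_order, progress_curve
from ugnp.config import RunConfig
from ugnp.io import write_table
from ugnp.kinetics import reduction_rate_ta, simulate_reduction
from ugnp.synth import generate_frames

config = RunConfig()
params = config.rates.to_parameters()
state = config.initial_reaction_state()
total0 = state.total_gold

c_ta_grid = np.geomspace(state.c_ta / 3.0, state.c_ta * 10.0 / 3.0, 8)
rows = []
for c_ta in c_ta_grid:
    cond = replace(state, c_ta=float(c_ta))
    rate_law = reduction_rate_ta(cond, params)

    # colorimetric route: simulate, render frames, extract progress, fit slope;
    # log-spaced times resolve the initial window at every TA level
    t = np.concatenate([[0.0], np.geomspace(1e-3, 200.0, 800)])
    trace = simulate_reduction(cond, params, t)
    conversion = trace.c_reduced / total0
    series = generate_frames(conversion / conversion.max(), t, size=(16, 16))
    curve = progress_curve(series)
    rate_color = estimate_initial_rate(curve, total0 * conversion[-5:].mean(),
                                       window_fraction=0.02)
    rows.append({"concentration": float(c_ta), "rate": rate_law,
                 "rate_colorimetric": rate_color})

df = pd.DataFrame(rows)
write_table(df, "results/initial_rates.csv", {"config_hash": config.config_hash()})

order_law, _ = fit_reaction_order(df["rate"], df["concentration"])
order_color, _ = fit_reaction_order(df["rate_colorimetric"], df["concentration"])
write_table(
    pd.DataFrame([{"route": "rate-law", "order": order_law},
                  {"route": "colorimetric", "order": order_color}]),
    "results/reaction_order.csv", {"config_hash": config.config_hash()},
)

print("Reaction order in TA (log-log OLS over one decade, 8 points):")
print(f"  direct rate-law evaluation : {order_law:.4f}")
print(f"  colorimetric pipeline      : {order_color:.4f}")
print("The direct route returns the model's TA order l = 1.1 exactly; the")
print("full colorimetric pipeline (simulate -> render -> red fraction ->")
print("initial slope) recovers it to within a few percent.")
print("Wrote results/initial_rates.csv, results/reaction_order.csv")
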