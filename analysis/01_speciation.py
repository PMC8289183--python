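#!/usr/bin/env python
"""Citrate speciation across pH and at the working medium.

Distributes the 2.2 mM sodium citrate of the seed recipe over its four
protonation states on a pH grid, and reports which species dominate at the
default working pH.  Writes results/speciation_curve.csv (pH, species,
concentration) and prints the working-point composition.
"""

import numpy as np
import pandas as pd

from ugnp.config import RunConfig
from ugnp.io import write_table
from ugnp.speciation import speciate_citrate

config = RunConfig()
sp = config.speciation

rows = []
for ph in np.arange(0.0, 14.0 + 1e-9, 0.05):
    st = speciate_citrate(sp.total_citrate, float(ph), sp.pKa)
    for species, c in (("CtH3", st.c_CtH3), ("CtH2-", st.c_CtH2_minus),
                       ("CtH2-2", st.c_CtH_2minus), ("Ct3-", st.c_Ct_3minus)):
        rows.append({"pH": round(float(ph), 3), "species": species, "concentration": c})
write_table(pd.DataFrame(rows), "results/speciation_curve.csv",
            {"total_citrate_M": sp.total_citrate, "pKa": list(sp.pKa)})

work = speciate_citrate(sp.total_citrate, sp.pH, sp.pKa)
print(f"Citrate speciation at working pH {sp.pH} (total {sp.total_citrate*1e3:.1f} mM):")
for name, c in (("CtH3", work.c_CtH3), ("CtH2-", work.c_CtH2_minus),
                ("CtH2-2", work.c_CtH_2minus), ("Ct3-", work.c_Ct_3minus)):
    print(f"  {name:7s} {c*1e6:10.3f} uM  ({100*c/work.total_citrate:5.2f} %)")
print("The reactive reducing species CtH2- sits at "
      f"{work.c_CtH2_minus*1e6:.1f} uM — a few percent of total citrate, so the")
print("citrate reduction route is present but far slower than the TA route.")
print("Wrote results/speciation_curve.csv")
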