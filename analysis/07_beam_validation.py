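"""Validate the cantilever solver against the closed-form beam solution.

A 100 x 10 mm rectangular cantilever (E = 20 GPa, nu = 0.3, P = 100 N,
t = 10 mm) is solved at a sequence of mesh sizes and compared with the
Timoshenko tip deflection; strain energy is checked against the
work-energy identity P*delta/2.  Writes beam_validation.csv.
"""

import os

import numpy as np
import pandas as pd

from _common import OUT_DIR
from mandiblescape.biomech import SolverParams, cantilever_beam_oracle, cantilever_solve
from mandiblescape.outlines import Outline

beam = Outline(np.array([[0.0, 0.0], [100, 0], [100, 10], [0, 10]]),
               id="beam", canonical=True)
oracle = cantilever_beam_oracle(100.0, 10.0)
rows = []
for h in (1.0, 0.667, 0.5, 0.333, 0.25):
    defl, se = cantilever_solve(beam, SolverParams(h=h))
    rows.append({"h_mm": h, "deflection_mm": defl, "strain_energy_Nmm": se,
                 "rel_error_vs_timoshenko_pct": 100 * (defl - oracle) / oracle})
df = pd.DataFrame(rows)
os.makedirs(OUT_DIR, exist_ok=True)
df.to_csv(os.path.join(OUT_DIR, "beam_validation.csv"), index=False)
print(f"Timoshenko oracle: {oracle:.4f} mm (Euler-Bernoulli 2.0 mm)")
print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
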