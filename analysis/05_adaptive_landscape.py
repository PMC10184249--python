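"""Optimize adaptive-landscape fitness weights per clade.

Fits quadratic performance surfaces for stiffness (negated strain energy),
mechanical advantage, speed (1/AR) and displacement (AR) over the warp
grid, then grid-searches the fitness-weight simplex (step 0.05) for the
combination each clade's taxa sit highest on; clades are compared by
overlap of their dlnL <= 2 support sets.  Writes landscape.json.
"""

import json
import os

from _common import OUT_DIR, run_stages

report = run_stages("simulate", "outlines", "biomech", "landscape")
with open(os.path.join(OUT_DIR, "landscape.json")) as fh:
    land = json.load(fh)
for g in ("A", "B"):
    rec = land[g]
    w = dict(zip(rec["traits"], [round(x, 2) for x in rec["weights"]]))
    print(f"clade {g}: weights {w}  z={rec['z']:.2f} "
          f"(support set: {rec['confidence_set_size']} candidates)")
print("pairwise:", land["pairwise"])
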