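"""Measure biomechanical traits on the warp grid and interpolate onto taxa.

Each valid warp shape is measured for mechanical advantage and aspect ratio
and put through the simulated cantilever bending test (20 GPa, 100 N
ventral load, 10 mm extrusion) after scaling to a common 100 mm jaw length;
taxon values come from bilinear interpolation at each taxon's (PC1, PC2)
position.  Writes warp_traits.csv and taxon_traits.csv.
"""

from _common import run_stages

report = run_stages("simulate", "outlines", "biomech")
c = report["counts"]["biomech"]
print(f"grid nodes populated: {c['grid_populated']}")
print(f"taxa interpolated: {c['taxa_in'] - c['taxa_dropped']} of {c['taxa_in']}")
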