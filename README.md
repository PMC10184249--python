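# mandiblescape

Analysis pipeline for studying how jaw **form** (2D mandible outline shape)
maps onto jaw **function** (lever mechanics and bending stiffness) across
clades, and how those functional traits evolve on a time-calibrated
phylogeny.

The pipeline goes end-to-end:

1. **Outlines → morphospace.** Closed mandible outlines (CSV polygons, TPS
   files or binary mask images) are resampled to equal arc-length
   semi-landmarks, superimposed by generalized Procrustes alignment, and
   decomposed by elliptic Fourier analysis (EFA) with the harmonic count
   calibrated to retain 99% of cumulative harmonic power
   Σₙ(aₙ²+bₙ²+cₙ²+dₙ²)/2.  PCA of the coefficient covariance gives the
   morphospace; a 10×10 lattice of *theoretical warp shapes* is
   reconstructed by inverse EFA at mean + PC1·v₁ + PC2·v₂, and
   self-intersecting reconstructions are flagged biologically impossible.
2. **Biomechanics.** On each valid warp: mechanical advantage
   MA = in-lever/out-lever (joint → coronoid apex over joint → anterior bite
   point), aspect ratio AR = depth/length (1/AR proxies closing speed), and
   a simulated cantilever bending test — the outline is extruded to a 10 mm
   plate, meshed into square plane-stress bilinear elements (E = 20 GPa,
   ν = 0.3), clamped at the posterior-dorsal and posterior-ventral extremes
   and loaded with 100 N ventrally at the anterior tip — yielding tip
   deflection (mm) and strain energy ½uᵀf (N·mm).  Per-taxon traits come
   from bilinear interpolation of the warp-grid values at each taxon's
   (PC1, PC2) position.
3. **Statistics.** Null tests of morphospace occupancy (observed taxa vs
   uniformly placed simulated taxa, Wilcoxon rank-sum), bootstrap/rarefied
   disparity contrasts, Table-style group trait summaries, body-mass
   allometry scans.
4. **Adaptive landscape.** Quadratic performance surfaces per trait,
   standardized over the morphospace lattice; combined landscape
   W = Σ wₙFₙ with fitness weights wₙ on the unit simplex; per-clade weights
   optimized by exhaustive simplex grid search of Σ ln Ŵ(taxon); clades
   compared via overlap of their ΔlnL ≤ 2 support sets.
5. **Trait evolution.** BM / OU (fixed root, fossil-tip safe) / EB
   likelihoods with σ² and root state profiled by GLS, AICc model weights;
   a two-rate search fitting a clade-specific rate scalar at every internal
   node; distance-based multivariate shape-rate comparison between two
   groups with permutation p-values; GLS ancestral states.

A first-class synthetic-data module generates jaw-like outlines with
controllable corpus depth and coronoid height, two-clade pure-birth time
trees (optionally with fossil tips), traits under BM/OU/EB/two-rate models,
and landscape scenarios with known weights — so every stage is testable
against ground truth with no downloads.

## Worked example

Run the numbered drivers (each is deterministic and idempotent; outputs go
to `results/analysis/`):

```sh
cd analysis
python 01_simulate_dataset.py
python 02_morphospace.py
python 05_adaptive_landscape.py
python 07_beam_validation.py
```

Output from the runs above:

```
simulated 80 taxa -> results/analysis
harmonics retained: 3
PC1+PC2 variance: 96.7%
warp models: 99 valid / 1 impossible
clade A: weights {'SE': 0.75, 'MA': 0.0, 'speed': 0.05, 'AR': 0.2}  z=0.53 (support set: 176 candidates)
clade B: weights {'SE': 0.3, 'MA': 0.0, 'speed': 0.4, 'AR': 0.3}  z=0.00 (support set: 143 candidates)
Timoshenko oracle: 2.0156 mm (Euler-Bernoulli 2.0 mm)
  h_mm  deflection_mm  rel_error_vs_timoshenko_pct
0.5000         1.9814                      -1.6970
0.2500         1.9606                      -2.7308
```

Reading this: the synthetic deep-jawed clade A sits highest on a landscape
dominated by the stiffness surface (weight 0.75 on negated strain energy) —
a "strength regime" — while the slender-jawed clade B is best explained by
a mixed speed/compliance regime; one of the 100 theoretical warp shapes is
geometrically impossible (its dorsal and ventral outlines cross) and is
excluded from the trait grid.  The bending solver lands within 2–3% of the
closed-form Timoshenko cantilever deflection.

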