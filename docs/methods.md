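# Methods

This note documents the models and procedures implemented in
`mandiblescape`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical decisions that
affect results.

## Outline geometry and the morphospace

**Canonical frame.** All analyses assume outlines in a canonical anatomical
frame: anterior tip at minimal x, dorsal up (+y), jaw joint at the
posterior (maximal-x) end, vertices counter-clockwise.  Loaders enforce the
orientation (`canonicalize`, with explicit `flip_x`/`flip_y` for images
digitized in other conventions) and roll the vertex sequence to start at
the anterior-most point (ties broken ventral-most), which also fixes
start-point correspondence across shapes after resampling.

**Resampling and alignment.** Outlines are resampled to k equally
arc-length-spaced points (default 300) and aligned by full generalized
Procrustes analysis: centring, unit centroid size, and iterative optimal
rotation onto the running consensus until the consensus moves < 1e-8.
Reflections are never applied.  The stored consensus is the coordinate-wise
mean of the aligned shapes.

**Elliptic Fourier analysis.** Because the chains are equally spaced in arc
length, harmonic coefficients are computed by the discrete Fourier
transform of the x(t), y(t) series — the trapezoid-rule form of the
elliptic Fourier integrals.  This makes the transform exactly invertible:
with all ⌊k/2⌋ harmonics the inverse reproduces the semi-landmarks to
machine precision (the Nyquist term is carried with its un-doubled weight
so even k round-trips exactly).  Harmonic power is Σ(aₙ²+bₙ²+cₙ²+dₙ²)/2;
the retained harmonic count H is the smallest whose cumulative power
fraction reaches the target (default 0.99), averaged across shapes by
default (`criterion="mean"`; a stricter per-shape criterion is available).
An optional moving-average smoother exists for noisy digitizations and is
off by default.

**Morphospace.** PCA is run on the raw (unstandardized) covariance of the
4H-dimensional coefficient vectors, the common practice for elliptic
Fourier data where coefficients share units.  PCA axis signs are arbitrary;
they are fixed deterministically by requiring the shape with the largest
absolute score on each axis to score positive.  Warp models are inverse-EFA
reconstructions on a regular nx×ny lattice (default 10×10) spanning the
observed PC1/PC2 ranges, with all other PCs at zero.  A warp is invalid iff
its outline self-intersects (checked with a ring-simplicity test; an O(n²)
segment oracle backs this in the tests).  Invalid warps model the
biologically impossible regions of the morphospace where dorsal and
ventral outlines cross.

## Biomechanical traits

**Lever traits.** AR = (max y − min y)/(max x − min x) over outline
vertices; MA = |joint → dorsal-most vertex| / |joint → anterior-most
vertex| with the joint at the posterior-most vertex.  Tie-breaks (ventral
for the joint and anterior point, posterior for the coronoid apex) make
the measurements deterministic on degenerate shapes such as rectangles.
The dorsal-most vertex operationalizes "apex of the coronoid/adductor
process"; a config option can restrict the search to the posterior half
for pathological shapes.  Both ratios are unitless and similarity-invariant
(tested to 1e-9).

**Cantilever bending simulation.** The outline is scaled to a common
anteroposterior length (default 100 mm — warp shapes are unit-size and the
physical testing convention is fixed-size models), extruded conceptually to
thickness t = 10 mm, and rasterized into square bilinear (Q4) plane-stress
elements: a cell is filled if its centre lies inside the polygon, and only
the largest connected block is kept so stray pixels cannot produce a
floating, singular subsystem.  Material: E = 20 000 N/mm² (20 GPa),
ν = 0.3 — standard bone-proxy values for linear static jaw models.  All
nodes within a patch around the posterior-dorsal and posterior-ventral
extreme points (the maximizers of x+y and x−y) are fully fixed; a total
load P = 100 N is applied in −y, split over the nodes of a patch at the
anterior-most point.  Patches have a *fixed physical radius* of
2·(length/150) — twice the default element size — widened to 2h on coarser
meshes.  A radius proportional to h would shrink to point constraints under
refinement, and 2D elasticity diverges logarithmically there; with the
fixed radius the tip deflection converges (measured 1.96–1.98 mm on the
100×10 mm benchmark against the 2.016 mm Timoshenko closed form
PL³/(3EI) + PL/(κGA), κ = 5/6).  If a patch catches no node (very thin
tips on extreme warps) the nearest active node is used.  Reported values:
deflection = mean −u_y over loaded nodes, capped at 10 mm to mirror a bench
test with limited crosshead travel (the raw value is kept alongside;
downstream analyses use the capped one), and strain energy ½uᵀf in N·mm
(×10⁻³ for J).  For this load case SE ≡ P·δ_raw/2 by the work-energy
identity.  Default h = length/150 gives ~10⁴ elements and sub-second
solves.

**Trait grid and interpolation.** Valid warp traits populate a regular
(PC1, PC2) lattice; invalid warps and analyst-excluded nodes form the
missing mask (exclusion is always explicit — no automatic outlier
detection, since "unrealistic" has no operational definition).  Taxon
traits are bilinear within each cell, exact at populated nodes; any query
in a cell with a missing corner, or outside the lattice, is missing (NaN),
never extrapolated.

## Occupancy, disparity and allometry

The occupancy null draws (PC1, PC2) points uniformly over the lattice
bounding box; draws landing where interpolation is missing are dropped (not
resampled) and the effective n is reported.  Each simulated set is compared
with the observed taxa by Wilcoxon rank-sum per variable (PC1, PC2 and the
four traits); the summary is the fraction of sets with p < 0.05 plus one
pooled test.  Note a calibration subtlety verified in testing: the
per-dataset p-values are uniform only over *joint* randomness; conditioning
on one fixed observed sample skews the significant fraction (typically
towards 0 for a typical sample).  Calibration checks therefore redraw the
observed taxa each replicate.

The rank-sum test uses exact enumeration for min(n, m) ≤ 8 without ties
and the tie- and continuity-corrected normal approximation otherwise; the
measured worst-case disagreement between the two at n = m = 8 is 0.011.

Disparity defaults to the sum of per-dimension variances (rotation
invariant); mean pairwise distance is also provided.  Comparisons are
bootstrapped within groups and rarefied to the smaller group's n; the
between-group p is the two-sided overlap of the rarefied distributions,
2·min(P(A>B), P(B>A)).  Group summaries report medians, means, A:B
percentage ratios, rank-sum and one-way ANOVA p-values, and count taxa
dropped per trait.  Allometry is OLS of each trait on log₁₀ mass, plus the
allometric exponent as the log-log slope of adductor mass on body mass.

## Adaptive landscape

Performance surfaces are 6-term quadratics fitted by OLS to the warp-grid
trait values and standardized (zero mean, unit variance) over a 50×50
evaluation lattice spanning the morphospace box, so every trait contributes
at equal variance.  The four default inputs are negated strain energy
(stiffness; higher = better), MA (bite force), 1/AR (speed) and AR
(displacement/compliance); negations are recorded on the surface metadata.
The combined landscape W = Σ wₙFₙ is min-max rescaled over the lattice into
(ε, 1], ε = 1e-6.  Group weights are found by exhaustive search of the
simplex lattice at step 0.05 (1771 candidates for four surfaces),
maximizing Σ ln Ŵ(taxon); the support set is {w : ΔlnL ≤ 2}, and groups are
compared by support-set overlap.  The group height z is the mean
standardized (pre-rescale) W at the optimum.

**Identifiability caveat.**  The weights are only weakly identified from
taxon positions: standardization and min-max rescaling absorb all scale
information, so neighbouring weight vectors (one 0.05 step apart) generate
taxon densities separated by only ~10⁻³ nats.  At realistic sample sizes
(tens of taxa) the *point* estimate wanders several grid steps, for any
quadratic surface design; the ΔlnL ≤ 2 support set is the meaningful
output and is what retains the generating weights in simulations.  A
`normalized=True` option subtracts n·ln(lattice-mean Ŵ), making the
criterion a proper density likelihood (consistent as n grows); the default
keeps the descriptive convention of summing ln Ŵ.

## Trait evolution on time trees

All models are Gaussian with the root state z₀ and rate σ² profiled in
closed form (GLS) and at most one remaining parameter optimized by bounded
1-D search.  Covariances (unit rate): BM — shared root-to-MRCA path length
t_a; OU with *fixed root* — e^(−α d_ij)(1−e^(−2α t_a))/(2α), valid on
non-ultrametric trees, which matters because fossil tips are first-class
here (a stationary-root variant is not provided); EB/ACDC — branch
segments [t₁, t₂] rescaled to (e^(r t₂)−e^(r t₁))/r with
r ∈ [−10/T, +10/T] (T = tree height), allowing deceleration or
acceleration; α ∈ [1e-8, 50/T].  Parameter counts: BM 2, OU 3, EB 3;
model selection by AICc weights.

A point verified in testing and worth knowing: on **ultrametric** trees the
fixed-root OU and accelerating EB covariances coincide, so OU can never
carry an Akaike weight above 0.5 there; with fossil (shortened) tips the
models separate cleanly and OU simulated at αT = 5 is recovered with
weight > 0.9.

**Two-rate search.** For every internal non-root node with ≥ 5 descendant
tips (scalars on smaller clades are weakly identified), BM is refit with a
free rate scalar on the clade including its stem, optimized on a log scale
in [1e-4, 1e4]; the best node is selected by AICc (k = 4: σ², z₀, scalar,
shift location; AIC also reported).  Because the best node is chosen over
~n candidates, the raw criterion comparison is anti-conservative (measured
~75% false-positive rate on homogeneous 150-tip data); a shift is therefore
only reported when it beats single-rate BM by ≥ 2 criterion units, the
usual support-region convention, which brings the false-positive rate to
~20% while leaving strong shifts (e.g. scalar 16 on a 40-tip clade)
recovered essentially always.  Ensemble summaries tally, per clade tip set,
the percentage of tree samples with an increase or decrease; tip sets are
mapped onto a reference topology and unmatched sets are reported as
"unmapped", never dropped.  Both exact-node and within-one-node summaries
can be derived from the tip sets.

**Multivariate shape rates.** Scores (taxa × PCs) are transformed by the
symmetric inverse square root of the BM covariance after removing the GLS
root estimate; a group's rate is its mean squared transformed deviation per
dimension, and the significance of the larger/smaller ratio comes from
permuting group labels (the transformed rows are exchangeable under the
null), p = (1 + #{perm ≥ obs})/(n_perm + 1).  Ancestral states are GLS
conditional means under BM.

## Synthetic data: what it emulates, and what it does not

Outlines are built from smooth arcs — a ventral arc, a rising dorsal corpus
line with a Gaussian coronoid bump, a posterior condyle taper —
deliberately *outside* the Fourier model class so EFA is tested on shapes
it cannot represent exactly.  Within the documented parameter box every
outline is closed, canonical and simple.  Datasets place two clades
(defaults: A deeper-jawed with taller coronoids than B, a
mammal-versus-non-mammal style contrast) on a pure-birth tree of height
250 Myr, with each jaw parameter evolved by BM along the tree and scaled so
its marginal tip standard deviation matches the configured value, then
clipped to the box; body masses are log-normal and independent of shape by
default (matching the observed absence of trait–mass allometry).
`fossilize` shortens a fraction of terminal branches to emulate extinct
tips.  Branch lengths are floored at 10⁻⁴ of tree height because exact
zero-length branches (which the birth-death sampler can emit) make the BM
covariance singular.

What passing tests on these data do **not** show: real digitization noise,
curve-sliding landmark error, 3D-to-2D projection artefacts, clade-specific
allometry, or the richer covariance structure of real jaw datasets (the
synthetic morphospace concentrates ~95% of variance on PC1, versus ~60% on
two axes in empirical datasets of comparable scope).

## Problem sizes and runtime

Default analysis runs use 80 taxa, 300 semi-landmarks, a 10×10 warp grid
(~10⁴ plane-stress elements per bending solve, ~100 solves ≈ 30 s), and
recovery/calibration experiments of 50–300 seeded replicates — sizes chosen
to keep a full reproduction in minutes on one CPU while leaving the
statistical checks well-powered.  `scripts/acceptance.py` completes in
about a minute.

## Known limitations

- The bending model is 2D plane stress with homogeneous isotropic material;
  no contact, no heterogeneous properties, no muscle force vectors.
- Landscape weights are weakly identified (above); treat point estimates as
  descriptive and compare support sets.
- The two-rate search fits one shift; nested or multiple shifts are
  summarized only through the ensemble tallies.
- Tree ensembles are consumed, never generated: divergence-time estimation
  and occurrence-based time-scaling are out of scope.
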