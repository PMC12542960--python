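# Methods

This note documents the models, conventions and numerical choices behind
`microdyn`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Coordinate and unit conventions

Stacks are `(t, z, y, x)`, single volumes `(z, y, x)`; physical coordinates
are micrometres in the same order. Default acquisition geometry follows
standard two-photon settings for cortical microglia: a 258-μm square field
of view at 512×512 pixels (0.504 μm/px), 50-μm stacks at 2-μm z-steps
acquired every 60 s for surveillance, or 25-μm stacks every 30 s for
chemotaxis. All analyses are anisotropy-aware: distances and volumes use the
per-axis voxel pitch.

## Synthetic microglia

A cell is a spherical soma (default radius 4 μm) plus a rooted tree of
tubular branches. Growth is parametrized by azimuth and a bounded z-slope
(|slope| ≤ 0.15 by default): this matches cells imaged in thin cortical
stacks, which appear flattened in z, and gives a hard guarantee that the
arbor stays inside the simulated volume (z-extent ≤ slope × total path
length). Each branch is a polyline of equal-length segments summing exactly
to its nominal length — `length_scale` at depth 0, decaying by 0.6 per
generation — with small azimuthal jitter between segments; after each branch
one uniform draw decides whether two children sprout. Because lengths are
exact and all randomness is a fixed pre-order sequence of uniform draws from
`default_rng(seed)`, ground-truth branch count and total length are exact
and the branching process can be replayed draw-for-draw (this is used as a
test oracle).

Rendering rasterizes each segment as a capsule: a voxel is set when its
centre lies within the branch radius of the segment, in physical
coordinates. This centre-of-voxel rule is exactly invertible — the truth
mask is by construction the binarization of the noiseless render. Intensity
is two-level (background 5, cell 100 by default); the label distribution of
real eGFP/lectin stains is not modelled, only the contrast that matters for
thresholding. Noise is Poisson photon noise (via a photon-scale parameter)
plus additive Gaussian read noise, applied after rendering and after any
drift — the order a microscope would impose.

Surveillance dynamics: each terminal branch gets a speed drawn from
N(mean, sd) truncated at zero (default 2 ± 0.5 μm/min, the scale of
cortical microglial process motility) and oscillates between 0.3× and 1.25×
its initial length, reflecting at the bounds; a global slowdown factor from
a configurable onset minute models acute pharmacological blockade. The soma
and internal branches are static — cortical microglia move mainly their
processes — so process dynamics are isolated in the ground truth, and
per-transition added/removed voxel counts are recorded as exact set
differences of consecutive truth masks.

Chemotaxis scenes are radial process rods (one per 10° by default)
converging on the ablation centre such that the true clear area follows
`A(t) = A_∞ + (A₀−A_∞)e^{−t/τ}` with A₀ = π·40², A_∞ = π·3² μm² by default.
Per-rod static multiplicative jitter (±6%) makes the front irregular; since
the fit is scale-equivariant this does not bias τ. The capsule end-cap is
offset by the rod radius so the nearest rendered voxel sits at the nominal
front.

Not emulated: optical PSF blur, photobleaching, multi-cell crowding, soma
displacement, true punctate labelling statistics. Passing tests therefore
demonstrate correctness of the measurement code on geometrically faithful
inputs, not robustness to every optical artefact of real tissue.

## Preprocessing

Background is a per-frame low-percentile constant (default 10th),
subtracted and clipped at zero; median filtering (default radius 1) is
applied per z-plane. Drift is modelled as per-frame rigid integer-voxel
translation: (y, x) estimated by phase cross-correlation of maximum-z
projections against a reference frame, then z from (z, x) projections.
Shifts are applied with constant fill; a normalized-correlation confidence
score flags unreliable frames, and shifts above 10% of the field of view
warn rather than fail. Manual cell selection is replaced by a reproducible
rule: Otsu threshold within a dilated bounding box around the seed
component, then the 26-connected component containing the seed
(26-connectivity keeps thin diagonal processes connected). The soma is the
largest inscribed sphere (anisotropic distance transform) near the
intensity-weighted centroid, intersected with the temporal minimum of the
masks so soma ⊆ mask holds at every frame.

## Surveillance metrics

PE/PR are computed on the full 3D masks (voxels), since the analysis runs
on z-stacks; a 2D variant is available by projecting first. The normalized
index divides by the mean raw index over baseline transitions (default
minutes 1–10; effect window 35–40); a fully static baseline raises an
explicit error, since the normalization is undefined. For binary masks the
"minimum-intensity projection over time" used for stationary processes
equals the temporal intersection of per-frame maximum-z projections; the
soma projection is excluded. The territory is the area of the 2D convex
hull of projected voxel centres (a 3D hull volume is available). With this
convention a filled square of side 10 μm has hull area 100 μm² and a cross
with tips at ±20 μm has 800 μm²; for ramified cells the hull far exceeds
the pixel-count area, but for convex blobs the centre convention can
undershoot it — the hull ≥ projected-area ordering is guaranteed only for
process-bearing morphologies, which is the intended domain. The
cumulative-surveillance delay extrapolates a least-squares line through the
final third of the slower trace to the faster condition's 15-min value; on
exactly linear traces with rate ratio 0.4 this yields the closed-form 150%
delay.

The motility index divides the raw index by mean projected cell area.
Size-invariance holds when cell size scales with arbor (more processes ⇒
proportionally more moving tips *and* more area); it is verified in
simulation at 6 vs 12 arms, where the raw index doubles and the motility
index agrees within 10%. For small cells the fixed soma area breaks exact
invariance — a property of the metric itself, not of the implementation.

## Chemotaxis quantification

The clear area divides the projected image into radial sectors (default 36,
i.e. 10° — a balance between front localization and noise); each sector's
front is the minimum centre-to-pixel distance, capped at the analysis
radius. A pixel is credited to every sector its footprint overlaps
(half-angle `atan(0.6·pixel/d)`), which keeps fronts well-defined when
sectors are narrower than the angular pixel spacing: a fully covered disc
then yields ≈0 clear area and 36-sector areas agree with fine polar-grid
integration within 2% for smooth fronts. The monoexponential fit uses
least squares initialized with A₀ = first value, A_∞ = last value, τ =
time to half-decay, with τ bounded to (0, 10× recording length];
non-convergence and decay-free traces are flagged, not raised. By default
the full trace is fitted; truncation at the first minimum is available for
traces with a hard plateau.

## Morphometrics

Skeletonization thins the mask on an isotropic grid (linear resampling to
the finest voxel pitch; 2-μm z-steps against sub-μm xy would otherwise bias
the medial axis), converts skeleton voxels to a 26-connected spatial graph
in μm coordinates, keeps the component containing the root (the node
nearest the soma centroid), and prunes rare thinning loops with a minimum
spanning tree on edge length. Sholl intersections count edges crossing each
concentric shell: an edge with endpoint distances d₀ < d₁ crosses r when
d₀ < r ≤ d₁, with distances within 1 nm of a shell snapped onto it so
exact-tie nodes partition cleanly. The "number of processes" is N(r) at the
first shell outside the soma radius (primary processes); the count of all
branch segments is also available, since figure conventions differ. Total
process length is the sum of Euclidean node-to-node distances; an optional
exclusion radius drops intra-soma skeleton edges, which otherwise inflate
the length by roughly one soma radius per primary branch. Skeleton-derived
lengths agree with simulator ground truth to within ~10% (voxelization and
tip erosion); graph-based Sholl counts are exact. Compartment ratios
restrict the signal mask to the cell, split it at the soma submask, and
report process/soma signal volume plus signal volume normalized to cell
volume; a soma without signal flags the ratio undefined rather than
dividing by zero.

## Statistics

Normality requires both Shapiro-Wilk and Anderson-Darling at α = 0.05 — a
conservative conjunction, configurable at the module level. Two normal
groups proceed to a two-sided F test (Student's t if equal variances,
Welch's t otherwise); any normality failure routes to Mann-Whitney U
(independent) or Wilcoxon signed-rank (paired). Paired normal data use the
paired t directly: a two-sample variance pre-test is meaningless for a
within-cell design, and the branch trace records this. For ≥3 groups,
Bartlett's test (the k-group generalization of the F test) decides between
one-way ANOVA + Tukey and Welch's ANOVA + Games-Howell (via pingouin); any
normality failure gives Kruskal-Wallis + Dunn with Bonferroni adjustment
and the standard tie correction.

Calibration: under matched null simulations each *chosen* test maintains
its nominal level (rejection rate conditional on the branch within the
binomial 95% CI of 0.05 at 10⁴ replicates). The unconditional rate of the
full adaptive procedure is slightly inflated under strong heteroscedasticity
(~0.057 at n = 20 per group with a 5:1 SD ratio), because the ~13% of
draws that fail a normality pre-test are routed to Mann-Whitney, which is
not size-valid under unequal variances. This is an inherent property of
normality-pretest decision trees, documented here rather than hidden.

Power analysis uses the noncentral-t formulation: power at n per group and
standardized effect d is `P(|T| > t_{1−α/2,2n−2})` for T noncentral-t with
df = 2n−2 and noncentrality d·√(n/2); the sample size is the smallest n
meeting the target. With control mean 100, SD 25, effect 50% (d = 2),
power 0.80, α = 0.05 two-sided this gives n = 6 (achieved power 0.876 at
n = 6, 0.791 at n = 5), matching Monte-Carlo power within simulation error.

## Problem sizes and determinism

Tests and the acceptance script use compact grids (~100–140 μm fields at
1 μm/px, 10–41 frames) — large enough for multi-branch arbors and
sub-voxel tip dynamics while keeping full runs to a couple of minutes. All
randomness flows from integer seeds through `numpy.random.default_rng`;
identical seeds give bit-identical stacks, and pipeline reports embed the
config hash, seed and package version.

## Known limitations

- Drift correction is rigid translation only; rotation or non-rigid tissue
  deformation is out of scope.
- Segmentation assumes one connected cell per seed point and two-level
  contrast; densely overlapping cells need manual separation upstream.
- Voxel skeletons lose ~1 branch radius at tips; lengths are accurate to a
  few percent, not exact.
- The clear-area metric assumes the ablation centre is visible in the
  projected field and that processes approach roughly radially.
- Sample-size planning covers the two-sample t design only.
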