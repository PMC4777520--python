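# Methods

This note documents the models, defaults and design decisions behind
msiseg, in the spirit of a methods appendix: what each stage assumes, which
knobs matter, what the synthetic phantom does and does not emulate, and
where the design was genuinely open.

## Data model

All datasets are binned onto one common m/z axis (Δm/z = 0.1 Da, half-open
bins `[k·Δ, (k+1)·Δ)` anchored at integer multiples of the bin width;
values within 1e-9 Da below an edge snap up, keeping the half-open
convention robust to floating-point representation). Rows carry a
hierarchical index (t, r, x, y). The matrix is stored sparse; filters drop
rows/columns but keep each column's original bin index, so every retained
column remains addressable by m/z throughout the chain. Binning conserves
in-range total intensity exactly.

## Square-root transform

MALDI intensity noise is approximately heteroscedastic with variance
proportional to the mean; the square root is the matching
variance-stabilizing transform and is applied element-wise before any
cross-spectrum comparison.

## Recalibration

Small per-spectrum and per-dataset m/z shifts are corrected by integer-bin
translations (±k bins, k ≤ 4 at the 0.1 Da bin width, so every single
shift is strictly below the 0.5 Da cutoff). Shifts are estimated by
FFT-based cross-correlation of median-normalized spectra against a median
reference, with ties resolved to the smallest |lag|, negative before
positive. Three passes run in order, each with freshly computed
references: toward the median spectrum of the spectrum's (t, r) stratum,
then of its dataset, then of its region across all time points. Only the
third pass moves datasets relative to each other.

Two robustness measures extend the basic scheme:

- **Degenerate references.** A per-bin median across datasets is
  identically zero when drift spreads the batch so far that no bin is
  occupied by half the rows of a stratum. In that case the stratum's mean
  spectrum (a hump over the drift spread, centered on the drift density)
  serves as the reference; the event is logged.
- **Fixpoint iteration.** The three-pass cycle repeats (up to 5 rounds)
  until a cycle applies no shift. When drifts are well below the cutoff
  the first cycle already aligns the batch and the second is a pure
  verification round; when the spread approaches the cutoff, the first
  cycle only rough-aligns and the recomputed medians of the next cycle
  pull the stragglers in. Each recorded shift respects the cutoff
  individually; the report lists (spectrum, round, pass, shift).

Alignment is to the batch consensus, not to absolute m/z truth: after
recalibration the batch can sit a bin or two off the nominal positions as
a whole, which is why feature extraction uses tolerance windows (below).
The shifts are pure translations; an affine (offset + slope) model is not
implemented.

Implementation notes: lag estimation runs on the matrix restricted to
occupied columns dilated by the maximum lag — exactly equivalent at the
allowed lags, since removed columns are zero in both spectrum and
reference — and in float32; both are performance choices with no effect on
the estimated lags.

## Background-image filter

Intensity images that look like known background ions are removed. The
shipped reference list contains DHB matrix cluster/fragment ions and a
placeholder adhesive-tape (siloxane-like) series; both should be adapted
to the experiment at hand. Pearson correlation is computed between
vectorized images over the foreground (ROI) pixels of all datasets; a bin
is removed when its maximum correlation against any reference image
reaches the threshold, and reference bins are removed unconditionally.
Constant images (e.g. tape ions absent from the foreground) have undefined
correlation and are retained.

The default threshold is r ≥ 0.9, i.e. the filter removes only images
essentially identical to a reference. The reason is a measured confound:
every raw image inherits the shared pixel-to-pixel sensitivity (gain)
pattern, which induces a broad positive correlation floor between flat-ish
biology images and matrix references (up to r ≈ 0.8 on the phantom); a
permissive threshold removes substantial biology, and does so
drift-dependently per dataset. Genuinely unstructured background images
are removed anyway by the ROI and VE stages, so the conservative threshold
loses nothing. Normalizing before correlating does not help: reference
images then inherit the inverse of each region's median signal and
correlate with region-specific biology even more strongly.

## Variance-explained filter

Each bin's image (per dataset, zero-filled into the bounding box of the
retained pixels, stacked row-wise across datasets into one matrix) is
scored with VE = σ₁²/Σσ_k² over its singular values — 1 for a rank-1
image, 0 for an all-zero one. The joint stack gives one decision per bin
for the whole batch and keeps structure visible even when only part of the
datasets carries it (all-zero blocks contribute nothing to any singular
value). Bins at or above the mean VE of all images are retained (the
boundary is inclusive: only strictly-below-mean images are filtered).
Vacant bins score 0 and fall below the mean, so on realistic batches this
stage removes the vacant bulk of the axis — it is the main bin reduction
of the pipeline.

A caveat worth knowing: the VE here is the raw (uncentered) ratio, so the
first component of any strictly positive image is dominated by its mean
level and dense positive noise can score as high as ring-shaped biology.
The filter therefore separates occupied from vacant/sparse bins well, but
it is not a sharp structured-vs-noise discriminator for dense images; the
curated target list is what ultimately excludes artifact channels from
X*.

## Normalization and feature selection

Every informative spectrum is divided by the median of its positive
retained intensities (rows without a positive entry are dropped with a
warning; afterwards each surviving row's positive median is exactly 1).
Targets from the peak list are then extracted with tolerance windows: each
target m/z snaps to the retained bin within ±2 bins of its nominal
position carrying the most signal, and its intensity is integrated over
the retained bins within ±2 bins of that center. The window is wide
enough that a one-bin residual misalignment never clips a finite-width
peak — with a narrower window, the clipped fraction differs per dataset
and imprints the time point on every profile of signal-sparse regions.
Targets snapped to the same center collide and only the lowest m/z of the
group is kept (this is how near-isobaric adduct pairs de-duplicate).
Profiles that are entirely zero on the selected features are dropped (the
cosine distance downstream is undefined for them).

The shipped target panel (`data/target_peaks.tsv`, 103 entries, 9 flagged
near-isobars) lists identified seed metabolites — hexose oligomers DP
2–13 as Na/K adducts, phosphatidylcholines and other lipids, hordatines
and hydroxycinnamic acid amides, and a few unidentified signals. On the
default phantom it collapses to 93 features after deduplication.

## H²SOM

Ring sizes follow r₁ = 7, r₍k+1₎ = 3·r₍k₎ − r₍k−1₎ (r₀ := 0): 1, 7, 21,
56, 147, … — the vertex rings of the regular {3,7} triangular tessellation
of the hyperbolic plane, the unique regular choice producing this
hierarchy. Nodes sit at equal angles per ring at hyperbolic radius 1.5·k;
each node's parent is the hyperbolically nearest node of the previous ring
(ties to the lower id), which gives every ring-1 node three ring-2
children and ring-3 fan-outs of 2–3.

Training is hierarchical and online. The root prototype is the normalized
mean profile. Each deeper ring initializes from its parents plus seeded
jitter (scale 0.05) and refines over `min(20·m, 100 000)` samples drawn
with dataset-balanced probabilities (each time point 1/|T|, uniform
within). The winner is found by beam search (default beam width 2) through
the already-trained upper rings; the winner and its ring neighbors move
toward the sample under an exponentially decaying learning rate
(0.5 → 0.01) and Gaussian ring-neighborhood (width 0.2 → 0.05), and are
re-normalized to unit length, so the cosine BMU is a maximal dot product.
All randomness flows from one seed; training is deterministic.

The narrow default neighborhood is a deliberate choice. With a wide
neighborhood (e.g. 2 → 0), every surplus unit is dragged into occupied
regions and each tight, well-separated cluster is split evenly — a
7-quantizer of 3 clusters then caps the level-1 region agreement (ARI)
near 0.55, as does k-means with k = 7. With the narrow neighborhood,
units specialize competitively: each well-separated cluster captures one
dominant node per ring, surplus nodes stay parked near their parent
direction and win nothing, and the refinement of within-cluster structure
is delegated to the deeper rings — the coarse-to-fine reading of the
hierarchy. The cost is that ring adjacency is not data-organized at a
given level (the color code still tracks lattice geometry). Widen the
neighborhood via `H2SOMParams` to trade back.

Assignment computes each profile's leaf BMU (beam search; with a beam at
least as wide as every ring it equals an exhaustive leaf scan) and maps it
to its ancestor at the requested level, so level-k clusters are exact
coarsenings of level-(k+1) clusters, and assignments are invariant to
positive per-profile scaling.

## Visualization

Lattice nodes project to the Poincaré disk (radius tanh(ρ/2) at their own
angle): the root at the origin, deeper rings at larger radii, everything
strictly inside the unit disk. Hue = (angle + rotation)/2π mod 1,
saturation = radius scaled so the outermost ring reaches 1 (maximal leaf
contrast), value = 1; the root is achromatic and a 2π rotation is the
identity. Cluster maps paint assigned pixels with their level-ancestor's
color, leave unassigned pixels transparent, and can composite over an
underlay raster. The interactive exploration of the original web tool is
replaced by the rotation parameter, per-level PNG renders, per-cluster
profile tables, and a JSON export (nodes, positions, colors, prototypes,
assignments) that an external viewer can consume.

## Synthetic phantom

The generator emulates an 8-time-point germinating-seed series on an
80×40 grid: a seed ellipse on background, an endosperm ellipse, and an
embryo lobe growing linearly with t. Region mean profiles assign compound
classes to compartments (secondary metabolites high in the embryo,
oligosaccharides and lipids in the endosperm, the unknown signals in the
remaining seed tissue, with low cross-region baselines and a deterministic
five-step per-feature modulation). Within the endosperm, the 11 Na/K
adduct pairs of the hexose series are weighted complementarily along the
normalized radial position (Na highest centrally, K toward the rim,
weights in [0.2, 0.8] so their sum is flat) — mirroring the observed
complementary adduct localization. DHB-like matrix ions appear in all
pixels, tape-like ions only in background pixels, and five unstructured
noise channels carry |N(0, 30)| intensity everywhere.

Per pixel, intensity = gain × max(0, mean + noise) with noise variance
σ²·mean (σ² = 4, i.e. ≈20% CV at the mid intensity level of 60 a.u.) and
log-normal per-pixel gain (σ = 0.25). Each ion is emitted as three m/z
samples (center ± fwhm/2, weights 0.5/0.25/0.25; default fwhm 0.15 Da)
approximating the finite peak width of profile-mode TOF data — essential
realism, because with zero-width stick peaks drifted datasets occupy
disjoint bins and cross-dataset median references degenerate, which real
profile data never exhibits. Setting `peak_fwhm_da = 0` gives idealized
stick spectra for exactness tests. Each dataset's m/z axis is translated
by a drift drawn from U(−0.3, +0.3) Da (configurable, or pinned
explicitly); the truth object records masks, drifts, profiles and seed.

Not emulated: isotope envelopes, ion suppression, chemical baseline,
spatial correlation of the gain field, 3D geometry. Passing tests on the
phantom therefore demonstrate the pipeline's mechanics (alignment,
filtering, normalization, clustering, rendering) under controlled
conditions — not performance on any real tissue batch, where peak density,
baseline and batch effects are harsher.

## Scale and determinism

Default problem sizes keep a full phantom analysis at roughly half a
minute on one CPU: 25,600 spectra × ~21k bins sparse, ~14k profiles × 93
features, 100k training samples per ring. Every stochastic component
(phantom, training) takes an explicit seed; the pipeline derives
per-stage seeds from one global seed, so stagewise and monolithic runs
are byte-identical.

## Known limitations

- Recalibration is integer-bin and translation-only; systematic sub-bin
  offsets survive (hence the tolerance-window extraction).
- The uncentered VE statistic separates occupied from vacant bins but not
  dense noise from ring-shaped structure (see above).
- The background filter's correlation is confounded by shared gain; it is
  deliberately conservative and relies on the ROI/VE stages and the
  curated target list for the rest.
- With a narrow training neighborhood, within-ring adjacency is not
  data-organized; the hue ordering of occupied nodes is driven by the
  lattice, not by profile similarity within a ring.
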