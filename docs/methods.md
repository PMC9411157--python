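# Methods

This note documents the models, conventions and numerical choices behind
`tjmesh`, what the synthetic generator does and does not emulate, and the
known limitations.

## Coordinate and intensity conventions

Pixel coordinates are 0-based, x rightwards (columns), y downwards (rows);
ROIs are half-open boxes `[origin, origin + size)`. Intensities are
promoted to float64 at load. Two physical pixel sizes coexist in STED
practice — 18.9 nm (acquisition) and 20 nm (the convention used for the
texture analysis) — both are carried explicitly by `PixelImage`; the
classification pipeline defaults to 20 nm.

## Texture features

Images are prefiltered with a 3×3 kernel sampled from a σ = 1 px Gaussian
and renormalized to sum 1 (reflect borders). GLCMs are accumulated at
offsets d ∈ {1, 3, 5, 10} px along the four standard directions; diagonal
directions step (d, d) pixels — the Chebyshev offset convention of the
classic texture toolkits, which differs from scikit-image's
Euclidean-rounded offsets (the reason the accumulation is done
in-package, by `bincount` over shifted index arrays). Matrices are
accumulated symmetrically and normalized to sum 1.

Of the Haralick statistics only sum average, sum variance and variance
(sum of squares) are used. Gray levels are indexed 1-based inside the
formulas (pair-sum index k ∈ [2, 2·Ng]); since features enter clustering
after centering/scaling, only relative values matter. 8-bit data are used
at native 256 levels; other ranges are linearly rebinned to 256 levels.
Per-distance features are the arithmetic mean over the four directions,
which makes them invariant under 90° image rotation.

## Segmentation and morphometry

Tubularity is the oriented-flux response in its Gaussian-smoothed
Hessian-equivalent form: at scale r the image (max-normalized to peak 1)
is smoothed with a Gaussian of σ = r px, the smaller Hessian eigenvalue is
negated and clamped at 0, and the response is γ-normalized by r² so scales
are comparable; the output is the maximum over r ∈ {2, 3, 4} px (strand
FWHM ≈ 3–4 px at 20 nm/px). The derivative kernels use a wide truncation
(8 σ) so a flat region has zero response rather than a spurious one
proportional to its intensity. The formulation was numerically stable at
r = 2, so no alternative ridge filter is needed.

The segmentation threshold is a fixed constant, 0.074, frozen once as the
Otsu threshold of the pooled tubularity response over five default-noise
class-B synthetic calibration images (`meshseg.calibrate_threshold` keeps
the procedure reproducible). After thresholding only the largest
8-connected component is retained (ties: first in scan order); an
all-below-threshold ROI yields an empty-flagged mask so QC can drop it.

Skeletons are obtained by thinning; junction nodes are 8-connected
clusters of skeleton pixels with ≥ 3 skeleton neighbours, branches the
8-connected components of the remaining pixels. Branch length sums
orthogonal steps as 1 px and diagonal steps as √2 px (via the branch's
minimum spanning tree, which equals the path for 1-px-wide branches) plus
one connecting step per adjacent junction node; a branch forming a closed
loop loses its closing step (rare, documented limitation). Junction
multiplicity is the number of incident branches (3 → triple, 4 →
quadruple).

Meshes are 4-connected components of the inverted mask not touching the
ROI border (mask 8-connectivity and background 4-connectivity are the
standard complementary pair); areas convert to nm² by the squared pixel
size and the reported variance is the population variance. Zero meshes is
a valid result (mean/var reported NaN; zeroed when assembled into feature
tables, where QC removes such ROIs anyway).

QC keeps an ROI iff 10 % ≤ segmented area ≤ 90 % and the skeleton has at
least 10 branches; boundary values are kept since the exclusion rules are
strict inequalities.

## Classification

Per-ROI rows are averaged per sample. The combined analysis applies
ln(x+1) — rather than ln(x), because morphometry counts can be 0 — then
column centering and unit-variance scaling (sample SD, the R `scale`
convention); constant columns are zeroed with a warning. Clustering is
agglomerative with average linkage under correlation distance (1 −
Pearson between rows); the texture-only analysis uses euclidean distance.
Merge heights of average linkage are asserted non-decreasing on every
run. The cluster count k is chosen by maximal mean silhouette (same
metric), ties to the smallest k — an explicit, reproducible replacement
for a visual dendrogram cut. PCA scores on the scaled matrix are provided
for visualization.

## Colocalization

Costes thresholds: total-least-squares regression of channel 2 on
channel 1 gives (a, b); T1 walks the sorted unique channel-1 intensities
downward (T2 = a·T1 + b) until the Pearson of pixels below both
thresholds is ≤ 0; candidates with undefined correlation are skipped and
exhaustion returns the lowest level. A non-positive global correlation or
slope short-circuits to the channel minima and the global Pearson is
reported — negative coefficients are biologically meaningful (segregation,
exclusion) and are never clipped. The walk is implemented as an
incremental O(N log N) sweep (each pixel leaves the below-set at most
once); tests assert equivalence with the naive exhaustive scan. The
"Pearson above threshold" uses the union (OR) of the two channels'
above-threshold sets; AND is available by flag. The PSF parameter
(default 2 px) only sets the block size of the optional block-scramble
significance test and never alters the coefficient.

## Line profiles and strand width

Profiles are sampled at 1 px steps with bilinear interpolation and
averaged across `width_px` parallel lines at 1 px spacing (defaults: 0.3
µm length, 10 px width). Fits are least-squares Gaussian + offset with
heuristic initialization (range/argmax/half-range) and loose sigma bounds;
non-convergence, a flat profile, or a sigma pinned at its bounds yields
`converged=False` rather than an exception. The reported FWHM is exactly
2.35 × σ — the deliberately rounded convention of the strand-width
protocol, not 2·√(2 ln 2) ≈ 2.3548.

## GHK permeametry

The dilution potential is apical minus basolateral, so the symmetric
solution pair (basolateral Ringer 140 mM Na⁺ / 128.8 mM Cl⁻; apical
mannitol-modified 80.5 / 69.3 mM) gives V = 0 at r = PNa/PCl = 1, V > 0
for r > 1, and limiting potentials (RT/F)·ln(140/80.5) ≈ +14.8 mV and
(RT/F)·ln(69.3/128.8) ≈ −16.6 mV at 310 K. The inverse is closed-form and
rejects potentials outside the open limiting interval. The multi-record
estimator minimizes squared potential residuals over log r, which
tolerates noisy records that individually fall outside the inversion
interval. Absolute permeabilities use the Kimizuka–Koketsu partition with
concentrations (not activities; an activity correction would enter as a
multiplicative factor and is out of scope) and conductance uncorrected
for a cell-free blank unless a blank TER is supplied. Default temperature
is 310.15 K (37 °C); tests evaluate closed forms at the temperature they
state. Tracer Papp uses an ordinary least-squares slope with explicit
unit conversions (min → s, ml → cm³); negative slopes are reported with a
warning, never clamped.

## Spectral FRET

Reference spectra are normalized to unit peak at construction; unmixing is
two-column least squares with negative coefficients clamped and the other
column refit (equivalent to NNLS for two columns). The acceptor
coefficient mixes sensitized emission and direct acceptor excitation,
which share a spectrum and cannot be separated by unmixing alone; the
direct component (from an acceptor-only control) is subtracted before the
ratio. Two instrument presets set the donor/acceptor readout wavelengths
(468/532 nm and 478/530 nm).

## Synthetic generator

Classes A and B build strand centerlines as Voronoi ridges of a
perturbed-grid point process whose spacing s satisfies s² = (π/4)·d² for
target mean mesh diameter d (A: 600 nm, B: 250 nm; the mean tessellation
cell area is s² exactly, and is reported as metadata). Class C is
jittered near-parallel sinusoids at 150 nm spacing; non-meshwork
phenotypes are uniform intensity, random punctae, and clustered punctae.
Centerlines are rendered as Gaussian-cross-section tubes (σ = 25 nm) via
a distance transform against densely sampled centerline points (0.15 px
step), blurred with a Gaussian PSF of σ = 21 nm (≈ 50 nm lateral FWHM,
typical STED resolution), scaled to `photon_scale` = 50 expected peak
counts, and corrupted with Poisson shot noise plus additive read noise
(SD 2 counts), clipped at zero. A straight noiseless strand therefore has
an exactly Gaussian cross-section of σ = √(25² + 21²) nm, which the tests
verify to within 2 %.

Two-channel modes: intermix/integrate/induction share identical
centerlines with independent noise (induction differs from intermixing
biologically — neither partner forms strands alone — but not
geometrically); segregate partitions every strand into alternating
single-channel stretches of 500 nm (a free parameter — measured segment
lengths in tissue vary widely — bounded below by the strand FWHM);
exclude clips two independent tessellations to opposite image halves.
Rasterization collisions at segment boundaries are removed from both
truth masks so the segregate/exclude truth sets are strictly disjoint.

What the generator does **not** emulate: 3D structure and out-of-focus
light, labeling stochasticity and antibody linkage error, strand
curvature distributions of real TJs, vesicle/ER phenotypes, detector
correlations, and drift. Passing tests therefore demonstrate correctness
of the measurement chain on images with known geometry and realistic
photon statistics — not robustness to every artifact of real microscopy.

## Problem sizes

Default synthetic images are 200×200 px at 20 nm/px (the analysis crop
size). The classification recovery runs 10 libraries × 3 classes × 5
images; colocalization uses 20 seeds per mode; strand-width recovery fits
1000 profiles at 5 % noise; GHK recovery uses 200 records at 0.5 mV noise
per ratio in {0.25, 1, 4, 15}. These sizes were chosen to give stable
statistics at desk scale.

## Known limitations

* Branch lengths ignore the closing step of cyclic branches and count one
  connecting step per adjacent junction cluster; junction clusters of
  irregular shape count as single junctions regardless of pixel count.
* The frozen segmentation threshold is calibrated for max-normalized
  images; inputs whose structures occupy a small dynamic range atop a
  bright background would need recalibration.
* Silhouette-based k selection can split a heterogeneous class when given
  very homogeneous replicate libraries; purity is robust to such splits
  but the selected k may exceed the designed class count in edge cases.
* The GHK model covers Na⁺/Cl⁻ only; multi-ion or bi-ionic extensions are
  out of scope.
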