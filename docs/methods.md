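# Methods

This note records the models, conventions and numerical choices behind
`neuromorph`, and what the synthetic-data tests do and do not establish
about real acquisitions.

## Calibration and raster conventions

All spatial parameters are specified in micrometers and converted with the
image calibration (default 0.207 µm/px, the published value for the
212.3 µm × 212.3 µm fields; a source that printed this as "0.207 mm" is
treated as a micrometer typo, since 212.3 µm over ~1025 px is only
consistent with µm). The generator rasterizes a field on a square grid of
`2·⌊field/(2·px)⌋` pixels — the field extent rounded down to an even pixel
count, 1024 px for the defaults.

Foreground convention, fixed package-wide: a pixel is foreground iff its
value is **strictly above** the threshold; ties go to background. All
component labeling and skeleton analysis uses 8-connectivity, matching
diagonal neurite continuity.

## Thresholding

Both automatic thresholds are pure functions of the gray-level histogram,
computed on the distinct observed values with multiplicities (equivalent to
the native 256- or 65,536-bin histogram since empty bins contribute
nothing; this also makes the methods exact on real-valued filter outputs).

* **Huang minimum-fuzziness** (nuclei): for each candidate split, each gray
  value receives membership `u(g) = 1/(1 + |g − μ_class|/C)` in its class
  (class mean μ, gray range C); the split minimizing the histogram-weighted
  binary Shannon entropy of the memberships wins. The returned threshold is
  the largest gray value of the optimal background class, which makes the
  threshold shift-equivariant under constant offsets.
* **Tsai moment-preserving** (neurite masks): the two-level image that
  preserves the histogram's first three moments determines a background
  fraction p₀; the threshold is the gray value whose cumulative fraction is
  closest to p₀ (ties toward the lower value).
* **IsoData intermeans** (cell scoring default): the classic iterative
  "default" threshold, provided for marker binarization.

Degenerate histograms (fewer than two distinct values) raise a dedicated
error; the neurite-mask builder catches it and contributes an empty mask
(a blank Map2 field is data, not an error).

## Mask assembly

The nuclei pipeline is Huang threshold → deletion of components with
equivalent-circle radius `√(area/π) < 20 px` → Euclidean-distance dilation
by 5 px. "Outlier removal" is implemented as component deletion because the
workflow applies it to a mask to drop small objects; a median-despeckle
alternative is available behind `MaskingParams.small_object_mode`. The
pre-expansion mask is the soma-counting substrate (expansion can fuse
neighbors), the expanded mask is the subtraction substrate.

The Map2 channel is duplicated and the two copies are contrast-enhanced
independently (0.1% saturated pixels, half at each tail — the symmetric
allocation is the common convention). The high-intensity branch blurs at
σ = 2 µm and takes the moments threshold; the LoG branch applies an
inverted Laplacian-of-Gaussian and takes the moments threshold of the
response mapped linearly onto the dtype range. Two numerical choices
matter:

* The filter responses are thresholded **as real values**, never
  re-quantized to the integer dtype: rounding dithers the faint mask
  boundary into stair-step contours that skeletonize into hairy spurs.
* The discrete LoG kernel's small DC leakage is subtracted so a constant
  image yields an exactly zero response.

The LoG scale has no published value. The default, σ = 2 µm, mirrors the
blur scale deliberately: the union of a thin (width-matched) LoG band with
the fat blurred high-intensity mask produces bead-string protrusions whose
skeletons are dominated by spurious short branches, while two masks at a
common scale union smoothly. We verified this empirically — LoG scales of
0.3–1.5 µm all degrade branch/junction recovery on synthetic scenes.

## Skeleton morphometry

Thinning is Zhang-style iterative border deletion (scikit-image), iterated
to a fixed point so skeletonization is idempotent; it preserves 8-connected
component counts. Zhang's scan order can kink the final pixel of a
symmetric ribbon off-center; Lee's thinning avoids that artifact but was
measurably worse at junction recovery on synthetic scenes, so Zhang is the
default.

Skeleton pixels are classified by 8-neighbor count (endpoint ≤ 1, slab 2,
junction ≥ 3); mutually adjacent junction pixels form one junction cluster.
Note that orthogonal T-junctions intrinsically produce a 3–4 pixel cluster
under 8-connectivity. A branch is a maximal slab path between terminals;
lengths accumulate the pixel size per orthogonal step and √2 pixel sizes
per diagonal step. Isolated closed loops count as one branch of their cycle
length; an isolated single pixel is an endpoint voxel but no branch
(branches always have positive length). Spur pruning is deliberately **off**
(no pruning is part of the reference workflow); `avg_branch_length` for a
zero-branch image is reported as 0 with an explicit missing-data flag so
tables stay rectangular. Average branch length is total length divided by
branch count per image.

Soma counting is automated as the number of 8-connected components of the
pre-expansion nuclei mask, replacing the reference workflow's manual
multipoint counting; on well-separated nuclei the two coincide.

## Synthetic acquisitions

The generator emulates the study's imaging conditions — not their optics in
detail. Defaults: 212.3 µm field, 0.207 µm/px, 12 cells per field, nucleus
diameters 9–15 µm, 2–4 neurites per cell, bifurcation probability 0.35 per
elongation step, segment lengths 6 µm + Exp(6 µm), neurite widths 1–3 px,
16-bit output with background 400, signal 8000, somatic Map2 glow 1.5×
signal, Poisson shot noise (0.05 photons per intensity unit) plus Gaussian
read noise (σ = 40). Parameter choices that deserve justification:

* **Nucleus diameters 9–15 µm**: the measurement pipeline itself deletes
  mask components below 20 px equivalent radius (8.28 µm diameter), so
  smaller nuclei are debris by definition and would make exact soma-count
  ground truth ill-posed.
* **Minimum segment length 6 µm** (shifted exponential): real arbors keep a
  minimum spacing between consecutive branch points; a pure exponential
  places heavy mass at near-zero spacings that no finite-resolution
  measurement could resolve.
* **DAPI edge ramp σ = 3 px (~0.6 µm)** and ≥ 2.5 µm placement gaps:
  chromatin-density falloff plus optical blur; this also lets the Huang
  nuclei mask extend slightly past the hard nuclear disk, as it does in
  real data, so the 5 px expansion covers the somatic Map2 glow.
* **Intensity levels are implementer-chosen**: the source imagery carries
  no published intensity statistics.

Neurites render as centerline distance profiles `exp(−d²/2σ_w²)` with
σ_w = w/2, truncated at d > w/2 + 1.5 px — the hard support bound makes the
channel-separation invariant exact (with noise off, every above-background
Map2 pixel lies inside the rendered geometry). Z-stacks are emulated as
dimmed copies around an in-focus plane whose maximum projection recovers
the single-plane image exactly; there is no 3-D growth, PSF or
photobleaching model. The knockout phenotype is emulated by lowering
`branching_prob` (and optionally neurites per cell) while holding `n_cells`
fixed, so soma counts match across groups by design.

Ground truth stores the grown forest (soma-root/junction/endpoint nodes,
branch polylines) and the morphometry derived from it: branches = contracted
edges, junctions = bifurcation nodes, endpoints = tips (the soma attachment
point is a root, not an endpoint), total length = Σ polyline lengths from
the nuclear boundary. Two caveats follow: the measured skeleton sees the
neurite only outside the *expanded* soma mask (measured totals run slightly
short of truth near roots), and 2-D crossings between independent neurites
are genuine junctions of the projected image that the tree ground truth
does not contain.

## What the synthetic tests show — and don't

On noise-free default scenes the pipeline recovers soma counts exactly and
branch counts to ~11% median relative error; junction counts recover to
~22%. That gap is a resolution limit, not a bug: a 2 µm filter scale yields
a ~4 µm-wide mask, so a daughter branch is invisible until it emerges from
its parent's halo, branch points closer than ~8 µm of path merge into one
cluster, and projected crossings add junctions absent from the tree truth.
Scene geometries that space branch points far enough to resolve junctions
grow longer arbors whose crossings inflate the branch error instead; the
two errors trade off and we report the defaults honestly rather than tune
the scene to the test. Centerline coverage of the final mask is typically
75–85% (the regression floor in the tests is 70%): branch tips erode by
roughly the filter scale, and that loss is shared by any workflow built on
these mask parameters.

Passing these tests therefore demonstrates correct implementation of the
stated workflow and faithful *relative* group comparisons (the phenotype
direction test recovers lower branch/junction counts and total length and
higher average branch length in the simulated knockout with halved
branching, all significant at n = 30 images/group). It does not certify
absolute accuracy on real images, whose noise, optics and morphology differ
from the growth model.

## Statistics

One-way ANOVA (scipy) across groups with Tukey HSD post-hoc comparisons by
default (Bonferroni-corrected pairwise t tests selectable); the post-hoc
method is recorded in every report. Boxplot summaries use linearly
interpolated quantiles and Tukey fences (1.5 × IQR) for outliers, so
reported numbers are bit-reproducible. The unpaired t test is the classical
equal-variance statistic; two-group ANOVA equals its square (checked
numerically). Stars: `*` ≤ 0.05, `**` ≤ 0.01, `***` ≤ 0.001,
`****` ≤ 0.0001. Images are the units of analysis within groups (matching
per-acquisition boxplots); replicate ids are carried as a column but no
mixed-effects model is fitted. A metric with zero within-group variance
everywhere (e.g. exact soma counts in noise-free simulations) has an
undefined F statistic; the experiment driver records the error for that
metric instead of failing the report.

## Problem sizes

The test suite and the acceptance script use the cohort design of the study
(10 acquisitions × 3 replicates × 2 groups at full 1024 px fields) for the
phenotype-direction check, 12–20 noise-free full-field scenes for recovery,
200 simulations for the type-I error, and smaller 53–106 µm fields for unit
tests of single stages — sizes chosen so the whole suite runs in minutes on
one CPU while keeping the cohort conditions faithful.
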