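# Methods

## Phantom model

The generator renders the imaging situation the pipeline targets: a
five-band wall of alternating echogenicity inside a darker,
contrast-filled lumen. A phantom is a piecewise-constant template plus
multiplicative noise.

**Geometry.** The wall occupies rows `[wall_top_row, wall_top_row +
wall_thickness)`; integer per-layer thicknesses are obtained by
rounding the first four of `proportions × wall_thickness` half-up and
giving the (possibly negative) remainder to the deepest layer, so the
band always totals exactly `wall_thickness` rows and the realized
(quantised) proportions can differ from the requested ones by up to
~2 px in the last layer. A layer that rounds to zero pixels is an
error. Optional bowing shifts each column down by a half-period cosine
bump of amplitude `curvature` px (zero at the lateral edges, maximal in
the centre), which is what makes rectangle labels strict subsets of the
wall. Default proportions are the normal standard vector renormalised
to sum to one; default echogenicities are 200/80/180/70/190 against a
background of 40 — alternating bright/dark with roughly 2.5:1
contrast, a typical appearance, and configurable because which
anatomical layers are hyperechoic varies with scanner and preparation.

**Speckle.** Fully developed speckle is emulated as i.i.d. unit-mean
gamma noise with shape `looks`, giving variance 1/looks (CV = 0.5 at
the default 4 looks) and strict positivity; `looks=None` is the
noise-free limit. The model is purely multiplicative and spatially
white: no point-spread function, attenuation, TGC, or correlated
speckle cells. Passing tests on phantoms therefore demonstrates
correctness of the algorithms under controlled contrast and noise, not
clinical performance.

**Cohorts.** Normals jitter around the normal template via a Dirichlet
draw with concentration `p/0.002` (component SD ≈ 0.02); abnormals
jitter around an effect-shifted template, the default effect doubling
the mucosal fraction before renormalisation (a large, unambiguous
thickening). Wall thickness and top row vary mildly between subjects.

## SRAD

Only the continuous PDE and the two diffusion-coefficient forms are
fixed by the method; the discretisation is the canonical explicit
4-neighbour scheme:

- central differences for ∇I, the 4-neighbour Laplacian for ∇²I, both
  with reflective borders implementing the zero-flux condition;
- the ICOV numerator ½(|∇I|/I)² − (1/16)(∇²I/I)² can go slightly
  negative in smooth regions and is clamped at zero before the square
  root;
- c(q) is clamped to [0,1] by default (both forms exceed 1 when
  q < q₀; the reciprocal form can even diverge), switchable;
- the update I ← I + Δt·div(c∇I) averages c onto cell faces, making
  inter-pixel fluxes antisymmetric so the global mean is conserved
  exactly under reflective boundaries (up to a 1e-8 positivity floor);
- Δt defaults to 0.05 with 100 iterations; the explicit scheme's
  stability bound Δt ≤ 0.25 is enforced.

q₀ is recomputed every iteration as SD/mean of a user-chosen
homogeneous window — on phantoms, the outer half of the lumen margin
above the ROI. Keeping the window a few pixels away from the wall
matters: diffusion bleeds wall brightness into adjacent lumen rows, and
a contaminated window inflates q₀ until every edge looks like speckle.
With q₀ = 0 (a fully smoothed window) c is defined as 1 everywhere,
which keeps the constant image an exact fixed point.

## Stratification

Layers are assumed to stack along ROI rows, i.e. a column crosses all
five bands; real images must be ROI-cropped so this holds. Per column,
the vertical Sobel response (3×3 kernel, reflective borders) is
smoothed with a 1-row Gaussian; the four largest local maxima at least
3 rows apart and strictly inside the wall extent are the inter-layer
boundaries. Wall extent comes from the mask when available (exact on
phantoms), else from the outermost gradient peaks. Fewer than four
interior peaks raises a "cannot stratify" error carrying the count —
the gate for walls whose five-layer structure is not resolvable.

Proportions are consecutive differences of (top, e₁..e₄, bottom)
normalised by the wall height; they sum to one by telescoping. Nine
columns evenly spaced across the middle 80% of the ROI width are
averaged component-wise and renormalised (pixel quantisation leaves
~1e-3 drift); columns that fail are skipped, and fewer than three
successes makes the ROI unstratifiable. Boundary localisation is
deliberately integer-pixel: a noise-free two-row gradient plateau
resolves to the upper row, so recovered proportions sit within ~1 px
per boundary of the rendered geometry.

## Detection

The fixed part of the architecture is the compact U-net described in the
README (ten 3×3 convolutions down the contracting path, four poolings
with channel doubling, four "deconvolution" upsamplings with skip
concatenation, per-pixel softmax). Everything else was open and is
config-exposed: pixel-wise cross-entropy loss (softmax output admits
nothing simpler), Adam at 2e-3, batch size 4, He initialisation,
bilinear resize of inputs to a fixed 2⁴-divisible size (nearest for
masks), defaults of 256×256 input and 8 base channels. Images are
normalised by the *dataset* mean intensity rather than per-image
min-max: per-image stretching turns a wall-free speckle field into
wall-like contrast and produces massive false positives on empty
frames. The ROI is the margin-padded bounding box of the largest
connected component of the predicted mask — how a noisy mask becomes a
single ROI is otherwise open, and this is the obvious deterministic
rule.

The network, including backpropagation, is a compact NumPy
implementation (`gastrolayer.nn`); its gradients are verified against
central finite differences in float64.

## Screening

`d` is implemented exactly as defined, with four terms; omitting
(x₅−s₅)² is not "corrected" (the fifth coordinate is jointly, not
individually, redundant) but `include_fifth_term=True` exists for
sensitivity analyses. The standard vector is estimated as the plain
component-wise mean without renormalisation — the reference s sums to
0.999 — and, by default, from training-split normals only (a "standard"
wall should be normal; `s_from="train_all"` restores the
all-patients reading). The split is stratified by label with
largest-remainder quotas so the overall train fraction is honoured
exactly. Threshold fitting enumerates midpoints between consecutive
distinct training d values plus below-min/above-max sentinels,
maximises training accuracy under "abnormal iff d ≥ t", and breaks
ties toward the smaller threshold; ties at the boundary classify as
abnormal — both conventions favour sensitivity, the natural bias for a
screening test. AUC is the standard trapezoidal/Mann–Whitney area of
the d score.

## Problem sizes and numerical choices in the test suite

Tests and the acceptance script run on one CPU core: stratification
recovery uses 50 phantoms with walls of 100–200 px at 4 looks and 100
SRAD iterations; end-to-end screening uses cohorts of 25 normal + 25
abnormal over five seeds (null-effect AUC is assessed as the mean over
seeds because a ~15-case test split makes single-seed AUC swing by
±0.2); detector checks train a 4-base-channel net for 12 epochs at
256×256 (flat walls) and 128×128 (curved-wall label-style comparison).
These sizes are the package's documented reference configurations.

## Known limitations

- The phantom's speckle is white and stationary; SRAD parameters tuned
  here may need adjustment on scanner data with correlated speckle.
- Boundary localisation is integer-pixel; sub-pixel refinement is out
  of scope.
- Layers are reported ordinally (1–5); no anatomical naming.
- The screening model is binary distance-thresholding; multi-class
  staging and between-group significance testing are not provided.
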