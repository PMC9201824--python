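# Methods

This note documents the models, algorithms and design choices behind
`cropnav`, in the spirit of a package methods appendix: what is computed,
under which assumptions, with which defaults, and what the built-in
evaluations do and do not demonstrate.

## Problem setting and coordinate conventions

Overhead images of row crops are segmented into a binary crop mask, and the
mask is reduced to straight row centerlines plus one navigation line.
Coordinates are 0-based, x = column (rightward), y = row (downward). Row
centerlines are parameterised by their abscissas at y = 0 and y = H−1, which
is numerically stable for the near-vertical rows that dominate this kind of
imagery (a slope–intercept form in y-on-x would blow up). Only straight rows
are modelled; curved rows, multispectral channels and photorealistic
rendering are out of scope.

## Synthetic field scenes

`cropnav.synthetic` renders parametric scenes: `n_rows` parallel bands of
width `row_width` (pixels) at `row_spacing`, slanted `row_angle` degrees
from vertical, on a textured soil background. Nuisance factors emulate the
variability of real field acquisitions — per-scanline Gaussian edge noise
(`jaggedness`, px), weed blobs (`weed_density` per 10⁴ px², radii in
`weed_radius_range`) drawn in crop-like colours, a linear shading ramp over
a random half-plane (`shade_fraction` of the image), and a `growth_stage`
in [0, 1] scaling band width (half width at 0) and canopy texture density.

Three properties are engineered in and tested:

- **Exact truth.** A pixel belongs to a band iff its column index lies in
  the continuous interval [c − w/2 + ε₁, c + w/2 + ε₂); at zero noise an
  integer-length interval covers exactly `row_width` pixels per scanline
  and the band centroid coincides with the ground-truth line, so recovery
  errors measure the algorithms, not the renderer.
- **Label purity.** Weeds and shade perturb only the rendered image, never
  the mask or the lines — they are distractors for the network.
- **Nesting.** Edge noise is drawn with a growth-independent layout, so for
  a fixed seed the mask grows monotonically with `growth_stage`.

Scenes are deterministic in `(params, seed)`; datasets derive per-sample
child seeds counter-style from `(seed, index)`, so reproducibility is
order-independent. Defaults (512×512, 4 rows, spacing 110 px, width 30 px,
jaggedness 2 px, weed density 0.5, shade 0.3) describe a mid-season field at
the scale of public crop-row detection imagery.

What the generator does *not* emulate: perspective distortion, row
curvature, occlusion by machinery, inter-row weeds that touch the canopy,
and realistic illumination. Passing the built-in suites therefore shows the
pipeline is correct and robust under controlled noise, not that the trained
weights transfer to real fields.

## The segmentation networks

Both networks live on `cropnav.nn`, a compact NumPy reverse-mode autodiff
core (im2col convolutions with stride/dilation, transposed convolution,
batch normalisation, PReLU, 2×2 max pooling with indices, separable
bilinear resizing, spatial dropout, Adam). Every operation's gradient is
validated against central finite differences in the test suite, and the
convolution forward pass against scipy's independent implementation.

**Classic baseline.** The original ENet layout: initial block (3×3/2
convolution concatenated with a 2×2 max-pool), stage 1 (downsample to 1/4
resolution + four regular bottlenecks at width 64), stage 2 (downsample to
1/8 + the regular/dilated-2/asym-5/dilated-4/regular/dilated-8/asym-5/
dilated-16 mix at width 128), an identical stage 3 without downsampling,
and a decoder whose upsampling bottlenecks restore resolution through the
max-pooling indices saved by the encoder, finished by a transposed
convolution. Bottlenecks are 1×1 reduce → main convolution → 1×1 expand
with batch norm, PReLU and spatial dropout (0.01 in stage 1, 0.1
elsewhere); downsampling main branches max-pool and zero-pad channels.

**Improved network.** Three structural changes:

1. *Residual boundary stream.* The output of bottleneck 1.0 initialises a
   residual map; after each stage-1 bottleneck the new pooling output is
   added into it. Before stage 2 the two maps are concatenated and
   projected back to the stage width by a 1×1 convolution (with BN +
   PReLU), while a stride-2 3×3 convolution (with BN) brings the residual
   map to the post-downsampling scale. The decoder bilinearly upsamples
   both streams in step; the classifier is a 1×1 convolution over their
   concatenation followed by bilinear upsampling to input size. Addition
   *within* a stage and concatenation *at stage entry* are deliberate: the
   former accumulates, the latter fuses channels.
2. *Convolution replacement.* Stage-1 bottlenecks 1.2–1.4 carry dilation-2,
   asymmetric-5 and dilation-4 convolutions — the same count of modules,
   larger receptive fields, no extra parameters from dilation itself.
3. *Compression.* Stage 3 is removed entirely; no max-unpooling indices are
   needed because the residual stream carries the boundary information.

Channel widths default to the classic ENet values (16 / 64 / 128), the
residual stream carries the stage-1 width (64), and a `width_multiplier`
scales every width for reduced-size experiments. Details the architecture
description leaves open were fixed to the conventions of the widely used
public ENet implementations and to the published parameter budget of the
design this follows: single-parameter PReLUs, bias-free convolutions ahead
of batch norm, and a bottleneck-internal width of a quarter of the wider of
the two interface widths. With those conventions the improved network
counts 273,244 trainable parameters (≈ 0.27 M) versus 372,211 (≈ 0.37 M)
for the rebuilt classic baseline; the parameter count is an exact sum over
trainable tensors, not a serialized-file size.

With two classes the network emits two score maps and the crop logit is
their difference, which is exactly the single-logit sigmoid formulation:
σ(s₁ − s₀) is the crop probability, thresholded at 0.5.

## Training objective and protocol

The loss is `BCE(logits, y) + Dice(σ(logits), y)`. BCE is computed from
logits with log-sum-exp stabilisation (the literal −[y log σ + (1−y)
log(1−σ)] overflows for large |logits|). Dice uses the *soft* formulation
1 − (2|Y∩Ŷ| + s)/(|Y| + |Ŷ| + s) with s = 0.1, required for
differentiability; hard masks are used only for reported IoU. Empty-vs-empty
IoU is defined as 1.0 so a correctly empty prediction is not penalised.

Defaults follow the study protocol: Adam, initial learning rate 1e-4,
decay coefficient 0.1 (applied at epoch 60 by default — the schedule is
configurable since only the coefficient is prescribed), batch size 8,
85 epochs at full scale, and augmentation by horizontal flip, vertical flip
and a ±90° rotation, each applied independently with probability 0.5 and
consistently to image, mask and lines. The rotation direction is drawn
uniformly; note that the composite "flip + flip + rotate" is *not* an
involution unless the two rotation draws cancel, which the tests account
for. Augmenting a vertical line through ±90° makes its y = 0 / y = H−1
parameterisation nearly singular; the abscissas are clipped to ±1e9 and the
mask/image remain exact, so training is unaffected.

The built-in scaled-down run — the one the evaluation suite executes —
trains the width-0.5 network on 200 synthetic 128×128 pairs for 10 epochs
(batch 8, lr 1e-4, augmentation 0.5) and evaluates held-out mean crop-class
IoU on 20 pairs. These sizes keep a pure-CPU run in the minutes range while
still exercising every layer, the full loss and the augmentation path.
Training is bitwise deterministic for a fixed seed (pure NumPy; one seed
drives shuffling, augmentation and dropout).

## Feature points and the improved RANSAC

Scan lines are placed at y = h·N, h = 8 by default — dense enough that a
512-row image yields 64 samples per row, sparse enough for real-time use.
In `per_run` mode every maximal foreground run contributes the midpoint of
its two edge intersections; `global` mode implements the literal
all-intersections mean (one point per scan line). `per_run` is the default
front end because the global mean of a multi-row image is a point *between*
rows and cannot yield per-row centerlines. A `vertical` scan orientation is
provided for near-horizontal rows; the 90°-rotation consistency of the
fitter is tested through it.

Candidate sampling draws two feature points and rejects pairs unless their
separation along the row direction exceeds T (default: one third of the
image extent; axis configurable, `y` for near-vertical rows, the literal
abscissa form via `separation_axis="x"`). The constraint serves two
purposes: it discards pairs unlikely to lie on the same row, and — by
forcing every candidate's inlier span l to be at least T — it makes the
density score

    score = m_t / (l + p),  p = 15,  maximised

discriminative: a full-height row line scores ≈ (H/h)/(H + p) ≈ 0.12,
while clutter alignments score an order of magnitude lower. (Read as a
density, the score prefers lines that collect many inliers per unit length;
p regularises short spans. Without the separation constraint a two-point
"line" of zero span would trivially win, which is why the two mechanisms
belong together.) If no pair satisfies the constraint the sampler falls
back to unconstrained draws with a logged warning.

Inliers are points within `dist_threshold` of the candidate (closed bound;
default 4 px = h/2 — the concept is prescribed, the value chosen to match
the scan density). After `max_iterations` = 500 draws (or an exhaustive
deterministic pair sweep, used by the oracle-equivalence tests) the best
consensus set is refined by *orthogonal* least squares — centroid plus
principal axis. Orthogonal rather than x-on-y regression keeps the refit
well-posed for any line orientation, which the rotation-consistency
invariant requires; for near-vertical rows the two coincide to first order.
Inliers, span and score are recomputed from the refitted line.

Multiple rows are extracted sequentially: fit, remove inliers, repeat. The
loop stops when fewer than `min_points_per_row` = 5 points remain, a fit's
consensus falls below that floor, or its density score drops under
`min_score` = 0.05 (half the scan lines spread over the full image height —
the point at which "structure" is indistinguishable from clutter; this
floor is what rejects ghost lines assembled from spurious points once the
true rows are consumed). The navigation line is the fitted row whose
mid-height abscissa is nearest the image centre, ties broken by score —
a declared convention; whether the operative line should instead bisect an
inter-row corridor is application-dependent and easily swapped.

Accuracy against ground truth pairs each navigation line with the true
centerline nearest in mid-height abscissa and counts the image correct when
the acute angle α ≤ 7°; a missing line counts as incorrect.

## Built-in evaluation suites

- *Line recovery, moderate noise*: 100 masks, 3–5 rows, angles within ±5°
  of vertical, jaggedness 2 px, 10 % spurious points injected uniformly
  into the point cloud; reports per-image angles, their maximum and the
  ≤ 7° fraction.
- *Line recovery, hard noise*: as above with jaggedness 4 px and 15 %
  spurious points.
- *Scaled-down training*: the 200-pair run described above, reporting
  held-out mean IoU.
- *Parameter accounting*: exact trainable-parameter counts of both
  architectures.

All suites regenerate their inputs from the provided seed at run time.

## Numerical choices and degenerate inputs

- Sigmoid and BCE never exponentiate positive arguments; probabilities in
  `segment_image` clip logits to ±60 before the final sigmoid.
- Batch norm uses ε = 1e-5 and momentum 0.1 with unbiased running variance;
  evaluation always uses running statistics.
- Bilinear resizing uses half-pixel centres and dense separable
  interpolation matrices (cached per size), so its adjoint is exact —
  gradients are the transposed matrices.
- Coincident candidate points raise a degenerate-geometry error and are
  skipped during exhaustive sweeps; all-identical point sets exhaust the
  sampler.
- Masks must be strictly binary; loaders binarise 8-bit PNGs at 128 and
  network probabilities at 0.5.
- He-normal initialisation seeded per build; two builds from the same spec
  and seed are bitwise identical.

## Known limitations

- The NumPy core is single-threaded apart from BLAS matmuls; full-scale
  (512×512, 85-epoch) training is supported but meant for patient CPUs —
  the package's evidence comes from the scaled-down protocol.
- The sequential RANSAC assumes rows are straight and roughly parallel to
  one image axis; strongly curved or fan-shaped plantings violate the
  separation heuristic.
- Detection accuracy treats the whole image's mask as one instance
  (IoU ≥ 0.6 per image), not per-row instances; per-row segmentation
  metrics would require instance labels the mask format does not carry.
- Synthetic-suite results bound algorithmic error only; domain transfer to
  real imagery must be established with real annotated data in the
  images/ + masks/ layout the loaders accept.
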