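# cropnav

Crop-row segmentation and visual navigation-line extraction for overhead
field imagery.

Field crops are sown in near-parallel rows, and a vehicle or UAV that wants
to follow them needs two things from each camera frame: a pixel-accurate
segmentation of the crop rows, and a straight navigation line fitted to the
row centerlines. `cropnav` implements both stages, together with a synthetic
field-scene generator that provides exact ground truth so the whole pipeline
can be trained and evaluated without any external dataset.

## What is inside

**Segmentation.** A lightweight encoder–decoder network in the ENet family,
with three changes aimed at boundary accuracy and model size:

- a *residual boundary stream*: the feature map produced by the first
  downsampling bottleneck seeds a second pathway that accumulates the output
  of every stage-1 bottleneck, preserving the low-dimensional boundary
  detail that the pooling pathway discards. The two streams are channel
  fused before stage 2 (a stride-2 3×3 convolution brings the residual map
  to the new scale), the decoder upsamples both by bilinear interpolation
  instead of max-unpooling, and a 1×1 classifier over their concatenation
  produces the per-class score maps;
- *convolution replacement*: stage-1 bottlenecks 1.2–1.4 use a dilation-2
  convolution, a 5-tap asymmetric pair and a dilation-4 convolution (a k×k
  kernel at dilation d covers d·(k−1)+1 pixels per side, so the receptive
  field grows at zero parameter cost);
- *model compression*: the repeated stage 3 of the classic design is
  removed.

At default widths the improved network has ≈ 0.27 M trainable parameters
versus ≈ 0.37 M for the classic ENet baseline, which is also included
(max-unpooling decoder, stage 3 and all) for comparison. Everything runs on
a small NumPy reverse-mode autodiff core shipped with the package
(`cropnav.nn`) — no GPU framework required. Training minimises
`BCEDiceLoss = BCELoss + DiceLoss` with sigmoid probabilities and Dice
smoothing 0.1, using Adam (lr 1e-4, decay 0.1, batch 8) and random
flip/rotation augmentation (p = 0.5 each). Segmentation quality is scored
by intersection-over-union; an image counts as correctly detected when
IoU ≥ 0.6.

**Line fitting.** The binary mask is scanned every *h* = 8 rows; each
foreground run yields a feature point (x = centre of the run's edge
intersections, y = h·N). An improved RANSAC then fits row centerlines: the
two seed points of every candidate must be separated by more than T (one
third of the image extent along the row direction), candidates are ranked by
the inlier-density score

    score = m_t / (l + p),        p = 15

with m_t the inlier count and l the inlier span, and the winning consensus
set is refined by least squares. Rows are extracted sequentially by inlier
removal; the centerline nearest the image centre becomes the navigation
line. Against ground truth, a navigation line is correct when its acute
angle α to the matched true centerline is at most 7°.

## Worked example

```python
import numpy as np
from cropnav import synthetic, navline

params = synthetic.FieldSceneParams(n_rows=4, row_angle=3.0, jaggedness=2.0)
sample = synthetic.generate_scene(params, seed=7)
result = navline.fit_navigation(sample.mask, rng=np.random.default_rng(0),
                                truth=sample.gt_lines)
print(f"fitted {len(result.row_lines)} row centerlines")
for line, angle in zip(result.row_lines, result.angles_vs_truth):
    print(f"  x_mid={line.x_mid:7.2f}  inliers={line.m_t:3d}  "
          f"score={line.score:.3f}  angle_error={angle:.3f} deg")
nav = result.navigation_line
print(f"navigation line: x(0)={nav.abscissa_at(0):.1f}, x(511)={nav.abscissa_at(511):.1f}")
```

prints

```
fitted 4 row centerlines
  x_mid=  90.50  inliers= 64  score=0.123  angle_error=0.224 deg
  x_mid= 200.62  inliers= 64  score=0.123  angle_error=0.180 deg
  x_mid= 310.53  inliers= 64  score=0.123  angle_error=0.114 deg
  x_mid= 420.97  inliers= 64  score=0.123  angle_error=0.089 deg
navigation line: x(0)=186.4, x(511)=214.8
```

Each fitted line reports its abscissa at image mid-height, consensus size
(64 = one inlier per scan line of a 512-pixel image at h = 8), density
score, and angular error versus the generator's ground truth — all four
rows of this 3°-slanted, 2-px-jagged scene are recovered to better than a
quarter of a degree. The navigation line is the second row, the one closest
to the image centre.

The same pipeline is available from the shell:

```bash
cropnav synth --out ds --n 20 --seed 3        # synthetic dataset with ground truth
cropnav train --data ds --checkpoint model.npz --width-multiplier 0.5
cropnav run --image ds/images/sample_0000.png --checkpoint model.npz --out out/
```

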