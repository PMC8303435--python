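# Methods

## Problem

In a videofluoroscopic swallowing study (VFSS), a lateral X-ray video records
a patient swallowing contrast-laden boluses at 30 fps. The superior-anterior
excursion of the hyoid bone during the swallow is a key kinematic marker of
swallowing function. `hyotrack` implements a fully automatic tracking
pipeline: per-pixel segmentation of three structures (hyoid bone, cervical
spine, calibration coin), extraction of per-frame object states, and
conversion of the hyoid's position into millimetres relative to the rigid
cervical spine.

## Segmentation network: BiFPN-U-Net(T)

* **Encoder.** A VGG16-style convolutional encoder (stage conv counts
  2/2/3/3/3, 3x3 kernels, ReLU, 2x2 max-pooling between stages) produces a
  five-level pyramid P1..P5 at strides 1, 2, 4, 8, 16. With a 224x224 input
  P5 is 14x14. The input is single-channel; weights are always randomly
  initialized (He). Transfer learning is deliberately not used: fluoroscopic
  frames are grayscale and at near-constant object scale, unlike the natural
  image corpora behind pretrained backbones.
* **BiFPN.** One (configurable) bidirectional fusion layer refines the
  pyramid. Each fusion node combines its resampled inputs with *fast
  normalized fusion*: out = sum_i relu(w_i) x_i / (eps + sum_j relu(w_j)),
  eps = 1e-4, followed by a 3x3 convolution. The top-down pathway runs
  P5 -> P1 with nearest-neighbour upsampling, the bottom-up pathway P1 -> P5
  with max-pool downsampling; intermediate top-down nodes feed the bottom-up
  nodes as in the standard BiFPN wiring. Learned weights let levels
  contribute unequally, which matters because the hyoid, spine and coin have
  very different sizes.
* **Bottleneck transformer (BOT).** On the refined P5 only — where the
  quadratic attention cost is trivial (a hard cap of 4096 positions is
  enforced) — a residual bottleneck block replaces the middle spatial
  convolution with global multi-head self-attention: 1x1 reduce, MHSA with
  learned relative height/width position encodings (content-position logits
  q·(R_h[dy] + R_w[dx]) added to the scaled content-content logits), 1x1
  expand, residual add. Global context is the design lever for re-finding a
  hyoid partly hidden behind the mandible and a coin near the image border.
* **Decoder.** A U-Net-style decoder walks the refined pyramid back up:
  at each level it concatenates the 2x-upsampled deeper feature, the BiFPN
  output, and the encoder skip, then applies two 3x3 conv+ReLU. A 1x1 head
  produces 4-class logits at full resolution. A single softmax over
  background/hyoid/spine/coin is used (the structures never legitimately
  overlap at a pixel), decoded by argmax with ties to the lower index.

## Training recipe

* **Loss.** Focal loss FL(p_t) = -alpha (1-p_t)^gamma log(p_t) averaged over
  pixels, alpha = 0.25, gamma = 2 (the canonical defaults), p_t clamped at
  1e-7. The hyoid occupies well under 1 % of pixels; gamma > 0 keeps easy
  background pixels from swamping the gradient.
* **Optimizer.** RAdam with the linear-scaling rule lr = 0.1 x batch / 256
  (batch 8 gives 0.003125). The rectified variance term makes the early
  epochs stable without a warmup schedule.
* **Schedule.** Up to 500 epochs with early stopping after 20 epochs without
  validation-loss improvement; the best-validation weights are restored.
  Training, shuffling and initialization are driven by one integer seed and
  reproduce bit-identically.
* **Framework.** The network runs on an in-package reverse-mode autodiff
  engine over NumPy (`hyotrack.nn`): im2col stride-1 convolution, 2x2
  max-pooling, nearest upsampling, softmax/log-softmax, batched matmul and
  relative-position attention, each with hand-derived adjoints that are
  gradient-checked against central finite differences in the test suite.
  It is CPU-only and single-threaded beyond BLAS; that bounds the problem
  sizes the defaults target (below).

## Object extraction

Per frame and class: presence requires >= 5 detected pixels (speckle guard);
the operating point is the arithmetic mean of the detected pixels'
coordinates (all pixels of the class — no connected-component filtering by
default, with an optional largest-component mode); the bounding box is the
tight half-open box; confidence is the mean predicted class probability over
the detected pixels. The coin's pixel diameter is the major axis of its
region from second central moments, D = 4 sqrt(lambda_max), which is exact
for a filled ellipse and rotation-invariant, so a tilted (elliptical) coin
still reads its true diameter; regions under 10 pixels fall back to the
maximum pairwise extent. Coordinates are x = column, y = row, origin
top-left, pixel centres at integer coordinates.

## Kinematics

Only frames where *all three* objects are detected are retained. Per
retained frame: DxR = Cx - Hx, DyR = Cy - Hy (spine minus hyoid, so global
head translation cancels); s = 24 / Dpxls mm per pixel from the 24 mm coin;
N(DxR) = s DxR, N(DyR) = s DyR; D(C,H) = sqrt(N(DxR)^2 + N(DyR)^2). The
clip-level scale uses the median coin diameter over retained frames by
default (per-frame scale available) so per-frame segmentation jitter of the
coin does not modulate the trajectory. The excursion summary is the
displacement from the first retained frame to the frame maximizing the
diagonal displacement, reported as absolute horizontal/vertical components
and the diagonal; "maximum elevation" is operationalized as that argmax
frame, which makes the three reported numbers self-consistent. No spine-axis
rotation correction is applied: the kinematic equations are purely
translational, and rotation correction is left as an extension.

## Evaluation

Pixel accuracy, recall, precision and Dice from pooled (micro-averaged)
confusion counts, and per class; ROC-AUC of the any-object score
(1 - P(background)) via the rank statistic; bounding-box average precision
at IoU 0.5 with greedy confidence-ordered matching (one detection per truth
per frame) and all-point interpolation of the precision-recall curve — the
modern convention, stated here because 11-point interpolation would differ;
mAP is the unweighted mean over the three classes. Trajectory RMSE is
computed per direction on the intersection of retained frames. Degenerate
denominators yield 1 when both prediction and truth are empty, else 0.

## Synthetic phantom

The generator renders what the tracker needs and nothing more: a static
bright spine column (six rounded vertebral blocks, right of centre), a small
hyoid ellipse executing one raised-cosine superior-anterior excursion pulse
(zero at frame 0, peak at half the motion period, zero at the full period),
and an axis-aligned coin ellipse anterior-inferior to the spine, never
overlapping it. Anterior is rendered toward smaller x, superior toward
smaller y. Optional nuisances: a mandible bar placed just above the hyoid's
peak position (hides the upper part of the hyoid only near peak elevation),
a coin field-of-view exit frame, global Gaussian head jitter applied to all
anatomy, and additive intensity noise. Intensities are flat plateaus
(hyoid 0.60, spine 0.80, coin 0.95, occluder 0.78) over a textured 0.20
background.

Defaults encode the study conditions: 30 fps, 224x224 frames, coin diameter
drawn from N(62.9, 7.6) px truncated above 20 px with a true diameter of
24 mm, peak excursion (8, 10) mm (anterior, superior — a realistic adult
swallow), one-second motion period. Head-motion magnitude is not
characterized in the source protocol, so the jitter default (0.5 px sd) is
an invented, clearly-labelled nuisance level. Ground truth records
full-shape hyoid centres (occlusion removes pixels, not the bone) plus the
visible-pixel centroid separately, so occlusion-induced centroid bias is
measurable.

What the phantom does *not* emulate: X-ray attenuation physics, bone
texture, bolus/contrast shadows, anatomical variability, mandible motion.
Passing phantom tests therefore demonstrates that the pipeline's machinery
is correct and that the architecture can learn and track under controlled
occlusion/noise — not clinical-grade performance on real fluoroscopy.

## Desk-scale benchmark sizes

The end-to-end benchmark (`hyotrack.benchmark`, also driven by
`scripts/acceptance.py`) uses the reduced profile: 96x96 input, encoder
widths divided by four (16/32/64/128/128), 16 BiFPN channels, batch 8,
lr 0.003125. It trains on 192 easy frames (four 48-frame clips, one with the
occluder on so occlusion is represented) and evaluates on a held-out clip
from the same distribution. The epoch budget defaults to 12: on these easy
clips the loss falls by three orders of magnitude well within that budget,
and all held-out metrics plateau. These sizes are the package's CPU-scale
defaults; every one of them is configurable upward, and the full 224x224
profile is the `NetworkConfig` default.

## Numerical choices and edge cases

* Fusion weights pass through ReLU before normalization; with all weights
  zero the eps guard returns (near) zero rather than dividing by zero.
* Argmax ties in pixel classification go to the lower class index, so exact
  ties favour background.
* Focal loss clamps p_t (and 1 - p_t) at 1e-7 before the power/log.
* The early-stopping counter compares strictly (`val < best`); a flat
  validation sequence therefore stops training after exactly `patience`
  non-improving epochs.
* `split_dataset` partitions whole clips with largest-remainder rounding and
  a seeded shuffle; one clip always lands in exactly one split.
* Checkpoints are NumPy `.npz` archives with the network configuration
  embedded as YAML — the package's native format.

## Known limitations

* The scale factor is sometimes written the other way around
  (s = Dpxls / 24); that form is dimensionally inconsistent with a scale
  defined as physical size per pixel, so this package uses
  s = 24 / Dpxls mm/px throughout.
* Whether the bottleneck transformer should replace part of the encoder's
  last stage or follow the BiFPN's P5 output is an interpretation; it is
  appended after the BiFPN P5 node here.
* Pure-NumPy training is orders of magnitude slower than GPU frameworks;
  the full 224x224 configuration with unreduced widths is provided and
  correct, but training it to convergence is not practical on one CPU core.
* Per-class binary heads, COCO-style multi-threshold mAP, temporal smoothing
  and velocity profiles are out of scope.
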