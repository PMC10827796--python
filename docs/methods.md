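# Methods

## Problem and model

`jawnet` addresses joint classification and localization of odontogenic
lesions — ameloblastoma (AB), odontogenic keratocyst (OKC) and dentigerous
cyst (DC), versus Normal — in panoramic dental radiographs. Panoramic images
are wide (nominally 3000x1500) while convolutional encoders have receptive
fields of only a few hundred pixels, so the model analyses the image as a
grid of patches and then couples the patches through attention:

**Stage 1 — patch analysis with mutually influencing attention.** The
working image (1500x750 after background cropping, resizing and per-image
standardization) is tiled into a 4x2 grid of 375x375 patches. Each patch is
encoded by a dense convolutional encoder (the 121-layer, growth-32 topology;
taps after transitions 1/2/3 at strides 8/16/32 give 47x47, 23x23 and 11x11
feature maps for a 375 input). An FPN-style proposal head predicts, for
every tap cell and three predefined box shapes (1:1, 2:1, 1:2), per-class
confidences, an objectness score and box offsets. The top-400 proposals by
objectness are merged into a local attention heatmap psi_fpn on the 11x11
grid by accumulating score-weighted soft box masks (fractional cell
coverage) and normalizing by the maximum; the merge is differentiable with
respect to the scores (the normalization constant is a stop-gradient). The
heatmap gates the deepest features,

    h_i = (C3 . C3 . C1)( Sigm(Nrm(B4)) * psi_fpn ),

where `Nrm` is per-channel spatial standardization (the operator is not
further specified in the architecture, so the simplest normalization that
bounds the gated activation in [0,1] was chosen). The K patch
representations are concatenated and convolved into one shared global map
h (512x11x11), which multiplies back into every patch's three layer
projections z_{i,l} = (ReLU . BN . C3)(pool(B_l)), l = 1..3 — giving the
attended feature z_i (1536 = 3x512 channels). Because h is computed from all
patches and applied to each, a perturbation of any one patch changes every
z_i (verified mechanically by a finite-difference test).

**Stage 2 — whole-image heads.** The z_i are stitched back into their grid
positions, z_x (1536x44x22), which feeds (a) the classification head
Sm(Mlp(Avg(C3 . C3 . Max . C1)(z_x))) with hidden widths 256/256 and a
4-way softmax, and (b) the localization branch: a 4-level strided conv
encoder E over the working image, fused at the bottleneck with z_x reduced
to 64 channels by a 1x1 conv, decoded with skip aggregation from every
encoder level to a sigmoid heatmap at half the working resolution
(750x375). The predicted class is the arg max of the softmax confidence
(a printed "arg min" in the source formula is treated as a typo — the
quantity is explicitly a confidence score); ties break to the lowest class
index. The binary segmentation is the heatmap thresholded at th_s = 0.5.

Localization targets are per-lesion isotropic Gaussians with peak 1 at the
(rounded) bbox centre and variance 50 px^2 at the 750x375 map; multiple
lesions combine by pointwise maximum so peak normalization survives.
Peak-normalized (not probability-normalized) Gaussians are used because a
fixed threshold of 0.5 is only meaningful under peak scaling.

## Losses

    L = lambda_cls * L_cls + lambda_loc * (lambda_h * L_h + lambda_s * L_s)

with all lambdas 1.0: L_cls the batch-mean 4-way cross entropy, L_h the
pixel-mean squared error against the Gaussian target, and L_s the focal
loss -(1-p_t)^gamma log p_t with gamma = 2.0 (the exponent is not given a
value in the source description; 2 follows the original focal-loss work).
The focal loss is applied to the continuous heatmap read as a per-pixel
probability against the binarized (>= th_s) target — thresholding is not
differentiable, so this reading is forced by trainability. Localization
terms are masked to zero for Normal samples; log arguments are clamped at
1e-8.

## Training protocol

Step 1 fine-tunes the backbone alone: random 375x375 crops, drawn so
windows overlapping a lesion bounding box occur exactly three times as
often as lesion-free windows (a 3:1 Bernoulli between the two window sets),
are decoded by a throwaway head into crop-level heatmaps under the focal
loss. Step 2 trains everything else end-to-end with every backbone
parameter and normalization statistic frozen (bitwise unchanged — asserted
exactly). Minibatches hold equal numbers of original and
LesionMix-synthesized samples; online augmentation applies horizontal and
vertical flips (p = 0.5 each), rotations up to +/-5 degrees, and
brightness/contrast jitter (strength 1.0 at the reference scale;
saturation/hue jitter is a no-op on single-channel images and is carried
as such, with a warning). Jitter strengths are a profile parameter: on
clipped single-channel images a strength of 1.0 lets the brightness factor
reach zero — an all-black image — so the desk-scale profile uses 0.25,
keeping the augmentation family intact while staying non-degenerate for a
1/8-width model (see `OnlineAugmentParams`).
Both steps use Adam (the optimizer is unspecified in the source; Adam is
the default choice for this model family) under the exponential schedule
mu_t = mu0 * 0.98^t, mu0 = 1e-4 (backbone) and 5e-4 (full model) at the
reference scale.

Geometric preprocessing (background crop + resize) runs once per sample and
online augmentation acts on the cached working-space image, with
standardization applied last: recomputing the Otsu content box on every
augmented variant would add an uncontrolled, epoch-varying anisotropic warp
(the jitter shifts the threshold and with it the crop by tens of pixels).

The test suite's trainability demonstration runs this protocol
deterministically — online augmentation and LesionMix synthesis disabled —
because it is a capacity check: the eight-phantom training set must be
memorised (train accuracy 1.0, large loss reduction, backbone bitwise
frozen), and stochastic augmentation exists precisely to prevent
memorisation of eight samples within a 200-update budget. The stochastic
protocol itself is exercised and asserted to train in the unit suite.

Splits are stratified by class at 0.75/0.10/0.15 with five folds whose test
partitions are disjoint (5 x 15% <= 100%); "five-fold cross validation on
the test set" combined with a fixed split ratio is ambiguous, and disjoint
re-splits are the reading that keeps every test image used at most once.
Offline oversampling (e.g. 75/97/193/200 -> 200/194/193/200) takes explicit
per-class targets, runs after splitting, and flags every duplicate.

## LesionMix

LesionMix cuts a donor lesion along its segmentation mask and pastes it
onto a Normal recipient at the donor's own coordinates by default (random
placement is available), producing a new sample labeled with the donor
class. Blending uses a signed-Euclidean-distance ramp of half-width
`feather_radius` (default 2 px): strictly outside the dilated mask the
output equals the recipient exactly; strictly inside the eroded mask it
equals the donor exactly; the band in between is a monotone blend. The
exactness is asserted bit-for-bit in the tests. Mixup (convex image blend)
and CutMix (rectangular paste) are included as baselines only.

## Synthetic phantoms

The clinical corpus (565 radiographs: 75 AB, 97 OKC, 193 DC, 200 Normal) is
private, so all tests run on generated phantoms that copy its statistical
structure: the class counts, a log-uniform lesion-area spread (the
published size distribution is available only as a figure, so a log-uniform
stand-in over a configurable range is used), a positional prior placing 80%
of lesions in the lower (posterior-mandible) quadrants
(q1:q2:q3:q4 = 0.1:0.1:0.4:0.4), and a near-black border. Images are a
parabolic bright mandible/maxilla arch with tooth-like ripples on a dark
noisy field. Lesion interiors are class-coded: AB gets dense
high-frequency "soap-bubble" septa, OKC coarser and milder loculation, DC a
smooth radiolucent interior with a bright corticated rim — so mean local
variance inside the lesion ranks AB > OKC > DC with an asserted margin, and
a classifier can separate the classes in principle. Every sample is a pure
function of (spec, seed). The phantoms make no attempt at anatomical
realism: passing tests demonstrate that the pipeline's mechanics (shapes,
losses, attention coupling, augmentation contracts, trainability) are
correct, not that clinical-grade accuracy would be reached on real
radiographs.

## Profiles and problem sizes

The reference profile reproduces every published dimension (375 patches,
4x2 grid, 47/23/11 taps, 512-channel global map, 1536x44x22 z_x, 750x375
output, top-400, sigma^2 = 50, th_s = 0.5, batch 48, 200 epochs). Its exact
reference parameter count (121-layer classifier, 3-channel input, 1000-way
head) is 7,978,856.

The tiny profile divides geometry by 5 (300x150 images, 75x75 patches,
taps 9/4/2, 150x75 output) and channel widths by 8, and scales every
quadratic geometric quantity by 1/25: the heatmap variance (50/25 = 2 px^2)
and the phantom lesion-area range (100-3000 px^2, the upper end truncated
at the largest lesion a 300x150 quadrant can host with the margin). Training demonstrations use
eight phantoms (two per class): step 1 runs 50 epochs and step 2 up to 100
epochs, which fits in minutes on one CPU core. Desk-scale training
hyperparameters that the source fixes only at full scale (batch size,
initial learning rate) are re-chosen for the 8x-narrower network — see
the profile defaults in `jawnet.config` — since a 1/8-width model at batch
8 neither needs nor tolerates the full-scale settings.

## Numerical choices

* All computation is float32, single-threaded numpy; training trajectories
  are bit-reproducible given (config, seed).
* The network layer is a purpose-built reverse-mode autodiff engine over
  numpy (`jawnet.nn`): im2col convolution with a BLAS matmul core,
  pointwise fast path for 1x1 convolutions, floor-semantics pooling
  (47 -> 23 -> 11), nearest-neighbour resizing, batch normalization with
  running statistics, Adam. Gradients are verified against central finite
  differences in the test suite.
* Background cropping thresholds with Otsu's method plus 1% padding.
* The global-attention output convolution uses a FiLM-style near-identity
  initialisation (small weights, bias 1), so the multiplicative calibration
  starts as the identity and the classifier is not starved through the
  z x h product at the beginning of training.
* Standardization is per image (whether the source standardizes per image
  or over the corpus is ambiguous; per image is the safer reading for
  variable exposure).
* Crop origins are snapped to the working-to-seg integer factor (2) so the
  crop-level target is exactly a window of the full target.
* The merged attention map falls back to all ones (no attenuation, with a
  warning) if no proposal covers the grid; sigmoid objectness makes this
  unreachable in practice.
* argmax ties break to the lowest class index; quadrant assignment at the
  exact image centre resolves to quadrant 1 (>= / <= tie-break).
* "IoU greater than 0.5" is strict; IoU of two empty masks is 1.

## Known limitations

* The published backbone receptive field (447x447) does not follow from
  the standard maximal-path recursion for the 121-layer topology; the
  calculator implements the standard recursion (which does reproduce the
  published 435 for ResNet-18) and the discrepancy is left undocumented at
  the source's side.
* The printed dimension formula for psi_fpn conflicts with the square
  patch evidence; the map is produced at the deepest-tap grid resolution.
* No pre-trained weights are shipped or required; all demonstrations start
  from seeded random initialisation.
* The localization decoder depth/width is not specified at the source; the
  minimal 4-level skip-aggregation decoder documented in the config
  defaults is used.
* Phantoms have at most a coarse anatomical layout; multi-lesion
  generation exists behind a flag but defaults to a single lesion.
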