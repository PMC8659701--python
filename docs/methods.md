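# Methods

## Rotated-box representation and conventions

A rotated box is `(xc, yc, wr, hr, θ)` with image coordinates (x rightward,
y downward, 0-based pixel centers) and θ in radians. The straightening
warp used to extract rotated regions applies

    [x']   [ sin θ   cos θ] [x − xr]   [wr/2]
    [y'] = [−cos θ   sin θ] [y − yr] + [hr/2]

to centered coordinates. This matrix is a rotation by (θ − 90°) — the
identity at θ = π/2 — so the package defines the `wr` side of a box to run
along the image direction `(sin θ, cos θ)`. With that convention the box is
axis-aligned (wr horizontal) at θ = π/2 and the warp maps the box corners
onto the corners of `[0, wr] × [0, hr]` at *every* angle, making polygon
geometry, rasterization and warping mutually consistent. A conventional
rotation-by-(−θ) warp is available via `warp_convention="standard"`.

Angles are canonicalized to `[−π/2, π/2)` at I/O boundaries by reduction
mod π (a rectangle is invariant under θ → θ + π). The remaining
`(wr, hr, θ) ↔ (hr, wr, θ ± π/2)` side-swap symmetry is resolved by
consumers that compare boxes (`boxes_equivalent` tries both
representatives). Offsets between boxes use the 5-tuple
`(tx, ty, tw, th, tθ)`: center shift projected on the reference box's
frame and divided by its sides, log size ratios, and the angle difference
reduced mod 2π and divided by 2π (a "turn fraction" in `[0, 1)`).
Degenerate edge-touching intersections count as IoU 0 (measure zero).

## Detector

Two stages. A small CNN backbone (stride-2 stages, GroupNorm + ReLU) feeds
a top-down feature pyramid with equal channels per level and strides
{4, 8, 16, 32, 64} (P6 is a 2× downsample of P5); depth and width are
configurable because the architectural contract is the pyramid shape, not
a particular stage recipe. The RPN scores 5 anchors per cell (ratios
{1:4, 1:2, 1:1, 2:1, 4:1}, side = `base_scale × stride` at 1:1) and
regresses horizontal deltas; proposals are decoded, clipped, and filtered
by horizontal NMS.

The RoI Transformer treats each horizontal proposal as a rotated box at
angle zero: RoI-Align (7×7 bins, 2×2 samples per bin) feeds a small FC
stack ending in a zero-initialized 5-dim layer, so an untrained learner
returns the proposal unchanged. The decoded rotated proposal is warped to
a 7×7 patch by bilinear sampling on the inverse warp grid, then a shared
FC layer (2048-d at full scale, configurable) and two sibling FCs produce
(K+1)-way class scores and per-class 5-parameter offsets.

Training loss: `L_D = L_RPN + α1·L_cls + α2·L_reg`, `α1 = α2 = 1`, where
`L_RPN` is objectness BCE + smooth-L1 on sampled anchors, `L_cls` is
cross entropy at the head and `L_reg` collects the smooth-L1 offset losses
of the learner and the head over matched positives (the method's loss
names the RPN, classification and regression terms; assigning the
learner's offsets to the regression term is this package's reading).
Per-stage RoI sampling uses batch sizes {256, 512, 512} at pos:neg
{1:1, 1:3, 1:3}; positives shortfall is filled with negatives. Matching
uses horizontal IoU for the proposal stage (0.7/0.3 RPN thresholds, with
the best anchor per ground truth forced positive) and rotated IoU (0.5)
afterwards.

**Angle regression.** The turn-fraction channel is discontinuous at the
0/1 wrap (a target of 0.999 and a prediction of 0.001 are 0.002 turns
apart). The smooth-L1 on that channel therefore uses the wrap-aware
difference `min(|d|, 1 − |d|)`, implemented by shifting the target to the
nearest whole turn of the prediction; the encoding itself is unchanged.
Without this, ground truths with angles just below the reference angle are
untrainable.

During training, jittered ground-truth horizontal boxes are appended to
the RPN proposals (standard practice to give the second stage positives
early); inference uses RPN proposals only. Score threshold 0.05 and
rotated NMS at IoU 0.5 (per category) produce the final detections.

## GLFS-Net

The local image keeps original pixel values inside the instance's oriented
box and zeros everything else (mean-fill available); it has the same size
as the global image — no crop-resize, so the two branches stay spatially
registered. A single shared-weight encoder (strides 2–4–8–16) processes
both; ASPP (rates {6, 12, 18} + image-level pooling, configurable) gives
the high-level features X_G and X_L at output stride 16, low-level
features are taken from the global branch at stride 4. The SE gate
squeezes X_G by global average pooling, applies two FC layers
(bottleneck C/16) and a sigmoid, and rescales X_G channel-wise; fusion is
element-wise addition with X_L followed by a 1×1 convolution. The decoder
concatenates 4×-upsampled fused features with channel-reduced low-level
features, applies two 3×3 convolutions, and a final 4× bilinear upsample
yields per-pixel foreground logits at input resolution (sides must divide
by 16).

The mask head is binary — instance foreground vs background — with the
category inherited from the detector. Loss: `L_S = α1·L_decode +
α2·L_aux`, `α1 = 1, α2 = 0.4`. The auxiliary head is a 1×1 convolution on
the fused stride-16 features supervised against the block-center
subsample of the target mask at its native resolution, so exact
predictions drive both terms to zero; the method's description of the
auxiliary term ("FC-layer loss") is ambiguous, and an auxiliary
pixel-classification head is this package's resolution. Training pairs
use ground-truth boxes (teacher forcing); inference uses detector boxes.

## Synthetic scenes

The generator emulates the *structure* of pediatric-elbow radiographs, not
their anatomy: 9 categories (3 elongated long-bone classes, 6 small oblong
ossification-center classes), each appearing at most once per scene;
AP-like and lateral-like layouts in which the long bones meet near a joint
center; additive composite intensity `clip(Σ intensity_i · density_i) +
Gaussian noise` with ground-truth masks taken before clipping, so overlap
pixels belong to every covering instance. Instances are soft-edged
capsules (segments dilated by a radius); each mask is the 0.5-level set of
its density and the stored oriented box is the minimum-area rectangle of
that mask, so the OBB–mask consistency invariant holds by construction.
Per-class length/width ranges (fractions of the image side) are fixed once
to span all five anchor aspect ratios and give each class a distinct
size/intensity signature; the olecranon-like instance always caps the
ulna-like instance's proximal end, guaranteeing at least one instance pair
with mask IoU ≥ 0.3 per scene (the heavily superimposed regime), enforced
by bounded retries.

Placement is confined to the image's inscribed circle so that rotation
augmentation never clips content. Augmentation rescales by a factor from
{0.5, 1, 1.5}, rotates uniformly in [−90°, 90°] about the image center and
flips horizontally with probability 0.5; the image is resampled, masks are
re-rendered from the analytically transformed capsule parameters, and the
oriented box is transformed in closed form (θ → θ − φ under rotation,
θ → −θ under flip) and then *refit* to the transformed mask, with the
analytic box selecting the 90°-swap representative. The refit keeps the
stored box exactly the minimum-area rectangle of its mask: minimum-area
rectangle angles of small rasterized shapes are ill-conditioned (we
measured up to tens of degrees of jitter for 6–14 px instances), so a
purely analytic update cannot stay within 1 px / 1° of the refit. What
passing these tests shows is internal consistency of the generator and
transforms — not anatomical realism; real radiographs add texture,
projection-dependent density, soft tissue and unossified cartilage that
the generator deliberately omits. A Sobel preprocessing op (replace one
RGB channel with the normalized gradient magnitude) is provided for
edge-emphasis experiments.

The 3:1:1 train/val/test split uses seeded shuffling with
largest-remainder rounding (100 → 60/20/20, 5 → 3/1/1).

## Evaluation

Mask AP follows COCO: greedy score-descending matching (each ground truth
used at most once), 101-point interpolated PR area. `AP0.50` and `AP0.85`
are reported per category; `mAP` averages thresholds 0.50:0.05:0.95 (the
mean over {0.50…0.95} is the standard reading of an otherwise undefined
"mAP" column). The FP decomposition evaluates all categories jointly and
forgives errors cumulatively: C85 and C50 are plain AP; Loc drops the
threshold to 0.1 (localization errors, best IoU in [0.1, 0.5), become
matches); Oth removes class-confusion false positives (unmatched
detections overlapping a ground truth of another class); BG removes the
remaining unmatched detections; FN additionally forgives missed ground
truths, closing the curve at 1. Each stage removes a superset of errors,
so the six areas are monotonically non-decreasing on any input. Box-level
evaluation (rasterized oriented boxes as masks) is available for judging
the detector alone.

## Numerical and scale choices

* All network code runs on the package's numpy autograd engine
  (`obbseg.nn`): im2col convolution, slice-scatter conv backward, bilinear
  resampling with gradients to the feature map only, fused stable losses;
  every op is validated against central finite differences in the tests.
  GroupNorm is used instead of BatchNorm because training is
  single-image.
* Desk-scale study conditions: the end-to-end checks train the detector on
  28 scenes at 64 px (2 pyramid levels, 12 channels, 128-d head FC, anchor
  base 4, reduced per-stage RoI batches {128, 96, 96} at the same
  pos:neg ratios) for 1400 iterations, and the segmenter on 12 instances
  from 128 px scenes for 1200 iterations; both use Adam (lr 2e-3 / 3e-3)
  with polynomial decay for fast overfitting on one CPU. Full-scale
  defaults in `obbseg.config` keep the prescribed settings (SGD, momentum
  0.9, weight decay 1e-4 / 5e-4, poly power 0.9, lr 0.02 / 0.01, batches
  {256, 512, 512}); the config snapshot marks which values are prescribed
  ("prescribed") and which are this package's decisions.
* These end-to-end checks measure training-set performance by design:
  they verify capacity, gradient correctness and the overlap capability
  (both overlapping instances' predicted masks cover their shared pixels),
  not generalization.

## Known limitations

* No ImageNet-style pretraining and no multi-GPU schedule; full-scale
  (1024 px, ResNet-50-class backbone) training is out of reach of the
  numpy engine and is configured but not exercised.
* The RPN objectness/regression terms are weighted 1:1 inside L_RPN (the
  method leaves the inner weighting unstated).
* `mAP` averaging and the auxiliary-head supervision follow the package's
  documented readings of ambiguous definitions (see above).
* Rotated IoU uses exact polygon clipping via shapely; no GPU kernels,
  no quadrilateral (non-rectangular) boxes, no crowd-region handling.
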