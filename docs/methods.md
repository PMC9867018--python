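# Methods

## Model and procedure

`pollenseg` treats single-particle SEM micrographs — one dominant pollen grain
plus small impurity clutter — and learns a binary segmenter and a 3-class
classifier jointly from image-level labels only.

**Unsupervised extraction.** A pseudo mask is derived from the image alone:

1. *Contour detection.* Gaussian smoothing (odd kernel side `k`, default 9;
   sigma from the kernel-size rule `0.3*((k-1)/2 - 1) + 0.8`, constant-mode
   filtering with bleed-over compensation so border gradients are unbiased),
   Sobel gradients, non-maximum suppression with the two neighbour magnitudes
   linearly interpolated along the gradient direction, and dual-threshold
   hysteresis. Thresholds (default 50/100) are in gradient units of the raw
   0–255 intensity scale. A 4-bin quantized NMS was considered and rejected:
   it systematically shifts edge pixels by one relative to the field-standard
   interpolated rule (scikit-image's detector, which this implementation
   matches exactly on random fixtures and which the tests use as an
   independent oracle).
2. *Opening.* The literal erosion–dilation opening of a 1-px-wide contour map
   with any disk erases every curve, so the opening is implemented as an area
   opening (an algebraic opening on the component lattice): 8-connected edge
   components smaller than `(2*open_radius + 1)^2` pixels are erased.
   Speck responses vanish, closed boundary curves — and hence the regions
   they enclose — are untouched, and the operator is idempotent.
3. *Fill and select.* Background is the 4-connected non-edge region reachable
   from the image border; everything else (enclosed regions plus their
   contours) is candidate foreground. 4-connectivity for the fill and
   8-connectivity for foreground components prevents diagonal leaks through
   1-px contours. Components that enclose no interior pixel (stray open
   curves), fall below 16 px, or are smaller than `area_keep_frac` (default
   0.5) of the largest component are discarded; ties with the largest are
   kept.
4. *Quality control.* A mask is accepted iff its foreground fraction lies in
   `qc_area_bounds` (default (0.05, 0.80) of the image) and it has at most
   `max_components` (default 1) components. This automated proxy replaces
   manual expert screening; rejected samples are excluded from segmenter
   training but remain in classifier training.

**Class-activation refinement.** For target class `c`, the activation map is
`ReLU(Σ_k α_k^c A^k)` with `α_k^c` the spatial mean of `∂y_c/∂A^k`, where
`A` is the last convolutional feature stack and the score gradient is 1 for
the target class and 0 otherwise. The map is bilinearly upsampled to image
resolution, min–max normalized, and binarized at threshold 0.5 (the threshold
is a free parameter; normalization-before-thresholding is the committed
convention). Refinement keeps the pseudo-mask component with maximal
intersection with the localization map — component selection rather than
pixelwise AND, because the goal is to drop whole co-occurring impurity
components without eroding grain structure (a pixelwise mode exists behind a
flag). Ties break by larger component, then smallest (row, col) anchor. An
empty or disjoint localization map leaves the mask unchanged with a warning
flag.

**Networks.** Both are deliberately tiny numpy implementations with explicit
backpropagation (float64 throughout, He initialization, Adam): a U-Net-style
encoder–decoder (default depth 2, width 8, < 1e5 parameters) emitting
per-pixel 2-class scores, and a DenseNet-style classifier (two dense blocks
whose layer `i` consumes `init_ch + i*growth` channels, a 1x1-conv + pool
transition, a final convolution feeding global average pooling and a linear
head). The classifier exposes its last-conv activations and head gradients,
which is the interface the activation mapping needs. With a GAP→linear head
the channel weights reduce analytically to `W[c,k]/Z`; the mapping is still
computed through the generic gradient interface so other heads work.

**Collaboration.** Round 0 trains the segmenter on QC-accepted pseudo masks
and the classifier on raw images. Each round `r >= 1`: activation maps at the
true training label refine every current mask; the segmenter is re-initialized
and retrained on the QC-accepted refined masks; its predicted masks build
mask-guided classifier inputs (`weight` mode: normalized image times mask —
the default, because it most directly removes clutter and keeps 1-channel
inputs; `concat` mode keeps the mask as a second channel); the classifier is
re-initialized and retrained. Re-initialization rather than fine-tuning is
the committed reading of "retrain"; per-round seeds derive from one seed
sequence, so runs are exactly reproducible. The loop stops after `rounds`
rounds or when refinement flips fewer than `stop_tol` (default 1%) of mask
pixels. Evaluation at round `r >= 1` builds test-set classifier inputs from
the segmenter's own predictions — ground truth is never consulted at
inference.

## Parameters that matter

| parameter | default | units / meaning |
|---|---|---|
| `low/high_threshold` | 50 / 100 | gradient magnitude on the 0–255 scale |
| `gaussian_kernel` | 9 | odd kernel side; sigma ≈ 1.7 |
| `area_keep_frac` | 0.5 | keep components ≥ this fraction of the largest |
| `qc_area_bounds` | (0.05, 0.80) | acceptable foreground fraction |
| `cam_threshold` | 0.5 | binarization of the normalized activation map |
| `seg_lr` / `cls_lr` | 1e-3 / 1e-4 | Adam learning rates, full protocol |
| `rounds` | 3 | collaboration rounds (full protocol) |
| `crop_from` → `crop_to` | 256 → 224 | random-crop augmentation |

The full protocol (100 epochs per task) is the `TrainConfig` default; the
desk profile (`TrainConfig.desk()`: 64x64 images, 12 segmenter / 60
classifier epochs, classifier lr raised to 1e-3 because the tiny
normalization-free DenseNet underfits at 1e-4 within a short schedule,
1 round) is what the tests and the acceptance script use, so the whole suite
fits comfortably on one CPU.

## What the synthetic generator does and does not emulate

It reproduces the *structural* premises: one dominant particle whose area
exceeds every impurity's (the area-selection premise), class-distinct
silhouette and surface texture (granular circle / smooth rounded rectangle /
intermediate-texture 2:1 ellipse — separable by mean local intensity
variance), impurities of grain-like intensity that sometimes touch or occlude
the grain rim (the hard failure mode), additive Gaussian noise, the 805:248:271
class imbalance and an 80/20 split. Intensities (background 60, particle ~185)
were fixed once so that boundary gradients clear the 50/100 thresholds while
interior texture mostly does not — i.e. the extraction task is nontrivial but
solvable, since no quantitative clutter statistics exist to calibrate
against.

It does **not** emulate SEM physics (charging, depth of field, detector
noise), irregular grain silhouettes, germination pores, or multi-particle
fields (detection cropping is assumed upstream). Passing tests therefore
demonstrate the *mechanism* — pseudo-label extraction, activation-guided
refinement, mask-guided classification, and their collaboration — not
instrument-level performance on real micrographs.

A consequence worth stating plainly: with the default `area_keep_frac` of
0.5, the relative-area filter already removes detached impurity components
from most pseudo masks, so activation-map refinement fires mainly on
extraction failures (merged or partial contours) and the measured mask-IoU
gain on synthetic data is at or near zero — the refinement guarantee here is
non-degradation, with whole-component removal demonstrated directly in the
refinement tests. On real data with heavier clutter (or a looser area
filter), refinement has more to remove.

## Numerical choices

* Ties in `predict` / `predict_mask` argmax resolve to the lower class index.
* Zero-denominator metrics report 0 with a `RuntimeWarning`, never NaN;
  classes absent from both prediction and ground truth are excluded from
  MIoU/MPA means.
* Display rounding is half-up to 3 decimals; internal values are full
  precision.
* Min–max normalization of a constant positive activation map yields all
  ones; of a nonpositive map, all zeros. Binarization at threshold 0 is
  strict (`> 0`).
* Largest-remainder class apportionment breaks remainder ties by class index.
* Mask PNGs are strict {0, 255}; any other value is a load error.
* Max-pool gradient is shared equally among tied maxima.

## Known limitations

* The numpy networks are CPU-bound; the full 100-epoch 224x224 protocol is
  configurable but slow — the desk profile is the practical operating point.
* The extraction stage assumes a closed boundary contour; very noisy images
  whose contours do not close produce empty masks (caught by QC rather than
  repaired).
* `concat` mask mode changes the classifier input width between round 0 and
  later rounds; since models are re-initialized per round this is sound, but
  checkpoints from different rounds are not weight-compatible.
* Impurities fused with the grain rim survive both area selection and
  component-level refinement; discarding them would need pixel-level texture
  cues, which is outside the mechanism implemented here.
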