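# pollenseg

Weakly supervised collaborative segmentation and classification of pollen
grains in cluttered SEM micrographs.

## The problem

Airborne-pollen monitoring increasingly relies on scanning electron microscopy
(SEM), where grain surface texture is sharp enough to distinguish allergenic
taxa (Cupressaceae, *Fraxinus*, *Ginkgo*, ...). Field samples, however, are
dirty: each micrograph contains one dominant pollen grain surrounded by dust
and sand-like impurity specks with intensity similar to the grain itself.
Classifiers trained on raw micrographs latch onto the clutter, and pixelwise
annotation for a supervised segmenter is prohibitively expensive.

`pollenseg` implements a collaborative learning scheme that needs only
image-level class labels:

1. **Unsupervised pollen extraction** — Canny contour detection (Gaussian
   smoothing, Sobel gradients, non-maximum suppression, dual-threshold
   hysteresis at 50/100 on the 0–255 gradient scale), an opening of the
   contour map that removes small-scale speck responses, flood filling from
   the image border, and relative-area selection. The premise: the grain
   encloses a considerably greater area than any impurity, so the large
   region(s) are the pollen pseudo mask. An automated QC rule (area-fraction
   bounds, single component) replaces manual expert screening.
2. **Class-activation refinement** — a densely connected CNN classifier
   yields gradient-weighted class-activation maps
   `L_c = ReLU(Σ_k α_k^c A^k)` with `α_k^c = (1/Z) Σ_ij ∂y_c/∂A^k_ij`;
   binarized, these localize the grain, and the pseudo-mask component with
   maximum intersection is kept — whole impurity components are discarded.
3. **Mask-guided classification** — classifier inputs are the image weighted
   (or concatenated) with its segmentation mask, suppressing clutter pixels.
4. **Collaboration** — a U-Net-style segmenter trained on the (refined)
   pseudo masks supplies masks to the classifier; the classifier's activation
   maps refine the segmenter's labels; both are retrained per round until the
   masks stop changing.

Evaluation uses one-vs-rest precision / recall / specificity / F1 with macro
averaging for classification, and MIoU / MPA / pixel accuracy over the pixel
confusion matrix for segmentation.

Because no public SEM pollen dataset exists, the package ships a first-class
synthetic generator (`pollenseg.synth`) that emulates the statistical
structure the method assumes: one dominant textured particle per image
(granular sphere / rounded rectangle / olive-shaped ellipse, one family per
taxon), small impurity specks that may touch the grain, Gaussian noise, and
the 805:248:271 class imbalance of the motivating survey — all bit-for-bit
reproducible from a seed.

## Worked example

```python
import pollenseg as ps

# one cluttered synthetic micrograph + its unsupervised pseudo mask
sample = ps.generate_sample(ps.SyntheticSpec(class_id=0, seed=0))
mask, qc = ps.extract_pseudo_mask(sample.image, ps.ExtractionConfig())
print(qc.accepted, round(qc.foreground_frac, 3))
# True 0.29

rep = ps.segmentation_metrics(mask, sample.gt_mask)
print(round(rep.miou, 3), round(rep.mpa, 3))
# 0.933 0.981
```

The extraction accepts the mask (foreground fraction 0.29 of the image) and
its agreement with the synthetic ground truth is MIoU 0.933 — the pseudo label
is already close to pixel-accurate on a clean grain, and the collaborative
loop exists to hold that quality when clutter intervenes.

A full desk-scale run from the command line:

```bash
pollenseg synth --n 100 --seed 7 --out-dir data/
pollenseg extract --images data/manifest.csv --out-masks masks/
pollenseg collab --manifest data/manifest.csv --rounds 1 --seed 7 --out run/
```

`run/metrics.json` holds per-round history: pseudo-mask IoU vs ground truth,
QC acceptance counts, classifier test accuracy, and segmenter test MIoU/MPA.

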