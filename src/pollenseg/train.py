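"""Training loops and the segmentation–classification collaboration.

The collaboration alternates two weakly supervised tasks:

* round 0 — the segmenter is trained on the unsupervised contour-based pseudo
  masks (quality-controlled ones only) and the classifier on the raw images;
* each later round — class-activation maps from the current classifier (seeded
  at the true image-level label) are binarized into localization maps which
  refine every training mask (maximum-intersection component selection); the
  segmenter is retrained from scratch on the refined masks; its predictions
  then build mask-guided classifier inputs, and the classifier is retrained.

The loop stops after ``rounds`` rounds or as soon as refinement flips less
than ``stop_tol`` of the mask pixels.  Everything is seeded: identical config
and seed reproduce identical models and metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize

from . import cam as cam_mod
from .metrics import segmentation_metrics
from .models import ClsArch, DenseNet, SegArch, UNet, build_classifier, build_segmenter
from .nn import Adam, cross_entropy, pixel_cross_entropy
from .pseudolabel import ExtractionConfig, extract_pseudo_mask, qc_mask
from .synth import LabeledSample

__all__ = [
    "TrainConfig",
    "CollabState",
    "mask_guided_input",
    "augment",
    "train_segmenter",
    "train_classifier",
    "collaborative_loop",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol for both tasks.

    Defaults follow the full-scale protocol (100 epochs, cross-entropy, Adam,
    lr 1e-3 for segmentation and 1e-4 for classification, 256->224 crops);
    :meth:`desk` returns the small profile used for laptop-scale experiments.
    """

    seg_epochs: int = 100
    seg_lr: float = 1e-3
    cls_epochs: int = 100
    cls_lr: float = 1e-4
    batch_size: int = 16
    crop_from: int = 256
    crop_to: int = 224
    rounds: int = 3
    mask_mode: str = "weight"
    cam_threshold: float = 0.5
    stop_tol: float = 0.01
    augment: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.seg_epochs < 1 or self.cls_epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.crop_to > self.crop_from:
            raise ValueError("crop_to must be <= crop_from")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.mask_mode not in ("weight", "concat"):
            raise ValueError("mask_mode must be 'weight' or 'concat'")
        if not 0.0 < self.stop_tol < 1.0:
            raise ValueError("stop_tol must lie in (0, 1)")

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        """Small single-CPU profile: 64x64 images, short schedules.

        The classifier learning rate is raised to 1e-3 here: the desk-scale
        DenseNet has no batch normalization and a 1e-4 rate leaves it
        underfit within the short schedule.
        """
        base = cls(seg_epochs=12, cls_epochs=60, cls_lr=1e-3, batch_size=16,
                   crop_from=64, crop_to=64, rounds=1)
        return replace(base, **overrides)


@dataclass
class CollabState:
    """Bookkeeping of the collaborative loop."""

    round: int
    masks: list[np.ndarray]
    qc_accepted: list[bool]
    segmenter: UNet
    classifier: DenseNet
    history: list[dict] = field(default_factory=list)


def mask_guided_input(image: np.ndarray, mask: np.ndarray, mode: str = "weight") -> np.ndarray:
    """Build a classifier input from an image and its segmentation mask.

    ``weight`` multiplies the normalized image by the mask (impurity pixels are
    zeroed out, 1 channel); ``concat`` stacks image and mask as 2 channels.
    """
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask).astype(float)
    if img.shape != m.shape:
        raise ValueError(f"image/mask shape mismatch: {img.shape} vs {m.shape}")
    if img.max() > 1.0:
        img = img / 255.0
    if mode == "weight":
        return (img * m)[None]
    if mode == "concat":
        return np.stack([img, m])
    raise ValueError("mode must be 'weight' or 'concat'")


def augment(sample: LabeledSample, seed: int, crop_from: Optional[int] = None,
            crop_to: Optional[int] = None) -> LabeledSample:
    """Seeded flips/rotations and random crop, applied identically to image and mask."""
    rng = np.random.default_rng(seed)
    img = sample.image
    mask = sample.gt_mask
    if crop_from is not None and img.shape[0] != crop_from:
        img = resize(img, (crop_from, crop_from), order=1, preserve_range=True,
                     anti_aliasing=True).astype(np.uint8)
        if mask is not None:
            mask = resize(mask.astype(float), (crop_from, crop_from), order=0,
                          preserve_range=True) > 0.5
    if rng.uniform() < 0.5:
        img = img[:, ::-1]
        mask = mask[:, ::-1] if mask is not None else None
    if rng.uniform() < 0.5:
        img = img[::-1]
        mask = mask[::-1] if mask is not None else None
    k = int(rng.integers(0, 4))
    img = np.rot90(img, k)
    mask = np.rot90(mask, k) if mask is not None else None
    if crop_to is not None:
        if crop_to > img.shape[0]:
            raise ValueError("crop_to larger than image")
        r0 = int(rng.integers(0, img.shape[0] - crop_to + 1))
        c0 = int(rng.integers(0, img.shape[1] - crop_to + 1))
        img = img[r0 : r0 + crop_to, c0 : c0 + crop_to]
        mask = mask[r0 : r0 + crop_to, c0 : c0 + crop_to] if mask is not None else None
    return LabeledSample(image=np.ascontiguousarray(img), label=sample.label,
                         gt_mask=np.ascontiguousarray(mask) if mask is not None else None,
                         split=sample.split)


def center_input(x: np.ndarray) -> np.ndarray:
    """Map [0, 1] model inputs to [-1, 1]; applied at every model boundary."""
    return 2.0 * x - 1.0


def _as_batch(images: Sequence[np.ndarray], center: bool = True) -> np.ndarray:
    x = np.stack([np.asarray(im, dtype=float) for im in images])
    if x.ndim == 3:  # (N, H, W) grayscale -> add channel
        x = x[:, None]
    if x.max() > 1.0:
        x = x / 255.0
    return center_input(x) if center else x


def _epochs(n: int, batch_size: int, epochs: int, rng: np.random.Generator):
    for _ in range(epochs):
        order = rng.permutation(n)
        for s in range(0, n, batch_size):
            yield order[s : s + batch_size]


def train_segmenter(model: UNet, images: Sequence[np.ndarray], masks: Sequence[np.ndarray],
                    cfg: TrainConfig) -> dict:
    """Fit the segmenter on (image, mask) pairs; returns the loss history."""
    cfg.validate()
    if len(images) == 0:
        raise ValueError("empty training set")
    if len(images) != len(masks):
        raise ValueError("images and masks must be paired")
    x = _as_batch(images)
    t = np.stack([np.asarray(m).astype(int) for m in masks])
    opt = Adam(model.params(), cfg.seg_lr)
    rng = np.random.default_rng(cfg.seed)
    losses = []
    for _ in range(cfg.seg_epochs):
        epoch_loss, nb = 0.0, 0
        for idx in _epochs(len(images), cfg.batch_size, 1, rng):
            loss, d = pixel_cross_entropy(model.forward(x[idx]), t[idx])
            opt.zero_grad()
            model.backward(d)
            opt.step()
            epoch_loss += loss
            nb += 1
        losses.append(epoch_loss / nb)
    return {"loss": losses}


def train_classifier(model: DenseNet, images: Sequence[np.ndarray], labels: Sequence[int],
                     masks: Optional[Sequence[np.ndarray]], cfg: TrainConfig) -> dict:
    """Fit the classifier on raw or mask-guided inputs; returns the loss history."""
    cfg.validate()
    if len(images) == 0:
        raise ValueError("empty training set")
    y = np.asarray(labels, dtype=int)
    ncls = model.arch.num_classes
    if ((y < 0) | (y >= ncls)).any():
        raise ValueError(f"labels must lie in [0, {ncls})")
    if masks is not None:
        x = center_input(np.stack([mask_guided_input(im, m, cfg.mask_mode)
                                   for im, m in zip(images, masks)]))
    else:
        x = _as_batch(images)
    opt = Adam(model.params(), cfg.cls_lr)
    rng = np.random.default_rng(cfg.seed)
    losses = []
    for _ in range(cfg.cls_epochs):
        epoch_loss, nb = 0.0, 0
        for idx in _epochs(len(images), cfg.batch_size, 1, rng):
            loss, d = cross_entropy(model.forward(x[idx]), y[idx])
            opt.zero_grad()
            model.backward(d)
            opt.step()
            epoch_loss += loss
            nb += 1
        losses.append(epoch_loss / nb)
    return {"loss": losses}


def _predict_masks(segmenter: UNet, images: Sequence[np.ndarray],
                   batch: int = 16) -> list[np.ndarray]:
    x = _as_batch(images)
    out = []
    for s in range(0, len(images), batch):
        out.extend(list(segmenter.predict_mask(x[s : s + batch])))
    return out


def _mean_iou(masks: Sequence[np.ndarray], gts: Sequence[Optional[np.ndarray]]) -> Optional[float]:
    vals = [
        (m & g).sum() / max((m | g).sum(), 1)
        for m, g in zip(masks, gts)
        if g is not None
    ]
    return float(np.mean(vals)) if vals else None


def collaborative_loop(
    samples: Sequence[LabeledSample],
    extraction_cfg: ExtractionConfig,
    train_cfg: TrainConfig,
    seg_arch: SegArch = SegArch(),
    cls_arch: ClsArch = ClsArch(),
) -> CollabState:
    """Run the full weakly supervised collaboration on image-level-labeled data.

    Only ``split == 'train'`` samples drive training; test samples are used for
    per-round evaluation (classifier inputs at round >= 1 are built from the
    segmenter's own predicted masks, never from ground truth).  Per-round
    metrics land in ``state.history``; ground-truth mask IoU entries appear
    only when samples carry synthetic ground truth.
    """
    train_cfg.validate()
    train = [s for s in samples if s.split == "train"]
    test = [s for s in samples if s.split == "test"]
    if not train:
        raise ValueError("no training samples")
    seeds = np.random.SeedSequence(train_cfg.seed).generate_state(2 * train_cfg.rounds + 2)
    seeds = [int(s % (2**31 - 1)) for s in seeds]

    # --- round 0: unsupervised pseudo masks + raw-image classifier
    masks, accepted = [], []
    for s in train:
        m, qc = extract_pseudo_mask(s.image, extraction_cfg)
        masks.append(m)
        accepted.append(qc.accepted)
    if not any(accepted):
        raise RuntimeError("quality control rejected every pseudo mask; cannot train")

    def cls_arch_for(masked: bool) -> ClsArch:
        # concat-mode inputs carry an extra mask channel; models are
        # re-initialized every round, so the width can differ per round
        ch = 2 if (masked and train_cfg.mask_mode == "concat") else 1
        return replace(cls_arch, in_ch=ch)

    segmenter = build_segmenter(seg_arch, seed=seeds[0])
    seg_imgs = [s.image for s, a in zip(train, accepted) if a]
    seg_msks = [m for m, a in zip(masks, accepted) if a]
    train_segmenter(segmenter, seg_imgs, seg_msks, replace(train_cfg, seed=seeds[0]))
    classifier = build_classifier(cls_arch_for(False), seed=seeds[1])
    train_classifier(classifier, [s.image for s in train], [s.label for s in train],
                     None, replace(train_cfg, seed=seeds[1]))
    state = CollabState(round=0, masks=masks, qc_accepted=accepted,
                        segmenter=segmenter, classifier=classifier)
    state.history.append(
        _evaluate(state, train, test, train_cfg, round_idx=0, flip_frac=None)
    )

    # --- collaboration rounds
    for r in range(1, train_cfg.rounds + 1):
        new_masks, flipped, total = [], 0, 0
        for s, m in zip(train, state.masks):
            inp = center_input(s.image.astype(float)[None] / 255.0)
            heat = cam_mod.grad_cam(state.classifier, inp, s.label)
            loc = cam_mod.binarize_cam(heat, train_cfg.cam_threshold)
            refined, _ = cam_mod.refine_mask(m, loc)
            flipped += int((refined ^ m).sum())
            total += m.size
            new_masks.append(refined)
        flip_frac = flipped / total
        accepted = [qc_mask(m, extraction_cfg).accepted for m in new_masks]
        if not any(accepted):
            raise RuntimeError("quality control rejected every refined mask")
        # retrain segmenter on refined masks, then classifier on its predictions
        seg = build_segmenter(seg_arch, seed=seeds[2 * r])
        seg_imgs = [s.image for s, a in zip(train, accepted) if a]
        seg_msks = [m for m, a in zip(new_masks, accepted) if a]
        train_segmenter(seg, seg_imgs, seg_msks, replace(train_cfg, seed=seeds[2 * r]))
        pred_masks = _predict_masks(seg, [s.image for s in train])
        cls = build_classifier(cls_arch_for(True), seed=seeds[2 * r + 1])
        train_classifier(cls, [s.image for s in train], [s.label for s in train],
                         pred_masks, replace(train_cfg, seed=seeds[2 * r + 1]))
        state.round = r
        state.masks = new_masks
        state.qc_accepted = accepted
        state.segmenter = seg
        state.classifier = cls
        state.history.append(
            _evaluate(state, train, test, train_cfg, round_idx=r, flip_frac=flip_frac)
        )
        if flip_frac < train_cfg.stop_tol:
            break
    return state


def _evaluate(state: CollabState, train, test, cfg: TrainConfig,
              round_idx: int, flip_frac) -> dict:
    entry: dict = {
        "round": round_idx,
        "n_qc_accepted": int(np.sum(state.qc_accepted)),
        "flip_frac": flip_frac,
        "train_mask_iou": _mean_iou(state.masks, [s.gt_mask for s in train]),
    }
    if test:
        imgs = [s.image for s in test]
        y = np.array([s.label for s in test])
        if round_idx == 0:
            x = _as_batch(imgs)
        else:
            pred_masks = _predict_masks(state.segmenter, imgs)
            x = center_input(np.stack([mask_guided_input(im, m, cfg.mask_mode)
                                       for im, m in zip(imgs, pred_masks)]))
        entry["test_accuracy"] = float((state.classifier.predict(x) == y).mean())
        gts = [s.gt_mask for s in test]
        if all(g is not None for g in gts):
            pred_masks = _predict_masks(state.segmenter, imgs)
            rep = segmentation_metrics(np.stack(pred_masks), np.stack(gts))
            entry["seg_test_miou"] = rep.miou
            entry["seg_test_mpa"] = rep.mpa
    return entry
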