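"""Unsupervised pollen extraction: contour detection to pseudo segmentation masks.

The stage turns a raw single-particle micrograph into a pixelwise pseudo label
without any human annotation, exploiting one structural fact: the pollen grain
encloses a considerably greater area than any impurity speck.  The pipeline is

1. Canny contour detection (Gaussian smoothing, Sobel gradients, 4-bin
   non-maximum suppression, dual-threshold hysteresis) — the "saliency map"
   describing boundaries of the grain and of the clutter;
2. opening of the contour map — an area opening that deletes small-scale speck
   responses while leaving closed boundary curves (and hence the areas they
   enclose) essentially unchanged;
3. flood fill from the image border to identify background, so every closed
   contour becomes a filled region, followed by relative-area selection that
   keeps only region(s) comparable to the largest one;
4. an automated quality-control rule (area-fraction bounds, component count)
   standing in for expert screening of failed extractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "ExtractionConfig",
    "QCResult",
    "canny_edges",
    "open_contours",
    "fill_and_select",
    "qc_mask",
    "extract_pseudo_mask",
]

_CROSS = ndi.generate_binary_structure(2, 1)  # 4-connectivity
_SQUARE = ndi.generate_binary_structure(2, 2)  # 8-connectivity


@dataclass(frozen=True)
class ExtractionConfig:
    """Knobs of the unsupervised extraction stage.

    The dual thresholds are in gradient-magnitude units of the raw 0–255
    intensity scale (Sobel of the Gaussian-smoothed image); ``gaussian_kernel``
    is the odd side length of the smoothing kernel, with sigma derived from it
    by the usual kernel-size rule sigma = 0.3*((k-1)/2 - 1) + 0.8.
    """

    gaussian_kernel: int = 9
    low_threshold: float = 50.0
    high_threshold: float = 100.0
    contour_width: int = 1
    open_radius: int = 1
    area_keep_frac: float = 0.5
    min_area: int = 16
    qc_area_bounds: tuple[float, float] = (0.05, 0.80)
    max_components: int = 1

    def validate(self) -> None:
        if self.gaussian_kernel < 3 or self.gaussian_kernel % 2 == 0:
            raise ValueError("gaussian_kernel must be odd and >= 3")
        if not 0 < self.low_threshold < self.high_threshold:
            raise ValueError("need 0 < low_threshold < high_threshold")
        if self.contour_width < 1:
            raise ValueError("contour_width must be >= 1")
        if self.open_radius < 0:
            raise ValueError("open_radius must be >= 0")
        if not 0.0 < self.area_keep_frac <= 1.0:
            raise ValueError("area_keep_frac must lie in (0, 1]")
        lo, hi = self.qc_area_bounds
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("qc_area_bounds must satisfy 0 <= lo < hi <= 1")

    @property
    def sigma(self) -> float:
        return 0.3 * ((self.gaussian_kernel - 1) / 2.0 - 1.0) + 0.8


@dataclass(frozen=True)
class QCResult:
    """Outcome of the automated pseudo-mask screening."""

    accepted: bool
    reason: Optional[str]
    foreground_frac: float
    n_components: int


def _check_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    return img.astype(float)


def _nonmax_suppress(gr: np.ndarray, gc: np.ndarray, mag: np.ndarray) -> np.ndarray:
    """Thin the gradient magnitude to local maxima along the gradient.

    The two neighbour magnitudes along the gradient direction are linearly
    interpolated from the surrounding octant; a pixel survives when its
    magnitude is >= both.  The 1-px image border is excluded (no full
    neighbourhood there).
    """

    def shift(a: np.ndarray, dr: int, dc: int) -> np.ndarray:
        p = np.pad(a, 1, mode="constant")
        return p[1 + dr : p.shape[0] - 1 + dr, 1 + dc : p.shape[1] - 1 + dc]

    ar, ac = np.abs(gr), np.abs(gc)
    eps = np.finfo(float).eps
    same_sign = (gr * gc) >= 0
    out = np.zeros_like(mag, dtype=bool)

    # gradient closer to the column axis -> neighbours left/right
    horiz = ac >= ar
    w = ar / (ac + eps)
    diag = np.where(same_sign, shift(mag, 1, 1), shift(mag, -1, 1))
    diag_o = np.where(same_sign, shift(mag, -1, -1), shift(mag, 1, -1))
    n1 = shift(mag, 0, 1) * (1 - w) + diag * w
    n2 = shift(mag, 0, -1) * (1 - w) + diag_o * w
    out |= horiz & (mag >= n1) & (mag >= n2)

    # gradient closer to the row axis -> neighbours up/down
    vert = ~horiz
    w = ac / (ar + eps)
    diag = np.where(same_sign, shift(mag, 1, 1), shift(mag, 1, -1))
    diag_o = np.where(same_sign, shift(mag, -1, -1), shift(mag, -1, 1))
    n1 = shift(mag, 1, 0) * (1 - w) + diag * w
    n2 = shift(mag, -1, 0) * (1 - w) + diag_o * w
    out |= vert & (mag >= n1) & (mag >= n2)

    out[0, :] = out[-1, :] = False
    out[:, 0] = out[:, -1] = False
    return out


def canny_edges(image: np.ndarray, cfg: ExtractionConfig = ExtractionConfig()) -> np.ndarray:
    """Dual-threshold contour detection on an 8-bit grayscale image.

    Gaussian smoothing, Sobel gradient magnitude/direction, non-maximum
    suppression with the neighbour magnitude interpolated along the gradient
    direction, then hysteresis: weak responses (>= low) survive only in
    8-connected components that contain a strong response (>= high).
    """
    cfg.validate()
    img = _check_image(image)
    # constant-mode smoothing with bleed-over compensation keeps border
    # gradients unbiased (same convention as the classic reference pipeline)
    smoothed = ndi.gaussian_filter(img, cfg.sigma, mode="constant")
    bleed = ndi.gaussian_filter(np.ones_like(img), cfg.sigma, mode="constant")
    smoothed = smoothed / (bleed + np.finfo(float).eps)
    gr = ndi.sobel(smoothed, axis=0)
    gc = ndi.sobel(smoothed, axis=1)
    mag = np.hypot(gr, gc)

    nms = _nonmax_suppress(gr, gc, mag)
    weak = nms & (mag >= cfg.low_threshold)
    strong = weak & (mag >= cfg.high_threshold)
    if not strong.any():
        edges = np.zeros_like(weak)
    else:
        labels, _ = ndi.label(weak, structure=_SQUARE)
        strong_labels = np.unique(labels[strong])
        edges = np.isin(labels, strong_labels) & weak
    if cfg.contour_width > 1:
        r = (cfg.contour_width - 1 + 1) // 2
        yy, xx = np.ogrid[-r : r + 1, -r : r + 1]
        edges = ndi.binary_dilation(edges, structure=yy * yy + xx * xx <= r * r)
    return edges


def open_contours(edges: np.ndarray, cfg: ExtractionConfig = ExtractionConfig()) -> np.ndarray:
    """Opening of the contour map: remove small-scale speck responses.

    Implemented as an area opening (component-size opening at 8-connectivity):
    8-connected edge components smaller than (2*open_radius+1)^2 pixels are
    erased.  Closed boundary curves pass through unchanged, so the area they
    enclose is preserved exactly, and the operator is idempotent.
    """
    cfg.validate()
    e = np.asarray(edges)
    if e.ndim != 2:
        raise ValueError("edge map must be 2-D")
    e = e.astype(bool)
    if cfg.open_radius == 0 or not e.any():
        return e.copy()
    min_size = (2 * cfg.open_radius + 1) ** 2
    labels, n = ndi.label(e, structure=_SQUARE)
    if n == 0:
        return e.copy()
    sizes = ndi.sum_labels(e, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_size) + 1
    return np.isin(labels, keep)


def fill_and_select(
    edges: np.ndarray, cfg: ExtractionConfig = ExtractionConfig()
) -> tuple[np.ndarray, bool]:
    """Fill closed contours and keep the large region(s).

    Background is the 4-connected non-edge region reachable from the image
    border; everything else (enclosed pixels plus the contours around them) is
    candidate foreground.  Components (8-connected) that enclose no interior
    pixel, fall below ``min_area``, or are smaller than
    ``area_keep_frac`` x the largest component are discarded.  Components tied
    with the largest are kept (``area_keep_frac <= 1`` keeps ties).

    Returns ``(mask, found)``; ``found`` is False when no closed region exists,
    in which case the mask is empty and the caller decides the QC fate.
    """
    cfg.validate()
    e = np.asarray(edges).astype(bool)
    if e.ndim != 2:
        raise ValueError("edge map must be 2-D")
    non_edge = ~e
    labels, _ = ndi.label(non_edge, structure=_CROSS)
    border = np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    border_ids = np.unique(border[border > 0])
    background = np.isin(labels, border_ids)
    fg = ~background
    enclosed = fg & non_edge
    if not enclosed.any():
        return np.zeros_like(e, dtype=bool), False

    comp, n = ndi.label(fg, structure=_SQUARE)
    idx = np.arange(1, n + 1)
    areas = ndi.sum_labels(fg, comp, index=idx)
    interior = ndi.sum_labels(enclosed, comp, index=idx)
    closed = interior > 0  # open stray curves enclose nothing
    if not closed.any():
        return np.zeros_like(e, dtype=bool), False
    largest = areas[closed].max()
    keep = closed & (areas >= max(cfg.min_area, cfg.area_keep_frac * largest))
    mask = np.isin(comp, idx[keep])
    return mask, True


def qc_mask(mask: np.ndarray, cfg: ExtractionConfig = ExtractionConfig()) -> QCResult:
    """Automated screening of a pseudo mask (area bounds, component count)."""
    cfg.validate()
    m = np.asarray(mask).astype(bool)
    frac = float(m.mean())
    _, n = ndi.label(m, structure=_SQUARE)
    lo, hi = cfg.qc_area_bounds
    if not m.any():
        return QCResult(False, "empty", frac, 0)
    if frac > hi:
        return QCResult(False, "too_large", frac, n)
    if frac < lo:
        return QCResult(False, "too_small", frac, n)
    if n > cfg.max_components:
        return QCResult(False, "multi_component", frac, n)
    return QCResult(True, None, frac, n)


def extract_pseudo_mask(
    image: np.ndarray, cfg: ExtractionConfig = ExtractionConfig()
) -> tuple[np.ndarray, QCResult]:
    """Full unsupervised extraction: contours -> opening -> fill/select -> QC."""
    edges = canny_edges(image, cfg)
    opened = open_contours(edges, cfg)
    mask, found = fill_and_select(opened, cfg)
    if not found:
        return mask, QCResult(False, "empty", 0.0, 0)
    return mask, qc_mask(mask, cfg)
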