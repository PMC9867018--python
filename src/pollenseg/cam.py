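"""Gradient-weighted class-activation mapping and pseudo-mask refinement.

Given a trained classifier, the class-activation heat map for class ``c`` is

    L_c = ReLU( sum_k alpha_k^c * A_k ),      alpha_k^c = (1/Z) sum_ij dy_c/dA_kij

where ``A_k`` are the last-conv feature channels and ``Z`` their spatial size.
The score gradient is seeded with 1 for the target class and 0 elsewhere.  The
map is bilinearly upsampled to image resolution and min–max normalized, then
binarized into a localization map of high-interest pixels.

Refinement combines the unsupervised contour-based pseudo mask with the
localization map: among the 8-connected components of the pseudo mask, the one
with the greatest overlap with the localization map is kept — whole impurity
components are discarded without eroding the particle itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize

__all__ = ["CamHeatmap", "grad_cam", "binarize_cam", "refine_mask"]

_SQUARE = ndi.generate_binary_structure(2, 2)


@dataclass
class CamHeatmap:
    """Normalized class-activation map at image resolution.

    ``values`` lie in [0, 1] (max 1 unless the map is identically zero);
    ``raw`` is the pre-normalization map at feature resolution.
    """

    values: np.ndarray
    raw: np.ndarray
    target_class: int


def grad_cam(classifier, image_input: np.ndarray, target_class: int) -> CamHeatmap:
    """Class-activation heat map of ``target_class`` for one model input.

    ``classifier`` must expose ``forward_with_features(x) -> (logits, A)`` and
    ``grad_wrt_features(dlogits) -> dA`` (see :class:`pollenseg.models.DenseNet`).
    ``image_input`` is a single ``(C, H, W)`` normalized input.
    """
    if not (hasattr(classifier, "forward_with_features") and hasattr(classifier, "grad_wrt_features")):
        raise TypeError("classifier does not expose last-conv activations/gradients")
    x = np.asarray(image_input, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected a single (C, H, W) model input")
    logits, a = classifier.forward_with_features(x[None])
    n_classes = logits.shape[1]
    if not 0 <= target_class < n_classes:
        raise ValueError(f"target_class {target_class} out of range [0, {n_classes})")
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    da = classifier.grad_wrt_features(dlogits)  # (1, K, h, w)
    alpha = da[0].mean(axis=(1, 2))  # global-average-pooled gradients
    raw = np.maximum(np.tensordot(alpha, a[0], axes=1), 0.0)  # ReLU(sum_k alpha_k A_k)
    up = resize(raw, x.shape[1:], order=1, mode="edge", anti_aliasing=False, preserve_range=True)
    return CamHeatmap(values=_minmax(up), raw=raw, target_class=int(target_class))


def _minmax(h: np.ndarray) -> np.ndarray:
    hmax, hmin = h.max(), h.min()
    if hmax <= 0.0:
        return np.zeros_like(h)
    if hmax == hmin:  # constant positive map
        return np.ones_like(h)
    return (h - hmin) / (hmax - hmin)


def binarize_cam(heatmap: CamHeatmap | np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Localization map: pixels whose normalized activation is >= threshold.

    At ``threshold == 0`` the comparison is strict (``> 0``), so an identically
    zero heat map always yields an empty localization map.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    values = heatmap.values if isinstance(heatmap, CamHeatmap) else np.asarray(heatmap)
    if threshold == 0.0:
        return values > 0.0
    return values >= threshold


def refine_mask(
    pseudo: np.ndarray, loc: np.ndarray, mode: str = "component"
) -> tuple[np.ndarray, bool]:
    """Select the maximum-intersection region of a pseudo mask.

    ``component`` mode keeps the 8-connected component of ``pseudo`` with the
    largest overlap with ``loc`` (ties: larger component, then smallest
    (row, col) anchor); ``intersect`` mode is the plain pixelwise AND, kept for
    comparison.  When ``loc`` is empty or disjoint from every component, the
    pseudo mask is returned unchanged with ``warning=True``.
    """
    p = np.asarray(pseudo).astype(bool)
    l = np.asarray(loc).astype(bool)
    if p.shape != l.shape:
        raise ValueError(f"mask/localization shape mismatch: {p.shape} vs {l.shape}")
    if mode not in ("component", "intersect"):
        raise ValueError("mode must be 'component' or 'intersect'")
    if mode == "intersect":
        inter = p & l
        if not inter.any():
            return p.copy(), True
        return inter, False
    labels, n = ndi.label(p, structure=_SQUARE)
    if n == 0 or not l.any():
        return p.copy(), True
    idx = np.arange(1, n + 1)
    overlaps = ndi.sum_labels(l, labels, index=idx)
    if overlaps.max() == 0:
        return p.copy(), True
    areas = ndi.sum_labels(p, labels, index=idx)
    # anchor = first foreground pixel in scan order, as a deterministic tiebreak
    flat_first = np.full(n, np.inf)
    rr, cc = np.nonzero(p)
    order = labels[rr, cc] - 1
    np.minimum.at(flat_first, order, rr * p.shape[1] + cc)
    best = sorted(range(n), key=lambda k: (-overlaps[k], -areas[k], flat_first[k]))[0]
    return labels == best + 1, False
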