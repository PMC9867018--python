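"""Network architectures: an encoder–decoder segmenter and a densely connected
classifier.

Both are deliberately narrow "desk-scale" variants of the canonical designs: a
U-Net-style encoder–decoder with skip connections for binary (pollen vs
background) segmentation, and a DenseNet-style classifier whose dense blocks
concatenate every previous layer's feature maps.  The classifier exposes its
last convolutional activations and the gradient of any class score w.r.t.
them, which is exactly the interface gradient-weighted class-activation
mapping needs.

Checkpoints are plain ``.npz`` files holding the architecture description and
every parameter array.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import (
    Adam,  # noqa: F401  (re-exported convenience)
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    Param,
    ReLU,
    Sequential,
    UpsampleNearest2d,
)

__all__ = ["SegArch", "ClsArch", "UNet", "DenseNet", "build_segmenter", "build_classifier",
           "save_model", "load_model"]


@dataclass(frozen=True)
class SegArch:
    """U-Net shape: ``depth`` pooling stages, ``width`` channels at full resolution."""

    depth: int = 2
    width: int = 8
    in_ch: int = 1
    num_classes: int = 2

    def validate(self) -> None:
        if self.depth < 1 or self.depth > 4:
            raise ValueError("depth must be in 1..4")
        if self.width < 1:
            raise ValueError("width must be >= 1")


@dataclass(frozen=True)
class ClsArch:
    """DenseNet shape: two dense blocks of ``block_layers`` layers, growth rate
    ``growth``, and a final ``feat_ch``-channel convolution feeding GAP."""

    init_ch: int = 12
    growth: int = 8
    block_layers: int = 2
    feat_ch: int = 24
    in_ch: int = 1
    num_classes: int = 3

    def validate(self) -> None:
        if min(self.init_ch, self.growth, self.block_layers, self.feat_ch) < 1:
            raise ValueError("all DenseNet size fields must be >= 1")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")


def _conv_block(in_ch: int, out_ch: int, rng) -> Sequential:
    return Sequential(Conv2d(in_ch, out_ch, rng=rng), ReLU(), Conv2d(out_ch, out_ch, rng=rng), ReLU())


class UNet:
    """Encoder–decoder with skip connections; per-pixel 2-class scores."""

    def __init__(self, arch: SegArch = SegArch(), seed: int = 0):
        arch.validate()
        self.arch = arch
        rng = np.random.default_rng(seed)
        w = arch.width
        self.enc = []
        ch = arch.in_ch
        for d in range(arch.depth):
            self.enc.append(_conv_block(ch, w * 2**d, rng))
            ch = w * 2**d
        self.pools = [MaxPool2d() for _ in range(arch.depth)]
        self.bottleneck = _conv_block(ch, w * 2**arch.depth, rng)
        self.ups = [UpsampleNearest2d() for _ in range(arch.depth)]
        self.dec = []
        ch = w * 2**arch.depth
        for d in reversed(range(arch.depth)):
            skip = w * 2**d
            self.dec.append(_conv_block(ch + skip, skip, rng))
            ch = skip
        self.head = Conv2d(ch, arch.num_classes, k=1, rng=rng)

    def params(self) -> list[Param]:
        ps: list[Param] = []
        for b in self.enc + [self.bottleneck] + self.dec:
            ps += b.params()
        return ps + self.head.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4:
            raise ValueError("expected (N, C, H, W) input")
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_ch = []
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            self._skip_ch.append(skip.shape[1])
            x = block.forward(np.concatenate([skip, x], axis=1))
        return self.head.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.head.backward(dy)
        dskips = []
        for block, up, sc in zip(reversed(self.dec), reversed(self.ups), reversed(self._skip_ch)):
            d = block.backward(dy)
            dskips.append(d[:, :sc])
            dy = up.backward(d[:, sc:])
        dy = self.bottleneck.backward(dy)
        # dskips were collected decoder-first (full resolution last); the encoder
        # unwinds from the deepest stage, so walk them in reverse
        for block, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(dskips)):
            dy = pool.backward(dy)
            dy = block.backward(dy + dskip)
        return dy

    def predict_mask(self, images: np.ndarray) -> np.ndarray:
        """Argmax foreground masks for normalized ``(N, 1, H, W)`` inputs.

        Ties at exactly equal scores resolve to the lower class index
        (background), which is what ``argmax`` returns first.
        """
        logits = self.forward(images)
        return np.argmax(logits, axis=1).astype(bool)


class _DenseBlock:
    def __init__(self, in_ch: int, layers: int, growth: int, rng):
        self.convs = [Conv2d(in_ch + i * growth, growth, rng=rng) for i in range(layers)]
        self.relus = [ReLU() for _ in range(layers)]
        self.out_ch = in_ch + layers * growth

    def params(self) -> list[Param]:
        return [p for c in self.convs for p in c.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        feats = [x]
        for conv, relu in zip(self.convs, self.relus):
            y = relu.forward(conv.forward(np.concatenate(feats, axis=1)))
            feats.append(y)
        self._chs = [f.shape[1] for f in feats]
        return np.concatenate(feats, axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # split the gradient of the concatenated output back onto each feature
        bounds = np.cumsum(self._chs)
        dfeats = [dy[:, s:e] for s, e in zip([0, *bounds[:-1]], bounds)]
        for i in reversed(range(len(self.convs))):
            d_in = self.convs[i].backward(self.relus[i].backward(dfeats[i + 1]))
            cb = np.cumsum(self._chs[: i + 1])
            for j, (s, e) in enumerate(zip([0, *cb[:-1]], cb)):
                dfeats[j] = dfeats[j] + d_in[:, s:e]
        return dfeats[0]


class DenseNet:
    """Densely connected classifier exposing its last-conv feature stack.

    ``forward_with_features`` returns ``(logits, A)`` where ``A`` is the
    activation of the final convolution (after ReLU); ``grad_wrt_features``
    backpropagates a logit gradient through the GAP + linear head only,
    yielding dscore/dA for class-activation mapping.
    """

    def __init__(self, arch: ClsArch = ClsArch(), seed: int = 0):
        arch.validate()
        self.arch = arch
        rng = np.random.default_rng(seed)
        self.stem = Sequential(Conv2d(arch.in_ch, arch.init_ch, rng=rng), ReLU(), MaxPool2d())
        self.block1 = _DenseBlock(arch.init_ch, arch.block_layers, arch.growth, rng)
        t1 = self.block1.out_ch // 2
        self.trans = Sequential(Conv2d(self.block1.out_ch, t1, k=1, rng=rng), ReLU(), MaxPool2d())
        self.block2 = _DenseBlock(t1, arch.block_layers, arch.growth, rng)
        self.final_conv = Conv2d(self.block2.out_ch, arch.feat_ch, rng=rng)
        self.final_relu = ReLU()
        self.gap = GlobalAvgPool()
        self.fc = Linear(arch.feat_ch, arch.num_classes, rng=rng)

    def params(self) -> list[Param]:
        return (self.stem.params() + self.block1.params() + self.trans.params()
                + self.block2.params() + self.final_conv.params() + self.fc.params())

    def forward_with_features(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if x.ndim != 4:
            raise ValueError("expected (N, C, H, W) input")
        x = self.stem.forward(x)
        x = self.block1.forward(x)
        x = self.trans.forward(x)
        x = self.block2.forward(x)
        a = self.final_relu.forward(self.final_conv.forward(x))
        self.feature_activations = a
        logits = self.fc.forward(self.gap.forward(a))
        return logits, a

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.forward_with_features(x)[0]

    def grad_wrt_features(self, dlogits: np.ndarray) -> np.ndarray:
        """Gradient of ``sum(dlogits * logits)`` w.r.t. the feature stack."""
        return self.gap.backward(self.fc.backward(dlogits))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        da = self.final_relu.backward(self.grad_wrt_features(dlogits))
        dx = self.final_conv.backward(da)
        dx = self.block2.backward(dx)
        dx = self.trans.backward(dx)
        dx = self.block1.backward(dx)
        return self.stem.backward(dx)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Predicted labels; score ties resolve to the lower class index."""
        return np.argmax(self.forward(images), axis=1)


def build_segmenter(arch: SegArch = SegArch(), seed: int = 0) -> UNet:
    return UNet(arch, seed=seed)


def build_classifier(arch: ClsArch = ClsArch(), seed: int = 0) -> DenseNet:
    return DenseNet(arch, seed=seed)


def save_model(model: UNet | DenseNet, path) -> None:
    kind = "unet" if isinstance(model, UNet) else "densenet"
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    meta = json.dumps({"kind": kind, "arch": asdict(model.arch)})
    np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path) -> UNet | DenseNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        if meta["kind"] == "unet":
            model: UNet | DenseNet = UNet(SegArch(**{k: v for k, v in meta["arch"].items()}))
        else:
            model = DenseNet(ClsArch(**{k: v for k, v in meta["arch"].items()}))
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"p{i}"]
    return model
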