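"""Gastric-wall detection with a compact U-net.

The gastric scene has little semantic variety -- essentially wall
versus contrast-filled cavity -- and clinical datasets are small, so a
small encoder-decoder with skip connections is the right size of model.
The encoder applies pairs of 3x3 convolutions with ReLU (ten
convolutions in total down the contracting path) and four 2x2
max-poolings, doubling the channel count at every scale; the decoder
mirrors it with four 2x2 transposed convolutions that halve the
channels, concatenating the saved same-scale encoder features along the
channel axis before each convolution pair, and a final 1x1 convolution
with pixel-wise softmax over {background, wall}.

The network is pure NumPy (see :mod:`gastrolayer.nn`), trained with
Adam on pixel-wise cross-entropy; it is deliberately tiny and runs on a
single CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from . import nn
from .errors import GastrolayerError, NoWallDetectedError


@dataclass(frozen=True)
class DetectorConfig:
    input_size: tuple[int, int] = (256, 256)
    depth: int = 4
    base_channels: int = 8
    epochs: int = 30
    batch_size: int = 4
    learning_rate: float = 2e-3
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise GastrolayerError("depth must be >= 1")
        f = 2**self.depth
        if self.input_size[0] % f or self.input_size[1] % f:
            raise GastrolayerError(f"input_size must be divisible by 2^depth = {f}")


class UNet:
    """Encoder-decoder with skip concatenation and 2-class softmax head."""

    def __init__(self, cfg: DetectorConfig):
        self.cfg = cfg
        self.norm_scale: float | None = None  # set by train_detector
        rng = np.random.default_rng(cfg.seed)
        C = cfg.base_channels
        self.enc: list[tuple[nn.Conv3x3, nn.ReLU, nn.Conv3x3, nn.ReLU]] = []
        self.pools: list[nn.MaxPool2] = []
        c_in = 1
        self.enc_channels = []
        for d in range(cfg.depth + 1):  # last level is the bottleneck
            c_out = C * 2**d
            self.enc.append((nn.Conv3x3(c_in, c_out, rng), nn.ReLU(),
                             nn.Conv3x3(c_out, c_out, rng), nn.ReLU()))
            self.enc_channels.append(c_out)
            if d < cfg.depth:
                self.pools.append(nn.MaxPool2())
            c_in = c_out
        self.dec: list[tuple[nn.Deconv2x2, nn.Conv3x3, nn.ReLU, nn.Conv3x3, nn.ReLU]] = []
        for d in reversed(range(cfg.depth)):
            c_out = C * 2**d
            self.dec.append((nn.Deconv2x2(c_in, c_out, rng),
                             nn.Conv3x3(2 * c_out, c_out, rng), nn.ReLU(),
                             nn.Conv3x3(c_out, c_out, rng), nn.ReLU()))
            c_in = c_out
        self.head = nn.Conv1x1(c_in, 2, rng)

    def layers(self):
        out: list[nn.Layer] = []
        for block in self.enc:
            out.extend(block)
        out.extend(self.pools)
        for block in self.dec:
            out.extend(block)
        out.append(self.head)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits (N, 2, H, W) for input (N, 1, H, W)."""
        skips = []
        for d, block in enumerate(self.enc):
            for layer in block:
                x = layer.forward(x)
            if d < self.cfg.depth:
                skips.append(x)
                x = self.pools[d].forward(x)
        self._skip_channels = []
        for i, (up, conv1, r1, conv2, r2) in enumerate(self.dec):
            x = up.forward(x)
            skip = skips[-(i + 1)]
            x = np.concatenate([skip, x], axis=1)
            for layer in (conv1, r1, conv2, r2):
                x = layer.forward(x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray):
        dx = self.head.backward(dlogits)
        dskips = []
        for up, conv1, r1, conv2, r2 in reversed(self.dec):
            for layer in (r2, conv2, r1, conv1):
                dx = layer.backward(dx)
            c_skip = dx.shape[1] // 2
            dskips.append(dx[:, :c_skip])
            dx = up.backward(dx[:, c_skip:])
        for d in reversed(range(len(self.enc))):
            if d < self.cfg.depth:
                dx = self.pools[d].backward(dx)
                dx = dx + dskips[d]
            for layer in reversed(self.enc[d]):
                dx = layer.backward(dx)
        return dx

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x))


def build_unet(cfg: DetectorConfig) -> UNet:
    """Construct the compact U-net; weights are seeded from ``cfg.seed``."""
    return UNet(cfg)


def _to_net_input(image: np.ndarray, size, scale: float) -> np.ndarray:
    # dataset-level scale (not per-image min-max) so that a wall-free image
    # stays dim instead of being stretched into wall-like contrast
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise GastrolayerError("detector input must be a 2-D image")
    resized = resize(image, size, order=1, anti_aliasing=True, preserve_range=True)
    return (resized / scale).astype(np.float32)


def _to_net_mask(mask: np.ndarray, size) -> np.ndarray:
    mask = np.asarray(mask)
    return resize(mask.astype(float), size, order=0, preserve_range=True).astype(np.int64) > 0


def train_detector(images, masks, cfg: DetectorConfig, model: UNet | None = None,
                   log: list | None = None) -> UNet:
    """Train the U-net on (image, mask) pairs with Adam.

    Inputs are resized to ``cfg.input_size`` (bilinear for images,
    nearest for masks) and min-max normalised per image.  Returns the
    trained model; per-epoch mean loss is appended to ``log`` when
    given.  Fixed ``cfg.seed`` makes the trajectory reproducible.
    """
    images = list(images)
    masks = list(masks)
    if len(images) == 0 or len(images) != len(masks):
        raise GastrolayerError("need equally many images and masks, at least one pair")
    for im, mk in zip(images, masks):
        if np.shape(im) != np.shape(mk):
            raise GastrolayerError("image/mask shape mismatch")

    scale = float(np.mean([np.mean(im) for im in images]))
    if scale <= 0:
        raise GastrolayerError("training images must have positive mean intensity")
    x = np.stack([_to_net_input(im, cfg.input_size, scale) for im in images])[:, None]
    y = np.stack([_to_net_mask(mk, cfg.input_size) for mk in masks]).astype(np.int64)

    if model is None:
        model = build_unet(cfg)
    model.norm_scale = scale
    opt = nn.Adam(model.layers(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(images)
    bs = max(1, min(cfg.batch_size, n))
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            logits = model.forward(x[idx])
            loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        if log is not None:
            log.append(float(np.mean(losses)))
    return model


def predict_mask(model: UNet, image: np.ndarray) -> np.ndarray:
    """Binary wall mask for ``image``, resized back to its original shape."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise GastrolayerError("detector input must be a 2-D image")
    scale = getattr(model, "norm_scale", None) or float(image.mean())
    x = _to_net_input(image, model.cfg.input_size, scale)[None, None]
    proba = model.predict_proba(x)[0]
    small = (proba[1] > proba[0]).astype(float)
    back = resize(small, image.shape, order=0, preserve_range=True)
    return (back > 0.5).astype(np.uint8)


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union |A and B| / |A or B| of two binary masks."""
    a = np.asarray(pred).astype(bool)
    b = np.asarray(truth).astype(bool)
    if a.shape != b.shape:
        raise GastrolayerError("masks must have the same shape")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise GastrolayerError("IoU undefined: both masks empty")
    return float(np.logical_and(a, b).sum() / union)


@dataclass(frozen=True)
class ROI:
    """Half-open rectangular bounds of the detected wall region."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def crop(self, image: np.ndarray) -> np.ndarray:
        return image[self.row_min:self.row_max, self.col_min:self.col_max]


def mask_to_roi(mask: np.ndarray, margin: int = 0) -> ROI:
    """Bounding box of the largest connected mask component, plus margin.

    The margin is clipped to the image bounds.  An empty mask means no
    wall was detected.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise NoWallDetectedError("no wall detected")
    labels, n = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    biggest = labels == (1 + int(np.argmax(sizes)))
    rows = np.flatnonzero(biggest.any(axis=1))
    cols = np.flatnonzero(biggest.any(axis=0))
    return ROI(
        row_min=max(0, int(rows[0]) - margin),
        row_max=min(mask.shape[0], int(rows[-1]) + 1 + margin),
        col_min=max(0, int(cols[0]) - margin),
        col_max=min(mask.shape[1], int(cols[-1]) + 1 + margin),
    )
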