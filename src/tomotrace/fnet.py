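"""Dual-decoder semantic segmentation CNN and its data plumbing.

The network is a U-shaped encoder with two concurrent decoders: decoder A
uses classic same-level skip connections; decoder B receives *all* encoder
levels at every stage, resampled to the working resolution and fused by
concatenation + 1x1 convolution. The two decoder outputs are concatenated
and reduced by a single final convolution; a sigmoid yields the per-pixel
foreground probability. A single-decoder variant (decoder A only, identical
encoder) is provided as the ablation baseline.

Images are normalised to [-1, 1] and processed in overlapping patches that
are stitched back by central cropping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mask import VolumeImage
from .nn import Conv2d, EarlyStopping, GroupNorm2d, Module, NAdam, Tensor

__all__ = [
    "FNetConfig", "FNet", "normalize_image", "patchify", "stitch",
    "fnet_forward", "train_fnet", "mask_from_probability", "predict_semantic",
]


@dataclass
class FNetConfig:
    n_levels: int = 5
    base_channels: int = 32
    dims: int = 2
    patch_shape: int = 256
    overlap: int = 32
    learning_rate: float = 1e-4
    patience_epochs: int = 250
    max_epochs: int = 1000
    dual_decoder: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.dims != 2:
            raise ValueError("only 2D patches are supported by this implementation")
        if self.patch_shape % (2 ** (self.n_levels - 1)):
            raise ValueError("patch_shape must be divisible by 2^(n_levels-1)")
        if self.overlap >= self.patch_shape:
            raise ValueError("overlap must be smaller than the patch edge")


def normalize_image(img: VolumeImage) -> VolumeImage:
    """Standardise then rescale to [-1, 1]; a constant image maps to zeros."""
    x = img.data.astype(float)
    std = x.std()
    if std == 0:
        return VolumeImage(np.zeros_like(x), img.pixel_size, "raw")
    x = (x - x.mean()) / std
    lo, hi = x.min(), x.max()
    x = 2.0 * (x - lo) / (hi - lo) - 1.0
    return VolumeImage(x, img.pixel_size, "raw")


def patchify(data: np.ndarray, patch_shape: int, overlap: int):
    """Tile a 2D image into overlapping square patches (zero-padded at the
    edges). Returns (patches, placements); placements are the top-left
    corners, sufficient to invert with :func:`stitch`."""
    if overlap >= patch_shape:
        raise ValueError("overlap must be smaller than the patch edge")
    H, W = data.shape
    stride = patch_shape - overlap
    starts_y = list(range(0, max(H - patch_shape, 0) + 1, stride))
    if starts_y[-1] + patch_shape < H:
        starts_y.append(starts_y[-1] + stride)
    starts_x = list(range(0, max(W - patch_shape, 0) + 1, stride))
    if starts_x[-1] + patch_shape < W:
        starts_x.append(starts_x[-1] + stride)
    patches, placements = [], []
    for y0 in starts_y:
        for x0 in starts_x:
            patch = np.zeros((patch_shape, patch_shape), dtype=float)
            ys, xs = slice(y0, min(y0 + patch_shape, H)), slice(x0, min(x0 + patch_shape, W))
            patch[:ys.stop - ys.start, :xs.stop - xs.start] = data[ys, xs]
            patches.append(patch)
            placements.append((y0, x0))
    return patches, placements


def stitch(patches, placements, image_shape, overlap: int) -> np.ndarray:
    """Reassemble patches by central cropping: away from image borders each
    patch contributes its interior, excluding an overlap/2 margin."""
    H, W = image_shape
    out = np.zeros(image_shape, dtype=float)
    margin = overlap // 2
    ps = patches[0].shape[0]
    for patch, (y0, x0) in zip(patches, placements):
        ty0 = y0 + (margin if y0 > 0 else 0)
        tx0 = x0 + (margin if x0 > 0 else 0)
        ty1 = min(y0 + ps - (margin if y0 + ps < H else 0), H)
        tx1 = min(x0 + ps - (margin if x0 + ps < W else 0), W)
        out[ty0:ty1, tx0:tx1] = patch[ty0 - y0:ty1 - y0, tx0 - x0:tx1 - x0]
    return out


class _ConvBlock(Module):
    """group norm -> conv -> LeakyReLU -> conv -> LeakyReLU"""

    def __init__(self, n_in: int, n_out: int, rng):
        self.norm = GroupNorm2d(n_in)
        self.conv1 = Conv2d(n_in, n_out, 3, rng)
        self.conv2 = Conv2d(n_out, n_out, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm(x)
        x = self.conv1(x).leaky_relu()
        return self.conv2(x).leaky_relu()


def _resample_to(x: Tensor, from_level: int, to_level: int) -> Tensor:
    """Move a feature map between pyramid levels (power-of-two scales)."""
    while from_level < to_level:      # need lower resolution
        x = x.max_pool2d()
        from_level += 1
    while from_level > to_level:      # need higher resolution
        x = x.upsample2x()
        from_level -= 1
    return x


class FNet(Module):
    """Encoder + dual decoder segmentation network (logit output)."""

    def __init__(self, config: FNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        L = config.n_levels
        ch = [config.base_channels * 2 ** i for i in range(L)]
        self.enc = [_ConvBlock(1 if i == 0 else ch[i - 1], ch[i], rng) for i in range(L)]
        # decoder A: classic U with same-level skips
        self.dec_a = [_ConvBlock(ch[i] + ch[i + 1], ch[i], rng) for i in range(L - 1)]
        if config.dual_decoder:
            # decoder B: all encoder levels resampled + previous state, fused 1x1
            self.fuse_b = [Conv2d(sum(ch) + ch[i + 1], ch[i], 1, rng) for i in range(L - 1)]
            self.dec_b = [_ConvBlock(ch[i], ch[i], rng) for i in range(L - 1)]
            self.final = Conv2d(2 * ch[0], 1, 1, rng)
        else:
            self.final = Conv2d(ch[0], 1, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        cfg = self.config
        L = cfg.n_levels
        feats = []
        h = x
        for i, block in enumerate(self.enc):
            h = block(h)
            feats.append(h)
            if i < L - 1:
                h = h.max_pool2d()
        a = feats[-1]
        for i in range(L - 2, -1, -1):
            a = Tensor.concat([feats[i], a.upsample2x()], axis=1)
            a = self.dec_a[i](a)
        if not cfg.dual_decoder:
            return self.final(a)
        b = feats[-1]
        for i in range(L - 2, -1, -1):
            gathered = [_resample_to(feats[j], j, i) for j in range(L)]
            b = Tensor.concat(gathered + [b.upsample2x()], axis=1)
            b = self.dec_b[i](self.fuse_b[i](b).leaky_relu())
        return self.final(Tensor.concat([a, b], axis=1))


def fnet_forward(model: FNet, patch: np.ndarray) -> np.ndarray:
    """Probability map for one patch (shape preserved, values in (0, 1))."""
    patch = np.asarray(patch, dtype=float)
    if patch.shape != (model.config.patch_shape, model.config.patch_shape):
        raise ValueError(
            f"patch shape {patch.shape} does not match config "
            f"({model.config.patch_shape})")
    logits = model(Tensor(patch[None, None]))
    return 1.0 / (1.0 + np.exp(-logits.data[0, 0]))


def _pixel_bce(logits: Tensor, target: np.ndarray) -> Tensor:
    return (logits.softplus() - logits * Tensor(target)).mean()


def train_fnet(train_set, val_set, config: FNetConfig, val_evaluator=None):
    """Train on (image_patch, binary_target_patch) pairs with NAdam and
    per-pixel BCE; early stop on validation-loss patience. Seeded and
    deterministic. Returns (model, history)."""
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    model = FNet(config)
    opt = NAdam(model.parameters(), lr=config.learning_rate)
    stopper = EarlyStopping(config.patience_epochs)
    rng = np.random.default_rng(config.seed)
    history = {"epoch": [], "train_loss": [], "val_loss": []}
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_set))
        losses = []
        for i in order:
            img, target = train_set[i]
            logits = model(Tensor(np.asarray(img, dtype=float)[None, None]))
            loss = _pixel_bce(logits, np.asarray(target, dtype=float)[None, None])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        if val_evaluator is not None:
            val_loss = float(val_evaluator(model))
        elif len(val_set):
            vlosses = []
            for img, target in val_set:
                logits = model(Tensor(np.asarray(img, dtype=float)[None, None]))
                vlosses.append(float(_pixel_bce(logits, np.asarray(target, dtype=float)[None, None]).data))
            val_loss = float(np.mean(vlosses))
        else:
            val_loss = float(np.mean(losses))
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        if stopper.update(val_loss):
            break
    return model, history


def mask_from_probability(probmap: VolumeImage | np.ndarray,
                          threshold: float = 0.5) -> VolumeImage:
    """Binary mask: 1 where probability > threshold."""
    if isinstance(probmap, VolumeImage):
        data, px = probmap.data, probmap.pixel_size
    else:
        data, px = np.asarray(probmap), 1.0
    return VolumeImage((data > threshold).astype(np.uint8), px, "binary")


def predict_semantic(model: FNet, img: VolumeImage) -> VolumeImage:
    """Full-image semantic probability map: normalise, patch, predict,
    stitch."""
    norm = normalize_image(img)
    cfg = model.config
    patches, placements = patchify(norm.data, cfg.patch_shape, cfg.overlap)
    probs = [fnet_forward(model, p) for p in patches]
    full = stitch(probs, placements, norm.data.shape, cfg.overlap)
    return VolumeImage(np.clip(full, 0.0, 1.0), img.pixel_size, "probability")
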