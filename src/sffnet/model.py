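"""Strided feature-fusion residual network (SFFNet) for 2-class lesion MRI.

The architecture is a ResNet101-style bottleneck backbone with three
modifications aimed at small-lesion texture classification:

* **CBAM** (convolutional block attention module) inserted in the stem,
  after conv1 -> BatchNorm -> ReLU and before max-pooling: sequential
  channel attention (shared two-layer bottleneck over average- and
  max-pooled descriptors) followed by spatial attention (a k x k
  convolution over the channelwise mean and max maps).
* **SRB** ("stationary residual block"): a bottleneck residual unit with
  normalization and activation moved *before* the first 1x1 convolution and
  the batch norm after the last 1x1 convolution removed, so consecutive
  stages do not stack redundant normalizations.
* **MFF** (multilayer feature fusion): the stem output X0 (S/2 resolution),
  the first-stage output X3 (S/4) and the last-stage output X6 (S/32) are
  fused by bilinear upsampling X3 twice and X6 sixteen times onto X0's grid
  and concatenating along channels:

      FL  = concat(X0, up2(X3))
      Ffu = concat(FL, up16(X6))

  The classifier is global average pooling over Ffu followed by a single
  fully connected layer.  Because the spatial mean of a concatenation is
  the concatenation of spatial means, the head pools each constituent map
  separately (the mean of an upsampled map is an exact linear functional of
  the source map), which avoids materializing Ffu during training.

For a 224x224 input with the default widths the named maps are
X0: B x 64 x 112 x 112, X3: B x 256 x 56 x 56, X6: B x 2048 x 7 x 7,
FL: B x 320 x 112 x 112, Ffu: B x 2368 x 112 x 112.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "SFFNetConfig",
    "FeatureMaps",
    "CBAM",
    "SRBlock",
    "SFFNet",
    "mff_fuse",
    "sffnet_forward",
    "load_pretrained",
    "save_checkpoint",
]


@dataclass
class SFFNetConfig:
    """Architecture hyperparameters.

    ``stage_block_counts`` (3, 4, 23, 3) gives the 101-layer backbone;
    the ``reduced`` preset (1, 1, 1, 1) keeps every resolution and width but
    one block per stage, sized for CPU-scale experiments.
    """

    stage_block_counts: tuple[int, int, int, int] = (3, 4, 23, 3)
    stem_channels: int = 64
    stage_out_channels: tuple[int, int, int, int] = (256, 512, 1024, 2048)
    num_classes: int = 2
    cbam_reduction: int = 16
    cbam_spatial_kernel: int = 7
    input_channels: int = 1
    input_size: int = 224
    init_seed: int = 0
    pretrained_weights: str | None = None

    def __post_init__(self):
        if any(n < 1 for n in self.stage_block_counts):
            raise ValueError("stage block counts must all be >= 1")
        if self.stem_channels % self.cbam_reduction != 0:
            raise ValueError(
                f"cbam_reduction {self.cbam_reduction} must divide "
                f"stem_channels {self.stem_channels}"
            )
        if self.cbam_spatial_kernel % 2 != 1:
            raise ValueError("cbam_spatial_kernel must be odd")
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be a multiple of 32")

    @classmethod
    def preset(cls, name: str, **overrides) -> "SFFNetConfig":
        presets = {
            "full": dict(stage_block_counts=(3, 4, 23, 3)),
            "reduced": dict(stage_block_counts=(1, 1, 1, 1)),
        }
        if name not in presets:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
        kwargs = dict(presets[name])
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class FeatureMaps:
    """Named intermediate maps of one forward pass (NumPy arrays)."""

    x0: np.ndarray
    x3: np.ndarray
    x6: np.ndarray
    fl: np.ndarray
    ffu: np.ndarray


class CBAM(nn.Module):
    """Sequential channel-then-spatial attention; shape preserving."""

    def __init__(self, channels: int, reduction: int, spatial_kernel: int, rng):
        super().__init__()
        if channels % reduction != 0:
            raise ValueError(f"reduction {reduction} does not divide {channels} channels")
        self.fc1 = nn.Linear(channels, channels // reduction, rng=rng)
        self.fc2 = nn.Linear(channels // reduction, channels, rng=rng)
        self.spatial_conv = nn.Conv2d(
            2, 1, spatial_kernel, stride=1, pad=(spatial_kernel - 1) // 2, bias=True, rng=rng
        )

    def _mlp(self, desc: Tensor) -> Tensor:
        return self.fc2(self.fc1(desc).relu())

    def channel_gate(self, x: Tensor) -> Tensor:
        avg = nn.global_avg_pool(x)
        mx = x.amax(axis=(2, 3))
        b, c = avg.shape
        return (self._mlp(avg) + self._mlp(mx)).sigmoid().reshape(b, c, 1, 1)

    def spatial_gate(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.amax(axis=1, keepdims=True)
        return self.spatial_conv(nn.concat([avg, mx], axis=1)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        x = x * self.channel_gate(x)
        return x * self.spatial_gate(x)


class SRBlock(nn.Module):
    """Pre-activation bottleneck residual block without a trailing norm.

    Branch: BN -> ReLU -> 1x1 (mid) -> BN -> ReLU -> 3x3 (mid, stride)
    -> BN -> ReLU -> 1x1 (out), with no batch norm after the last conv.
    Shortcut: identity when shapes match, else strided 1x1 projection + BN.
    """

    def __init__(self, in_ch: int, mid_ch: int, out_ch: int, stride: int, rng):
        super().__init__()
        self.in_ch = in_ch
        self.bn1 = nn.BatchNorm2d(in_ch)
        self.conv1 = nn.Conv2d(in_ch, mid_ch, 1, rng=rng)
        self.bn2 = nn.BatchNorm2d(mid_ch)
        self.conv2 = nn.Conv2d(mid_ch, mid_ch, 3, stride=stride, pad=1, rng=rng)
        self.bn3 = nn.BatchNorm2d(mid_ch)
        self.conv3 = nn.Conv2d(mid_ch, out_ch, 1, rng=rng)
        if stride != 1 or in_ch != out_ch:
            self.shortcut_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng)
            self.shortcut_bn = nn.BatchNorm2d(out_ch)
        else:
            self.shortcut_conv = None
            self.shortcut_bn = None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"block expects {self.in_ch} channels, got {x.shape[1]}")
        h = self.bn1(x).relu()
        h = self.conv1(h)
        h = self.bn2(h).relu()
        h = self.conv2(h)
        h = self.bn3(h).relu()
        h = self.conv3(h)
        if self.shortcut_conv is not None:
            sc = self.shortcut_bn(self.shortcut_conv(x))
        else:
            sc = x
        return h + sc


def mff_fuse(x0: Tensor | np.ndarray, x3: Tensor | np.ndarray, x6: Tensor | np.ndarray):
    """Fuse shallow/middle/deep maps onto the shallow grid.

    Returns ``(fl, ffu)`` where ``fl = concat(x0, up2(x3))`` and
    ``ffu = concat(fl, up16(x6))``.  Raises when the spatial ratios are not
    exactly 2 (x0 : x3) and 16 (x0 : x6).
    """
    x0 = x0 if isinstance(x0, Tensor) else Tensor(x0)
    x3 = x3 if isinstance(x3, Tensor) else Tensor(x3)
    x6 = x6 if isinstance(x6, Tensor) else Tensor(x6)
    h0, h3, h6 = x0.shape[2], x3.shape[2], x6.shape[2]
    w0, w3, w6 = x0.shape[3], x3.shape[3], x6.shape[3]
    if (h0, w0) != (2 * h3, 2 * w3):
        raise ValueError(
            f"mff_fuse: x0 grid {h0}x{w0} must be exactly 2x the x3 grid {h3}x{w3}"
        )
    if (h0, w0) != (16 * h6, 16 * w6):
        raise ValueError(
            f"mff_fuse: x0 grid {h0}x{w0} must be exactly 16x the x6 grid {h6}x{w6}"
        )
    fl = nn.concat([x0, nn.upsample_bilinear(x3, 2)], axis=1)
    ffu = nn.concat([fl, nn.upsample_bilinear(x6, 16)], axis=1)
    return fl, ffu


class SFFNet(nn.Module):
    def __init__(self, config: SFFNetConfig | None = None):
        super().__init__()
        cfg = config or SFFNetConfig()
        self.config = cfg
        rng = np.random.default_rng(cfg.init_seed)

        self.stem_conv = nn.Conv2d(cfg.input_channels, cfg.stem_channels, 7, stride=2, pad=3, rng=rng)
        self.stem_bn = nn.BatchNorm2d(cfg.stem_channels)
        self.cbam = CBAM(cfg.stem_channels, cfg.cbam_reduction, cfg.cbam_spatial_kernel, rng)

        stages = []
        in_ch = cfg.stem_channels
        for stage_idx, (n_blocks, out_ch) in enumerate(
            zip(cfg.stage_block_counts, cfg.stage_out_channels)
        ):
            mid_ch = out_ch // 4
            blocks = nn.ModuleList()
            for b in range(n_blocks):
                stride = 2 if (stage_idx > 0 and b == 0) else 1
                blocks.append(SRBlock(in_ch, mid_ch, out_ch, stride, rng))
                in_ch = out_ch
            stages.append(blocks)
        self.stage1, self.stage2, self.stage3, self.stage4 = stages

        fused_ch = cfg.stem_channels + cfg.stage_out_channels[0] + cfg.stage_out_channels[3]
        self.fused_channels = fused_ch
        self.fc = nn.Linear(fused_ch, cfg.num_classes, rng=rng)
        self.fc.bias.data[...] = 0.0

    # -- pieces -----------------------------------------------------------
    def stem_forward(self, x: Tensor) -> Tensor:
        size = self.config.input_size
        if x.shape[2] != size or x.shape[3] != size:
            raise ValueError(
                f"expected {size}x{size} input, got {x.shape[2]}x{x.shape[3]}"
            )
        if x.shape[1] != self.config.input_channels:
            raise ValueError(
                f"expected {self.config.input_channels} input channel(s), got {x.shape[1]}"
            )
        h = self.stem_bn(self.stem_conv(x)).relu()
        return self.cbam(h)

    def backbone_features(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        x0 = self.stem_forward(x)
        h = nn.max_pool2d(x0, kernel=3, stride=2, pad=1)
        for blk in self.stage1:
            h = blk(h)
        x3 = h
        for blk in self.stage2:
            h = blk(h)
        for blk in self.stage3:
            h = blk(h)
        for blk in self.stage4:
            h = blk(h)
        return x0, x3, h

    def forward(self, x: Tensor) -> Tensor:
        """Logits via the pooled-fusion head (Ffu never materialized)."""
        x0, x3, x6 = self.backbone_features(x)
        pooled = nn.concat(
            [
                nn.global_avg_pool(x0),
                nn.global_avg_pool_upsampled(x3, 2),
                nn.global_avg_pool_upsampled(x6, 16),
            ],
            axis=1,
        )
        return self.fc(pooled)

    def summary(self) -> str:
        """Plain-text architecture summary with per-part parameter counts."""
        cfg = self.config
        s = cfg.input_size
        parts = [
            ("stem (conv7x7/s2 + BN + CBAM)", [self.stem_conv, self.stem_bn, self.cbam]),
            ("stage1 (conv2_x)", list(self.stage1)),
            ("stage2 (conv3_x)", list(self.stage2)),
            ("stage3 (conv4_x)", list(self.stage3)),
            ("stage4 (conv5_x)", list(self.stage4)),
            ("head (fused GAP + fc)", [self.fc]),
        ]
        lines = [
            f"SFFNet(blocks={cfg.stage_block_counts}, input={cfg.input_channels}"
            f"x{s}x{s}, classes={cfg.num_classes})",
            f"  X0: {cfg.stem_channels}@{s // 2}  X3: {cfg.stage_out_channels[0]}"
            f"@{s // 4}  X6: {cfg.stage_out_channels[3]}@{s // 32}"
            f"  Ffu: {self.fused_channels}@{s // 2}",
        ]
        for name, mods in parts:
            count = sum(p.data.size for m in mods for p in m.parameters())
            lines.append(f"  {name}: {count:,} params")
        lines.append(f"  total: {self.num_parameters():,} params")
        return "\n".join(lines)

    def predict_proba(self, images: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Eval-mode class probabilities for a stack of images (N,C,S,S)."""
        was_training = self.training
        self.eval()
        out = []
        for lo in range(0, len(images), batch_size):
            logits = self.forward(Tensor(images[lo : lo + batch_size]))
            out.append(nn.softmax(logits.data))
        self.train(was_training)
        return np.concatenate(out, axis=0)


def sffnet_forward(model: SFFNet, images: np.ndarray) -> tuple[np.ndarray, FeatureMaps]:
    """Eval-mode forward pass that also materializes all named feature maps.

    Returns logits (B x num_classes) and the full :class:`FeatureMaps`,
    including the fused maps FL and Ffu.  Use small batches: Ffu is large.
    """
    was_training = model.training
    model.eval()
    try:
        x = Tensor(np.asarray(images, dtype=np.float32))
        x0, x3, x6 = model.backbone_features(x)
        fl, ffu = mff_fuse(x0, x3, x6)
        pooled = nn.concat(
            [
                nn.global_avg_pool(x0),
                nn.global_avg_pool_upsampled(x3, 2),
                nn.global_avg_pool_upsampled(x6, 16),
            ],
            axis=1,
        )
        logits = model.fc(pooled)
    finally:
        model.train(was_training)
    return logits.data, FeatureMaps(x0.data, x3.data, x6.data, fl.data, ffu.data)


def save_checkpoint(model: SFFNet, path: str | Path) -> None:
    np.savez(path, **model.state_dict())


def load_pretrained(model: SFFNet, weights_path: str | Path, strict: bool = False) -> dict:
    """Copy tensors from an ``.npz`` checkpoint into the model by name.

    Tensors are copied when both the name and the shape match.  A stem conv
    saved with 3 input channels is averaged down to a single channel when
    the model is single-channel (and replicated when going the other way),
    so ImageNet-style weights can seed a grayscale model.  Returns a report
    dict with ``matched``, ``skipped`` (name or shape mismatch on the
    checkpoint side) and ``missing`` (model tensors the file lacks).
    In strict mode any skipped or missing tensor raises.
    """
    with np.load(weights_path) as data:
        ckpt = {k: data[k] for k in data.files}
    own = dict(model.named_parameters())
    bufs = dict(model.named_buffers())
    matched, skipped = [], []
    for name, arr in ckpt.items():
        target = own.get(name)
        tdata = target.data if target is not None else bufs.get(name)
        if tdata is None:
            skipped.append(name)
            continue
        if arr.shape != tdata.shape:
            adapted = _adapt_stem(arr, tdata.shape)
            if adapted is None:
                skipped.append(name)
                continue
            arr = adapted
        tdata[...] = arr
        matched.append(name)
    missing = [n for n in list(own) + list(bufs) if n not in matched]
    report = {"matched": matched, "skipped": skipped, "missing": missing}
    if strict and (skipped or missing):
        raise ValueError(
            f"strict checkpoint load failed; skipped={skipped} missing={missing}"
        )
    return report


def _adapt_stem(arr: np.ndarray, target_shape: tuple[int, ...]) -> np.ndarray | None:
    """Adapt a conv weight across input-channel counts (1 <-> 3)."""
    if arr.ndim != 4 or len(target_shape) != 4:
        return None
    if arr.shape[0] != target_shape[0] or arr.shape[2:] != tuple(target_shape[2:]):
        return None
    if arr.shape[1] == 3 and target_shape[1] == 1:
        return arr.mean(axis=1, keepdims=True)
    if arr.shape[1] == 1 and target_shape[1] == 3:
        return np.repeat(arr, 3, axis=1) / 3.0
    return None
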