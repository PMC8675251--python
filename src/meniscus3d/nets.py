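"""Volumetric encoder architectures and MLP heads.

Two encoders are provided, both 3D translations of residual image
classifiers:

* ``ResNet50-3D`` — 7x7x7 stem (stride 2), 3x3x3 max-pool (stride 2), then
  16 bottleneck blocks in four groups of 3, 4, 6 and 3 with group strides
  (1, 2, 2, 2); global average pooling yields 2048·width features.  Total
  spatial downsampling factor 32.
* ``DRN-C-26-3D`` — a dilated residual network: the max-pool is replaced by
  two residual basic blocks, the last two residual groups trade stride for
  dilation (2 and 4), and two final non-residual blocks with decreasing
  dilation (2, 1) remove gridding artefacts; global average pooling yields
  512·width features.  Total downsampling factor 8, which preserves detail
  in small cropped inputs.

Every convolution is followed by batch normalisation and (except where a
residual sum intervenes) a ReLU.  A ``width_multiplier`` scales all channel
counts while preserving the block structure, so a quarter-width model is an
architecturally faithful miniature of the full-scale network.

Heads are three-layer MLPs (in -> hidden -> hidden -> out) with dropout on
the hidden activations; their outputs are raw logits / box coordinates, with
sigmoid applied by the assembled model.

For strongly anisotropic inputs a per-axis stride guard drops a stage's
stride to 1 on any axis whose extent has already collapsed to a single
voxel, so thin-slab volumes remain processable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor

__all__ = [
    "EncoderConfig", "HeadConfig", "build_resnet50_3d", "build_drn_c26_3d",
    "build_head", "assemble_model", "MultiTaskModel",
    "RESNET50_GROUP_SIZES", "DRN_C26_LEVELS",
]

#: bottleneck blocks per group (He et al. ResNet-50 layout)
RESNET50_GROUP_SIZES = (3, 4, 6, 3)

#: DRN-C-26 level table translated to 3D: (base channels, number of blocks,
#: stride of the first block, dilation, residual connections used)
DRN_C26_LEVELS = (
    (16, 1, 1, 1, True),    # replaces max-pool (1/2)
    (32, 1, 2, 1, True),    # replaces max-pool (2/2)
    (64, 2, 2, 1, True),
    (128, 2, 2, 1, True),
    (256, 2, 1, 2, True),   # stride replaced by dilation
    (512, 2, 1, 4, True),
    (512, 1, 1, 2, False),  # de-gridding blocks
    (512, 1, 1, 1, False),
)


@dataclass
class EncoderConfig:
    kind: str = "resnet50"                    # "resnet50" | "drn_c_26"
    width_multiplier: float = 1.0
    input_shape: tuple = (32, 64, 64)         # (slices, rows, cols)

    def __post_init__(self):
        if self.kind not in ("resnet50", "drn_c_26"):
            raise ValueError(f"unknown encoder kind {self.kind!r}")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        if len(self.input_shape) != 3:
            raise ValueError("input_shape must be a triple")

    def scaled(self, base: int) -> int:
        return max(1, int(round(base * self.width_multiplier)))


@dataclass
class HeadConfig:
    in_features: int
    hidden_units: int = 2048
    out_units: int = 6
    dropout: float = 0.3

    def __post_init__(self):
        if self.out_units not in (6, 12):
            raise ValueError("out_units must be 6 (classifier) or 12 (box head)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def _guarded_stride(size: tuple, want: int) -> tuple:
    """Per-axis stride: keep `want` only on axes that can still shrink."""
    return tuple(want if s >= 2 else 1 for s in size)


def _conv_out(size: tuple, k: int, stride: tuple, p: int, d: int = 1) -> tuple:
    return tuple((s + 2 * p - (k - 1) * d - 1) // st + 1 for s, st in zip(size, stride))


class Bottleneck(nn.Module):
    """1x1x1 reduce -> 3x3x3 -> 1x1x1 expand (x4), with residual connection."""

    expansion = 4

    def __init__(self, in_ch: int, mid_ch: int, stride: tuple, rng):
        super().__init__()
        out_ch = mid_ch * self.expansion
        self.conv1 = nn.Conv3d(in_ch, mid_ch, 1, rng=rng)
        self.bn1 = nn.BatchNorm3d(mid_ch)
        self.conv2 = nn.Conv3d(mid_ch, mid_ch, 3, stride=stride, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm3d(mid_ch)
        self.conv3 = nn.Conv3d(mid_ch, out_ch, 1, rng=rng)
        self.bn3 = nn.BatchNorm3d(out_ch)
        self.relu = nn.ReLU()
        if in_ch != out_ch or any(s != 1 for s in stride):
            self.down_conv = nn.Conv3d(in_ch, out_ch, 1, stride=stride, rng=rng)
            self.down_bn = nn.BatchNorm3d(out_ch)
        else:
            self.down_conv = None
        self.out_channels = out_ch

    def forward(self, x):
        y = self.relu(self.bn1(self.conv1(x)))
        y = self.relu(self.bn2(self.conv2(y)))
        y = self.bn3(self.conv3(y))
        sc = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return self.relu(y + sc)


class BasicBlock(nn.Module):
    """Two 3x3x3 convolutions, optionally dilated, optionally residual."""

    def __init__(self, in_ch: int, out_ch: int, stride: tuple, dilation: int,
                 residual: bool, rng):
        super().__init__()
        self.conv1 = nn.Conv3d(in_ch, out_ch, 3, stride=stride,
                               padding=dilation, dilation=dilation, rng=rng)
        self.bn1 = nn.BatchNorm3d(out_ch)
        self.conv2 = nn.Conv3d(out_ch, out_ch, 3, padding=dilation,
                               dilation=dilation, rng=rng)
        self.bn2 = nn.BatchNorm3d(out_ch)
        self.relu = nn.ReLU()
        self.residual = residual
        if residual and (in_ch != out_ch or any(s != 1 for s in stride)):
            self.down_conv = nn.Conv3d(in_ch, out_ch, 1, stride=stride, rng=rng)
            self.down_bn = nn.BatchNorm3d(out_ch)
        else:
            self.down_conv = None
        self.out_channels = out_ch

    def forward(self, x):
        y = self.relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        if self.residual:
            sc = x if self.down_conv is None else self.down_bn(self.down_conv(x))
            y = y + sc
        return self.relu(y)


class _Encoder(nn.Module):
    """Stem + block stack + global average pooling."""

    def __init__(self):
        super().__init__()
        self.feature_length = None  # set by builders

    def forward(self, x):
        x = self.stem_relu(self.stem_bn(self.stem(x)))
        if getattr(self, "pool", None) is not None:
            x = self.pool(x)
        x = self.blocks(x)
        return self.gap(x)


def build_resnet50_3d(cfg: EncoderConfig, rng: np.random.Generator | None = None) -> _Encoder:
    """ResNet-50 translated to 3D; returns an encoder ending in GAP features."""
    if cfg.kind != "resnet50":
        raise ValueError("config kind must be 'resnet50'")
    rng = rng if rng is not None else np.random.default_rng(0)
    enc = _Encoder()
    size = tuple(cfg.input_shape)
    stem_ch = cfg.scaled(64)
    stride = _guarded_stride(size, 2)
    enc.stem = nn.Conv3d(1, stem_ch, 7, stride=stride, padding=3, rng=rng)
    enc.stem_bn = nn.BatchNorm3d(stem_ch)
    enc.stem_relu = nn.ReLU()
    size = _conv_out(size, 7, stride, 3)
    stride = _guarded_stride(size, 2)
    enc.pool = nn.MaxPool3d(3, stride=stride, padding=1)
    size = _conv_out(size, 3, stride, 1)
    blocks = nn.ModuleList()
    in_ch = stem_ch
    for gi, n_blocks in enumerate(RESNET50_GROUP_SIZES):
        mid = cfg.scaled(64 * 2 ** gi)
        for bi in range(n_blocks):
            if bi == 0 and gi > 0:
                stride = _guarded_stride(size, 2)
                size = _conv_out(size, 3, stride, 1)
            else:
                stride = (1, 1, 1)
            block = Bottleneck(in_ch, mid, stride, rng)
            blocks.append(block)
            in_ch = block.out_channels
    enc.blocks = blocks
    enc.gap = nn.GlobalAvgPool3d()
    enc.feature_length = in_ch
    enc.output_size = size
    enc.downsample_factor = 32
    if min(size) < 1:
        raise ValueError(f"input_shape {cfg.input_shape} too small for ResNet50-3D")
    return enc


def build_drn_c26_3d(cfg: EncoderConfig, rng: np.random.Generator | None = None) -> _Encoder:
    """Dilated residual network DRN-C-26 translated to 3D."""
    if cfg.kind != "drn_c_26":
        raise ValueError("config kind must be 'drn_c_26'")
    rng = rng if rng is not None else np.random.default_rng(0)
    enc = _Encoder()
    size = tuple(cfg.input_shape)
    stem_ch = cfg.scaled(16)
    enc.stem = nn.Conv3d(1, stem_ch, 7, stride=1, padding=3, rng=rng)
    enc.stem_bn = nn.BatchNorm3d(stem_ch)
    enc.stem_relu = nn.ReLU()
    enc.pool = None
    blocks = nn.ModuleList()
    in_ch = stem_ch
    for base_ch, n_blocks, want_stride, dilation, residual in DRN_C26_LEVELS:
        out_ch = cfg.scaled(base_ch)
        for bi in range(n_blocks):
            if bi == 0 and want_stride > 1:
                stride = _guarded_stride(size, want_stride)
                size = _conv_out(size, 3, stride, dilation, dilation)
            else:
                stride = (1, 1, 1)
            block = BasicBlock(in_ch, out_ch, stride, dilation, residual, rng)
            blocks.append(block)
            in_ch = out_ch
    enc.blocks = blocks
    enc.gap = nn.GlobalAvgPool3d()
    enc.feature_length = in_ch
    enc.output_size = size
    enc.downsample_factor = 8
    if min(size) < 1:
        raise ValueError(f"input_shape {cfg.input_shape} too small for DRN-C-26-3D")
    return enc


def build_head(cfg: HeadConfig, rng: np.random.Generator | None = None) -> nn.Module:
    """Three-layer MLP head; outputs raw logits / coordinates (no activation).

    Hidden layers use He initialisation; the output layer starts near zero
    (He scaled by 1e-2) so initial probabilities sit at 0.5 and initial box
    predictions at the grid center — keeps the sigmoids out of saturation
    at the start of training.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    drop_rng = np.random.default_rng(rng.integers(2 ** 31))
    out_layer = nn.Linear(cfg.hidden_units, cfg.out_units, rng)
    out_layer.weight.data *= 0.01
    return nn.Sequential(
        nn.Linear(cfg.in_features, cfg.hidden_units, rng),
        nn.ReLU(),
        nn.Dropout(cfg.dropout, np.random.default_rng(drop_rng.integers(2 ** 31))),
        nn.Linear(cfg.hidden_units, cfg.hidden_units, rng),
        nn.ReLU(),
        nn.Dropout(cfg.dropout, np.random.default_rng(drop_rng.integers(2 ** 31))),
        out_layer,
    )


_APPROACH_ENCODER = {"full_scale": "resnet50", "bb_crop": "drn_c_26", "bb_loss": "resnet50"}


class MultiTaskModel(nn.Module):
    """Encoder + classifier head (+ optional box-regression head).

    ``forward`` returns sigmoid tear probabilities, and for the multi-task
    variant additionally the twelve sigmoid-squashed relative box values
    (medial box first, lateral second).
    """

    def __init__(self, approach: str, encoder: _Encoder, cls_head: nn.Module,
                 box_head: nn.Module | None = None):
        super().__init__()
        self.approach = approach
        self.encoder = encoder
        self.cls_head = cls_head
        self.box_head = box_head

    def features(self, x: Tensor) -> Tensor:
        return self.encoder(x)

    def logits(self, x: Tensor):
        feats = self.features(x)
        cls = self.cls_head(feats)
        if self.box_head is not None:
            return cls, self.box_head(feats)
        return cls

    def forward(self, x: Tensor):
        out = self.logits(x)
        if self.box_head is not None:
            cls, box = out
            return cls.sigmoid(), box.sigmoid()
        return out.sigmoid()


def assemble_model(approach: str, encoder_cfg: EncoderConfig,
                   head_cfgs: list[HeadConfig] | None = None,
                   seed: int = 0) -> MultiTaskModel:
    """Build the model for one of the three detection approaches."""
    if approach not in _APPROACH_ENCODER:
        raise ValueError(f"unknown approach {approach!r}")
    if encoder_cfg.kind != _APPROACH_ENCODER[approach]:
        raise ValueError(
            f"approach {approach!r} requires encoder {_APPROACH_ENCODER[approach]!r}, "
            f"got {encoder_cfg.kind!r}")
    rng = np.random.default_rng(seed)
    if encoder_cfg.kind == "resnet50":
        encoder = build_resnet50_3d(encoder_cfg, rng)
    else:
        encoder = build_drn_c26_3d(encoder_cfg, rng)
    n_feat = encoder.feature_length
    if head_cfgs is None:
        head_cfgs = [HeadConfig(in_features=n_feat, out_units=6)]
        if approach == "bb_loss":
            head_cfgs.append(HeadConfig(in_features=n_feat, out_units=12))
    expected_heads = 2 if approach == "bb_loss" else 1
    if len(head_cfgs) != expected_heads:
        raise ValueError(f"approach {approach!r} needs {expected_heads} head(s)")
    for hc in head_cfgs:
        if hc.in_features != n_feat:
            raise ValueError(
                f"head in_features {hc.in_features} != encoder features {n_feat}")
    cls_head = build_head(head_cfgs[0], rng)
    box_head = build_head(head_cfgs[1], rng) if approach == "bb_loss" else None
    if head_cfgs[0].out_units != 6 or (box_head is not None and head_cfgs[1].out_units != 12):
        raise ValueError("classifier head must have 6 outputs, box head 12")
    return MultiTaskModel(approach, encoder, cls_head, box_head)
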