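"""Parallel CNN + transformer encoder with per-stage information exchange.

The CNN branch is a ResNet50 topology (bottleneck residual blocks, stage
depths 3-4-6-3, strides 4/8/16/32, output channels 256/512/1024/2048 at full
width). The transformer branch runs at the same four strides: its stem is two
Focus slicing embeddings (stride 4 total), and each stage applies one or more
blocks of ``t + SGA(LN(t))`` -> SE channel gating -> ``t + MLP(LN(t))``,
operating on 2-D feature maps throughout (SGA is a spatial-group gate, so no
token flattening is needed).

At every stage the same-resolution CNN features are projected (1x1 conv) and
added into the transformer input; in ``bidirectional`` fusion mode the
transformer features are projected back and added into the CNN stream before
its next stage. Per stage a fused skip ``conv1x1(concat(cnn, proj(trans)))``
is produced for the decoder. Spatial grids of the two branches are asserted
identical at every fusion point — never silently resampled.

Channel widths scale with ``width_multiplier`` for CPU-scale work; the
default multiplier 1.0 is the full model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .attention_blocks import SpatialGroupAttention, SqueezeExcitation
from .focus_embedding import FocusEmbed
from .nn import Tensor

__all__ = ["EncoderConfig", "StageFeatures", "CNNBranch", "TransformerBlock", "DualEncoder"]

_STAGE_DEPTHS = (3, 4, 6, 3)  # ResNet50
_STAGE_PLANES = (64, 128, 256, 512)
_EXPANSION = 4


@dataclass
class EncoderConfig:
    backbone: str = "resnet50"
    pretrained: bool = False
    trans_channels: tuple[int, ...] = (64, 128, 256, 512)
    sga_groups: int = 8
    se_reduction: int = 16
    fusion_mode: str = "bidirectional"  # or "cnn_to_trans"
    width_multiplier: float = 1.0
    mlp_ratio: float = 4.0
    blocks_per_stage: int = 1
    skip_channels: tuple[int, ...] = (64, 128, 256, 512)
    sga_eps: float = 1e-5

    def __post_init__(self):
        if self.backbone != "resnet50":
            raise ValueError(f"unsupported backbone {self.backbone!r}")
        if self.fusion_mode not in ("bidirectional", "cnn_to_trans"):
            raise ValueError(f"unknown fusion mode {self.fusion_mode!r}")
        if self.pretrained:
            raise ValueError(
                "pretrained backbone weights are not bundled; build with pretrained=False"
            )
        if len(self.trans_channels) != 4 or len(self.skip_channels) != 4:
            raise ValueError("both branches use exactly 4 stages")

    def scaled(self, channels: tuple[int, ...]) -> tuple[int, ...]:
        return tuple(int(round(c * self.width_multiplier)) for c in channels)

    @property
    def cnn_channels(self) -> tuple[int, ...]:
        return self.scaled(tuple(p * _EXPANSION for p in _STAGE_PLANES))


@dataclass
class StageFeatures:
    """Per-stage outputs of the encoder at strides 4, 8, 16, 32."""

    cnn: list = field(default_factory=list)
    trans: list = field(default_factory=list)
    fused_skips: list = field(default_factory=list)


def _conv_bn(cin: int, cout: int, k: int, stride: int = 1, dilation: int = 1) -> nn.Sequential:
    pad = dilation * (k - 1) // 2
    return nn.Sequential(
        nn.Conv2d(cin, cout, k, stride=stride, padding=pad, dilation=dilation, bias=False),
        nn.BatchNorm2d(cout),
    )


class Bottleneck(nn.Module):
    def __init__(self, cin: int, planes: int, stride: int = 1):
        super().__init__()
        cout = planes * _EXPANSION
        self.conv1 = _conv_bn(cin, planes, 1)
        self.conv2 = _conv_bn(planes, planes, 3, stride=stride)
        self.conv3 = _conv_bn(planes, cout, 1)
        self.downsample = _conv_bn(cin, cout, 1, stride=stride) if (stride != 1 or cin != cout) else None

    def forward(self, x: Tensor) -> Tensor:
        identity = self.downsample(x) if self.downsample is not None else x
        out = self.conv1(x).relu()
        out = self.conv2(out).relu()
        out = self.conv3(out)
        return (out + identity).relu()


class CNNBranch(nn.Module):
    """ResNet50-topology feature extractor exposing stem and per-stage forward."""

    def __init__(self, cfg: EncoderConfig, in_channels: int = 3):
        super().__init__()
        w = cfg.width_multiplier
        stem_ch = int(round(64 * w))
        self.stem_conv = _conv_bn(in_channels, stem_ch, 7, stride=2)
        self.pool = nn.MaxPool2d(3, 2, 1)
        self.stages = nn.ModuleList()
        self.stage_channels: list[int] = []
        cin = stem_ch
        for i, (depth, planes) in enumerate(zip(_STAGE_DEPTHS, _STAGE_PLANES)):
            planes = int(round(planes * w))
            blocks = [Bottleneck(cin, planes, stride=1 if i == 0 else 2)]
            cin = planes * _EXPANSION
            blocks += [Bottleneck(cin, planes) for _ in range(depth - 1)]
            self.stages.append(nn.Sequential(*blocks))
            self.stage_channels.append(cin)

    def stem(self, x: Tensor) -> Tensor:
        return self.pool(self.stem_conv(x).relu())

    def forward_stage(self, x: Tensor, stage_index: int) -> Tensor:
        if not 0 <= stage_index <= 3:
            raise ValueError(f"stage_index {stage_index} outside 0..3")
        stage = self.stages[stage_index]
        expected = stage.layers[0].conv1.layers[0].in_channels
        if x.shape[1] != expected:
            raise ValueError(f"stage {stage_index} expects {expected} channels, got {x.shape[1]}")
        return stage(x)

    def forward(self, x: Tensor) -> list[Tensor]:
        feats = []
        h = self.stem(x)
        for i in range(4):
            h = self.forward_stage(h, i)
            feats.append(h)
        return feats


class TransformerBlock(nn.Module):
    """Pre-norm block: t + SGA(LN(t)), then SE gating, then t + MLP(LN(t))."""

    def __init__(self, channels: int, cfg: EncoderConfig):
        super().__init__()
        self.norm1 = nn.ChannelLayerNorm(channels)
        self.attn = SpatialGroupAttention(cfg.sga_groups, cfg.sga_eps)
        self.se = SqueezeExcitation(channels, cfg.se_reduction)
        self.norm2 = nn.ChannelLayerNorm(channels)
        hidden = int(round(channels * cfg.mlp_ratio))
        self.mlp = nn.Sequential(
            nn.Conv2d(channels, hidden, 1), nn.ReLU(), nn.Conv2d(hidden, channels, 1)
        )

    def forward(self, t: Tensor) -> Tensor:
        t = t + self.attn(self.norm1(t))
        t = self.se(t)
        return t + self.mlp(self.norm2(t))


def _check_same_grid(a: Tensor, b: Tensor, what: str) -> None:
    if a.shape[2:] != b.shape[2:]:
        raise ValueError(f"{what}: spatial grids differ, {a.shape} vs {b.shape}")


class DualEncoder(nn.Module):
    """Four-stage dual encoder; ``mode`` selects dual / cnn_only / vit_only."""

    def __init__(self, cfg: EncoderConfig, mode: str = "dual", attention_factory=None):
        super().__init__()
        if mode not in ("dual", "cnn_only", "vit_only"):
            raise ValueError(f"unknown encoder mode {mode!r}")
        self.cfg = cfg
        self.mode = mode
        t_ch = cfg.scaled(cfg.trans_channels)
        self.trans_channels = t_ch
        if mode != "vit_only":
            self.cnn = CNNBranch(cfg)
        if mode != "cnn_only":
            self.focus1 = FocusEmbed(3, t_ch[0])
            self.focus2 = FocusEmbed(t_ch[0], t_ch[0])
            self.blocks = nn.ModuleList()
            self.downsamples = nn.ModuleList()
            for i, ch in enumerate(t_ch):
                stage = [TransformerBlock(ch, cfg) for _ in range(cfg.blocks_per_stage)]
                if attention_factory is not None:  # variant hook (e.g. MHA ablation)
                    for blk in stage:
                        blk.attn = attention_factory(ch)
                self.blocks.append(nn.Sequential(*stage))
                if i < 3:
                    self.downsamples.append(FocusEmbed(ch, t_ch[i + 1]))
        if mode == "dual":
            c_ch = self.cnn.stage_channels
            s_ch = cfg.scaled(cfg.skip_channels)
            self.proj_c2t = nn.ModuleList(nn.Conv2d(c, t, 1) for c, t in zip(c_ch, t_ch))
            self.proj_t2c = nn.ModuleList(nn.Conv2d(t, c, 1) for c, t in zip(c_ch, t_ch))
            self.proj_skip = nn.ModuleList(nn.Conv2d(t, t, 1) for t in t_ch)
            self.fuse = nn.ModuleList(
                nn.Conv2d(c + t, s, 1) for c, t, s in zip(c_ch, t_ch, s_ch)
            )
            self.skip_channels = list(s_ch)
        elif mode == "cnn_only":
            self.skip_channels = list(self.cnn.stage_channels)
        else:
            self.skip_channels = list(t_ch)

    # -- per-operation surface --------------------------------------------

    def transformer_stage_forward(self, t_in: Tensor, c_same: Tensor | None, stage: int) -> Tensor:
        if c_same is not None:
            _check_same_grid(t_in, c_same, f"transformer stage {stage}")
            t_in = t_in + self.proj_c2t[stage](c_same)
        return self.blocks[stage](t_in)

    def exchange(self, c: Tensor, t: Tensor, stage: int) -> tuple[Tensor, Tensor]:
        _check_same_grid(c, t, f"exchange at stage {stage}")
        if self.cfg.fusion_mode == "bidirectional":
            c = c + self.proj_t2c[stage](t)
        return c, t

    # -- full encode -------------------------------------------------------

    def forward(self, image: Tensor) -> StageFeatures:
        h, w = image.shape[2:]
        if h % 32 or w % 32:
            raise ValueError(f"input size {h}x{w} must be divisible by 32")
        sf = StageFeatures()
        if self.mode == "cnn_only":
            sf.cnn = self.cnn(image)
            sf.fused_skips = list(sf.cnn)
            return sf
        t = self.focus2(self.focus1(image))
        if self.mode == "vit_only":
            for i in range(4):
                t = self.blocks[i](t)
                sf.trans.append(t)
                if i < 3:
                    t = self.downsamples[i](t)
            sf.fused_skips = list(sf.trans)
            return sf
        c = self.cnn.stem(image)
        for i in range(4):
            c = self.cnn.forward_stage(c, i)
            t = self.transformer_stage_forward(t, c, i)
            c, t = self.exchange(c, t, i)
            sf.cnn.append(c)
            sf.trans.append(t)
            _check_same_grid(c, t, f"skip fusion at stage {i}")
            sf.fused_skips.append(self.fuse[i](nn.concat([c, self.proj_skip[i](t)], axis=1)))
            if i < 3:
                t = self.downsamples[i](t)
        return sf


def encode(image: np.ndarray, encoder: DualEncoder) -> StageFeatures:
    """Convenience wrapper: run the encoder on a raw numpy image batch."""
    return encoder(Tensor(np.asarray(image, dtype=np.float32)))
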