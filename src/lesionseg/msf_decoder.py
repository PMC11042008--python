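"""Multi-scale fusion (ASPP-style) block and the channel-slicing decoder.

The MSF block runs four parallel convolution branches over the same input —
a 1x1 branch (dilation code 0) and 3x3 branches at dilations 3, 6 and 9
(effective receptive fields 7, 13 and 19 pixels), all same-padded —
concatenates them and fuses with a 1x1 convolution, preserving resolution.

The decoder applies MSF at the deepest fused skip, then walks stages 2 -> 0:
bilinear x2 upsampling, channel-slice fusion with that stage's skip, and a
3x3 conv + BN + ReLU. Channel-slice fusion splits both inputs into two
contiguous channel halves and interleaves them (skip_A, up_A, skip_B, up_B)
before a 1x1 fusing conv, so features with different receptive fields mix at
exact resolution. A final bilinear x4 upsample and 1x1 conv produce one
logit channel at input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .dual_encoder import StageFeatures
from .nn import Tensor

__all__ = ["MSFConfig", "DecoderConfig", "MSFBlock", "ChannelSliceFuse", "Decoder", "predict_mask"]


@dataclass
class MSFConfig:
    rates: tuple[int, ...] = (0, 3, 6, 9)  # 0 = 1x1 branch; d > 0 = 3x3 conv, dilation d
    branch_channels: int = 0  # 0 -> out_channels // 2


@dataclass
class DecoderConfig:
    decoder_channels: tuple[int, ...] = (64, 128, 256, 512)
    msf_rates: tuple[int, ...] = (0, 3, 6, 9)
    msf_position: str = "bottleneck"  # or "all_stages"
    threshold: float = 0.5
    use_msf: bool = True  # False -> plain 3x3 conv at the bottleneck (ablation)

    def __post_init__(self):
        if self.msf_position not in ("bottleneck", "all_stages"):
            raise ValueError(f"unknown msf_position {self.msf_position!r}")


class MSFBlock(nn.Module):
    """Parallel dilated branches, concatenated and fused by a 1x1 conv.

    Branches are plain convolutions (bias included); the surrounding decoder
    applies its own normalisation/nonlinearity.
    """

    def __init__(self, in_channels: int, out_channels: int, cfg: MSFConfig | None = None):
        super().__init__()
        cfg = cfg or MSFConfig()
        self.rates = tuple(cfg.rates)
        branch_ch = cfg.branch_channels or max(out_channels // 2, 1)
        self.branches = nn.ModuleList()
        for r in self.rates:
            if r == 0:
                self.branches.append(nn.Conv2d(in_channels, branch_ch, 1))
            else:
                self.branches.append(nn.Conv2d(in_channels, branch_ch, 3, padding=r, dilation=r))
        self.fuse = nn.Conv2d(branch_ch * len(self.rates), out_channels, 1)

    def forward(self, x: Tensor) -> Tensor:
        return self.fuse(nn.concat([b(x) for b in self.branches], axis=1))


class ChannelSliceFuse(nn.Module):
    """Half-split both inputs, interleave (skip_A, up_A, skip_B, up_B), 1x1 conv."""

    def __init__(self, skip_channels: int, up_channels: int, out_channels: int):
        super().__init__()
        if skip_channels % 2 or up_channels % 2:
            raise ValueError(
                f"channel slicing needs even channel counts, got skip={skip_channels}, up={up_channels}"
            )
        self.skip_channels = skip_channels
        self.up_channels = up_channels
        self.fuse = nn.Conv2d(skip_channels + up_channels, out_channels, 1)

    @staticmethod
    def interleave(skip: Tensor, up: Tensor) -> Tensor:
        if skip.shape[2:] != up.shape[2:]:
            raise ValueError(f"spatial mismatch: skip {skip.shape} vs up {up.shape}")
        cs, cu = skip.shape[1], up.shape[1]
        if cs % 2 or cu % 2:
            raise ValueError(f"odd channel counts: skip={cs}, up={cu}")
        sa, sb = skip[:, : cs // 2], skip[:, cs // 2 :]
        ua, ub = up[:, : cu // 2], up[:, cu // 2 :]
        return nn.concat([sa, ua, sb, ub], axis=1)

    def forward(self, skip: Tensor, up: Tensor) -> Tensor:
        return self.fuse(self.interleave(skip, up))


class Decoder(nn.Module):
    def __init__(self, skip_channels: list[int], cfg: DecoderConfig | None = None):
        super().__init__()
        if len(skip_channels) != 4:
            raise ValueError("decoder expects skips for 4 stages")
        cfg = cfg or DecoderConfig()
        self.cfg = cfg
        d = cfg.decoder_channels
        if cfg.use_msf:
            self.bottleneck = MSFBlock(skip_channels[3], d[3], MSFConfig(rates=cfg.msf_rates))
        else:
            self.bottleneck = nn.Conv2d(skip_channels[3], d[3], 3, padding=1)
        self.bottleneck_post = nn.Sequential(nn.BatchNorm2d(d[3]), nn.ReLU())
        self.fuses = nn.ModuleList()
        self.refines = nn.ModuleList()
        self.stage_msf = nn.ModuleList()
        for i in (2, 1, 0):
            self.fuses.append(ChannelSliceFuse(skip_channels[i], d[i + 1], d[i]))
            self.refines.append(
                nn.Sequential(nn.Conv2d(d[i], d[i], 3, padding=1, bias=False), nn.BatchNorm2d(d[i]), nn.ReLU())
            )
            if cfg.use_msf and cfg.msf_position == "all_stages":
                self.stage_msf.append(MSFBlock(d[i], d[i], MSFConfig(rates=cfg.msf_rates)))
        self.head = nn.Conv2d(d[0], 1, 1)

    def forward(self, sf: StageFeatures) -> Tensor:
        if len(sf.fused_skips) != 4 or any(s is None for s in sf.fused_skips):
            raise ValueError("decoder needs fused skips for all 4 stages")
        x = self.bottleneck_post(self.bottleneck(sf.fused_skips[3]))
        for k, i in enumerate((2, 1, 0)):
            x = nn.resize_bilinear(x, 2)
            x = self.fuses[k](sf.fused_skips[i], x)
            x = self.refines[k](x)
            if len(self.stage_msf):
                x = self.stage_msf[k](x)
        return self.head(nn.resize_bilinear(x, 4))


def predict_mask(logits: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarise 1-channel logits: sigmoid(logit) >= threshold -> 1 (boundary in)."""
    from .nn.tensor import _sigmoid

    probs = _sigmoid(np.asarray(logits, dtype=np.float64))
    return (probs >= threshold).astype(np.uint8)
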