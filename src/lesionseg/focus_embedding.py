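"""Focus slicing patch embedding: space-to-depth followed by a projection.

Instead of cutting an image into coarse non-overlapping patches and
flattening them to vectors, the Focus stem rearranges each 2x2 pixel block
into four channels — a lossless, invertible permutation of pixels — and then
applies a learned 3x3 convolution + batch norm + SiLU to the channel-expanded
map. The spatial stride is exactly 2 and no pixel value is discarded, so the
attention branch keeps full pixel accuracy and 2-D spatial layout (no
positional encodings are needed).

The slicing canon: output channel blocks are the (even-row, even-col),
(odd-row, even-col), (even-row, odd-col), (odd-row, odd-col) sub-grids, in
that order.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor
from .nn.tensor import SLICE_ORDER, space_to_depth_inverse

__all__ = ["SLICE_ORDER", "space_to_depth_slice", "inverse_slice", "FocusEmbed"]


def space_to_depth_slice(x: np.ndarray) -> np.ndarray:
    """Numpy slicing op: (B, C, H, W) -> (B, 4C, H/2, W/2). H, W must be even."""
    return nn.space_to_depth(Tensor(np.asarray(x, dtype=np.float32))).data


def inverse_slice(y: np.ndarray) -> np.ndarray:
    """Exact inverse: (B, 4C, H/2, W/2) -> (B, C, H, W)."""
    return space_to_depth_inverse(np.asarray(y, dtype=np.float32))


class FocusEmbed(nn.Module):
    """Slice 2x2 neighbourhoods to channels, then conv3x3 + BN + SiLU.

    One application halves H and W; the transformer stem applies it twice to
    reach the stride-4 grid of the CNN branch's first stage.
    """

    def __init__(self, in_channels: int, out_channels: int):
        super().__init__()
        self.conv = nn.Conv2d(4 * in_channels, out_channels, kernel_size=3, stride=1, padding=1)
        self.norm = nn.BatchNorm2d(out_channels)
        self.act = nn.SiLU()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.norm(self.conv(nn.space_to_depth(x))))
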