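"""Spatial group attention (SGA) and squeeze-and-excitation (SE) gating.

SGA splits the channel axis into G groups and, per group, compares every
spatial position against the group's global mean descriptor by dot product.
The resulting significance map is standardised (zero mean, unit population
std per group), optionally passed through a learnable per-group affine, and
squashed by a sigmoid into a (0,1) gate that multiplies every channel of the
group at that position. Groups are processed on an explicit group axis and
re-concatenated along channels — batch items are never mixed.

SE compresses each channel to its spatial mean (squeeze), passes the
descriptor through a two-layer bottleneck ``sigmoid(W2 relu(W1 z))``
(excitation), and rescales each channel by its gate.

The module offers both pure-numpy reference functions (the spec-level
operations, convenient for verification) and trainable :class:`~lesionseg.nn.Module`
wrappers used inside the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "GroupedFeatureMap",
    "group_feature_map",
    "ungroup_feature_map",
    "sga_group_mean",
    "sga_significance",
    "sga_normalize",
    "sga_forward",
    "se_squeeze",
    "se_excite",
    "se_scale",
    "SpatialGroupAttention",
    "SqueezeExcitation",
]


# ---------------------------------------------------------------------------
# Grouped view


@dataclass
class GroupedFeatureMap:
    """View of a (B, C, H, W) feature map as (B, G, C/G, m) with m = H*W.

    A pure reshape: :func:`ungroup_feature_map` restores the original array
    bit-exactly.
    """

    values: np.ndarray  # (B, G, C/G, m)
    group_count: int
    spatial_shape: tuple[int, int]


def group_feature_map(x: np.ndarray, groups: int) -> GroupedFeatureMap:
    b, c, h, w = x.shape
    if groups < 1 or c % groups:
        raise ValueError(f"channel count {c} not divisible by group count {groups}")
    return GroupedFeatureMap(x.reshape(b, groups, c // groups, h * w), groups, (h, w))


def ungroup_feature_map(g: GroupedFeatureMap) -> np.ndarray:
    b, G, cg, m = g.values.shape
    h, w = g.spatial_shape
    return g.values.reshape(b, G * cg, h, w)


# ---------------------------------------------------------------------------
# SGA reference operations (numpy)


def sga_group_mean(g: GroupedFeatureMap) -> np.ndarray:
    """Global context s = (1/m) sum_i x_i per (batch, group); shape (B, G, C/G)."""
    if g.values.shape[-1] < 1:
        raise ValueError("empty spatial extent: a group needs at least one position")
    return g.values.mean(axis=-1)


def sga_significance(g: GroupedFeatureMap, ctx: np.ndarray) -> np.ndarray:
    """Dot product of each position's sub-feature with the group context.

    Returns unnormalised coefficients of shape (B, G, m).
    """
    if ctx.shape != g.values.shape[:-1]:
        raise ValueError(f"context shape {ctx.shape} does not match grouping {g.values.shape[:-1]}")
    return np.einsum("bgcm,bgc->bgm", g.values, ctx)


def sga_normalize(coeff: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Standardise per (batch, group): subtract mean, divide by population std + eps.

    A constant map has zero std and maps to exact zeros (the eps guard).
    """
    mean = coeff.mean(axis=-1, keepdims=True)
    std = coeff.std(axis=-1, keepdims=True)  # population std
    return (coeff - mean) / (std + eps)


def sga_forward(
    x: np.ndarray,
    groups: int,
    eps: float = 1e-5,
    gamma: np.ndarray | None = None,
    beta: np.ndarray | None = None,
) -> np.ndarray:
    """Reference SGA: gate = sigmoid(gamma * t + beta), output = x * gate.

    `gamma`/`beta` are per-group (length G); defaults 1 and 0. At those
    defaults a spatially constant input yields t = 0 everywhere, hence a gate
    of exactly 0.5.
    """
    g = group_feature_map(x, groups)
    ctx = sga_group_mean(g)
    coeff = sga_significance(g, ctx)
    t = sga_normalize(coeff, eps)
    if gamma is None:
        gamma = np.ones(groups, dtype=x.dtype)
    if beta is None:
        beta = np.zeros(groups, dtype=x.dtype)
    gate = 1.0 / (1.0 + np.exp(-(gamma[None, :, None] * t + beta[None, :, None])))
    gated = g.values * gate[:, :, None, :]
    return ungroup_feature_map(GroupedFeatureMap(gated, groups, g.spatial_shape))


# ---------------------------------------------------------------------------
# SE reference operations (numpy)


def se_squeeze(u: np.ndarray) -> np.ndarray:
    """Channel descriptor z_c = spatial mean of channel c; shape (B, C)."""
    return u.mean(axis=(2, 3))


def se_excite(z: np.ndarray, w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    """Gate s = sigmoid(W2 relu(W1 z)); strictly inside (0, 1)."""
    c = z.shape[1]
    if w1.shape[1] != c:
        raise ValueError(f"W1 has {w1.shape[1]} input features, descriptor has {c}")
    if w2.shape != (c, w1.shape[0]):
        raise ValueError(f"W2 shape {w2.shape} inconsistent with W1 {w1.shape}")
    hidden = np.maximum(z @ w1.T, 0.0)
    return 1.0 / (1.0 + np.exp(-(hidden @ w2.T)))


def se_scale(u: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Rescale channel c of u by gate s_c."""
    if s.shape[1] != u.shape[1]:
        raise ValueError(f"gate length {s.shape[1]} != channel count {u.shape[1]}")
    return u * s[:, :, None, None]


# ---------------------------------------------------------------------------
# Trainable modules


class SpatialGroupAttention(nn.Module):
    """Trainable SGA block with per-group affine (gamma, beta) on the
    standardised significance, initialised to gamma=1, beta=0."""

    def __init__(self, groups: int = 8, eps: float = 1e-5):
        super().__init__()
        self.groups = groups
        self.eps = eps
        self.gamma = nn.Parameter(np.ones(groups, dtype=np.float32))
        self.beta = nn.Parameter(np.zeros(groups, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        G = self.groups
        if c % G:
            raise ValueError(f"channel count {c} not divisible by group count {G}")
        m = h * w
        xg = x.reshape(b, G, c // G, m)
        ctx = xg.mean(axis=-1, keepdims=True)                    # (B,G,Cg,1)
        coeff = (xg * ctx).sum(axis=2, keepdims=True)            # (B,G,1,m) dot products
        mean = coeff.mean(axis=-1, keepdims=True)
        std = (((coeff - mean) ** 2.0).mean(axis=-1, keepdims=True)).sqrt()
        t = (coeff - mean) / (std + self.eps)
        gate = (self.gamma.reshape(1, G, 1, 1) * t + self.beta.reshape(1, G, 1, 1)).sigmoid()
        return (xg * gate).reshape(b, c, h, w)


class SqueezeExcitation(nn.Module):
    """Trainable SE block; `channels` must be divisible by `reduction`."""

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        if channels % reduction:
            raise ValueError(f"channels {channels} not divisible by reduction ratio {reduction}")
        self.channels = channels
        self.reduction = reduction
        self.fc1 = nn.Linear(channels, channels // reduction, bias=False)
        self.fc2 = nn.Linear(channels // reduction, channels, bias=False)

    def forward(self, u: Tensor) -> Tensor:
        b, c, h, w = u.shape
        z = u.mean(axis=(2, 3))                   # squeeze
        s = self.fc2(self.fc1(z).relu()).sigmoid()  # excite
        return u * s.reshape(b, c, 1, 1)          # scale
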