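"""Full segmentation model assembly and the four ablation variants.

Variants:

``full``
    dual CNN + transformer encoder, MSF decoder.
``cnn_only``
    CNN branch only; decoder skips are the raw CNN stage features.
``vit_only``
    transformer branch only (Focus stem); skips are the transformer features.
``no_sga``
    the full model with every SGA gate replaced by standard 4-head
    self-attention over the flattened stage grid (the mechanism SGA replaces).
``no_aspp``
    the full model with the MSF block replaced by a single 3x3 convolution.

``width_multiplier`` scales every channel width for CPU-scale runs; 1.0 is
the full-size model. Checkpoints are single ``.npz`` files holding the
weights plus the embedded JSON config, so a model rebuilds from its
checkpoint alone.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .dual_encoder import DualEncoder, EncoderConfig
from .msf_decoder import Decoder, DecoderConfig
from .nn import Tensor, softmax

__all__ = [
    "VARIANTS",
    "VariantSpec",
    "ModelConfig",
    "MultiHeadSelfAttention",
    "SegmentationModel",
    "build_model",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("full", "cnn_only", "vit_only", "no_sga", "no_aspp")


@dataclass
class VariantSpec:
    name: str = "full"
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in VARIANTS:
            raise ValueError(f"unknown variant {self.name!r}; valid: {', '.join(VARIANTS)}")


@dataclass
class ModelConfig:
    input_size: int = 224
    variant: str = "full"
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    mha_heads: int = 4  # used only by the no_sga variant

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        enc = d.pop("encoder", {})
        dec = d.pop("decoder", {})
        for key in ("trans_channels", "skip_channels"):
            if key in enc:
                enc[key] = tuple(enc[key])
        for key in ("decoder_channels", "msf_rates"):
            if key in dec:
                dec[key] = tuple(dec[key])
        return cls(encoder=EncoderConfig(**enc), decoder=DecoderConfig(**dec), **d)

    @classmethod
    def reduced(cls, width_multiplier: float, input_size: int = 96) -> "ModelConfig":
        """Width-scaled config for CPU-scale runs.

        The SE reduction ratio scales with the width so the excitation
        bottleneck keeps the same hidden width as the full model (e.g. at
        multiplier 0.25, 16-channel stages use ratio 4, preserving 4 hidden
        units instead of collapsing to 1).
        """
        cfg = cls(input_size=input_size)
        cfg.encoder.width_multiplier = width_multiplier
        cfg.encoder.se_reduction = max(1, int(round(cfg.encoder.se_reduction * width_multiplier)))
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


class MultiHeadSelfAttention(nn.Module):
    """Standard softmax self-attention over the flattened spatial grid."""

    def __init__(self, channels: int, heads: int = 4):
        super().__init__()
        if channels % heads:
            raise ValueError(f"channels {channels} not divisible by heads {heads}")
        self.channels = channels
        self.heads = heads
        self.qkv = nn.Conv2d(channels, 3 * channels, 1)
        self.proj = nn.Conv2d(channels, channels, 1)

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        hd, dh = self.heads, c // self.heads
        qkv = self.qkv(x).reshape(b, 3, hd, dh, h * w)
        q = qkv[:, 0].transpose(0, 1, 3, 2)  # (B, heads, m, dh)
        k = qkv[:, 1]                        # (B, heads, dh, m)
        v = qkv[:, 2].transpose(0, 1, 3, 2)  # (B, heads, m, dh)
        attn = softmax((q @ k) * (dh ** -0.5), axis=-1)
        out = (attn @ v).transpose(0, 1, 3, 2).reshape(b, c, h, w)
        return self.proj(out)


class SegmentationModel(nn.Module):
    """Encoder + decoder; ``forward`` returns lesion probabilities in [0, 1]."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        name = config.variant
        mode = {"cnn_only": "cnn_only", "vit_only": "vit_only"}.get(name, "dual")
        attn_factory = None
        if name == "no_sga":
            attn_factory = lambda ch: MultiHeadSelfAttention(ch, config.mha_heads)
        self.encoder = DualEncoder(config.encoder, mode=mode, attention_factory=attn_factory)
        dec_cfg = config.decoder
        if name == "no_aspp":
            dec_cfg = DecoderConfig(**{**asdict(dec_cfg), "use_msf": False})
        dec_cfg = DecoderConfig(
            **{
                **asdict(dec_cfg),
                "decoder_channels": config.encoder.scaled(dec_cfg.decoder_channels),
            }
        )
        self.decoder = Decoder(self.encoder.skip_channels, dec_cfg)

    def forward_logits(self, image: Tensor) -> Tensor:
        return self.decoder(self.encoder(image))

    def forward(self, image: Tensor) -> Tensor:
        lo, hi = float(image.data.min()), float(image.data.max())
        if lo < -20.0 or hi > 20.0:
            warnings.warn(
                f"input range [{lo:.1f}, {hi:.1f}] looks unnormalized; expected roughly unit scale",
                stacklevel=2,
            )
        return self.forward_logits(image).sigmoid()

    def predict(self, image: np.ndarray, threshold: float | None = None) -> np.ndarray:
        """Binary masks (B, H, W) for a numpy image batch (no grad tracking)."""
        from .msf_decoder import predict_mask

        was_training = self.training
        self.eval()
        logits = self.forward_logits(Tensor(np.asarray(image, dtype=np.float32)))
        if was_training:
            self.train()
        thr = self.decoder.cfg.threshold if threshold is None else threshold
        return predict_mask(logits.data[:, 0], thr)


def build_model(spec: VariantSpec | str, config: ModelConfig | None = None, seed: int | None = None) -> SegmentationModel:
    """Construct a variant; ``seed`` resets weight init for reproducibility."""
    if isinstance(spec, str):
        spec = VariantSpec(spec)
    config = config or ModelConfig()
    cfg_dict = config.to_dict()
    for key, value in spec.overrides.items():
        if key in ("encoder", "decoder") and isinstance(value, dict):
            cfg_dict[key].update(value)
        else:
            cfg_dict[key] = value
    cfg_dict["variant"] = spec.name
    config = ModelConfig.from_dict(cfg_dict)
    if seed is not None:
        nn.seed_all(seed)
    return SegmentationModel(config)


def save_checkpoint(model: SegmentationModel, path) -> None:
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8
    ).copy()
    np.savez_compressed(path, **state)


def load_checkpoint(path, expected_config: ModelConfig | None = None) -> SegmentationModel:
    with np.load(path) as data:
        state = {k: data[k] for k in data.files}
    config = ModelConfig.from_dict(json.loads(state.pop("__config__").tobytes().decode()))
    if expected_config is not None and expected_config.to_dict() != config.to_dict():
        raise ValueError(
            "checkpoint/architecture mismatch: "
            f"checkpoint config hash {config.config_hash()} vs expected {expected_config.config_hash()}"
        )
    model = SegmentationModel(config)
    model.load_state_dict(state)
    model.eval()
    return model
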