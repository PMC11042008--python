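"""Training and evaluation harness for the segmentation models.

Defaults mirror the documented study setup: 224x224 inputs, Adam with
initial learning rate 1e-4 (no schedule), batch size 4, up to 100 epochs,
flip/transpose/rotation/linear-intensity augmentation. The loss is binary
cross-entropy plus soft Dice (smoothing 1.0). Runs are fully seeded — weight
init, batch order and augmentation sampling all derive from ``cfg.seed`` —
so a repeated run reproduces its losses bit for bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from . import metrics as metrics_mod
from . import nn
from .model_variants import ModelConfig, SegmentationModel, VariantSpec, build_model, save_checkpoint
from .nn import Tensor
from .synthetic_data import AugmentationSpec, LesionSample, augment

__all__ = [
    "CHANNEL_MEAN",
    "CHANNEL_STD",
    "TrainConfig",
    "RunLog",
    "normalize_image",
    "segmentation_loss",
    "load_isic_layout",
    "train",
    "evaluate",
    "write_overlay",
]

# Channel statistics of large natural-image corpora; the conventional
# normalisation for ResNet-style backbones.
CHANNEL_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
CHANNEL_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

_LOSSES = ("bce_dice", "bce", "dice")


@dataclass
class TrainConfig:
    input_size: int = 224
    learning_rate: float = 1e-4
    batch_size: int = 4
    max_epochs: int = 100
    loss: str = "bce_dice"
    seed: int = 0
    device: str = "cpu"
    variant: str = "full"
    width_multiplier: float = 1.0
    augmentation: AugmentationSpec | None = field(default_factory=AugmentationSpec)
    channel_mean: tuple[float, float, float] = tuple(CHANNEL_MEAN.tolist())
    channel_std: tuple[float, float, float] = tuple(CHANNEL_STD.tolist())

    def __post_init__(self):
        if self.loss not in _LOSSES:
            raise ValueError(f"unknown loss {self.loss!r}; valid: {', '.join(_LOSSES)}")
        if self.batch_size < 1 or self.max_epochs < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size/max_epochs must be >= 1 and learning_rate > 0")
        if self.input_size % 32:
            raise ValueError(f"input_size {self.input_size} must be divisible by 32")

    def model_config(self) -> ModelConfig:
        cfg = ModelConfig.reduced(self.width_multiplier, self.input_size)
        cfg.variant = self.variant
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        aug = raw.pop("augmentation", "default")
        cfg = cls(**raw)
        if aug is None:
            cfg.augmentation = None
        elif isinstance(aug, dict):
            cfg.augmentation = AugmentationSpec(**aug)
        return cfg


@dataclass
class RunLog:
    config: dict
    seed: int
    param_count: int
    epochs: list = field(default_factory=list)
    best_epoch: int = -1
    best_dice: float = -1.0
    checkpoint: str | None = None

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            header = {k: v for k, v in asdict(self).items() if k != "epochs"}
            fh.write(json.dumps({"run": header}) + "\n")
            for e in self.epochs:
                fh.write(json.dumps(e) + "\n")


def normalize_image(image: np.ndarray, mean=CHANNEL_MEAN, std=CHANNEL_STD) -> np.ndarray:
    """(H, W, 3) in [0,1] -> normalised (3, H, W) float32."""
    arr = (np.asarray(image, dtype=np.float32) - np.asarray(mean, dtype=np.float32)) / np.asarray(
        std, dtype=np.float32
    )
    return arr.transpose(2, 0, 1)


def _batch_input(samples: list[LesionSample], cfg: TrainConfig) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([normalize_image(s.image, cfg.channel_mean, cfg.channel_std) for s in samples])
    masks = np.stack([s.mask for s in samples]).astype(np.float32)
    return imgs, masks


def segmentation_loss(probs: Tensor, mask: np.ndarray, kind: str = "bce_dice") -> Tensor:
    """BCE and/or soft-Dice loss on probabilities in [0, 1].

    The soft-Dice term uses smoothing 1.0 in numerator and denominator and is
    pooled over the whole batch. Zero exactly when probs equal the mask (the
    BCE term is bounded below by its clamping epsilon).
    """
    mask = np.asarray(mask, dtype=np.float32)
    if probs.shape[-2:] != mask.shape[-2:] or probs.shape[0] != mask.shape[0]:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs mask {mask.shape}")
    if kind not in _LOSSES:
        raise ValueError(f"unknown loss {kind!r}")
    m = Tensor(mask.reshape(probs.shape))
    total = None
    if kind in ("bce", "bce_dice"):
        p = probs.clip(1e-7, 1.0 - 1e-7)
        bce = -(m * p.log() + (1.0 - m) * (1.0 - p).log()).mean()
        total = bce
    if kind in ("dice", "bce_dice"):
        inter = (probs * m).sum()
        dice = 1.0 - (2.0 * inter + 1.0) / (probs.sum() + m.sum() + 1.0)
        total = dice if total is None else total + dice
    return total


def load_isic_layout(data_dir, input_size: int | None = None) -> list[LesionSample]:
    """Load `<ID>.{jpg,png,jpeg}` / `<ID>_segmentation.png` pairs.

    Images resize bilinearly, masks by nearest neighbour; unpaired files are
    an error that names every orphan.
    """
    root = Path(data_dir)
    img_dir, mask_dir = root / "images", root / "masks"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise FileNotFoundError(f"{root} must contain images/ and masks/ subfolders")
    images = {p.stem: p for p in sorted(img_dir.iterdir()) if p.suffix.lower() in (".jpg", ".jpeg", ".png")}
    masks = {p.stem.removesuffix("_segmentation"): p for p in sorted(mask_dir.glob("*_segmentation.png"))}
    orphans = sorted(set(images) ^ set(masks))
    if orphans:
        raise ValueError(f"unpaired image/mask IDs: {', '.join(orphans)}")
    samples = []
    for sample_id, img_path in images.items():
        img = Image.open(img_path).convert("RGB")
        msk = Image.open(masks[sample_id]).convert("L")
        if input_size is not None:
            img = img.resize((input_size, input_size), Image.BILINEAR)
            msk = msk.resize((input_size, input_size), Image.NEAREST)
        image = np.asarray(img, dtype=np.float32) / 255.0
        mask = (np.asarray(msk) > 127).astype(np.uint8)
        samples.append(LesionSample(image, mask, {"id": sample_id}))
    return samples


def train(
    cfg: TrainConfig,
    train_samples: list[LesionSample],
    val_samples: list[LesionSample] | None = None,
    out_dir=None,
    max_steps: int | None = None,
    model: SegmentationModel | None = None,
) -> tuple[RunLog, SegmentationModel]:
    """Seeded training loop with per-epoch validation and best-Dice checkpointing."""
    nn.seed_all(cfg.seed)
    if model is None:
        model = build_model(VariantSpec(cfg.variant), cfg.model_config())
    model.train()
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    log = RunLog(config=asdict(cfg), seed=cfg.seed, param_count=model.num_parameters())

    step = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_samples))
        losses = []
        t0 = time.time()
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_samples[i] for i in order[start : start + cfg.batch_size]]
            if cfg.augmentation is not None:
                batch = [augment(s, cfg.augmentation, rng) for s in batch]
            imgs, masks = _batch_input(batch, cfg)
            probs = model(Tensor(imgs))
            loss = segmentation_loss(probs, masks[:, None], cfg.loss)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            step += 1
            if max_steps is not None and step >= max_steps:
                break
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses)), "seconds": round(time.time() - t0, 2)}
        if val_samples:
            report = evaluate(model, val_samples, cfg)[0]
            entry["val_dice"] = report.dice
            entry["val_iou"] = report.iou
            if report.dice > log.best_dice:
                log.best_dice = report.dice
                log.best_epoch = epoch
                if out is not None:
                    log.checkpoint = str(out / "best.npz")
                    save_checkpoint(model, log.checkpoint)
        log.epochs.append(entry)
        if max_steps is not None and step >= max_steps:
            break
    if out is not None:
        if log.checkpoint is None:
            log.checkpoint = str(out / "last.npz")
            save_checkpoint(model, log.checkpoint)
        log.dump(out / "run_log.jsonl")
    return log, model


def evaluate(
    model: SegmentationModel,
    samples: list[LesionSample],
    cfg: TrainConfig | None = None,
    threshold: float | None = None,
) -> tuple[metrics_mod.MetricsReport, metrics_mod.MetricsReport, list]:
    """(micro summary, macro summary, per-image (id, report, counts)) for a dataset."""
    cfg = cfg or TrainConfig(input_size=samples[0].image.shape[0])
    was_training = model.training
    model.eval()
    per_image = []
    counts = []
    bs = max(1, cfg.batch_size)
    for start in range(0, len(samples), bs):
        chunk = samples[start : start + bs]
        imgs, _ = _batch_input(chunk, cfg)
        preds = model.predict(imgs, threshold)
        for s, pred in zip(chunk, preds):
            c = metrics_mod.confusion_counts(pred, s.mask)
            counts.append(c)
            per_image.append((s.meta.get("id", f"sample_{len(per_image)}"), metrics_mod.compute_metrics(c), c))
    if was_training:
        model.train()
    micro = metrics_mod.aggregate(counts, "micro")
    macro = metrics_mod.aggregate(counts, "macro")
    return micro, macro, per_image


def write_overlay(sample: LesionSample, pred_mask: np.ndarray, path) -> None:
    """Plumbing: save the image with ground-truth (green) and predicted (red) contours."""
    from scipy.ndimage import binary_erosion

    img = (sample.image * 255).astype(np.uint8).copy()
    for mask, color in ((sample.mask, (0, 255, 0)), (pred_mask, (255, 0, 0))):
        m = mask.astype(bool)
        edge = m & ~binary_erosion(m)
        img[edge] = color
    Image.fromarray(img).save(path)
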