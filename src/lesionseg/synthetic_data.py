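"""Seeded synthetic dermoscopy-like images with exact lesion masks.

The generator emulates the regime skin-lesion segmentation targets: a
low-contrast, irregularly shaped darker region on a textured skin-tone
background, optionally occluded by dark hair-like arcs. A lesion is an
ellipse whose radius is modulated by a low-order random Fourier series
(harmonics 2..5), so the boundary is irregular but star-shaped — hence the
mask is simply connected for moderate irregularity. The mask is the exact
perturbed-ellipse interior; the image darkens that region by ``contrast``
(with a slightly blurred edge so the boundary is not a trivial step) and
adds lesion texture.

Everything is a pure function of its seed: the same seed reproduces the same
sample bit for bit.

The augmentation set is horizontal/vertical flips, transpose (row-column
flip), random rotation and a per-image linear intensity transform; geometric
ops are applied identically to image and mask (mask nearest-neighbour, so it
stays strictly binary), the intensity transform to the image only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.draw import bezier_curve

__all__ = [
    "LesionSample",
    "AugmentationSpec",
    "generate_lesion_sample",
    "generate_dataset",
    "augment",
    "flip_horizontal",
    "flip_vertical",
    "transpose_sample",
    "rotate_sample",
    "linear_intensity",
    "write_isic_dataset",
]

_SKIN_TONE = np.array([0.80, 0.60, 0.52])  # light reddish skin base (RGB)


@dataclass
class LesionSample:
    image: np.ndarray  # (H, W, 3) float32 in [0, 1]
    mask: np.ndarray   # (H, W) uint8 in {0, 1}
    meta: dict = field(default_factory=dict)


@dataclass
class AugmentationSpec:
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    p_transpose: float = 0.5
    p_rotate: float = 0.5
    rotate_range: float = 30.0  # degrees, symmetric
    p_intensity: float = 0.5
    gain_range: tuple[float, float] = (0.8, 1.2)
    offset_range: tuple[float, float] = (-0.1, 0.1)
    seed: int = 0


def _smooth_noise(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.normal(size=(size, size)), sigma=sigma)
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def _lesion_geometry(rng: np.random.Generator, size: int, irregularity: float):
    center = rng.uniform(0.38, 0.62, size=2) * size
    axes = rng.uniform(0.16, 0.30, size=2) * size
    angle = rng.uniform(0.0, np.pi)
    amps = rng.normal(0.0, 1.0, size=4) * irregularity / np.arange(2, 6)
    phases = rng.uniform(0.0, 2 * np.pi, size=4)
    return center, axes, angle, amps, phases


def _rasterize(size: int, center, axes, angle, amps, phases) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - center[0], xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (dx * ca + dy * sa) / axes[0]
    v = (-dx * sa + dy * ca) / axes[1]
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    r = np.ones_like(theta)
    for k, (a, p) in enumerate(zip(amps, phases), start=2):
        r += a * np.cos(k * theta + p)
    return (rho <= np.clip(r, 0.25, None)).astype(np.uint8)


def generate_lesion_sample(
    seed: int,
    size: int = 96,
    contrast: float = 0.3,
    irregularity: float = 0.15,
    hair_count: int = 0,
    foreground_bounds: tuple[float, float] = (0.02, 0.6),
) -> LesionSample:
    """One synthetic image + exact binary mask, fully determined by ``seed``."""
    if size < 32:
        raise ValueError(f"size {size} too small (minimum 32)")
    if not 0.0 < contrast <= 1.0:
        raise ValueError(f"contrast must lie in (0, 1], got {contrast}")
    rng = np.random.default_rng(seed)

    # background: skin tone + per-channel low-frequency shading + fine grain
    image = np.empty((size, size, 3), dtype=np.float64)
    for ch in range(3):
        image[:, :, ch] = (
            _SKIN_TONE[ch]
            + 0.05 * _smooth_noise(rng, size, sigma=size / 8)
            + 0.015 * rng.normal(size=(size, size))
        )

    # lesion geometry, resampled until the foreground fraction is in bounds
    for _ in range(50):
        geom = _lesion_geometry(rng, size, irregularity)
        mask = _rasterize(size, *geom)
        frac = mask.mean()
        if foreground_bounds[0] <= frac <= foreground_bounds[1]:
            break
    else:
        raise RuntimeError("could not draw a lesion within the foreground bounds")

    # darken the lesion with a softly blurred edge + internal texture
    soft = ndimage.gaussian_filter(mask.astype(np.float64), sigma=1.0)
    texture = 0.04 * _smooth_noise(rng, size, sigma=2.0) * mask
    image -= (contrast * soft + texture)[:, :, None]

    for _ in range(hair_count):
        _draw_hair(rng, image, size)

    center, axes, angle, amps, phases = geom
    meta = {
        "seed": int(seed),
        "size": int(size),
        "center": tuple(map(float, center)),
        "axes": tuple(map(float, axes)),
        "angle": float(angle),
        "contrast": float(contrast),
        "irregularity": float(irregularity),
        "hair_count": int(hair_count),
        "foreground_fraction": float(frac),
    }
    return LesionSample(np.clip(image, 0.0, 1.0).astype(np.float32), mask, meta)


def _draw_hair(rng: np.random.Generator, image: np.ndarray, size: int) -> None:
    pts = rng.integers(0, size, size=6)
    rr, cc = bezier_curve(pts[0], pts[1], pts[2], pts[3], pts[4], pts[5], weight=2, shape=(size, size))
    shade = rng.uniform(0.2, 0.4)
    for dr in (0, 1):  # ~2 px thick strands
        r2 = np.clip(rr + dr, 0, size - 1)
        image[r2, cc] = image[r2, cc] * (1.0 - shade)


def generate_dataset(
    n: int,
    size: int = 96,
    seed: int = 0,
    split: float = 0.8,
    **sample_kwargs,
) -> tuple[list[LesionSample], np.ndarray, np.ndarray]:
    """n seeded samples plus a deterministic train/test index split."""
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    children = np.random.SeedSequence(seed).spawn(n)
    samples = [
        generate_lesion_sample(int(c.generate_state(1)[0] % (2**31)), size=size, **sample_kwargs)
        for c in children
    ]
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(n * split))
    return samples, np.sort(order[:n_train]), np.sort(order[n_train:])


# ---------------------------------------------------------------------------
# Augmentations


def flip_horizontal(s: LesionSample) -> LesionSample:
    return replace(s, image=s.image[:, ::-1].copy(), mask=s.mask[:, ::-1].copy())


def flip_vertical(s: LesionSample) -> LesionSample:
    return replace(s, image=s.image[::-1].copy(), mask=s.mask[::-1].copy())


def transpose_sample(s: LesionSample) -> LesionSample:
    """Row-column flip (matrix transpose of the spatial axes)."""
    return replace(s, image=s.image.transpose(1, 0, 2).copy(), mask=s.mask.T.copy())


def _border_color(image: np.ndarray) -> np.ndarray:
    border = np.concatenate([image[0], image[-1], image[:, 0], image[:, -1]])
    return np.median(border, axis=0)


def rotate_sample(s: LesionSample, angle_deg: float) -> LesionSample:
    """Rotate jointly; exact lattice rotation for multiples of 90 degrees.

    Exposed corners are filled with the image's border-median colour rather
    than black, so rotation does not imprint a learnable dark frame.
    """
    if angle_deg % 90 == 0:
        k = int(angle_deg // 90) % 4
        return replace(s, image=np.rot90(s.image, k).copy(), mask=np.rot90(s.mask, k).copy())
    fill = _border_color(s.image)
    image = np.stack(
        [
            ndimage.rotate(s.image[:, :, ch], angle_deg, reshape=False, order=1, cval=fill[ch], mode="constant")
            for ch in range(3)
        ],
        axis=-1,
    )
    mask = ndimage.rotate(s.mask, angle_deg, reshape=False, order=0, cval=0, mode="constant")
    return replace(s, image=np.clip(image, 0.0, 1.0).astype(np.float32), mask=mask.astype(np.uint8))


def linear_intensity(s: LesionSample, gain: float, offset: float) -> LesionSample:
    return replace(s, image=np.clip(s.image * gain + offset, 0.0, 1.0).astype(np.float32))


def augment(
    sample: LesionSample,
    spec: AugmentationSpec,
    rng: np.random.Generator | None = None,
) -> LesionSample:
    """Apply the stochastic augmentation pipeline; rng defaults to spec.seed."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    s = sample
    if rng.random() < spec.p_hflip:
        s = flip_horizontal(s)
    if rng.random() < spec.p_vflip:
        s = flip_vertical(s)
    if rng.random() < spec.p_transpose:
        s = transpose_sample(s)
    if rng.random() < spec.p_rotate:
        s = rotate_sample(s, rng.uniform(-spec.rotate_range, spec.rotate_range))
    if rng.random() < spec.p_intensity:
        s = linear_intensity(s, rng.uniform(*spec.gain_range), rng.uniform(*spec.offset_range))
    return s


# ---------------------------------------------------------------------------
# ISIC-style folder output


def write_isic_dataset(samples: list[LesionSample], out_dir) -> list[str]:
    """Write images/SYN_%07d.jpg and masks/SYN_%07d_segmentation.png pairs."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    ids = []
    for i, s in enumerate(samples):
        sample_id = f"SYN_{i:07d}"
        Image.fromarray((s.image * 255).round().astype(np.uint8)).save(
            out / "images" / f"{sample_id}.jpg", quality=95
        )
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(
            out / "masks" / f"{sample_id}_segmentation.png"
        )
        ids.append(sample_id)
    return ids
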