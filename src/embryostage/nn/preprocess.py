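"""Image preprocessing and training-time augmentation.

The preprocessing pipeline is: contrast-limited adaptive histogram
equalisation on the raw grayscale frame, resize to the model input size,
replication of the single channel into R, G and B, then standardisation
with the ImageNet channel statistics.  Augmentation applies
rotation+shift, horizontal flip, and noise-or-blur independently, each
with its configured probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, transform

__all__ = [
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "AugmentationPolicy",
    "preprocess_image",
    "augment",
]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass(frozen=True)
class AugmentationPolicy:
    p_rotate_shift: float = 0.3
    p_flip: float = 0.5
    p_noise_blur: float = 0.5
    clahe: bool = True
    channel_means: tuple[float, float, float] = IMAGENET_MEAN
    channel_stds: tuple[float, float, float] = IMAGENET_STD
    max_rotate_degrees: float = 15.0
    max_shift_fraction: float = 0.08

    def __post_init__(self) -> None:
        for name in ("p_rotate_shift", "p_flip", "p_noise_blur"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


def preprocess_image(
    raw: np.ndarray,
    image_size: int,
    clahe: bool = True,
    channel_means: tuple[float, float, float] = IMAGENET_MEAN,
    channel_stds: tuple[float, float, float] = IMAGENET_STD,
) -> np.ndarray:
    """Grayscale frame -> standardized (3, image_size, image_size) float array.

    CLAHE runs on the frame at its native resolution, before resizing.
    """
    raw = np.asarray(raw)
    if raw.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {raw.shape}")
    img = raw.astype(np.float64)
    if img.max() > 1.0:
        img = img / 255.0
    img = np.clip(img, 0.0, 1.0)
    if clahe:
        # tiles of half the frame: local enough to even out illumination,
        # large enough not to erase object-scale structure on small frames
        kernel = max(8, img.shape[0] // 2)
        img = exposure.equalize_adapthist(img, kernel_size=kernel)
    if img.shape != (image_size, image_size):
        img = transform.resize(
            img, (image_size, image_size), order=1, anti_aliasing=True, mode="reflect"
        )
    chans = [
        (img - m) / s for m, s in zip(channel_means, channel_stds)
    ]
    return np.stack(chans, axis=0).astype(np.float64)


def augment(
    image: np.ndarray,
    policy: AugmentationPolicy | None = None,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Randomly transform a grayscale frame; deterministic per seed.

    Transforms draw their decisions in a fixed order (rotate+shift,
    flip, noise-or-blur) so results are reproducible for a given seed
    regardless of which probabilities are zero.
    """
    policy = policy or AugmentationPolicy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {img.shape}")

    do_rot = rng.random() < policy.p_rotate_shift
    angle = float(rng.uniform(-policy.max_rotate_degrees, policy.max_rotate_degrees))
    shift = rng.uniform(
        -policy.max_shift_fraction, policy.max_shift_fraction, size=2
    ) * np.array(img.shape)
    do_flip = rng.random() < policy.p_flip
    do_noise_blur = rng.random() < policy.p_noise_blur
    use_noise = rng.random() < 0.5
    noise_sigma = float(rng.uniform(1.0, 5.0))
    blur_sigma = float(rng.uniform(0.5, 1.5))
    noise_field = rng.normal(0.0, 1.0, img.shape)

    if do_rot:
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
        img = ndimage.shift(img, shift, order=1, mode="nearest")
    if do_flip:
        img = img[:, ::-1]
    if do_noise_blur:
        if use_noise:
            img = img + noise_sigma * noise_field
        else:
            img = ndimage.gaussian_filter(img, blur_sigma)
    return np.clip(img, 0, 255) if image.dtype == np.uint8 else img
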