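"""Deterministic preprocessing: contrast enhancement, mask preparation, and
the masked-image construction feeding the mass-detection track.

Images are contrast-enhanced by CLAHE (clip limit 2.0 on the conventional
0-40 scale, 8x8 tile grid) followed by global histogram equalization; masks
are only resized (nearest neighbour) and never contrast-processed.  The
mass track receives the element-wise product of the preprocessed image with
the organ mask predicted by the organ track, so no ground-truth organ mask
leaks into mass inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure, transform

__all__ = ["PreprocessConfig", "enhance_contrast", "prepare_mask",
           "mask_kidney_image", "resize_image", "rescale"]


@dataclass
class PreprocessConfig:
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    apply_clahe_prob: float = 1.0  # 1.0 = deterministic inference path
    target_size: tuple[int, int] = (224, 224)
    rescale_factor: float = 1.0 / 255.0

    def __post_init__(self):
        if self.clahe_clip_limit <= 0:
            raise ValueError("clip limit must be positive")
        if min(self.clahe_tile_grid) < 1:
            raise ValueError("tile grid must be >= 1x1")
        if not 0 <= self.apply_clahe_prob <= 1:
            raise ValueError("probability must lie in [0, 1]")


def _clahe(gray01: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    h, w = gray01.shape
    gy, gx = cfg.clahe_tile_grid
    kernel = (max(h // gy, 1), max(w // gx, 1))
    # scikit-image normalizes the clip limit by the bin count; 2.0 on the
    # conventional integer scale corresponds to 2/256 here.
    return exposure.equalize_adapthist(
        np.clip(gray01, 0.0, 1.0), kernel_size=kernel,
        clip_limit=cfg.clahe_clip_limit / 256.0, nbins=256,
    )


def _hist_equalize(gray01: np.ndarray) -> np.ndarray:
    return exposure.equalize_hist(gray01, nbins=256)


def enhance_contrast(image: np.ndarray, cfg: PreprocessConfig | None = None,
                     apply_clahe: bool = True) -> np.ndarray:
    """CLAHE then global histogram equalization, on the raw [0, 255] range.

    Multi-channel images are enhanced on their luminance and the channels
    rescaled proportionally, so hue is untouched.  Output spans [0, 255].
    """
    cfg = cfg or PreprocessConfig()
    image = np.asarray(image, dtype=np.float64)
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite pixels")
    if image.ndim == 2:
        x = image / 255.0
        if x.max() > x.min():
            if apply_clahe:
                x = _clahe(x, cfg)
            x = _hist_equalize(x)
        else:
            x = np.full_like(x, x.flat[0])
        return x * 255.0
    lum = image.mean(axis=2)
    lum_out = enhance_contrast(lum, cfg, apply_clahe=apply_clahe)
    ratio = lum_out / np.maximum(lum, 1e-6)
    return np.clip(image * ratio[:, :, None], 0.0, 255.0)


def prepare_mask(mask: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Nearest-neighbour resize to the target size; values stay in {0, 1}."""
    cfg = cfg or PreprocessConfig()
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask values must be in {0, 1}")
    if mask.shape == tuple(cfg.target_size):
        return mask.copy()
    out = transform.resize(
        mask.astype(np.uint8), cfg.target_size, order=0,
        anti_aliasing=False, preserve_range=True,
    )
    return out.astype(np.uint8)


def resize_image(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of a raw-range image, preserving the value range."""
    if image.shape[:2] == tuple(size):
        return np.asarray(image, dtype=np.float64)
    return transform.resize(
        np.asarray(image, dtype=np.float64), size, order=1,
        anti_aliasing=False, preserve_range=True,
    )


def rescale(image: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Map the raw [0, 255] range onto [0, 1]."""
    cfg = cfg or PreprocessConfig()
    return np.asarray(image, dtype=np.float32) * np.float32(cfg.rescale_factor)


def mask_kidney_image(image: np.ndarray, predicted_mask: np.ndarray) -> np.ndarray:
    """Element-wise product image * mask (mask broadcast across channels)."""
    image = np.asarray(image)
    predicted_mask = np.asarray(predicted_mask)
    if image.shape[:2] != predicted_mask.shape:
        raise ValueError(
            f"image {image.shape[:2]} and mask {predicted_mask.shape} "
            "dimensions differ"
        )
    if image.ndim == 3:
        return image * predicted_mask[:, :, None]
    return image * predicted_mask
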