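"""Paired stochastic augmentation for image/mask training samples.

Every realized transform applies the identical spatial map to the image
(bilinear) and its mask (nearest neighbour), so the correspondence between
pixels and labels is preserved; intensity jitter touches the image only.
The stack and its defaults: horizontal/vertical flips (p 0.5 each), rotation
within +/-20 degrees (p 0.5), brightness/contrast jitter (p 0.3), and an
elastic deformation (alpha 1, sigma 50, alpha_affine 50, p 0.3) built from a
Gaussian-smoothed random displacement field plus a random 3-point affine
jitter, sampled with reflective borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["AugmentConfig", "RealizedTransform", "draw_transform", "augment_pair"]


@dataclass
class AugmentConfig:
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    rotation_limit_degrees: float = 20.0
    p_rotate: float = 0.5
    p_brightness_contrast: float = 0.3
    brightness_limit: float = 0.2
    contrast_limit: float = 0.2
    elastic_alpha: float = 1.0
    elastic_sigma: float = 50.0
    elastic_alpha_affine: float = 50.0
    p_elastic: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("p_hflip", "p_vflip", "p_rotate",
                     "p_brightness_contrast", "p_elastic"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.rotation_limit_degrees < 0:
            raise ValueError("rotation limit must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class RealizedTransform:
    """One concrete draw from the augmentation stack."""

    hflip: bool = False
    vflip: bool = False
    angle_degrees: float = 0.0
    brightness: float = 0.0
    contrast: float = 0.0
    displacement: tuple[np.ndarray, np.ndarray] | None = None  # (dy, dx)

    @property
    def is_geometric_identity(self) -> bool:
        return (not self.hflip and not self.vflip
                and self.angle_degrees == 0.0 and self.displacement is None)

    def source_coords(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Source-pixel coordinates sampled for each output pixel of the
        rotation+elastic part of the map (flips are handled separately as
        exact array reversals)."""
        h, w = shape
        yy, xx = np.meshgrid(np.arange(h, dtype=np.float64),
                             np.arange(w, dtype=np.float64), indexing="ij")
        if self.angle_degrees != 0.0:
            theta = np.deg2rad(self.angle_degrees)
            cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
            yc, xc = yy - cy, xx - cx
            # inverse rotation: output pixel samples from rotated source
            yy = cy + np.cos(theta) * yc - np.sin(theta) * xc
            xx = cx + np.sin(theta) * yc + np.cos(theta) * xc
        if self.displacement is not None:
            dy, dx = self.displacement
            yy = yy + dy
            xx = xx + dx
        return yy, xx

    def _warp(self, arr: np.ndarray, order: int) -> np.ndarray:
        out = arr
        if self.hflip:
            out = out[:, ::-1]
        if self.vflip:
            out = out[::-1, :]
        if self.angle_degrees != 0.0 or self.displacement is not None:
            yy, xx = self.source_coords(out.shape[:2])
            if out.ndim == 3:
                out = np.stack(
                    [ndimage.map_coordinates(out[..., c], [yy, xx], order=order,
                                             mode="reflect")
                     for c in range(out.shape[2])], axis=-1)
            else:
                out = ndimage.map_coordinates(out, [yy, xx], order=order,
                                              mode="reflect")
        return np.ascontiguousarray(out)

    def apply_image(self, image: np.ndarray) -> np.ndarray:
        out = self._warp(np.asarray(image, dtype=np.float64), order=1)
        if self.contrast != 0.0 or self.brightness != 0.0:
            out = out * (1.0 + self.contrast) + self.brightness * 255.0
            out = np.clip(out, 0.0, 255.0)
        return out

    def apply_mask(self, mask: np.ndarray) -> np.ndarray:
        out = self._warp(np.asarray(mask, dtype=np.float64), order=0)
        return (out > 0.5).astype(np.uint8)


def _elastic_displacement(shape: tuple[int, int], cfg: AugmentConfig,
                          rng: np.random.Generator):
    h, w = shape
    dy = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)),
                                 cfg.elastic_sigma, mode="reflect") * cfg.elastic_alpha
    dx = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)),
                                 cfg.elastic_sigma, mode="reflect") * cfg.elastic_alpha
    if cfg.elastic_alpha_affine > 0:
        # 3-point affine jitter: displace a reference triangle by up to
        # alpha_affine pixels and add the induced affine flow field.
        c = np.array([[h / 2, w / 2], [h / 2 + h / 4, w / 2],
                      [h / 2, w / 2 + w / 4]], dtype=np.float64)
        jitter = rng.uniform(-cfg.elastic_alpha_affine,
                             cfg.elastic_alpha_affine, (3, 2))
        src, dst = c, c + jitter
        a = np.hstack([dst, np.ones((3, 1))])
        coef = np.linalg.solve(a, src)  # maps output coords -> source coords
        yy, xx = np.meshgrid(np.arange(h, dtype=np.float64),
                             np.arange(w, dtype=np.float64), indexing="ij")
        sy = coef[0, 0] * yy + coef[1, 0] * xx + coef[2, 0]
        sx = coef[0, 1] * yy + coef[1, 1] * xx + coef[2, 1]
        dy += sy - yy
        dx += sx - xx
    return dy, dx


def draw_transform(shape: tuple[int, int], cfg: AugmentConfig,
                   rng: np.random.Generator) -> RealizedTransform:
    t = RealizedTransform()
    t.hflip = cfg.p_hflip > 0 and rng.random() < cfg.p_hflip
    t.vflip = cfg.p_vflip > 0 and rng.random() < cfg.p_vflip
    if cfg.p_rotate > 0 and rng.random() < cfg.p_rotate:
        t.angle_degrees = float(rng.uniform(-cfg.rotation_limit_degrees,
                                            cfg.rotation_limit_degrees))
    if cfg.p_brightness_contrast > 0 and rng.random() < cfg.p_brightness_contrast:
        t.brightness = float(rng.uniform(-cfg.brightness_limit, cfg.brightness_limit))
        t.contrast = float(rng.uniform(-cfg.contrast_limit, cfg.contrast_limit))
    if cfg.p_elastic > 0 and rng.random() < cfg.p_elastic:
        t.displacement = _elastic_displacement(shape, cfg, rng)
    return t


def augment_pair(image: np.ndarray, mask: np.ndarray, cfg: AugmentConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw one transform and apply it to both members of the pair."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask dimensions differ")
    t = draw_transform(mask.shape, cfg, rng)
    return t.apply_image(image), t.apply_mask(mask)
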