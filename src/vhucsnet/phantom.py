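"""Synthetic organ-with-mass phantoms.

Each phantom is a grayscale slice containing an elliptical "organ" with a
brighter disc-shaped "mass" attached to (protruding from) the organ
boundary, plus the paired organ and mass ground-truth masks.  The three
tissue classes are piecewise-constant intensities (background 30, organ 110,
mass 190 by default) overlaid with a smooth Gaussian texture field and
independent Gaussian pixel noise, then clipped to [0, 255] and quantized to
8 bits so PNG round-trips are exact.

The organ mask is the union of the ellipse and the mass disc, so the mass is
always contained in the organ — the containment the fusion stage enforces at
prediction time holds in the ground truth by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import SamplePair, save_image, save_mask

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset", "generate_arrays"]


@dataclass
class PhantomSpec:
    image_size: tuple[int, int] = (64, 64)
    organ_axes_range: tuple[tuple[float, float], tuple[float, float]] = (
        (14.0, 22.0), (11.0, 18.0))
    mass_radius_range: tuple[float, float] = (5.0, 9.0)
    mass_on_boundary: bool = True
    intensity_bg: float = 30.0
    intensity_organ: float = 110.0
    intensity_mass: float = 190.0
    noise_sd: float = 8.0
    texture_sd: float = 5.0
    channels: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (self.intensity_bg < self.intensity_organ < self.intensity_mass):
            raise ValueError(
                "intensities must satisfy background < organ < mass")
        if self.mass_radius_range[1] >= min(a[0] for a in self.organ_axes_range):
            raise ValueError(
                "max mass radius must be smaller than the min organ semi-axis")
        if self.mass_radius_range[0] < 0:
            raise ValueError("mass radius must be >= 0")


def _filled_ellipse(shape, cy, cx, a, b, theta) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    yr = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
    xr = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
    return ((yr / a) ** 2 + (xr / b) ** 2 <= 1.0).astype(np.uint8)


def _filled_disc(shape, cy, cx, r) -> np.ndarray:
    if r <= 0:
        return np.zeros(shape, dtype=np.uint8)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    return (((yy - cy) ** 2 + (xx - cx) ** 2) <= r * r).astype(np.uint8)


def generate_phantom(spec: PhantomSpec, index: int) -> SamplePair:
    """One phantom, fully determined by (spec.seed, index)."""
    rng = np.random.default_rng((spec.seed, index))
    h, w = spec.image_size
    (a_lo, a_hi), (b_lo, b_hi) = spec.organ_axes_range
    a = rng.uniform(a_lo, a_hi)
    b = rng.uniform(b_lo, b_hi)
    theta = rng.uniform(0.0, np.pi)
    cy = rng.uniform(h / 2 - h / 16, h / 2 + h / 16)
    cx = rng.uniform(w / 2 - w / 16, w / 2 + w / 16)
    ellipse = _filled_ellipse((h, w), cy, cx, a, b, theta)

    r_lo, r_hi = spec.mass_radius_range
    r = rng.uniform(r_lo, r_hi) if r_hi > 0 else 0.0
    phi = rng.uniform(0.0, 2 * np.pi)
    if spec.mass_on_boundary:
        # mass centre on the ellipse contour at parametric angle phi
        ey = a * np.cos(phi) * np.cos(theta) - b * np.sin(phi) * np.sin(theta)
        ex = a * np.cos(phi) * np.sin(theta) + b * np.sin(phi) * np.cos(theta)
        my, mx = cy + ey, cx + ex
    else:
        frac = rng.uniform(0.0, 0.5)
        my = cy + frac * a * np.cos(phi)
        mx = cx + frac * b * np.sin(phi)
    mass = _filled_disc((h, w), my, mx, r)

    organ = np.maximum(ellipse, mass)  # the mass protrudes; organ contains it
    image = np.full((h, w), spec.intensity_bg, dtype=np.float64)
    image[organ == 1] = spec.intensity_organ
    image[mass == 1] = spec.intensity_mass
    if spec.texture_sd > 0:
        from scipy.ndimage import gaussian_filter

        field = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 4.0, mode="reflect")
        sd = field.std()
        if sd > 0:
            image += field / sd * spec.texture_sd
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, (h, w))
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    if spec.channels == 3:
        image = np.repeat(image[:, :, None], 3, axis=2)
    return SamplePair(f"phantom_{index:05d}", image, organ, mass)


def generate_arrays(n: int, spec: PhantomSpec, start: int = 0) -> list[SamplePair]:
    return [generate_phantom(spec, i) for i in range(start, start + n)]


def generate_dataset(n: int, spec: PhantomSpec, out_dir) -> Path:
    """Write n image/organ-mask/mass-mask PNG triples plus a CSV manifest.

    The layout mirrors what :func:`vhucsnet.data_io.load_pairs` expects.
    Returns the manifest path.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    for sub in ("images", "masks", "mass_masks"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        pair = generate_phantom(spec, i)
        save_image(out_dir / "images" / f"{pair.id}.png", pair.image)
        save_mask(out_dir / "masks" / f"{pair.id}.png", pair.mask)
        save_mask(out_dir / "mass_masks" / f"{pair.id}.png", pair.mass_mask)
        rows.append({"id": pair.id,
                     "organ_area": int(pair.mask.sum()),
                     "mass_area": int(pair.mass_mask.sum())})
    manifest = out_dir / "manifest.csv"
    frame = pd.DataFrame(rows)
    for key, value in vars(spec).items():
        frame[f"spec_{key}"] = str(value)
    frame.to_csv(manifest, index=False)
    return manifest
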