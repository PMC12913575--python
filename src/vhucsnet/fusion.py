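"""Fusing the organ and mass masks into one labeled segmentation.

The final raster uses three labels — 0 background, 1 organ, 2 mass — with
the containment guarantee mass ⊆ organ: a pixel is labeled mass only where
both tracks agree it lies inside the organ, and mass predictions falling
outside the organ are suppressed as misclassifications.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

__all__ = ["fuse_masks", "decompose_labels", "save_labeled_mask",
           "save_overlay", "LABEL_BACKGROUND", "LABEL_ORGAN", "LABEL_MASS"]

LABEL_BACKGROUND, LABEL_ORGAN, LABEL_MASS = 0, 1, 2


def fuse_masks(organ: np.ndarray, mass: np.ndarray) -> np.ndarray:
    """Pixelwise overlay: 2 where organ & mass, 1 where organ only, else 0."""
    organ = np.asarray(organ)
    mass = np.asarray(mass)
    if organ.shape != mass.shape:
        raise ValueError(f"mask shapes differ: {organ.shape} vs {mass.shape}")
    labels = (organ > 0).astype(np.uint8)
    labels[(organ > 0) & (mass > 0)] = LABEL_MASS
    return labels


def decompose_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`fuse_masks`: (organ, mass) binary layers."""
    labels = np.asarray(labels)
    organ = (labels >= LABEL_ORGAN).astype(np.uint8)
    mass = (labels == LABEL_MASS).astype(np.uint8)
    return organ, mass


def save_labeled_mask(path, labels: np.ndarray):
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1, 2)).all():
        raise ValueError("labels must be in {0, 1, 2}")
    Image.fromarray(labels.astype(np.uint8)).save(path)


def save_overlay(path, image: np.ndarray, labels: np.ndarray):
    """Color overlay: organ contour in green, mass filled in red."""
    from scipy import ndimage

    image = np.asarray(image)
    if image.ndim == 2:
        rgb = np.repeat(image[:, :, None], 3, axis=2).astype(np.float64)
    else:
        rgb = image.astype(np.float64)
    rgb = np.clip(rgb, 0, 255)
    organ, mass = decompose_labels(labels)
    contour = organ.astype(bool) & ~ndimage.binary_erosion(
        organ.astype(bool), ndimage.generate_binary_structure(2, 1),
        border_value=0)
    rgb[contour] = (0.0, 220.0, 0.0)
    mass_b = mass.astype(bool)
    rgb[mass_b] = 0.5 * rgb[mass_b] + 0.5 * np.array([255.0, 0.0, 0.0])
    Image.fromarray(rgb.astype(np.uint8)).save(path)
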