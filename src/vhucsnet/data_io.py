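"""Dataset I/O: paired image/mask loading, PNG round-trips, and the
deterministic train/val/test split.

Datasets are mirrored folders of 8-bit PNGs pairing by filename stem:

    images/<id>.png   masks/<id>.png   [mass_masks/<id>.png]

Masks are binarized on load (any pixel > 0 is foreground).  The split rule
computes ``n_train = floor(n * (1 - r_val - r_test))`` and divides the
remainder proportionally between validation (floor) and test (rest), which
is exact for the usual 80/10/10 protocol on any n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "SamplePair", "SplitSpec", "SplitResult", "load_pairs", "load_image",
    "load_mask", "save_image", "save_mask", "split_dataset", "split_ids",
    "write_manifest", "read_manifest", "load_nifti_slices",
]


@dataclass
class SamplePair:
    """One image with its organ mask and (optionally) mass mask.

    image: (H, W) or (H, W, C) array in the raw [0, 255] range.
    mask / mass_mask: (H, W) arrays over {0, 1}.
    """

    id: str
    image: np.ndarray
    mask: np.ndarray
    mass_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"{self.id}: image {self.image.shape[:2]} and mask "
                f"{self.mask.shape} dimensions differ"
            )
        if self.mass_mask is not None and self.mass_mask.shape != self.mask.shape:
            raise ValueError(f"{self.id}: mass mask dimensions differ")


@dataclass
class SplitSpec:
    r_val: float = 0.1
    r_test: float = 0.1
    shuffle_seed: int = 0

    def __post_init__(self):
        if not (0 < self.r_val < 1 and 0 < self.r_test < 1):
            raise ValueError("split ratios must lie in (0, 1)")
        if self.r_val + self.r_test >= 1:
            raise ValueError("r_val + r_test must be < 1")


@dataclass
class SplitResult:
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]


def load_image(path: Path) -> np.ndarray:
    img = Image.open(path)
    if img.mode not in ("L", "RGB"):
        img = img.convert("RGB" if "A" in img.mode or img.mode == "P" else "L")
    return np.asarray(img)


def load_mask(path: Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 0).astype(np.uint8)


def save_image(path: Path, image: np.ndarray):
    arr = np.clip(np.round(np.asarray(image)), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def save_mask(path: Path, mask: np.ndarray):
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask values must be in {0, 1}")
    Image.fromarray((arr * 255).astype(np.uint8)).save(path)


def load_pairs(image_dir, mask_dir, mass_dir=None) -> list[SamplePair]:
    """Load matched PNG pairs in lexicographic id order.

    Orphans (an image without a mask or vice versa) and pairs with unequal
    dimensions are rejected with a diagnostic naming the offending id.
    """
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    images = {p.stem: p for p in sorted(image_dir.glob("*.png"))}
    masks = {p.stem: p for p in sorted(mask_dir.glob("*.png"))}
    orphans = sorted(set(images) ^ set(masks))
    if orphans:
        raise FileNotFoundError(
            f"unpaired ids (present in only one of {image_dir.name}/"
            f"{mask_dir.name}): {orphans}"
        )
    mass = {}
    if mass_dir is not None:
        mass = {p.stem: p for p in sorted(Path(mass_dir).glob("*.png"))}
    pairs = []
    for sid in sorted(images):
        image = load_image(images[sid])
        mask = load_mask(masks[sid])
        if image.shape[:2] != mask.shape:
            raise ValueError(
                f"{sid}: image {image.shape[:2]} and mask {mask.shape} differ"
            )
        mm = load_mask(mass[sid]) if sid in mass else None
        pairs.append(SamplePair(sid, image, mask, mm))
    return pairs


def _floor_stable(x: float) -> int:
    """floor() robust to values like 8012.0 represented as 8011.9999...9."""
    nearest = round(x)
    if math.isclose(x, nearest, rel_tol=0.0, abs_tol=1e-9 * max(1.0, abs(x))):
        return int(nearest)
    return int(math.floor(x))


def split_dataset(n: int, spec: SplitSpec) -> tuple[int, int, int]:
    """Partition sizes for an n-sample dataset.

    train = floor(n*(1 - r_val - r_test)); the remainder is divided
    proportionally, validation taking the floor and test the rest.
    """
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    n_train = _floor_stable(n * (1.0 - spec.r_val - spec.r_test))
    remainder = n - n_train
    n_val = _floor_stable(remainder * spec.r_val / (spec.r_val + spec.r_test))
    n_test = remainder - n_val
    for name, count in (("train", n_train), ("val", n_val), ("test", n_test)):
        if count <= 0:
            raise ValueError(
                f"{name} partition would be empty for n={n} with "
                f"r_val={spec.r_val}, r_test={spec.r_test}"
            )
    return n_train, n_val, n_test


def split_ids(ids: list[str], spec: SplitSpec,
              groups: list[str] | None = None) -> SplitResult:
    """Shuffle ids with the spec seed, then assign by the split-count rule.

    If `groups` is given (e.g. patient ids), whole groups are kept in one
    subset: groups are shuffled and assigned greedily until each subset
    reaches its sample quota.
    """
    rng = np.random.default_rng(spec.shuffle_seed)
    if groups is None:
        order = list(np.array(ids, dtype=object)[rng.permutation(len(ids))])
        n_train, n_val, _ = split_dataset(len(ids), spec)
        return SplitResult(order[:n_train],
                           order[n_train:n_train + n_val],
                           order[n_train + n_val:])
    if len(groups) != len(ids):
        raise ValueError("groups must parallel ids")
    by_group: dict[str, list[str]] = {}
    for sid, grp in zip(ids, groups):
        by_group.setdefault(grp, []).append(sid)
    names = sorted(by_group)
    names = list(np.array(names, dtype=object)[rng.permutation(len(names))])
    n_train, n_val, _ = split_dataset(len(ids), spec)
    out: list[list[str]] = [[], [], []]
    quotas = [n_train, n_train + n_val, len(ids)]
    bucket = 0
    placed = 0
    for name in names:
        members = by_group[name]
        while bucket < 2 and placed >= quotas[bucket]:
            bucket += 1
        out[bucket].extend(members)
        placed += len(members)
    return SplitResult(*out)


def write_manifest(path: Path, split: SplitResult):
    rows = (
        [{"id": i, "subset": "train"} for i in split.train_ids]
        + [{"id": i, "subset": "val"} for i in split.val_ids]
        + [{"id": i, "subset": "test"} for i in split.test_ids]
    )
    pd.DataFrame(rows, columns=["id", "subset"]).to_csv(path, index=False)


def read_manifest(path: Path) -> SplitResult:
    df = pd.read_csv(path, dtype=str)
    return SplitResult(
        df.loc[df.subset == "train", "id"].tolist(),
        df.loc[df.subset == "val", "id"].tolist(),
        df.loc[df.subset == "test", "id"].tolist(),
    )


def load_nifti_slices(image_path, mask_path=None, axis: int = 2):
    """Adapter: slice a NIfTI volume (and optional mask volume) into 2-D
    SamplePairs along `axis` (default axial)."""
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(image_path)).dataobj)
    lo, hi = float(vol.min()), float(vol.max())
    scaled = (vol - lo) / (hi - lo) * 255.0 if hi > lo else np.zeros_like(vol)
    mvol = None
    if mask_path is not None:
        mvol = (np.asanyarray(nib.load(str(mask_path)).dataobj) > 0).astype(np.uint8)
        if mvol.shape != vol.shape:
            raise ValueError("image and mask volume shapes differ")
    stem = Path(str(image_path)).name.split(".")[0]
    pairs = []
    for k in range(vol.shape[axis]):
        img = np.take(scaled, k, axis=axis)
        msk = (np.take(mvol, k, axis=axis) if mvol is not None
               else np.zeros(img.shape, dtype=np.uint8))
        pairs.append(SamplePair(f"{stem}_{k:04d}", img, msk))
    return pairs
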