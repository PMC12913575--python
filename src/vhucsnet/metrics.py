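"""Segmentation evaluation: overlap, boundary-distance and aggregate statistics.

Overlap metrics use the epsilon-smoothed Dice similarity coefficient

    DSC = (2 |P ∩ G| + eps) / (|P| + |G| + eps)

and the Jaccard index IoU = (|P ∩ G| + eps) / (|P ∪ G| + eps), which are
related by DSC = 2*IoU / (1 + IoU) at eps = 0.  The training objective is
``dice_loss = 1 - soft DSC`` with real-valued (probability) intersections.

Boundary metrics (HD95, ASSD) are computed on the 4-connectivity erosion
residue of each mask with Euclidean distances, optionally scaled by a pixel
spacing; HD95 is the 95th percentile of the pooled directed nearest-boundary
distances, ASSD the mean of the two directed average surface distances.

Aggregates follow the mean +/- SD [95% CI] convention with a fixed normal
multiplier of 1.96 and the population SD formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "MetricConfig", "MetricsReport", "dice", "dice_loss", "iou",
    "hd95", "assd", "confusion_counts", "aggregate_report", "evaluate_masks",
]


@dataclass
class MetricConfig:
    epsilon: float = 1e-6
    hd_percentile: float = 95.0
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    empty_sentinel: bool = False
    """If True, boundary metrics return 0.0 when both masks are empty
    instead of raising."""

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0 < self.hd_percentile <= 100:
            raise ValueError("hd_percentile must be in (0, 100]")


def _check_pair(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    return pred.astype(bool), gt.astype(bool)


def dice(pred, gt, cfg: MetricConfig | None = None) -> float:
    cfg = cfg or MetricConfig()
    p, g = _check_pair(pred, gt)
    inter = np.logical_and(p, g).sum()
    return float((2.0 * inter + cfg.epsilon) / (p.sum() + g.sum() + cfg.epsilon))


def iou(pred, gt, cfg: MetricConfig | None = None) -> float:
    cfg = cfg or MetricConfig()
    p, g = _check_pair(pred, gt)
    inter = np.logical_and(p, g).sum()
    union = np.logical_or(p, g).sum()
    return float((inter + cfg.epsilon) / (union + cfg.epsilon))


def dice_loss(pred_prob, gt, cfg: MetricConfig | None = None) -> float:
    """1 - soft Dice with real-valued intersection |P.G| = sum(p*g)."""
    cfg = cfg or MetricConfig()
    p = np.asarray(pred_prob, dtype=np.float64)
    g = np.asarray(gt, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shapes differ: {p.shape} vs {g.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    soft = (2.0 * (p * g).sum() + cfg.epsilon) / (p.sum() + g.sum() + cfg.epsilon)
    return float(1.0 - soft)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """4-connectivity erosion residue: mask minus its interior."""
    struct = ndimage.generate_binary_structure(2, 1)
    interior = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return mask & ~interior

def _directed_distances(a: np.ndarray, b: np.ndarray,
                        spacing: tuple[float, float]) -> np.ndarray:
    """For each boundary pixel of `a`, distance to the nearest boundary pixel
    of `b` (Euclidean, spacing-scaled), via a distance transform of ~b."""
    dt = ndimage.distance_transform_edt(~b, sampling=spacing)
    return dt[a]


def _surface_distance_sets(pred, gt, cfg: MetricConfig):
    p, g = _check_pair(pred, gt)
    if not p.any() or not g.any():
        if cfg.empty_sentinel and not p.any() and not g.any():
            return None
        raise ValueError("boundary metrics require non-empty masks")
    bp, bg = _boundary(p), _boundary(g)
    d_pg = _directed_distances(bp, bg, cfg.pixel_spacing)
    d_gp = _directed_distances(bg, bp, cfg.pixel_spacing)
    return d_pg, d_gp


def hd95(pred, gt, cfg: MetricConfig | None = None) -> float:
    cfg = cfg or MetricConfig()
    sets = _surface_distance_sets(pred, gt, cfg)
    if sets is None:
        return 0.0
    d_pg, d_gp = sets
    return float(np.percentile(np.concatenate([d_pg, d_gp]), cfg.hd_percentile))


def assd(pred, gt, cfg: MetricConfig | None = None) -> float:
    cfg = cfg or MetricConfig()
    sets = _surface_distance_sets(pred, gt, cfg)
    if sets is None:
        return 0.0
    d_pg, d_gp = sets
    return float((d_pg.mean() + d_gp.mean()) / 2.0)


def confusion_counts(pred, gt) -> tuple[int, int, int, int]:
    """Pixelwise (TP, FP, FN, TN)."""
    p, g = _check_pair(pred, gt)
    tp = int(np.logical_and(p, g).sum())
    fp = int(np.logical_and(p, ~g).sum())
    fn = int(np.logical_and(~p, g).sum())
    tn = int(np.logical_and(~p, ~g).sum())
    return tp, fp, fn, tn


def aggregate_report(values) -> tuple[float, float, float, float]:
    """(mean, population SD, mean - 1.96 SD, mean + 1.96 SD)."""
    values = np.asarray(list(values), dtype=np.float64)
    if values.size == 0:
        raise ValueError("aggregate_report needs at least one value")
    m = float(values.mean())
    sd = float(values.std(ddof=0))
    return m, sd, m - 1.96 * sd, m + 1.96 * sd


@dataclass
class MetricsReport:
    """Per-sample metrics plus mean +/- SD [95% CI] aggregates and pooled
    pixel confusion counts."""

    ids: list[str] = field(default_factory=list)
    per_sample: dict[str, list[float]] = field(
        default_factory=lambda: {"dice": [], "iou": [], "hd95": [], "assd": []}
    )
    confusion: tuple[int, int, int, int] = (0, 0, 0, 0)

    def aggregates(self) -> dict[str, tuple[float, float, float, float]]:
        return {
            name: aggregate_report(vals)
            for name, vals in self.per_sample.items()
            if vals and all(np.isfinite(vals))
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"id": self.ids, **self.per_sample})

    def summary_dict(self) -> dict:
        out: dict = {"confusion": dict(zip(("TP", "FP", "FN", "TN"), self.confusion))}
        for name, (m, sd, lo, hi) in self.aggregates().items():
            out[name] = {"mean": m, "sd": sd, "ci_low": lo, "ci_high": hi}
        return out


def evaluate_masks(pred_masks, gt_masks, ids=None,
                   cfg: MetricConfig | None = None) -> MetricsReport:
    """Score a sequence of predicted masks against ground truth."""
    cfg = cfg or MetricConfig(empty_sentinel=True)
    report = MetricsReport()
    tp = fp = fn = tn = 0
    for k, (p, g) in enumerate(zip(pred_masks, gt_masks)):
        report.ids.append(ids[k] if ids is not None else str(k))
        report.per_sample["dice"].append(dice(p, g, cfg))
        report.per_sample["iou"].append(iou(p, g, cfg))
        try:
            report.per_sample["hd95"].append(hd95(p, g, cfg))
            report.per_sample["assd"].append(assd(p, g, cfg))
        except ValueError:
            report.per_sample["hd95"].append(float("nan"))
            report.per_sample["assd"].append(float("nan"))
        c = confusion_counts(p, g)
        tp, fp, fn, tn = tp + c[0], fp + c[1], fn + c[2], tn + c[3]
    report.confusion = (tp, fp, fn, tn)
    return report
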