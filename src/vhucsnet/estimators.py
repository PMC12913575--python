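"""scikit-learn-style estimators wrapping the two tracks and their fusion.

`OrganSegmenter` (transformer-enhanced U-Net) and `MassDetector`
(contrast-optimized PDN) are binary segmenters with the usual
fit/predict/predict_proba surface over image arrays; `DualTrackSegmenter`
composes them sequentially — it trains the organ track first, builds the
mass track's inputs by masking each image with the *predicted* organ mask
(ground-truth organ masks are never on the mass track's inference path),
and fuses the two predictions into a labeled raster (0 background, 1 organ,
2 mass) with mass-inside-organ suppression.

X is an (n, H, W) or (n, H, W, C) array of raw-range [0, 255] images; y is
an (n, H, W) binary mask array for the single-track estimators and an
(n, H, W) {0, 1, 2} labeled array for the dual-track one.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import fusion, metrics
from .augment import AugmentConfig
from .cond_pdn import PDN, PDNConfig
from .preprocess import PreprocessConfig, enhance_contrast, mask_kidney_image
from .train import TrainConfig, predict_prob, train_model
from .vhu_net import VHUNet, VHUNetConfig, count_parameters, model_size_mib

__all__ = ["OrganSegmenter", "MassDetector", "DualTrackSegmenter"]


def _as_image_array(X) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim not in (3, 4):
        raise ValueError("X must be (n, H, W) or (n, H, W, C)")
    return X


class _TrackMixin:
    """Shared fit plumbing for the two single-track estimators."""

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            epochs=self.epochs, seed=self.seed, augment=self.augment,
            r_val=self.r_val,
        )

    def _preprocess_all(self, X: np.ndarray) -> np.ndarray:
        if not self.preprocess:
            return np.asarray(X, dtype=np.float32)
        cfg = PreprocessConfig(target_size=tuple(self.input_size))
        return np.stack([enhance_contrast(img, cfg) for img in X]).astype(np.float32)

    def _fit_track(self, model, X, y):
        X = _as_image_array(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        Xp = self._preprocess_all(X)
        if self.r_val > 0 and len(Xp) >= 10:
            # internal holdout for best-checkpoint selection
            n_val = max(1, int(round(len(Xp) * self.r_val)))
            order = np.random.default_rng(self.seed).permutation(len(Xp))
            val_idx, tr_idx = order[:n_val], order[n_val:]
        else:
            tr_idx, val_idx = np.arange(len(Xp)), np.array([], dtype=int)
        self.history_ = train_model(
            model, Xp[tr_idx], y[tr_idx], self._train_config(),
            Xp[val_idx] if len(val_idx) else None,
            y[val_idx] if len(val_idx) else None,
            augment_cfg=AugmentConfig(seed=self.seed) if self.augment else None,
            threshold=self.threshold,
        )
        self.model_ = model
        self.n_parameters_ = count_parameters(model)
        self.size_mib_ = model_size_mib(self.n_parameters_)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = _as_image_array(X)
        return predict_prob(self.model_, self._preprocess_all(X),
                            batch_size=min(self.batch_size, 16))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) > self.threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean Dice of thresholded predictions against y."""
        pred = self.predict(X)
        return float(np.mean([metrics.dice(p, g) for p, g in zip(pred, y)]))


class OrganSegmenter(_TrackMixin, BaseEstimator):
    """Transformer-enhanced U-Net organ segmenter.

    Defaults are the CPU desk preset (64x64 single-channel input, widths
    divided by 4); pass ``input_size=(224, 224), in_channels=3,
    width_divisor=1, attn_token_limit=4096`` for the full-scale
    configuration.
    """

    def __init__(self, input_size=(64, 64), in_channels=1, width_divisor=4,
                 patch_size=2, attn_token_limit=256, epochs=10, batch_size=16,
                 learning_rate=1e-3, augment=True, r_val=0.1, threshold=0.5,
                 preprocess=True, seed=0):
        self.input_size = input_size
        self.in_channels = in_channels
        self.width_divisor = width_divisor
        self.patch_size = patch_size
        self.attn_token_limit = attn_token_limit
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.augment = augment
        self.r_val = r_val
        self.threshold = threshold
        self.preprocess = preprocess
        self.seed = seed

    def fit(self, X, y):
        cfg = VHUNetConfig(
            input_size=tuple(self.input_size), in_channels=self.in_channels,
            patch_size=self.patch_size, width_divisor=self.width_divisor,
            attn_token_limit=self.attn_token_limit,
        )
        self.config_ = cfg
        return self._fit_track(VHUNet(cfg, seed=self.seed), X, y)


class MassDetector(_TrackMixin, BaseEstimator):
    """Contrast-optimized PDN mass segmenter.

    Expects masked images (image x organ mask); in the dual-track pipeline
    those are produced from organ-track predictions.  Contrast enhancement
    is off by default because its input was already preprocessed upstream.
    """

    def __init__(self, input_size=(64, 64), in_channels=1, width_divisor=4,
                 pool_stages=3, epochs=10, batch_size=16, learning_rate=1e-3,
                 augment=True, r_val=0.1, threshold=0.5, preprocess=False,
                 seed=0):
        self.input_size = input_size
        self.in_channels = in_channels
        self.width_divisor = width_divisor
        self.pool_stages = pool_stages
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.augment = augment
        self.r_val = r_val
        self.threshold = threshold
        self.preprocess = preprocess
        self.seed = seed

    def fit(self, X, y):
        cfg = PDNConfig(
            in_channels=self.in_channels, input_size=tuple(self.input_size),
            width_divisor=self.width_divisor, pool_stages=self.pool_stages,
            threshold=self.threshold,
        )
        self.config_ = cfg
        return self._fit_track(PDN(cfg, seed=self.seed), X, y)


class DualTrackSegmenter(BaseEstimator):
    """Sequential dual-track pipeline: organ track, predicted-mask gating,
    mass track, and label fusion.

    fit(X, y) takes labeled masks y over {0 background, 1 organ, 2 mass};
    the organ target is y >= 1 and the mass target y == 2.  predict(X)
    returns labeled masks with the mass ⊆ organ guarantee.
    """

    def __init__(self, input_size=(64, 64), in_channels=1, width_divisor=4,
                 epochs=10, batch_size=16, learning_rate=1e-3, augment=True,
                 r_val=0.1, threshold=0.5, mass_threshold=0.5, seed=0):
        self.input_size = input_size
        self.in_channels = in_channels
        self.width_divisor = width_divisor
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.augment = augment
        self.r_val = r_val
        self.threshold = threshold
        self.mass_threshold = mass_threshold
        self.seed = seed

    def _shared(self) -> dict:
        return dict(input_size=self.input_size, in_channels=self.in_channels,
                    width_divisor=self.width_divisor, epochs=self.epochs,
                    batch_size=self.batch_size,
                    learning_rate=self.learning_rate, augment=self.augment,
                    r_val=self.r_val, seed=self.seed)

    def _masked_inputs(self, X) -> np.ndarray:
        """Mass-track inputs: preprocessed image x *predicted* organ mask."""
        organ_pred = self.organ_.predict(X)
        Xp = self.organ_._preprocess_all(_as_image_array(X))
        masked = np.stack([
            mask_kidney_image(img, m) for img, m in zip(Xp, organ_pred)
        ]).astype(np.float32)
        self.last_mass_input_source_ = "predicted-organ-mask"
        return masked

    def fit(self, X, y):
        y = np.asarray(y)
        if not np.isin(y, (0, 1, 2)).all():
            raise ValueError("y must be labeled masks over {0, 1, 2}")
        if (y == 2).sum() == 0:
            raise ValueError(
                "no mass pixels in y; generate phantoms with mass masks or "
                "provide mass annotations")
        organ_gt = (y >= 1).astype(np.uint8)
        mass_gt = (y == 2).astype(np.uint8)
        self.organ_ = OrganSegmenter(threshold=self.threshold,
                                     **self._shared()).fit(X, organ_gt)
        masked = self._masked_inputs(X)
        self.mass_ = MassDetector(threshold=self.mass_threshold,
                                  **self._shared()).fit(masked, mass_gt)
        return self

    def predict_components(self, X) -> tuple[np.ndarray, np.ndarray]:
        """(organ masks, mass masks) before fusion."""
        organ = self.organ_.predict(X)
        mass = self.mass_.predict(self._masked_inputs(X))
        return organ, mass

    def predict(self, X) -> np.ndarray:
        organ, mass = self.predict_components(X)
        return np.stack([fusion.fuse_masks(o, m) for o, m in zip(organ, mass)])

    def score(self, X, y) -> float:
        """Mean of organ and mass Dice on fused predictions."""
        rep = self.evaluate(X, y)
        return float((rep["organ"].aggregates()["dice"][0]
                      + rep["mass"].aggregates()["dice"][0]) / 2.0)

    def save(self, directory) -> None:
        """Write organ.npz / mass.npz checkpoints plus a text summary."""
        from pathlib import Path

        from .train import save_checkpoint, summarize_checkpoint

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_checkpoint(directory / "organ.npz", self.organ_.model_,
                        "vhu_net", self.organ_.config_)
        save_checkpoint(directory / "mass.npz", self.mass_.model_,
                        "cond_pdn", self.mass_.config_)
        lines = [summarize_checkpoint(directory / f"{k}.npz")
                 for k in ("organ", "mass")]
        (directory / "summary.txt").write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, directory, **params) -> "DualTrackSegmenter":
        """Rebuild a fitted estimator from checkpoints written by save()."""
        from pathlib import Path

        from .train import load_checkpoint

        directory = Path(directory)
        kind_o, ocfg, ostate = load_checkpoint(directory / "organ.npz")
        kind_m, mcfg, mstate = load_checkpoint(directory / "mass.npz")
        if (kind_o, kind_m) != ("vhu_net", "cond_pdn"):
            raise ValueError(
                f"unexpected checkpoint kinds {kind_o}/{kind_m}")
        vcfg = VHUNetConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in ocfg.items()})
        pcfg = PDNConfig(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in mcfg.items()})
        est = cls(input_size=vcfg.input_size, in_channels=vcfg.in_channels,
                  width_divisor=vcfg.width_divisor,
                  mass_threshold=pcfg.threshold, **params)
        organ = OrganSegmenter(input_size=vcfg.input_size,
                               in_channels=vcfg.in_channels,
                               width_divisor=vcfg.width_divisor,
                               attn_token_limit=vcfg.attn_token_limit,
                               threshold=est.threshold, seed=est.seed)
        organ.config_ = vcfg
        organ.model_ = VHUNet(vcfg, seed=est.seed)
        organ.model_.load_state_dict(ostate)
        organ.model_.eval()
        mass = MassDetector(input_size=pcfg.input_size,
                            in_channels=pcfg.in_channels,
                            width_divisor=pcfg.width_divisor,
                            pool_stages=pcfg.pool_stages,
                            threshold=pcfg.threshold, seed=est.seed)
        mass.config_ = pcfg
        mass.model_ = PDN(pcfg, seed=est.seed)
        mass.model_.load_state_dict(mstate)
        mass.model_.eval()
        est.organ_, est.mass_ = organ, mass
        return est

    def evaluate(self, X, y) -> dict[str, metrics.MetricsReport]:
        """MetricsReports for the fused organ (label >= 1) and mass
        (label == 2) layers against labeled ground truth."""
        y = np.asarray(y)
        labels = self.predict(X)
        out = {}
        for name, (pred, gt) in {
            "organ": (labels >= 1, y >= 1),
            "mass": (labels == 2, y == 2),
        }.items():
            out[name] = metrics.evaluate_masks(
                pred.astype(np.uint8), gt.astype(np.uint8),
                cfg=metrics.MetricConfig(empty_sentinel=True))
        return out
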