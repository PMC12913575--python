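"""Training loop, history bookkeeping and checkpoints.

Both tracks train identically: Adam on the epsilon-smoothed soft Dice loss,
per-epoch validation, and best-checkpoint selection by validation Dice.
All randomness (shuffling, augmentation draws) flows from one seeded
generator, so a fixed seed reproduces a run bitwise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import metrics
from .augment import AugmentConfig, augment_pair
from .autodiff import Tensor, no_grad
from .layers import Module
from .optim import Adam

__all__ = ["TrainConfig", "History", "soft_dice_loss", "train_model",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 35
    seed: int = 0
    augment: bool = True
    width_divisor: int = 1
    input_preset: str = "full-224"  # full-224 | full-256 | desk-64
    r_val: float = 0.1
    r_test: float = 0.1

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    val_iou: list[float] = field(default_factory=list)

    def __len__(self):
        return len(self.train_loss)


def soft_dice_loss(prob: Tensor, target: np.ndarray, eps: float = 1e-6) -> Tensor:
    """1 - mean per-sample soft Dice between a probability map tensor
    (N, 1, H, W) and a binary target array of the same shape."""
    t = np.asarray(target, dtype=np.float32)
    inter = (prob * Tensor(t)).sum(axis=(1, 2, 3))
    denom = prob.sum(axis=(1, 2, 3)) + t.sum(axis=(1, 2, 3))
    return (1.0 - (2.0 * inter + eps) / (denom + eps)).mean()


def _forward_prob(model: Module, xb: np.ndarray) -> Tensor:
    out = model(Tensor(xb))
    if isinstance(out, tuple):  # PDN returns (prob, mask)
        out = out[0]
    return out


def train_model(model: Module, images: np.ndarray, masks: np.ndarray,
                cfg: TrainConfig, val_images: np.ndarray | None = None,
                val_masks: np.ndarray | None = None,
                augment_cfg: AugmentConfig | None = None,
                threshold: float = 0.5) -> History:
    """Train in place; returns the history.  Restores the best-validation-
    Dice parameters at the end when a validation set is given.

    `images` are raw-range (n, H, W[, C]) arrays (augmentation operates on
    the raw scale); `masks` are (n, H, W) over {0, 1}.  Rescaling to [0, 1]
    and NCHW conversion happen internally.
    """
    if len(images) == 0:
        raise ValueError("empty dataset")
    if len(images) != len(masks):
        raise ValueError("images and masks counts differ")
    rng = np.random.default_rng(cfg.seed)
    if cfg.augment and augment_cfg is None:
        augment_cfg = AugmentConfig()
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history = History()
    best_dice, best_state = -1.0, None
    n = len(images)
    for _ in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = [], []
            for i in idx:
                img, msk = images[i], masks[i]
                if cfg.augment:
                    img, msk = augment_pair(img, msk, augment_cfg, rng)
                xb.append(img)
                yb.append(msk)
            x = _to_nchw(np.stack(xb)) / np.float32(255.0)
            y = np.stack(yb)[:, None].astype(np.float32)
            prob = _forward_prob(model, x)
            loss = soft_dice_loss(prob, y)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(f"non-finite training loss ({value})")
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(value)
        history.train_loss.append(float(np.mean(epoch_losses)))
        if val_images is not None and len(val_images):
            vloss, vdice, viou = _validate(model, val_images, val_masks,
                                           cfg.batch_size, threshold)
            history.val_loss.append(vloss)
            history.val_dice.append(vdice)
            history.val_iou.append(viou)
            if vdice > best_dice:
                best_dice, best_state = vdice, model.state_dict()
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return history


def _to_nchw(batch: np.ndarray) -> np.ndarray:
    batch = np.asarray(batch, dtype=np.float32)
    if batch.ndim == 3:
        return batch[:, None]
    return np.ascontiguousarray(batch.transpose(0, 3, 1, 2))


def predict_prob(model: Module, images: np.ndarray, batch_size: int = 16,
                 rescaled: bool = False) -> np.ndarray:
    """Probability maps (n, H, W) for raw-range images, in eval mode."""
    model.eval()
    out = []
    for start in range(0, len(images), batch_size):
        x = _to_nchw(np.stack(images[start : start + batch_size]))
        if not rescaled:
            x = x / np.float32(255.0)
        with no_grad():
            prob = _forward_prob(model, x)
        out.append(prob.data[:, 0])
    return np.concatenate(out, axis=0)


def _validate(model, images, masks, batch_size, threshold):
    probs = predict_prob(model, images, batch_size)
    losses = [metrics.dice_loss(p, m) for p, m in zip(probs, masks)]
    pred = (probs > threshold).astype(np.uint8)
    dices = [metrics.dice(p, m) for p, m in zip(pred, masks)]
    ious = [metrics.iou(p, m) for p, m in zip(pred, masks)]
    return float(np.mean(losses)), float(np.mean(dices)), float(np.mean(ious))


# -- checkpoints -------------------------------------------------------------

def save_checkpoint(path, model: Module, kind: str, config) -> None:
    """Single-file archive: parameter/buffer arrays + JSON-encoded config."""
    meta = json.dumps({"kind": kind, "config": asdict(config)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path):
    """Returns (kind, config_dict, state_dict)."""
    with np.load(path) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    return meta["kind"], meta["config"], state


def summarize_checkpoint(path) -> str:
    from .vhu_net import model_size_mib

    kind, cfg, state = load_checkpoint(path)
    count = int(sum(v.size for k, v in state.items() if "running_" not in k))
    return (f"{Path(str(path)).name}: {kind}, {count:,} parameters, "
            f"{model_size_mib(count):.2f} MiB fp32")
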