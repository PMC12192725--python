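"""Training loop: Adam + cosine-annealed learning rate + early stopping.

The schedule is ``lr = lr_min + 0.5 (lr_max - lr_min)(1 + cos(pi e / T))``
evaluated once per epoch.  Early stopping halts when the validation loss
fails to strictly decrease (tolerance 1e-6) for ``patience`` consecutive
epochs; the best-epoch weights, not the last, are kept.  All randomness
(shuffling, augmentation) flows from the single seed in ``TrainConfig``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, no_grad
from .data import AugmentationConfig, DatasetManifest, augment_pair, load_pair, resize_pair
from .losses import LossConfig, combined_loss_t, dice_coefficient
from .model import RMISNet, save_checkpoint
from .nn import Adam

__all__ = [
    "TrainConfig",
    "TrainState",
    "EarlyStopper",
    "cosine_lr",
    "fit",
    "predict_mask",
    "predict_proba",
]


@dataclass(frozen=True)
class TrainConfig:
    lr_max: float = 1e-4
    lr_min: float = 0.0
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 8
    max_epochs: int = 500
    patience: int = 2
    t_max: int | None = None  # defaults to max_epochs
    seed: int = 0
    threshold: float = 0.5
    target_train_dice: float | None = None  # optional convergence stop (overfit demos)

    def __post_init__(self):
        if self.lr_min > self.lr_max:
            raise ValueError("lr_min must not exceed lr_max")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")

    @property
    def effective_t_max(self) -> int:
        return self.max_epochs if self.t_max is None else self.t_max


@dataclass
class TrainState:
    epoch: int = 0
    best_val_loss: float = float("inf")
    best_epoch: int = 0
    epochs_since_improvement: int = 0
    history: list[dict] = field(default_factory=list)
    best_weights: dict | None = None
    best_norm_stats: dict | None = None


class EarlyStopper:
    """Strict-decrease early stopping with best-epoch bookkeeping."""

    def __init__(self, patience: int = 2, tol: float = 1e-6):
        self.patience = patience
        self.tol = tol
        self.best = float("inf")
        self.best_epoch = 0
        self.since = 0
        self.epoch = 0

    def update(self, loss: float) -> bool:
        """Record one epoch's validation loss; return True to stop."""
        self.epoch += 1
        if loss < self.best - self.tol:
            self.best = loss
            self.best_epoch = self.epoch
            self.since = 0
            return False
        self.since += 1
        return self.since >= self.patience


def cosine_lr(epoch: int, config: TrainConfig) -> float:
    """Cosine-annealed learning rate at a given (0-based) epoch."""
    t_max = config.effective_t_max
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    if epoch > t_max:
        return config.lr_min
    return config.lr_min + 0.5 * (config.lr_max - config.lr_min) * (
        1.0 + np.cos(epoch / t_max * np.pi)
    )


# ---------------------------------------------------------------------------
# inference helpers
# ---------------------------------------------------------------------------

def predict_proba(model: RMISNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel foreground probability (logistic transform of logits)."""
    batched = image.ndim == 4
    x = image if batched else image[None]
    was_training = model.training
    model.eval()
    with no_grad():
        logits = model(Tensor(np.asarray(x, dtype=np.float32)))
        probs = logits.sigmoid().data
    if was_training:
        model.train()
    return probs if batched else probs[0]


def predict_mask(model: RMISNet, image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary mask: 1 where probability strictly exceeds the threshold.

    The tie (probability exactly equal to the threshold, e.g. logit 0 at
    threshold 0.5) maps to background.
    """
    probs = predict_proba(model, image)
    return (probs > threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _load_split(manifest: DatasetManifest, split: str, image_size):
    images, masks = [], []
    for rec in manifest.subset(split):
        img_path, mask_path = manifest.resolve(rec)
        image, mask = load_pair(img_path, mask_path)
        if image_size is not None:
            image, mask = resize_pair(image, mask, image_size)
        images.append(image)
        masks.append(mask)
    return images, masks


def _epoch_loss(model, images, masks, loss_config, batch_size) -> float:
    """Mean over batches of the compound loss, in evaluation mode."""
    model.eval()
    losses = []
    with no_grad():
        for start in range(0, len(images), batch_size):
            x = np.stack(images[start : start + batch_size])
            y = np.stack(masks[start : start + batch_size])[:, None]
            probs = model(Tensor(x)).sigmoid()
            losses.append(float(combined_loss_t(probs, y, loss_config).data))
    model.train()
    return float(np.mean(losses))


def _train_dice(model, images, masks, threshold) -> float:
    scores = []
    for image, mask in zip(images, masks):
        pred = predict_mask(model, image, threshold)[0]
        scores.append(dice_coefficient(pred.astype(float), mask))
    return float(np.mean(scores))


def fit(
    model: RMISNet,
    manifest: DatasetManifest,
    train_config: TrainConfig = TrainConfig(),
    loss_config: LossConfig = LossConfig(),
    *,
    augment: AugmentationConfig | None = None,
    image_size: tuple[int, int] | None = None,
    out_dir=None,
    log_console: bool = False,
) -> TrainState:
    """Optimise the model on the manifest's train split.

    Per epoch: shuffle, forward, compound loss, Adam step at the cosine
    learning rate; track validation loss, early-stop on ``patience``
    non-improving epochs, and snapshot the best weights.  With ``out_dir``
    the epoch log (CSV), best checkpoint and resolved config are written.
    """
    train_images, train_masks = _load_split(manifest, "train", image_size)
    val_images, val_masks = _load_split(manifest, "val", image_size)
    if not train_images or not val_images:
        raise ValueError("manifest needs nonempty train and val splits")

    rng = np.random.default_rng(np.random.SeedSequence(train_config.seed))
    optimizer = Adam(
        model.parameters(), beta1=train_config.beta1, beta2=train_config.beta2
    )
    stopper = EarlyStopper(patience=train_config.patience)
    state = TrainState()
    log_rows = []
    model.train()

    for epoch in range(train_config.max_epochs):
        lr = cosine_lr(epoch, train_config)
        order = rng.permutation(len(train_images))
        epoch_losses = []
        for bstart in range(0, len(order), train_config.batch_size):
            idx = order[bstart : bstart + train_config.batch_size]
            xs, ys = [], []
            for i in idx:
                image, mask = train_images[i], train_masks[i]
                if augment is not None:
                    image, mask = augment_pair(image, mask, augment, rng)
                xs.append(image)
                ys.append(mask)
            x = Tensor(np.stack(xs).astype(np.float32))
            y = np.stack(ys)[:, None]
            probs = model(x).sigmoid()
            loss = combined_loss_t(probs, y, loss_config)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {bstart // train_config.batch_size}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step(lr)
            epoch_losses.append(float(loss.data))

        train_loss = float(np.mean(epoch_losses))
        val_loss = _epoch_loss(
            model, val_images, val_masks, loss_config, train_config.batch_size
        )
        state.epoch = epoch + 1
        row = {
            "epoch": epoch + 1,
            "lr": lr,
            "train_loss": train_loss,
            "val_loss": val_loss,
        }
        if train_config.target_train_dice is not None:
            row["train_dice"] = _train_dice(
                model, train_images, train_masks, train_config.threshold
            )
        state.history.append(row)
        log_rows.append(row)
        if log_console:
            print(
                f"epoch {epoch + 1:4d}  lr {lr:.2e}  "
                f"train {train_loss:.4f}  val {val_loss:.4f}"
            )
        if val_loss < state.best_val_loss - stopper.tol:
            state.best_val_loss = val_loss
            state.best_epoch = epoch + 1
            state.best_weights = model.state_dict()
            state.best_norm_stats = model.norm_stats()
        stop = stopper.update(val_loss)
        state.epochs_since_improvement = stopper.since
        if (
            train_config.target_train_dice is not None
            and row.get("train_dice", 0.0) >= train_config.target_train_dice
        ):
            break
        if stop:
            break

    if state.best_weights is not None:
        model.load_state_dict(state.best_weights)
        model.load_norm_stats(state.best_norm_stats)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fields = list(log_rows[0].keys())
        with open(out_dir / "training_log.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            for row in log_rows:
                writer.writerow({k: f"{v:.8g}" if k != "epoch" else v for k, v in row.items()})
        save_checkpoint(model, out_dir / "checkpoint.npz")
    return state
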