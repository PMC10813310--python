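"""Training objective, Dice evaluation, and the supervised training loop.

The loss is a multi-class soft Dice with squared-denominator per-class

    D_k = 2 * sum_i p_ik g_ik / (sum_i p_ik^2 + sum_i g_ik^2),

averaged over all six classes (background included), loss = 1 - mean_k D_k;
an epsilon stabilizes classes absent from both prediction and truth.  This
handles the heavy class imbalance of lobe segmentation, where background
dominates and lobes differ in size.  Evaluation uses the hard overlap
DSC = 2 TP / (2 TP + FP + FN) per lobe; for exactly one-hot probabilities
the soft and hard forms coincide.

The training recipe: Xavier initialization, Adam with learning rate 1e-4 and
weight decay 1e-5, learning rate multiplied by 0.96 every 2 epochs, 50
epochs, mini-batches of 16 slices, augmentation on training slices only, and
the checkpoint with the best validation Dice is kept.
"""

from __future__ import annotations

import copy
from dataclasses import asdict, dataclass, field

import numpy as np

from . import augment, nn
from .model import UNet
from .nn.tensor import Tensor
from .volume import N_CLASSES, LabelMap, SliceSample, Volume

EPS = 1e-6


class TrainingDivergenceError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"loss became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclass
class TrainConfig:
    """Hyperparameters of one training run (defaults = the full recipe)."""

    lr0: float = 1e-4
    weight_decay: float = 1e-5
    lr_gamma: float = 0.96
    lr_every: int = 2
    epochs: int = 50
    batch_size: int = 16
    seed: int = 0
    use_ssl: bool = False
    use_attention: bool = False
    augmentation_class: str = "none"

    def validate(self) -> None:
        if self.lr0 <= 0:
            raise ValueError(f"lr0 must be > 0, got {self.lr0}")
        if not 0 < self.lr_gamma <= 1:
            raise ValueError(f"lr_gamma must lie in (0, 1], got {self.lr_gamma}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")


def lr_schedule(epoch: int, lr0: float = 1e-4, gamma: float = 0.96, every: int = 2) -> float:
    """lr(e) = lr0 * gamma ** floor(e / every)."""
    return nn.exponential_decay_lr(epoch, lr0, gamma, every)


def one_hot(mask: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """(..., H, W) int labels -> (..., C, H, W) float32 one-hot."""
    eye = np.eye(n_classes, dtype=np.float32)
    oh = eye[mask]  # (..., H, W, C)
    return np.moveaxis(oh, -1, -3)


def dice_loss(probabilities: Tensor | np.ndarray, onehot_truth: np.ndarray) -> Tensor:
    """1 - mean over the 6 classes of the squared-denominator soft Dice."""
    if not isinstance(probabilities, Tensor):
        probabilities = Tensor(probabilities)
    g = np.asarray(onehot_truth, dtype=probabilities.data.dtype)
    if probabilities.shape != g.shape or probabilities.shape[-3] != N_CLASSES:
        raise ValueError(
            f"probabilities {probabilities.shape} and one-hot truth {g.shape} "
            f"must align with {N_CLASSES} channels"
        )
    axes = tuple(i for i in range(probabilities.ndim) if i != probabilities.ndim - 3)
    gt = Tensor(g)
    inter = (probabilities * gt).sum(axis=axes)
    denom = (probabilities**2).sum(axis=axes) + Tensor((g**2).sum(axis=axes))
    dk = (inter * 2.0 + EPS) / (denom + EPS)
    return 1.0 - dk.mean()


def dsc(pred_labels: np.ndarray, true_labels: np.ndarray, k: int) -> float:
    """Hard Dice 2TP / (2TP + FP + FN) for class k; 1.0 if k absent in both."""
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    if pred_labels.shape != true_labels.shape:
        raise ValueError(f"shape mismatch: {pred_labels.shape} vs {true_labels.shape}")
    p = pred_labels == k
    g = true_labels == k
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    if tp + fp + fn == 0:
        return 1.0  # correctly predicted absence
    return 2.0 * tp / (2.0 * tp + fp + fn)


@dataclass
class EvaluationReport:
    """Per-lobe and mean Dice of one prediction/ground-truth pair (or pool)."""

    per_class_dice: dict[int, float]
    mean_dice: float
    n_instances: int = 1

    def to_dict(self) -> dict:
        return {
            "per_class_dice": {str(k): v for k, v in self.per_class_dice.items()},
            "mean_dice": self.mean_dice,
            "n_instances": self.n_instances,
        }


def evaluate(pred: LabelMap | np.ndarray, truth: LabelMap | np.ndarray) -> EvaluationReport:
    """Per-class DSC for the five lobes and their mean (background excluded)."""
    p = pred.data if isinstance(pred, LabelMap) else np.asarray(pred)
    g = truth.data if isinstance(truth, LabelMap) else np.asarray(truth)
    per_class = {k: dsc(p, g, k) for k in range(1, N_CLASSES)}
    return EvaluationReport(per_class_dice=per_class, mean_dice=float(np.mean(list(per_class.values()))))


def mean_foreground_dice(pred: np.ndarray, truth: np.ndarray) -> float:
    return evaluate(pred, truth).mean_dice


def select_balanced_slices(samples: list[SliceSample], n: int) -> list[SliceSample]:
    """Pick `n` slices greedily maximizing the minimum pooled lobe-class area.

    Small-scale experiments (overfit checks, quick demos) need every lobe
    class represented with substantial area; plain z-subsampling leaves the
    apical/basal lobes nearly absent.  Selection is deterministic.
    """
    if n > len(samples):
        raise ValueError(f"cannot select {n} slices from {len(samples)}")
    areas = np.stack(
        [[(s.mask == k).sum() for k in range(N_CLASSES)] for s in samples]
    ).astype(float)
    picked: list[int] = []
    pool = np.zeros(N_CLASSES)
    for _ in range(n):
        best, best_key = -1, None
        for i in range(len(samples)):
            if i in picked:
                continue
            cand = pool + areas[i]
            key = (cand[1:].min(), cand[1:].sum())
            if best_key is None or key > best_key:
                best, best_key = i, key
        picked.append(best)
        pool += areas[best]
    return [samples[i] for i in sorted(picked)]


@dataclass
class TrainResult:
    best_state: dict[str, np.ndarray]
    best_epoch: int
    best_val_dice: float
    history: list[dict] = field(default_factory=list)
    config: TrainConfig | None = None


def _forward_labels(model: UNet, images: np.ndarray, batch_size: int) -> np.ndarray:
    """Slice-wise argmax prediction for a stack of (1, H, W) images."""
    out = []
    for start in range(0, len(images), batch_size):
        logits = model(Tensor(images[start : start + batch_size]))
        out.append(logits.data.argmax(axis=1))
    return np.concatenate(out, axis=0)


def validation_dice(model: UNet, samples: list[SliceSample], batch_size: int = 16) -> float:
    """Pooled mean foreground Dice of a model over a slice set."""
    was_training = model.training
    model.eval()
    images = np.stack([s.image for s in samples])
    pred = _forward_labels(model, images, batch_size)
    truth = np.stack([s.mask for s in samples])
    model.train(was_training)
    return mean_foreground_dice(pred, truth)


def train(
    model: UNet,
    train_slices: list[SliceSample],
    val_slices: list[SliceSample],
    config: TrainConfig,
    max_steps: int | None = None,
) -> TrainResult:
    """Run the supervised recipe and return the best-on-validation checkpoint.

    Augmentation (per ``config.augmentation_class``) is applied to training
    slices only, re-drawn every epoch.  ``max_steps`` optionally caps the
    total number of optimizer steps for scaled-down runs.
    """
    config.validate()
    if not train_slices or not val_slices:
        raise ValueError("train and validation slice sets must be non-empty")
    ss = np.random.SeedSequence(config.seed)
    order_rng, aug_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    policy = augment.build_policy(config.augmentation_class)
    opt = nn.Adam(model.parameters(), lr=config.lr0, weight_decay=config.weight_decay)
    history: list[dict] = []
    best_state, best_epoch, best_dice = None, -1, -np.inf
    steps = 0
    for epoch in range(config.epochs):
        opt.lr = lr_schedule(epoch, config.lr0, config.lr_gamma, config.lr_every)
        model.train()
        order = order_rng.permutation(len(train_slices))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            if max_steps is not None and steps >= max_steps:
                break
            idx = order[start : start + config.batch_size]
            batch = [train_slices[i] for i in idx]
            if policy.transforms:
                batch = [augment.apply_policy(policy, s, aug_rng) for s in batch]
            images = np.stack([s.image for s in batch])
            masks = np.stack([s.mask for s in batch])
            logits = model(Tensor(images))
            probs = logits.softmax(axis=1)
            loss = dice_loss(probs, one_hot(masks))
            if not np.isfinite(loss.data):
                raise TrainingDivergenceError(epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            steps += 1
            epoch_losses.append(float(loss.data))
        val_dice = validation_dice(model, val_slices, config.batch_size)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)) if epoch_losses else float("nan"),
                "val_dice": val_dice,
                "lr": opt.lr,
                "steps": steps,
            }
        )
        if val_dice > best_dice:
            best_dice, best_epoch = val_dice, epoch
            best_state = copy.deepcopy(model.state_dict())
        if max_steps is not None and steps >= max_steps:
            break
    model.load_state_dict(best_state)
    return TrainResult(
        best_state=best_state,
        best_epoch=best_epoch,
        best_val_dice=float(best_dice),
        history=history,
        config=config,
    )


def predict_volume(model: UNet, volume: Volume, batch_size: int = 16,
                   native_inplane: bool = False) -> LabelMap:
    """Slice-wise segmentation of a normalized volume.

    Each axial slice is resized to the model's input resolution, the per-
    pixel argmax over the six channels is taken, and slices are reassembled
    in order.  With ``native_inplane`` the label slices are resized back to
    the volume's in-plane shape with nearest-neighbor interpolation.
    """
    from skimage.transform import resize

    size = model.config.input_size
    nz, ny, nx = volume.shape
    if volume.data.min() < 0 or volume.data.max() > 1:
        raise ValueError("predict_volume expects a [0, 1]-normalized volume")
    images = np.empty((nz, 1, size, size), dtype=np.float32)
    for k in range(nz):
        sl = volume.data[k]
        if sl.shape != (size, size):
            sl = resize(sl, (size, size), order=1, preserve_range=True, anti_aliasing=False)
        images[k, 0] = np.clip(sl, 0.0, 1.0)
    was_training = model.training
    model.eval()
    labels = _forward_labels(model, images, batch_size).astype(np.uint8)
    model.train(was_training)
    sz, sy, sx = volume.spacing_mm
    if native_inplane and (ny, nx) != (size, size):
        back = np.stack(
            [
                resize(sl, (ny, nx), order=0, preserve_range=True, anti_aliasing=False)
                for sl in labels
            ]
        ).astype(np.uint8)
        return LabelMap(back, volume.spacing_mm, volume.origin, volume.direction)
    spacing = (sz, sy * ny / size, sx * nx / size)
    return LabelMap(labels, spacing, volume.origin, volume.direction)


def history_to_json(result: TrainResult) -> dict:
    return {
        "best_epoch": result.best_epoch,
        "best_val_dice": result.best_val_dice,
        "history": result.history,
        "config": asdict(result.config) if result.config else None,
    }
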