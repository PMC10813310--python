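"""Jigsaw-puzzle self-supervised pretraining for the segmentation encoder.

A 256x256 slice is cut into a 4x4 grid of 64x64 patches, the patches are
permuted, and the network must predict each source patch's board position —
a 16-way classification per patch, trained with cross-entropy and no manual
labels.  The classification head reads the encoder bottleneck (512, 16, 16),
reduces it through five Conv-BatchNorm-ReLU pairs (256, 128, 64, 32, 16
channels), and maps the flattened features through fully connected layers of
widths 512 and 128 (dropout 0.25 each) to a final 256-way output reshaped to
(16, 16) logits: one row per patch, one column per position.  After
pretraining, the encoder weights are transferred into the segmentation
network and the head is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import UNet, UNetConfig
from .nn import functional as F
from .nn.tensor import Tensor

GRID = 4
N_PATCHES = GRID * GRID


class PermutationError(ValueError):
    pass


@dataclass
class JigsawTask:
    """A shuffled image, its grid geometry, and the position targets."""

    shuffled_image: np.ndarray  # (1, H, W)
    grid: tuple[int, int]
    permutation: np.ndarray  # source patch index -> board position
    target: np.ndarray  # per board patch (row-major), its original position


def _check_permutation(permutation: np.ndarray) -> np.ndarray:
    perm = np.asarray(permutation)
    if perm.shape != (N_PATCHES,) or not np.array_equal(np.sort(perm), np.arange(N_PATCHES)):
        raise PermutationError(f"permutation must be a bijection on 0..{N_PATCHES - 1}")
    return perm.astype(np.intp)


def _patches(image: np.ndarray) -> np.ndarray:
    h, w = image.shape
    ph, pw = h // GRID, w // GRID
    return image.reshape(GRID, ph, GRID, pw).transpose(0, 2, 1, 3).reshape(N_PATCHES, ph, pw)


def _assemble(patches: np.ndarray, h: int, w: int) -> np.ndarray:
    ph, pw = h // GRID, w // GRID
    return patches.reshape(GRID, GRID, ph, pw).transpose(0, 2, 1, 3).reshape(h, w)


def make_jigsaw(image: np.ndarray, permutation: np.ndarray) -> JigsawTask:
    """Shuffle a square image's 4x4 patch grid by `permutation`.

    ``permutation[s]`` is the board position receiving source patch ``s``.
    The prediction target lists, for each patch of the *shuffled* image in
    board order, the position it originally came from — i.e. the inverse
    permutation.  (Predicting per-input-patch positions is the standard
    formulation of the pretext: each visible patch is classified by where it
    belongs.)
    """
    perm = _check_permutation(permutation)
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[0]
    h, w = img.shape
    if h % GRID or w % GRID:
        raise ValueError(f"image sides must be divisible by {GRID}, got {(h, w)}")
    src = _patches(img)
    out = np.empty_like(src)
    out[perm] = src
    return JigsawTask(
        shuffled_image=_assemble(out, h, w)[None].copy(),
        grid=(GRID, GRID),
        permutation=perm.copy(),
        target=np.argsort(perm),
    )


def unshuffle(task: JigsawTask) -> np.ndarray:
    """Invert the shuffle; bit-exact reconstruction of the source image."""
    img = task.shuffled_image[0]
    boards = _patches(img)
    return _assemble(boards[task.permutation], *img.shape)[None]


def sample_permutation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random bijection on the 16 patch indices."""
    return rng.permutation(N_PATCHES)


@dataclass
class JigsawHeadConfig:
    """Widths of the patch-position classifier head.

    The default configuration is the published full-scale design: the conv
    reduction stack and a global MLP (512 -> 128 -> 256) over the flattened
    features, reshaped to (16, 16) logits.  For scaled-down encoders
    ``per_patch_readout`` replaces the global MLP with a weight-shared MLP
    applied to each board patch's latent block: the global MLP needs orders
    of magnitude more optimization steps to break the per-patch routing
    symmetry than small-scale budgets allow, while the shared readout is
    position-equivariant by construction and learns in a few hundred steps.
    """

    in_channels: int = 512
    latent_size: int = 16
    conv_widths: tuple[int, ...] = (256, 128, 64, 32, 16)
    fc_widths: tuple[int, ...] = (512, 128)
    dropout: float = 0.25
    per_patch_readout: bool = False

    @classmethod
    def for_unet(cls, config: UNetConfig, **overrides) -> "JigsawHeadConfig":
        """Head sized for an encoder; published design at the full 512 latent,
        proportionally narrowed (with floors) plus per-patch readout below it."""
        c, s, _ = config.latent_shape
        scale = config.encoder_widths[-1] / 512.0
        defaults = cls()
        conv = tuple(max(int(round(w * scale)), 16) for w in defaults.conv_widths)
        fc = tuple(
            max(int(round(w * scale)), floor)
            for w, floor in zip(defaults.fc_widths, (128, 64))
        )
        kwargs = dict(
            in_channels=c,
            latent_size=s,
            conv_widths=conv,
            fc_widths=fc,
            per_patch_readout=scale < 1.0,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


class JigsawHead(nn.Module):
    """Conv reduction stack + dropout-regularized readout onto (16, 16) logits."""

    def __init__(self, config: JigsawHeadConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.rng = np.random.default_rng(rng.integers(2**31))
        prev = config.in_channels
        blocks = []
        for w in config.conv_widths:
            blocks.append(nn.ConvBlock(prev, w, rng))
            prev = w
        self.convs = nn.Sequential(*blocks)
        cell = config.latent_size // GRID  # latent cells per board patch side
        if config.per_patch_readout:
            per_cell = config.conv_widths[-1] * cell * cell
            hidden = max(config.fc_widths[0] // 8, 32)
            self.fc1 = nn.Linear(per_cell, hidden, rng)
            self.fc_out = nn.Linear(hidden, N_PATCHES, rng)
        else:
            flat = config.conv_widths[-1] * config.latent_size**2
            self.fc1 = nn.Linear(flat, config.fc_widths[0], rng)
            self.fc2 = nn.Linear(config.fc_widths[0], config.fc_widths[1], rng)
            self.fc_out = nn.Linear(config.fc_widths[1], N_PATCHES * N_PATCHES, rng)

    def forward(self, latent: Tensor) -> Tensor:
        n = latent.shape[0]
        expected = (self.config.in_channels, self.config.latent_size, self.config.latent_size)
        if tuple(latent.shape[1:]) != expected:
            raise ValueError(f"latent shape {latent.shape[1:]} does not match head input {expected}")
        h = self.convs(latent)
        if self.config.per_patch_readout:
            c, s = h.shape[1], h.shape[2]
            cell = s // GRID
            # (n, C, s, s) -> (n * 16, C * cell * cell), one row per board patch
            blocks = h.reshape(n, c, GRID, cell, GRID, cell).transpose(0, 2, 4, 1, 3, 5)
            blocks = blocks.reshape(n * N_PATCHES, c * cell * cell)
            z = F.dropout(self.fc1(blocks).relu(), self.config.dropout, self.rng, self.training)
            return self.fc_out(z).reshape(n, N_PATCHES, N_PATCHES)
        h = h.reshape(n, -1)
        h = F.dropout(self.fc1(h).relu(), self.config.dropout, self.rng, self.training)
        h = F.dropout(self.fc2(h).relu(), self.config.dropout, self.rng, self.training)
        return self.fc_out(h).reshape(n, N_PATCHES, N_PATCHES)


def jigsaw_forward(encoder: UNet, head: JigsawHead, task: JigsawTask) -> np.ndarray:
    """Forward one task through encoder bottleneck + head; returns (16, 16) logits."""
    x = Tensor(task.shuffled_image[None])
    _, latent = encoder.encode(x)
    return head(latent).data[0]


def jigsaw_loss(logits: Tensor | np.ndarray, target: np.ndarray) -> Tensor:
    """Mean per-patch cross-entropy between row-softmax logits and positions.

    `logits` is (..., 16, 16); `target` the matching (..., 16) integer
    position labels.
    """
    if not isinstance(logits, Tensor):
        logits = Tensor(logits)
    target = np.asarray(target)
    if target.min() < 0 or target.max() >= N_PATCHES:
        raise ValueError("target positions must lie in 0..15")
    logp = logits.log_softmax(axis=-1)
    onehot = np.eye(N_PATCHES, dtype=logits.data.dtype)[target]
    return -(logp * Tensor(onehot)).sum() * (1.0 / target.size)


def patch_accuracy(logits: np.ndarray, target: np.ndarray) -> float:
    return float((logits.argmax(axis=-1) == target).mean())


@dataclass
class PretrainConfig:
    """Pretext-task training settings (shares the segmentation recipe)."""

    epochs: int = 5
    batch_size: int = 16
    lr0: float = 1e-4
    weight_decay: float = 1e-5
    lr_gamma: float = 0.96
    lr_every: int = 2
    seed: int = 0


@dataclass
class PretrainResult:
    encoder_state: dict[str, np.ndarray]
    history: list[dict] = field(default_factory=list)
    eval_accuracy: float = float("nan")

    @property
    def final_accuracy(self) -> float:
        """Patch-position accuracy after training (eval mode, dropout off)."""
        if np.isfinite(self.eval_accuracy):
            return self.eval_accuracy
        return self.history[-1]["patch_accuracy"] if self.history else float("nan")


def pretrain_encoder(
    samples: list,
    unet_config: UNetConfig | None = None,
    config: PretrainConfig | None = None,
    encoder: UNet | None = None,
    head: JigsawHead | None = None,
) -> PretrainResult:
    """Train encoder + jigsaw head on unlabeled slices; labels are never read.

    Returns the trained encoder weights plus per-epoch pretext loss and
    patch-position accuracy.  Deterministic for a fixed seed.
    """
    if not samples:
        raise ValueError("pretraining requires a non-empty slice dataset")
    config = config or PretrainConfig()
    unet_config = unet_config or UNetConfig()
    rng = np.random.default_rng(config.seed)
    if encoder is None:
        encoder = UNet(unet_config, np.random.default_rng(int(rng.integers(2**31))))
    if head is None:
        head = JigsawHead(
            JigsawHeadConfig.for_unet(encoder.config),
            np.random.default_rng(int(rng.integers(2**31))),
        )
    images = [s.image if hasattr(s, "image") else np.asarray(s) for s in samples]
    params = list(encoder.parameters()) + list(head.parameters())
    opt = nn.Adam(params, lr=config.lr0, weight_decay=config.weight_decay)
    history = []
    for epoch in range(config.epochs):
        opt.lr = nn.exponential_decay_lr(epoch, config.lr0, config.lr_gamma, config.lr_every)
        order = rng.permutation(len(images))
        losses, accs = [], []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            tasks = [make_jigsaw(images[i], sample_permutation(rng)) for i in idx]
            batch = np.stack([t.shuffled_image for t in tasks])
            target = np.stack([t.target for t in tasks])
            _, latent = encoder.encode(Tensor(batch))
            logits = head(latent)
            loss = jigsaw_loss(logits, target)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            accs.append(patch_accuracy(logits.data, target))
        history.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "patch_accuracy": float(np.mean(accs)),
                "lr": opt.lr,
            }
        )
    # final accuracy in evaluation mode (dropout off, running batch stats)
    encoder.eval()
    head.eval()
    eval_rng = np.random.default_rng(config.seed + 1)
    correct, total = 0, 0
    for start in range(0, len(images), config.batch_size):
        chunk = images[start : start + config.batch_size]
        tasks = [make_jigsaw(img, sample_permutation(eval_rng)) for img in chunk]
        batch = np.stack([t.shuffled_image for t in tasks])
        target = np.stack([t.target for t in tasks])
        _, latent = encoder.encode(Tensor(batch))
        logits = head(latent)
        correct += int((logits.data.argmax(axis=-1) == target).sum())
        total += target.size
    encoder.train()
    head.train()
    return PretrainResult(
        encoder_state=encoder.encoder_state(),
        history=history,
        eval_accuracy=correct / total,
    )


class TransferError(ValueError):
    pass


def transfer_encoder(pretrained: dict[str, np.ndarray], model: UNet) -> UNet:
    """Copy pretext encoder tensors into a segmentation model, in place.

    Every encoder tensor must match in name and shape; decoder, gates, and
    head are left untouched and the jigsaw head is simply not part of the
    state being transferred.
    """
    own = model.state_dict()
    enc_keys = [k for k in own if k.startswith("enc")]
    missing = [k for k in enc_keys if k not in pretrained]
    if missing:
        raise TransferError(f"pretrained weights missing encoder tensors: {missing[:3]}")
    mismatched = [
        k for k in enc_keys if pretrained[k].shape != own[k].shape
    ]
    if mismatched:
        k = mismatched[0]
        raise TransferError(
            f"encoder tensor shape mismatch: '{k}' model {own[k].shape} "
            f"vs pretrained {pretrained[k].shape} (and {len(mismatched) - 1} more)"
        )
    params = dict(model.named_parameters())
    buffers = dict(model.named_buffers())
    for k in enc_keys:
        if k in params:
            params[k].data = pretrained[k].astype(params[k].data.dtype).copy()
        else:
            buffers[k][...] = pretrained[k]
    return model
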