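"""2D U-Net for six-class lobe segmentation, with optional attention gates.

The network is a five-stage encoder-decoder: each stage applies two
Conv(3x3)-BatchNorm-ReLU units; 2x2 max pooling halves resolution between
encoder stages, and the decoder mirrors them with bilinear upsampling and
skip-connection concatenation.  With the default widths (64, 128, 256, 512,
512) a 256x256 input yields a (512, 16, 16) bottleneck — the latent the
self-supervised pretext head consumes — and (6, 256, 256) output logits
(5 lobes + background; softmax is applied by the loss / inference code, not
stored in the model output).

Attention gates (additive attention: project skip and gating features,
add, ReLU, 1x1 projection, sigmoid) multiply each skip connection by a
coefficient map in [0, 1], letting the decoder suppress irrelevant regions
such as the body shell without any lung-localization preprocessing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, concat

DEFAULT_WIDTHS = (64, 128, 256, 512, 512)


@dataclass
class UNetConfig:
    in_channels: int = 1
    out_channels: int = 6
    encoder_widths: tuple[int, ...] = DEFAULT_WIDTHS
    use_attention: bool = False
    input_size: int = 256

    def validate(self) -> None:
        if self.out_channels != 6:
            raise ValueError(f"out_channels must be 6 (5 lobes + background), got {self.out_channels}")
        if self.in_channels != 1:
            raise ValueError(f"in_channels must be 1 (grayscale CT), got {self.in_channels}")
        if len(self.encoder_widths) != 5:
            raise ValueError(f"encoder_widths must have 5 stages, got {self.encoder_widths}")
        if any(w < 2 for w in self.encoder_widths):
            raise ValueError(f"encoder widths must be >= 2, got {self.encoder_widths}")
        if self.input_size % 16 != 0:
            raise ValueError(f"input_size must be divisible by 16, got {self.input_size}")

    @property
    def latent_shape(self) -> tuple[int, int, int]:
        s = self.input_size // 16
        return (self.encoder_widths[-1], s, s)


class AttentionGate(nn.Module):
    """Additive attention gate on one skip connection.

    The gating signal is the immediately deeper decoder feature (half the
    skip resolution); it is bilinearly upsampled, both inputs are projected
    to an internal width, summed, passed through ReLU and a 1x1 projection,
    and squashed with a sigmoid into coefficients in [0, 1] that scale the
    skip features elementwise.
    """

    def __init__(self, skip_ch: int, gate_ch: int, rng: np.random.Generator):
        super().__init__()
        inter = max(skip_ch // 2, 1)
        self.theta_x = nn.Conv2d(skip_ch, inter, 1, 0, rng)
        self.phi_g = nn.Conv2d(gate_ch, inter, 1, 0, rng)
        self.psi = nn.Conv2d(inter, 1, 1, 0, rng)
        self.force_identity = False  # test hook: bypass gating (alpha == 1)
        self.last_alpha: np.ndarray | None = None

    def forward(self, skip: Tensor, gating: Tensor) -> Tensor:
        if self.force_identity:
            self.last_alpha = np.ones((skip.shape[0], 1) + skip.shape[2:], dtype=np.float32)
            return skip
        g = F.upsample_bilinear2(gating)
        q = (self.theta_x(skip) + self.phi_g(g)).relu()
        alpha = self.psi(q).sigmoid()
        self.last_alpha = alpha.data
        return skip * alpha


class UNet(nn.Module):
    def __init__(self, config: UNetConfig, rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        w = config.encoder_widths
        self.enc0 = nn.ConvBlock(config.in_channels, w[0], rng)
        self.enc1 = nn.ConvBlock(w[0], w[1], rng)
        self.enc2 = nn.ConvBlock(w[1], w[2], rng)
        self.enc3 = nn.ConvBlock(w[2], w[3], rng)
        self.enc4 = nn.ConvBlock(w[3], w[4], rng)  # bottleneck / SSL tap
        # half the encoder width, but never narrower than the class count
        # (the last decoder stage feeds the 6-way 1x1 head directly)
        dec_w = [max(w[i] // 2, 8) for i in range(4)]
        prev = w[4]
        for i in reversed(range(4)):
            if config.use_attention:
                setattr(self, f"gate{i}", AttentionGate(w[i], prev, rng))
            setattr(self, f"dec{i}", nn.ConvBlock(prev + w[i], dec_w[i], rng))
            prev = dec_w[i]
        self.head = nn.Conv2d(dec_w[0], config.out_channels, 1, 0, rng)

    def encode(self, x: Tensor) -> tuple[list[Tensor], Tensor]:
        """Run the contracting path; returns (skip features, bottleneck)."""
        skips = []
        h = x
        for i in range(4):
            h = self._modules[f"enc{i}"](h)
            skips.append(h)
            h = F.max_pool2(h)
        return skips, self.enc4(h)

    def forward(self, x: Tensor) -> Tensor:
        skips, h = self.encode(x)
        for i in reversed(range(4)):
            up = F.upsample_bilinear2(h)
            skip = skips[i]
            if self.config.use_attention:
                skip = self._modules[f"gate{i}"](skip, h)
            h = self._modules[f"dec{i}"](concat([up, skip], axis=1))
        return self.head(h)

    def attention_maps(self) -> list[np.ndarray]:
        """Per-skip-level gate coefficients from the latest forward pass."""
        if not self.config.use_attention:
            return []
        return [self._modules[f"gate{i}"].last_alpha for i in range(4)]

    def encoder_state(self) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.state_dict().items() if k.startswith("enc")}


def build_unet(config: UNetConfig | None = None, seed: int = 0) -> UNet:
    """Construct a baseline U-Net with Xavier-initialized weights."""
    config = config or UNetConfig()
    if config.use_attention:
        raise ValueError("config.use_attention is set; call build_attention_unet")
    return UNet(config, np.random.default_rng(seed))


def build_attention_unet(config: UNetConfig | None = None, seed: int = 0) -> UNet:
    """Construct the attention-gated variant (one gate per skip connection)."""
    config = config or UNetConfig(use_attention=True)
    config.use_attention = True
    return UNet(config, np.random.default_rng(seed))


# -- checkpointing ---------------------------------------------------------


def save_checkpoint(model: nn.Module, path: str | Path, config: UNetConfig | None = None,
                    meta: dict | None = None) -> None:
    """Serialize weights (.npz) with a JSON sidecar recording config + provenance."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = {"meta": meta or {}}
    if config is not None:
        sidecar["config"] = asdict(config)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    """Load a weights file and its sidecar; returns (state_dict, sidecar)."""
    path = Path(path)
    if not path.suffix == ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as data:
        state = {k: data[k].copy() for k in data.files}
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return state, sidecar


def load_model(path: str | Path) -> UNet:
    """Rebuild a U-Net from a checkpoint, validating config compatibility."""
    state, sidecar = load_checkpoint(path)
    if "config" not in sidecar:
        raise ValueError(f"checkpoint {path} has no config sidecar")
    cfg = sidecar["config"]
    cfg["encoder_widths"] = tuple(cfg["encoder_widths"])
    config = UNetConfig(**cfg)
    model = UNet(config, np.random.default_rng(0))
    model.load_state_dict(state)
    return model
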