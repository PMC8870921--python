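"""Configurable 2D U-Net for slice-wise brain extraction and lesion segmentation.

One implementation serves both networks; they differ only by configuration.
The encoder halves the spatial size ``depth`` times with 2x2 max pooling and
doubles the channel width per level; the decoder mirrors it with non-learned
2x nearest-neighbour up-sampling followed by convolutions, concatenating the
matching encoder feature map at each level. Convolutions use 'same' padding,
so feature maps never shrink and skip connections need no cropping. The head
is a 1x1 convolution with a sigmoid, producing a per-pixel membership map.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .layers import Adam, BatchNorm2d, Conv2d, MaxPool2x2, Param, ReLU, Upsample2x

__all__ = ["UNetConfig", "UNet", "ModelHandle", "build_unet", "forward",
           "count_parameters", "save_checkpoint", "load_checkpoint"]


@dataclasses.dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters.

    ``depth`` is the number of pooling levels; the input side length must be
    divisible by 2**depth. Channel widths double per level starting at
    ``base_channels``, capped at ``max_channels`` (default 16 -> 256 for the
    full-size depth-5 network). ``foreground_prior`` sets the initial head
    bias to the prior's logit, the standard initialisation for segmentation
    targets that occupy a small fraction of the image (e.g. lesions).
    """

    depth: int = 5
    base_channels: int = 16
    max_channels: int = 256
    kernel: int = 3
    batch_norm: bool = True
    in_shape: tuple[int, int] = (256, 256)
    foreground_prior: float = 0.5

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        div = 2 ** self.depth
        if any(s % div for s in self.in_shape):
            raise ValueError(
                f"input shape {self.in_shape} not divisible by 2^depth = {div}"
            )
        if not (0 < self.foreground_prior < 1):
            raise ValueError("foreground_prior must be in (0, 1)")

    def width(self, level: int) -> int:
        """Channel width at encoder level (level == depth is the bottleneck)."""
        return min(self.base_channels * 2 ** level, self.max_channels)


def _conv_block(c_in: int, c_out: int, cfg: UNetConfig, rng, name: str) -> list:
    layers: list = [Conv2d(c_in, c_out, cfg.kernel, rng, name=f"{name}.conv1")]
    if cfg.batch_norm:
        layers.append(BatchNorm2d(c_out, name=f"{name}.bn1"))
    layers.append(ReLU())
    layers.append(Conv2d(c_out, c_out, cfg.kernel, rng, name=f"{name}.conv2"))
    if cfg.batch_norm:
        layers.append(BatchNorm2d(c_out, name=f"{name}.bn2"))
    layers.append(ReLU())
    return layers


class UNet:
    """Encoder–decoder segmentation network producing sigmoid memberships."""

    def __init__(self, cfg: UNetConfig, seed: int) -> None:
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.enc_blocks: list[list] = []
        self.pools: list[MaxPool2x2] = []
        c_in = 1
        for d in range(cfg.depth):
            w = cfg.width(d)
            self.enc_blocks.append(_conv_block(c_in, w, cfg, rng, f"enc{d}"))
            self.pools.append(MaxPool2x2())
            c_in = w
        wb = cfg.width(cfg.depth)
        self.bottleneck = _conv_block(c_in, wb, cfg, rng, "bottleneck")
        self.ups: list[Upsample2x] = []
        self.dec_blocks: list[list] = []
        c_in = wb
        for d in reversed(range(cfg.depth)):
            w = cfg.width(d)
            self.ups.append(Upsample2x())
            self.dec_blocks.append(_conv_block(c_in + w, w, cfg, rng, f"dec{d}"))
            c_in = w
        # prior-informed head bias: the sigmoid starts at the expected
        # foreground fraction, so rare-class tasks need not spend their
        # (lr-bounded) optimiser steps on driving the output to background
        prior_logit = float(np.log(cfg.foreground_prior / (1.0 - cfg.foreground_prior)))
        self.head = Conv2d(c_in, 1, 1, rng, name="head", bias_init=prior_logit)

    # -- plumbing -----------------------------------------------------------

    def _all_layers(self) -> list:
        layers: list = []
        for blk in self.enc_blocks:
            layers.extend(blk)
        layers.extend(self.bottleneck)
        for blk in self.dec_blocks:
            layers.extend(blk)
        layers.append(self.head)
        return layers

    @property
    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self._all_layers():
            out.extend(layer.params)
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params)

    # -- forward / backward -------------------------------------------------

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Pre-sigmoid scores for a batch of slices (N, H, W) -> (N, H, W, 1)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            for layer in blk:
                x = layer.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        for layer in self.bottleneck:
            x = layer.forward(x, train)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x, train)
            self._skip_channels.append((skip.shape[3], x.shape[3]))
            x = np.concatenate([skip, x], axis=3)
            for layer in blk:
                x = layer.forward(x, train)
        return self.head.forward(x, train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Per-pixel membership probabilities in (0, 1), shaped (N, H, W)."""
        z = self.forward_logits(x, train)
        return _sigmoid(z[..., 0])

    def backward(self, grad_logits: np.ndarray) -> np.ndarray:
        g = self.head.backward(grad_logits)
        skip_grads = []
        for blk, up, (c_skip, _) in zip(
            reversed(self.dec_blocks), reversed(self.ups), reversed(self._skip_channels)
        ):
            for layer in reversed(blk):
                g = layer.backward(g)
            skip_grads.append(g[..., :c_skip])
            g = up.backward(np.ascontiguousarray(g[..., c_skip:]))
        for layer in reversed(self.bottleneck):
            g = layer.backward(g)
        # skip_grads was collected shallowest-first; encoder unwinds deepest-first
        for blk, pool, gs in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(skip_grads)
        ):
            g = pool.backward(g) + gs
            for layer in reversed(blk):
                g = layer.backward(g)
        return g


# The public handle is the network itself (it carries its config and seed).
ModelHandle = UNet


def build_unet(cfg: UNetConfig, seed: int) -> UNet:
    """Instantiate a U-Net with deterministic (seeded He) initialisation."""
    return UNet(cfg, seed)


def forward(model: UNet, batch: np.ndarray) -> np.ndarray:
    """Eval-mode membership maps for a batch of slices shaped (N, H, W)."""
    if batch.ndim != 3:
        raise ValueError(f"expected (N, H, W) batch, got shape {batch.shape}")
    expected = tuple(model.cfg.in_shape)
    if batch.shape[1:] != expected:
        raise ValueError(f"slices are {batch.shape[1:]}, model expects {expected}")
    return forward_tiles(model, batch)


def forward_tiles(model: UNet, batch: np.ndarray, chunk: int = 16) -> np.ndarray:
    """Eval forward in chunks to bound peak memory."""
    outs = [model.forward(batch[i:i + chunk], train=False)
            for i in range(0, batch.shape[0], chunk)]
    return np.concatenate(outs, axis=0)


def count_parameters(cfg: UNetConfig) -> int:
    """Closed-form trainable-parameter count for a configuration."""
    def conv(c_in, c_out, k):
        return c_out * c_in * k * k + c_out

    def block(c_in, c_out):
        n = conv(c_in, c_out, cfg.kernel) + conv(c_out, c_out, cfg.kernel)
        if cfg.batch_norm:
            n += 4 * c_out  # two BN layers, gamma+beta each
        return n

    total = 0
    c_in = 1
    for d in range(cfg.depth):
        w = cfg.width(d)
        total += block(c_in, w)
        c_in = w
    wb = cfg.width(cfg.depth)
    total += block(c_in, wb)
    c_in = wb
    for d in reversed(range(cfg.depth)):
        w = cfg.width(d)
        total += block(c_in + w, w)
        c_in = w
    total += conv(c_in, 1, 1)
    return total


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: UNet, path: str | Path) -> None:
    """Save weights, running statistics and the embedded config (.npz)."""
    arrays: dict[str, np.ndarray] = {}
    for p in model.params:
        arrays[f"param/{p.name}"] = p.value
    for i, layer in enumerate(model._all_layers()):
        if isinstance(layer, BatchNorm2d):
            arrays[f"running/{i}/mean"] = layer.running_mean
            arrays[f"running/{i}/var"] = layer.running_var
    cfg = dataclasses.asdict(model.cfg)
    cfg["in_shape"] = list(cfg["in_shape"])
    arrays["config_json"] = np.frombuffer(
        json.dumps({"cfg": cfg, "seed": model.seed}).encode(), dtype=np.uint8
    )
    np.savez(str(path), **arrays)


def load_checkpoint(path: str | Path) -> UNet:
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["config_json"].tobytes()).decode())
        cfg_d = meta["cfg"]
        cfg_d["in_shape"] = tuple(cfg_d["in_shape"])
        model = UNet(UNetConfig(**cfg_d), seed=meta["seed"])
        byname = {f"param/{p.name}": p for p in model.params}
        for key in data.files:
            if key.startswith("param/"):
                byname[key].value = data[key].astype(np.float32)
        for i, layer in enumerate(model._all_layers()):
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = data[f"running/{i}/mean"].astype(np.float32)
                layer.running_var = data[f"running/{i}/var"].astype(np.float32)
    return model
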