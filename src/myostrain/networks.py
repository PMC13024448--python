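"""Spatiotemporal encoder–decoder networks for displacement regression.

Two variants regress per-frame normalized x/y displacement images from a
binary cine myocardium-mask sequence, treated as a 3-D (time, row, col)
volume:

* ``myonet`` — a 5-level U-Net whose per-level block is a *spatial* conv
  (kernel 1x3x3) followed by a *temporal* conv (kernel 3x1x1), each with
  normalization and ReLU; the two deepest encoder levels dilate the
  spatial conv by (1,2,2) and the temporal conv by (2,1,1) to widen the
  spatiotemporal receptive field without losing resolution.
* ``resmyonet`` — the same topology with each block replaced by a residual
  block: main path conv→norm→ReLU→conv→norm, an identity (or 1x1x1
  projection) shortcut, summed, then tanh.

Pooling is spatial-only (1x2x2): the temporal axis is never reduced — a
20-frame cine could not survive five halvings. The decoder mirrors the
encoder with nearest-neighbour (1,2,2) upsampling and skip concatenation;
the head is a 1x1x1 convolution to 2 channels with a sigmoid, bounding the
output to the normalized displacement range (0, 1).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import numpy as np

from . import nn
from .data_io import AffineScale

__all__ = ["NetworkConfig", "build_network", "forward", "MyoNet",
           "save_checkpoint", "load_checkpoint"]

SPATIAL_KERNEL = (1, 3, 3)
TEMPORAL_KERNEL = (3, 1, 1)
SPATIAL_DILATION = (1, 2, 2)
TEMPORAL_DILATION = (2, 1, 1)


@dataclasses.dataclass
class NetworkConfig:
    variant: str = "myonet"                 # "myonet" | "resmyonet"
    levels: int = 5
    base_channels: int = 16
    channel_cap: int = 256
    dilated_levels: tuple[int, ...] = (3, 4)  # deepest two encoder levels
    out_channels: int = 2

    def __post_init__(self):
        if self.variant not in ("myonet", "resmyonet"):
            raise ValueError(f"unsupported variant {self.variant!r}")
        if self.levels != 5 or self.out_channels != 2:
            raise ValueError("the architecture is fixed at 5 levels, 2 output channels")

    def channels(self) -> list[int]:
        return [min(self.base_channels * 2 ** l, self.channel_cap)
                for l in range(self.levels)]

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _kaiming(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class _Conv:
    def __init__(self, rng, cin, cout, kernel, dilation=(1, 1, 1)):
        self.w = nn.Tensor(_kaiming(rng, (cout, cin) + tuple(kernel)), requires_grad=True)
        self.b = nn.Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
        self.dilation = dilation

    def __call__(self, x):
        return nn.conv3d(x, self.w, self.b, self.dilation)

    def params(self):
        return [self.w, self.b]


class _PlainBlock:
    """MyoNet level: spatial conv → norm → ReLU → temporal conv → norm → ReLU."""

    def __init__(self, rng, cin, cout, dilated: bool):
        sd = SPATIAL_DILATION if dilated else (1, 1, 1)
        td = TEMPORAL_DILATION if dilated else (1, 1, 1)
        self.conv_s = _Conv(rng, cin, cout, SPATIAL_KERNEL, sd)
        self.bn_s = nn.BatchNorm3d(cout)
        self.conv_t = _Conv(rng, cout, cout, TEMPORAL_KERNEL, td)
        self.bn_t = nn.BatchNorm3d(cout)

    def __call__(self, x):
        x = nn.relu(self.bn_s(self.conv_s(x)))
        return nn.relu(self.bn_t(self.conv_t(x)))

    def params(self):
        return (self.conv_s.params() + self.bn_s.params()
                + self.conv_t.params() + self.bn_t.params())

    def norms(self):
        return [self.bn_s, self.bn_t]


class _ResBlock:
    """ResMyoNet level: (conv→norm→ReLU→conv→norm) + shortcut, then tanh."""

    def __init__(self, rng, cin, cout, dilated: bool):
        sd = SPATIAL_DILATION if dilated else (1, 1, 1)
        td = TEMPORAL_DILATION if dilated else (1, 1, 1)
        self.conv_s = _Conv(rng, cin, cout, SPATIAL_KERNEL, sd)
        self.bn_s = nn.BatchNorm3d(cout)
        self.conv_t = _Conv(rng, cout, cout, TEMPORAL_KERNEL, td)
        self.bn_t = nn.BatchNorm3d(cout)
        self.proj = _Conv(rng, cin, cout, (1, 1, 1)) if cin != cout else None

    def __call__(self, x):
        main = self.bn_t(self.conv_t(nn.relu(self.bn_s(self.conv_s(x)))))
        short = self.proj(x) if self.proj is not None else x
        return nn.tanh(nn.add(main, short))

    def params(self):
        p = (self.conv_s.params() + self.bn_s.params()
             + self.conv_t.params() + self.bn_t.params())
        if self.proj is not None:
            p += self.proj.params()
        return p

    def norms(self):
        return [self.bn_s, self.bn_t]


class MyoNet:
    """5-level spatiotemporal U-Net (plain or residual blocks)."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        Block = _PlainBlock if cfg.variant == "myonet" else _ResBlock
        ch = cfg.channels()
        self.enc = []
        cin = 1
        for l in range(cfg.levels):
            self.enc.append(Block(rng, cin, ch[l], dilated=l in cfg.dilated_levels))
            cin = ch[l]
        self.dec = []
        for l in range(cfg.levels - 2, -1, -1):   # levels 3,2,1,0
            self.dec.append(Block(rng, ch[l + 1] + ch[l], ch[l], dilated=False))
        self.head = _Conv(rng, ch[0], cfg.out_channels, (1, 1, 1))

    # -- parameter plumbing -------------------------------------------------
    def blocks(self):
        return self.enc + self.dec

    def params(self) -> list[nn.Tensor]:
        p = []
        for blk in self.blocks():
            p += blk.params()
        return p + self.head.params()

    def norms(self):
        out = []
        for blk in self.blocks():
            out += blk.norms()
        return out

    @property
    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.params())

    def train_mode(self, flag: bool = True):
        for bn in self.norms():
            bn.training = flag
        return self

    def eval_mode(self):
        return self.train_mode(False)

    def state_arrays(self) -> list[np.ndarray]:
        arrs = [p.data for p in self.params()]
        for bn in self.norms():
            arrs += [bn.running_mean, bn.running_var]
        return arrs

    def load_state_arrays(self, arrs: list[np.ndarray]) -> None:
        ps = self.params()
        for p, a in zip(ps, arrs[: len(ps)]):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint/parameter shape mismatch")
            p.data = a.copy()
        rest = arrs[len(ps):]
        for bn, (m, v) in zip(self.norms(), zip(rest[0::2], rest[1::2])):
            bn.running_mean = m.copy()
            bn.running_var = v.copy()

    # -- forward ------------------------------------------------------------
    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        skips = []
        for l, blk in enumerate(self.enc):
            x = blk(x)
            if l < self.cfg.levels - 1:
                skips.append(x)
                x = nn.maxpool_hw(x)
        for blk, skip in zip(self.dec, reversed(skips)):
            x = nn.upsample_hw(x)
            x = nn.concat_channels(x, skip)
            x = blk(x)
        return nn.sigmoid(self.head(x))


def build_network(cfg: NetworkConfig, seed: int = 0) -> MyoNet:
    """Instantiate a network with seeded Kaiming initialization."""
    return MyoNet(cfg, seed=seed)


def forward(model: MyoNet, masks: np.ndarray) -> np.ndarray:
    """Predict normalized displacement images for one mask sequence.

    ``masks``: (T, H, W) binary. Returns (2, T, H, W) in (0, 1). H and W
    must be divisible by 2^(levels−1) = 16 so five resolution levels fit.
    """
    masks = np.asarray(masks, dtype=np.float32)
    if masks.ndim != 3:
        raise ValueError("expected a (T, H, W) mask stack")
    T, H, W = masks.shape
    div = 2 ** (model.cfg.levels - 1)
    if H % div or W % div:
        raise ValueError(f"H and W must be divisible by {div}, got {H}x{W}")
    model.eval_mode()
    out = model(nn.Tensor(masks[None, None]))
    return out.data[0]


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: MyoNet, scale: AffineScale | None = None,
                    epoch: int | None = None, val_loss: float | None = None,
                    seed: int | None = None) -> None:
    meta = {
        "config": dataclasses.asdict(model.cfg),
        "config_hash": model.cfg.hash(),
        "init_seed": model.seed,
        "epoch": epoch,
        "val_loss": val_loss,
        "seed": seed,
        "d_max": scale.d_max if scale is not None else None,
    }
    arrs = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=json.dumps(meta), **arrs)


def load_checkpoint(path):
    """Returns (model in eval mode, AffineScale | None, metadata dict)."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        arrs = [z[f"arr_{i}"] for i in range(len(z.files) - 1)]
    cfg = NetworkConfig(**meta["config"])
    model = MyoNet(cfg, seed=meta.get("init_seed", 0))
    model.load_state_arrays(arrs)
    model.eval_mode()
    scale = AffineScale(d_max=meta["d_max"]) if meta.get("d_max") else None
    return model, scale, meta
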