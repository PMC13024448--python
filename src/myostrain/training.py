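"""Scan-level splitting, flip augmentation, and the optimization loop.

The dataset is split at the *scan* level so that no slice of a validation
or test scan ever reaches a training batch (leakage guard, asserted when
batches are built). Training minimizes the three-part loss with RMSprop
(initial learning rate 1e-3, batch size 4, 100 epochs at full scale) and
keeps the parameters of the epoch with the lowest validation total loss.
Accuracy is reported as 1 minus the normalized mean squared error of the
displacement images: the fields live on the unit normalized scale, so the
MSE is already normalized by the squared dynamic range (= 1).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import losses, nn
from .data_io import AffineScale, denormalize, normalize
from .networks import MyoNet

__all__ = ["TrainConfig", "SplitAssignment", "TrainHistory", "split_scans",
           "augment_flip", "train_model", "accuracy", "TrainingDiverged"]


class TrainingDiverged(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.epoch = epoch


@dataclasses.dataclass
class TrainConfig:
    optimizer: str = "rmsprop"
    learning_rate: float = 1e-3
    batch_size: int = 4
    epochs: int = 100
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    augment_flips: tuple[str, ...] = ("horizontal", "vertical")
    flip_probability: float = 0.5
    seed: int = 0
    selection: str = "best_validation_loss"

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclasses.dataclass
class SplitAssignment:
    assignment: dict[str, str]      # scan_id -> "train" | "val" | "test"

    def scans(self, part: str) -> list[str]:
        return sorted(k for k, v in self.assignment.items() if v == part)

    def part_of(self, scan_id: str) -> str:
        return self.assignment[scan_id]


@dataclasses.dataclass
class TrainHistory:
    epochs: list[dict]              # per-epoch records
    best_epoch: int                 # 1-based, minimal validation l_total

    def train_total(self, epoch: int) -> float:
        return self.epochs[epoch - 1]["train"]["l_total"]

    def val_total(self, epoch: int) -> float:
        return self.epochs[epoch - 1]["val"]["l_total"]


def split_scans(scan_ids, fractions=(0.8, 0.1, 0.1), seed: int = 0) -> SplitAssignment:
    """Shuffle scans and carve validation/test sets of max(1, round(f*N)).

    Splitting at scan level (never slice level) prevents leakage between
    sets when a scan contributes multiple slices.
    """
    ids = sorted(map(str, scan_ids))
    N = len(ids)
    if N < 3:
        raise ValueError(f"need at least 3 scans to split, got {N}")
    if len(set(ids)) != N:
        raise ValueError("duplicate scan ids")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(N)]
    n_val = max(1, round(fractions[1] * N))
    n_test = max(1, round(fractions[2] * N))
    if n_val + n_test >= N:
        raise ValueError("too few scans for the requested fractions")
    assignment = {}
    for s in order[:n_val]:
        assignment[s] = "val"
    for s in order[n_val:n_val + n_test]:
        assignment[s] = "test"
    for s in order[n_val + n_test:]:
        assignment[s] = "train"
    return SplitAssignment(assignment=assignment)


def augment_flip(masks: np.ndarray, displacement, axis: str,
                 scale: AffineScale | None = None):
    """Mirror a sample along an image axis, fixing displacement signs.

    ``horizontal`` mirrors columns and negates u_x; ``vertical`` mirrors
    rows and negates u_y. When the displacement is given in *normalized*
    form (a (2, T, H, W) array), the negation is applied on the signed
    scale by round-tripping through ``scale``. A
    :class:`~myostrain.data_io.DisplacementSequence` is flipped in signed
    mm directly. Applying the same flip twice is the identity.
    """
    if axis not in ("horizontal", "vertical"):
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    flip_ax = -1 if axis == "horizontal" else -2
    masks_f = np.flip(masks, axis=flip_ax).copy()

    from .data_io import DisplacementSequence
    if isinstance(displacement, DisplacementSequence):
        ux = np.flip(displacement.ux, axis=flip_ax).copy()
        uy = np.flip(displacement.uy, axis=flip_ax).copy()
        if axis == "horizontal":
            ux = -ux
        else:
            uy = -uy
        fg = np.flip(displacement.foreground_mask, axis=flip_ax).copy()
        return masks_f, dataclasses.replace(displacement, ux=ux, uy=uy,
                                            foreground_mask=fg)
    norm = np.asarray(displacement)
    if norm.ndim != 4 or norm.shape[0] != 2:
        raise ValueError("normalized displacement must be (2, T, H, W)")
    if scale is None:
        raise ValueError("flipping normalized fields requires the AffineScale")
    flipped = np.flip(norm, axis=flip_ax)
    comp = 0 if axis == "horizontal" else 1
    out = np.empty_like(flipped)
    for c in range(2):
        d, fg = denormalize(flipped[c], scale)
        if c == comp:
            d = -d
        out[c] = normalize(d, scale, fg)
    return masks_f, out


def accuracy(pred, target) -> float:
    """1 − normalized MSE of the displacement images (unit dynamic range)."""
    return 1.0 - losses.mse_loss(pred, target)


def _batch(samples: list[dict]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s["masks"] for s in samples]).astype(np.float32)[:, None]
    y = np.stack([s["target"] for s in samples])
    return x, y


def train_model(model: MyoNet, data: dict, cfg: TrainConfig):
    """Optimize the model on phantom/real samples; return (best state, history).

    ``data`` = {"train": [...], "val": [...], "scale": AffineScale} where
    each sample is a dict with keys ``masks`` (T, H, W), ``target``
    normalized (2, T, H, W), ``scan_id`` and ``split``. Samples marked as
    belonging to validation/test scans are rejected from training batches.
    The run is fully seeded: data order and flip draws come from
    ``cfg.seed``, parameter init from the model's own seed.
    """
    train_set = list(data["train"])
    val_set = list(data["val"])
    scale = data.get("scale")
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be nonempty")
    for s in train_set:
        if s.get("split", "train") != "train":
            raise ValueError(
                f"leakage: sample of scan {s.get('scan_id')} marked "
                f"{s.get('split')!r} appeared in the training set")

    if cfg.optimizer != "rmsprop":
        raise ValueError("only the RMSprop optimizer is supported")
    opt = nn.RMSprop(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []
    best = {"epoch": -1, "val": np.inf, "state": None}

    for epoch in range(1, cfg.epochs + 1):
        model.train_mode()
        order = rng.permutation(len(train_set))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = []
            for idx in order[start:start + cfg.batch_size]:
                s = train_set[idx]
                masks, target = s["masks"], s["target"]
                for ax in cfg.augment_flips:
                    if rng.random() < cfg.flip_probability:
                        masks, target = augment_flip(masks, target, ax, scale)
                batch.append({"masks": masks, "target": target})
            x, y = _batch(batch)
            opt.zero_grad()
            pred = model(nn.Tensor(x))
            bd = losses.total_loss(pred, y)
            if not np.isfinite(bd.l_total):
                raise TrainingDiverged(epoch)
            bd.total_tensor.backward()
            opt.step()
            epoch_losses.append(bd)

        train_rec = _mean_breakdown(epoch_losses)
        val_rec, val_acc = _evaluate(model, val_set)
        train_acc = 1.0 - train_rec["l_mse"]
        history.append({"epoch": epoch, "train": train_rec, "val": val_rec,
                        "train_accuracy": train_acc, "val_accuracy": val_acc})
        if val_rec["l_total"] < best["val"]:
            best = {"epoch": epoch, "val": val_rec["l_total"],
                    "state": [a.copy() for a in model.state_arrays()]}

    model.load_state_arrays(best["state"])
    model.eval_mode()
    return model, TrainHistory(epochs=history, best_epoch=best["epoch"])


def _mean_breakdown(bds) -> dict:
    keys = ("l_mse", "l_smooth", "l_custom", "l_total")
    return {k: float(np.mean([getattr(b, k) for b in bds])) for k in keys}


def _evaluate(model: MyoNet, samples: list[dict]):
    model.eval_mode()
    recs = []
    accs = []
    for s in samples:
        x, y = _batch([s])
        pred = model(nn.Tensor(x))
        bd = losses.total_loss(pred.data, y)
        recs.append(bd)
        accs.append(accuracy(pred.data, y))
    keys = ("l_mse", "l_smooth", "l_custom", "l_total")
    rec = {k: float(np.mean([getattr(b, k) for b in recs])) for k in keys}
    return rec, float(np.mean(accs))
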