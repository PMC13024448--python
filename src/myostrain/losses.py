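"""The three-part displacement-regression objective.

All losses operate on *normalized* displacement images — the (2, T, H, W)
form in which the networks emit them, with the x channel first, foreground
values in [32/255, 1] and background exactly 0:

* ``mse_loss`` — per frame, the per-pixel mean of the squared error summed
  over both components, averaged over frames;
* ``smooth_l1_loss`` — component-wise Huber penalty (quadratic below unit
  error, linear above), summed over components, averaged over pixels and
  frames;
* ``custom_masked_loss`` — the squared-error term restricted to pixels
  where *both* target components exceed the 0.125 background threshold
  (i.e. where the reference tagging produced a displacement), averaged
  over those m pixels per frame, 0 for frames with empty foreground;
* ``total_loss`` — the unweighted sum of the three.

Each loss accepts the prediction as a plain ndarray (pure evaluation) or
as an :class:`~myostrain.nn.Tensor` (differentiable, for training); the
target is always an ndarray. Shapes may carry a leading batch axis, over
which the losses average.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .data_io import FOREGROUND_THRESHOLD

__all__ = ["LossBreakdown", "mse_loss", "smooth_l1_loss", "custom_masked_loss",
           "total_loss"]


@dataclasses.dataclass
class LossBreakdown:
    """Scalar loss components and their bookkeeping."""

    l_mse: float
    l_smooth: float
    l_custom: float
    l_total: float
    foreground_counts: np.ndarray | None = None   # m per (batch,) frame
    per_pixel_sq: np.ndarray | None = None        # z_ij maps (debug mode)
    total_tensor: "nn.Tensor | None" = None       # differentiable total, if requested


def _canon(a) -> np.ndarray:
    """Canonical shape (N, 2, T, H, W)."""
    a = np.asarray(a)
    if a.ndim == 4:
        a = a[None]
    if a.ndim != 5 or a.shape[1] != 2:
        raise ValueError(f"expected (2, T, H, W) or (N, 2, T, H, W), got {a.shape}")
    return a


def _check(pred_data: np.ndarray, target: np.ndarray) -> None:
    if pred_data.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred_data.shape} vs target {target.shape}")


def _pixels_per_frame(shape) -> float:
    return float(shape[-1] * shape[-2])


def mse_loss(pred, target):
    """Mean over frames of the per-pixel mean of (dx^2 + dy^2)."""
    target = _canon(target)
    if isinstance(pred, nn.Tensor):
        pd = _canon(pred.data)
        _check(pd, target)
        diff = pd - target
        denom = diff.size / 2.0          # N * T * H * W
        val = float((diff ** 2).sum() / denom)

        def _bw(g):
            nn._accum(pred, (g * 2.0 * diff / denom).reshape(pred.data.shape))

        return nn.Tensor(np.asarray(val), parents=(pred,), backward=_bw)
    pd = _canon(pred)
    _check(pd, target)
    diff = pd - target
    return float((diff ** 2).sum() / (diff.size / 2.0))


def smooth_l1_loss(pred, target):
    """Huber-style penalty on the paired (dx, dy) error at each pixel.

    Where *both* component errors are below 1 the penalty is quadratic,
    0.5(dx^2 + dy^2); otherwise it is the linear |dx| + |dy| - 0.5.
    Averaged over pixels and frames. Along either component axis the two
    branches meet at |d| = 1 with matching value (0.5) and slope.
    """
    target = _canon(target)
    is_tensor = isinstance(pred, nn.Tensor)
    pd = _canon(pred.data if is_tensor else pred)
    _check(pd, target)
    diff = pd - target
    absd = np.abs(diff)
    small = (absd[:, 0] < 1.0) & (absd[:, 1] < 1.0)      # (N, T, H, W)
    quad = 0.5 * (diff ** 2).sum(axis=1)
    lin = absd.sum(axis=1) - 0.5
    per_pixel = np.where(small, quad, lin)
    denom = per_pixel.size                               # N * T * H * W
    val = float(per_pixel.sum() / denom)
    if not is_tensor:
        return val

    def _bw(g):
        grad = np.where(small[:, None], diff, np.sign(diff)) / denom
        nn._accum(pred, (g * grad).reshape(pred.data.shape))

    return nn.Tensor(np.asarray(val), parents=(pred,), backward=_bw)


def custom_masked_loss(pred, target, threshold: float = FOREGROUND_THRESHOLD,
                       debug: bool = False):
    """Squared error averaged over tag-foreground pixels, per frame.

    Foreground is decided on the *target*: both normalized components must
    exceed ``threshold``. Frames without foreground contribute 0.
    """
    target = _canon(target)
    is_tensor = isinstance(pred, nn.Tensor)
    pd = _canon(pred.data if is_tensor else pred)
    _check(pd, target)
    fg = (target[:, 0] > threshold) & (target[:, 1] > threshold)  # (N, T, H, W)
    m = fg.sum(axis=(-1, -2)).astype(np.float64)                  # (N, T)
    diff = pd - target
    z = (diff ** 2).sum(axis=1) * fg                              # (N, T, H, W)
    frame_sums = z.sum(axis=(-1, -2))
    with np.errstate(invalid="ignore", divide="ignore"):
        frame_loss = np.where(m > 0, frame_sums / np.where(m > 0, m, 1.0), 0.0)
    val = float(frame_loss.mean())
    if not is_tensor:
        return (val, m, z) if debug else val

    n_frames_total = frame_loss.size

    def _bw(g):
        w = np.where(m > 0, 1.0 / (np.where(m > 0, m, 1.0) * n_frames_total), 0.0)
        grad = 2.0 * diff * fg[:, None] * w[:, None, :, None, None]
        nn._accum(pred, (g * grad).reshape(pred.data.shape))

    t = nn.Tensor(np.asarray(val), parents=(pred,), backward=_bw)
    return (t, m, z) if debug else t


def total_loss(pred, target, debug: bool = False) -> LossBreakdown:
    """All three components on the same pair; the total is their exact sum."""
    is_tensor = isinstance(pred, nn.Tensor)
    l1 = mse_loss(pred, target)
    l2 = smooth_l1_loss(pred, target)
    l3 = custom_masked_loss(pred, target, debug=debug)
    m = z = None
    if debug:
        l3, m, z = l3
    if is_tensor:
        tot = nn.add(nn.add(l1, l2), l3)
        return LossBreakdown(
            l_mse=l1.item(), l_smooth=l2.item(), l_custom=l3.item(),
            l_total=tot.item(), foreground_counts=m, per_pixel_sq=z,
            total_tensor=tot)
    return LossBreakdown(l_mse=l1, l_smooth=l2, l_custom=l3,
                         l_total=l1 + l2 + l3, foreground_counts=m, per_pixel_sq=z)
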