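"""Data model, invertible displacement normalization, and NIfTI/CSV I/O.

Conventions used throughout the package:

* arrays are row-major with 0-based indices;
* ``u_x`` is displacement along the column direction, ``u_y`` along the row
  direction, both in mm;
* displacement fields are Lagrangian — defined on the frame-0 (reference)
  grid, so the field of frame 0 is identically zero;
* normalized displacement images map the signed range [−d_max, +d_max] to
  8-bit intensities [32, 255] divided by 255, with background exactly 0.
  The lower foreground bound is therefore 32/255 ≈ 0.1255, strictly above
  the 0.125 threshold that separates background from foreground everywhere
  downstream (losses, denormalization).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger("myostrain")

INTENSITY_LO = 32
INTENSITY_HI = 255
FOREGROUND_THRESHOLD = 0.125


@dataclasses.dataclass
class CineSequence:
    """A stack of binary short-axis myocardium masks over the cardiac cycle."""

    frames: np.ndarray          # (T, H, W), values {0, 1}
    pixel_spacing: float        # mm / pixel
    scan_id: str = "scan"
    slice_id: str = "slice"

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("CineSequence frames must be (T, H, W)")
        vals = np.unique(self.frames)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("mask values must be in {0, 1}")
        if self.n < 2:
            raise ValueError("a cine sequence needs at least 2 frames")

    @property
    def n(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclasses.dataclass
class AffineScale:
    """Invertible affine map between signed mm and 8-bit-style intensities.

    Signed displacement d in [−d_max, +d_max] maps to intensity
    32 + (d + d_max)(255 − 32)/(2 d_max); normalized values are
    intensity / 255. Background pixels carry the sentinel 0.
    """

    d_max: float
    intensity_lo: int = INTENSITY_LO
    intensity_hi: int = INTENSITY_HI
    background_sentinel: float = 0.0

    def __post_init__(self):
        if not self.d_max > 0:
            raise ValueError("d_max must be positive")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "d_max": self.d_max,
            "intensity_lo": self.intensity_lo,
            "intensity_hi": self.intensity_hi,
        }, indent=2))

    @classmethod
    def from_json(cls, path) -> "AffineScale":
        d = json.loads(Path(path).read_text())
        return cls(d_max=d["d_max"], intensity_lo=d.get("intensity_lo", INTENSITY_LO),
                   intensity_hi=d.get("intensity_hi", INTENSITY_HI))


@dataclasses.dataclass
class DisplacementSequence:
    """Per-frame signed in-plane displacement fields on the reference grid."""

    ux: np.ndarray              # (T, H, W) mm, column direction
    uy: np.ndarray              # (T, H, W) mm, row direction
    foreground_mask: np.ndarray  # (H, W) bool — where the field is defined
    pixel_spacing: float
    scan_id: str = "scan"
    slice_id: str = "slice"
    scale: AffineScale | None = None

    def __post_init__(self):
        self.ux = np.asarray(self.ux, dtype=np.float64)
        self.uy = np.asarray(self.uy, dtype=np.float64)
        self.foreground_mask = np.asarray(self.foreground_mask, dtype=bool)
        if self.ux.shape != self.uy.shape or self.ux.ndim != 3:
            raise ValueError("ux/uy must both be (T, H, W)")
        if self.foreground_mask.shape != self.ux.shape[1:]:
            raise ValueError("foreground mask must match the field's H, W")

    @property
    def n(self) -> int:
        return self.ux.shape[0]

    def max_abs(self) -> float:
        m = self.foreground_mask
        if not m.any():
            return 0.0
        return max(np.abs(self.ux[:, m]).max(), np.abs(self.uy[:, m]).max())

    def normalized(self, scale: AffineScale | None = None) -> np.ndarray:
        """Return the (2, T, H, W) normalized form (x channel first)."""
        s = scale or self.scale
        if s is None:
            raise ValueError("no AffineScale attached or provided")
        m = np.broadcast_to(self.foreground_mask, self.ux.shape)
        nx = normalize(self.ux, s, m)
        ny = normalize(self.uy, s, m)
        return np.stack([nx, ny])


def fit_scale(displacements, margin: float = 0.0) -> AffineScale:
    """Fit the shared symmetric half-range d_max over a collection of fields.

    ``margin`` pads d_max multiplicatively (0.1 → 10% headroom), so unseen
    fields slightly beyond the training range still normalize in-bounds.
    """
    seqs = list(displacements)
    if not seqs:
        raise ValueError("empty displacement collection")
    if not any(s.foreground_mask.any() for s in seqs):
        raise ValueError("no foreground pixels in the collection")
    d_max = max(s.max_abs() for s in seqs)
    if d_max <= 0:
        raise ValueError("degenerate scale: all displacements are zero")
    return AffineScale(d_max=d_max * (1.0 + margin))


def normalize(d: np.ndarray, scale: AffineScale, foreground: np.ndarray) -> np.ndarray:
    """Map signed mm to normalized [32/255, 1] on foreground, 0 on background."""
    d = np.asarray(d, dtype=np.float64)
    over = np.abs(d) > scale.d_max
    n_over = int(np.count_nonzero(over & foreground))
    if n_over:
        logger.warning("normalize: clamped %d foreground values beyond ±d_max", n_over)
    dc = np.clip(d, -scale.d_max, scale.d_max)
    span = scale.intensity_hi - scale.intensity_lo
    intensity = scale.intensity_lo + (dc + scale.d_max) * span / (2.0 * scale.d_max)
    out = intensity / float(scale.intensity_hi)
    return np.where(foreground, out, scale.background_sentinel)


def denormalize(v: np.ndarray, scale: AffineScale,
                threshold: float = FOREGROUND_THRESHOLD):
    """Invert :func:`normalize`.

    Returns ``(d, foreground)``: the signed mm field and the mask of pixels
    deemed foreground (normalized value > threshold); background entries of
    ``d`` are set to 0 and excluded from the mask.
    """
    v = np.asarray(v, dtype=np.float64)
    foreground = v > threshold
    intensity = v * float(scale.intensity_hi)
    span = scale.intensity_hi - scale.intensity_lo
    d = (intensity - scale.intensity_lo) * (2.0 * scale.d_max) / span - scale.d_max
    return np.where(foreground, d, 0.0), foreground


def center_crop(stack: np.ndarray, size: int = 128) -> np.ndarray:
    """Centered spatial crop of a (..., H, W) stack to size x size."""
    H, W = stack.shape[-2:]
    if H < size or W < size:
        raise ValueError(f"cannot center-crop {H}x{W} to {size}x{size}: input smaller")
    r0 = (H - size) // 2
    c0 = (W - size) // 2
    out = stack[..., r0:r0 + size, c0:c0 + size]
    if out.any():
        # warn if the foreground centroid fell outside the crop window
        fg = np.argwhere(stack.reshape(-1, H, W).sum(axis=0) > 0)
        if fg.size:
            cr, cc = fg.mean(axis=0)
            if not (r0 <= cr < r0 + size and c0 <= cc < c0 + size):
                logger.warning("center_crop: foreground centroid outside crop window")
    return out


# ---------------------------------------------------------------------------
# NIfTI round trips
# ---------------------------------------------------------------------------

def _affine(spacing: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = spacing
    return aff


def write_volume(obj, path) -> None:
    """Write a CineSequence or DisplacementSequence as NIfTI.

    Masks are stored (H, W, T) uint8; displacement fields (H, W, T, 2)
    float32 with an AffineScale JSON sidecar when one is attached.
    """
    path = Path(path)
    if isinstance(obj, CineSequence):
        arr = np.ascontiguousarray(obj.frames.transpose(1, 2, 0)).astype(np.uint8)
        img = nib.Nifti1Image(arr, _affine(obj.pixel_spacing))
        img.header.set_zooms((obj.pixel_spacing, obj.pixel_spacing, 1.0))
        nib.save(img, str(path))
    elif isinstance(obj, DisplacementSequence):
        arr = np.stack([obj.ux, obj.uy], axis=-1).transpose(1, 2, 0, 3).astype(np.float32)
        img = nib.Nifti1Image(np.ascontiguousarray(arr), _affine(obj.pixel_spacing))
        img.header.set_zooms((obj.pixel_spacing, obj.pixel_spacing, 1.0, 1.0))
        nib.save(img, str(path))
        mask_img = nib.Nifti1Image(obj.foreground_mask.astype(np.uint8),
                                   _affine(obj.pixel_spacing))
        nib.save(mask_img, str(_companion_path(path, "_fg")))
        if obj.scale is not None:
            obj.scale.to_json(_sidecar_path(path))
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")


def _companion_path(path, tag: str) -> Path:
    """Path of a companion file: volume.nii.gz -> volume<tag>.nii.gz etc."""
    s = str(path)
    for suf in (".nii.gz", ".nii"):
        if s.endswith(suf):
            return Path(s[: -len(suf)] + tag + suf)
    return Path(s + tag + ".nii.gz")


def _sidecar_path(path) -> Path:
    s = str(path)
    for suf in (".nii.gz", ".nii"):
        if s.endswith(suf):
            return Path(s[: -len(suf)] + "_scale.json")
    return Path(s + "_scale.json")


def read_volume(path, expected_frames: int | None = None):
    """Read a NIfTI volume back into a CineSequence or DisplacementSequence.

    3-D volumes (H, W, T) are interpreted as mask stacks; 4-D volumes
    (H, W, T, 2) as displacement fields. An adjacent ``*_scale.json``
    sidecar, if present, is attached as the AffineScale.
    """
    path = Path(path)
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    spacing = float(img.header.get_zooms()[0])
    if arr.ndim == 3:
        frames = arr.transpose(2, 0, 1)
        if expected_frames is not None and frames.shape[0] != expected_frames:
            raise ValueError(
                f"frame axis has {frames.shape[0]} frames, expected {expected_frames}")
        return CineSequence(frames=frames.astype(np.uint8), pixel_spacing=spacing)
    if arr.ndim == 4:
        if arr.shape[-1] != 2:
            raise ValueError(
                f"component axis (last) has size {arr.shape[-1]}, expected 2 (ux, uy)")
        u = arr.transpose(2, 0, 1, 3)
        if expected_frames is not None and u.shape[0] != expected_frames:
            raise ValueError(
                f"frame axis has {u.shape[0]} frames, expected {expected_frames}")
        fg_path = _companion_path(path, "_fg")
        if fg_path.exists():
            fg = np.asarray(nib.load(str(fg_path)).dataobj).astype(bool)
        else:
            fg = (np.abs(u[..., 0]) + np.abs(u[..., 1]) > 0).any(axis=0)
        sidecar = _sidecar_path(path)
        scale = AffineScale.from_json(sidecar) if sidecar.exists() else None
        return DisplacementSequence(
            ux=u[..., 0].astype(np.float64), uy=u[..., 1].astype(np.float64),
            foreground_mask=fg, pixel_spacing=spacing, scale=scale)
    raise ValueError(
        f"unsupported NIfTI rank {arr.ndim}: expected 3 axes (H, W, T) for masks "
        "or 4 axes (H, W, T, 2) for displacements")
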