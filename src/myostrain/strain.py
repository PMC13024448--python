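"""Lagrangian strain from dense displacement fields.

Pipeline per frame: displacement u = (u_x, u_y) in mm on the reference
grid → spatial gradient by masked central finite differences (one-sided at
mask edges) → deformation gradient F = I + ∇u → Green–Lagrange tensor
E = (FᵀF − I)/2 → projection onto the local circumferential and radial
directions about the LV center → per-pixel Ecc and Err maps → averages
over the six AHA short-axis segments.

Gradients are taken in pixel units (u / pixel_spacing against unit pixel
steps), which makes F dimensionless; E is invariant to rigid motion and,
because central differences are exact for affine fields, rigid or uniform
-scaling displacement fields reproduce their closed-form strains to
round-off.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .data_io import DisplacementSequence

logger = logging.getLogger("myostrain")

__all__ = ["DeformationState", "PolarFrame", "lv_center", "polar_frame",
           "compute_strain_maps", "aha_segment_labels", "segment_strain_table",
           "sequence_strain_tables", "peak_strain", "AHA_SEGMENT_NAMES"]

AHA_SEGMENT_NAMES = {1: "anterior", 2: "anteroseptal", 3: "inferoseptal",
                     4: "inferior", 5: "inferolateral", 6: "anterolateral"}


@dataclasses.dataclass
class DeformationState:
    """Per-pixel deformation gradient and Green–Lagrange tensor."""

    F: np.ndarray          # (H, W, 2, 2)
    E: np.ndarray          # (H, W, 2, 2), symmetric where valid
    validity: np.ndarray   # (H, W) bool — pixels with computable gradients


@dataclasses.dataclass
class PolarFrame:
    """Local radial/circumferential unit vectors about the LV center."""

    center: tuple[float, float]    # (row, col) pixels
    e_r: np.ndarray                # (H, W, 2) — (x, y) components, center→pixel
    e_c: np.ndarray                # (H, W, 2) — e_r rotated +90° (counterclockwise)


def lv_center(mask: np.ndarray) -> tuple[float, float]:
    """Sub-pixel centroid of the myocardium mask (automatic LV localization)."""
    mask = np.asarray(mask).astype(bool)
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValueError("empty myocardium mask")
    # a C-shaped (interrupted) wall still has a well-defined centroid, but
    # flag it: the centroid may sit off the true blood-pool center
    from scipy import ndimage
    n_comp = ndimage.label(mask)[1]
    if n_comp > 1:
        logger.warning("lv_center: mask has %d connected components", n_comp)
    r, c = idx.mean(axis=0)
    return float(r), float(c)


def polar_frame(shape: tuple[int, int], center: tuple[float, float]) -> PolarFrame:
    H, W = shape
    cr, cc = center
    rows, cols = np.mgrid[0:H, 0:W].astype(np.float64)
    dx = cols - cc               # x = column direction
    dy = rows - cr               # y = row direction
    r = np.hypot(dx, dy)
    with np.errstate(invalid="ignore", divide="ignore"):
        ex = np.where(r > 0, dx / r, 1.0)
        ey = np.where(r > 0, dy / r, 0.0)
    e_r = np.stack([ex, ey], axis=-1)
    e_c = np.stack([-ey, ex], axis=-1)    # +90° rotation of e_r
    return PolarFrame(center=center, e_r=e_r, e_c=e_c)


def _masked_gradient(f: np.ndarray, mask: np.ndarray, axis: int):
    """d f / d axis with unit pixel step, respecting the mask.

    Central difference where both neighbours are in-mask, one-sided where
    exactly one is, invalid where neither. Returns (gradient, valid).
    """
    fwd = np.roll(f, -1, axis=axis)
    bwd = np.roll(f, 1, axis=axis)
    m_fwd = np.roll(mask, -1, axis=axis)
    m_bwd = np.roll(mask, 1, axis=axis)
    # rolled-over borders are outside the grid
    edge_lo = [slice(None)] * f.ndim
    edge_hi = [slice(None)] * f.ndim
    edge_lo[axis] = 0
    edge_hi[axis] = -1
    m_bwd = m_bwd.copy()
    m_fwd = m_fwd.copy()
    m_bwd[tuple(edge_lo)] = False
    m_fwd[tuple(edge_hi)] = False

    grad = np.zeros_like(f)
    both = m_fwd & m_bwd
    only_f = m_fwd & ~m_bwd
    only_b = ~m_fwd & m_bwd
    grad[both] = (fwd[both] - bwd[both]) / 2.0
    grad[only_f] = fwd[only_f] - f[only_f]
    grad[only_b] = f[only_b] - bwd[only_b]
    valid = mask & (m_fwd | m_bwd)
    return grad, valid


def compute_strain_maps(ux: np.ndarray, uy: np.ndarray, mask: np.ndarray,
                        frame: PolarFrame, pixel_spacing: float):
    """One frame: displacement (mm) → (DeformationState, Ecc map, Err map).

    Ecc/Err maps are strain fractions (not percent), NaN where invalid.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty myocardium mask")
    upx = np.asarray(ux, dtype=np.float64) / pixel_spacing   # pixels
    upy = np.asarray(uy, dtype=np.float64) / pixel_spacing
    dux_dx, vx1 = _masked_gradient(upx, mask, axis=1)   # x = columns
    dux_dy, vy1 = _masked_gradient(upx, mask, axis=0)
    duy_dx, vx2 = _masked_gradient(upy, mask, axis=1)
    duy_dy, vy2 = _masked_gradient(upy, mask, axis=0)
    valid = mask & vx1 & vy1 & vx2 & vy2
    if not valid.any():
        raise ValueError("mask too thin: no pixel has an in-mask neighbour "
                         "in both directions")

    H, W = mask.shape
    gradu = np.empty((H, W, 2, 2))
    gradu[..., 0, 0] = dux_dx
    gradu[..., 0, 1] = dux_dy
    gradu[..., 1, 0] = duy_dx
    gradu[..., 1, 1] = duy_dy
    F = np.eye(2) + gradu
    E = 0.5 * (np.einsum("hwki,hwkj->hwij", F, F) - np.eye(2))

    ec, er = frame.e_c, frame.e_r
    ecc = np.einsum("hwi,hwij,hwj->hw", ec, E, ec)
    err = np.einsum("hwi,hwij,hwj->hw", er, E, er)
    ecc = np.where(valid, ecc, np.nan)
    err = np.where(valid, err, np.nan)
    return DeformationState(F=F, E=E, validity=valid), ecc, err


def aha_segment_labels(mask: np.ndarray, center: tuple[float, float],
                       reference_angle: float = 90.0) -> np.ndarray:
    """Assign mask pixels to the six AHA sectors by polar angle.

    Angles are measured counterclockwise (image "up" = 90°) from the
    positive x (column) direction; sector s covers
    [reference_angle + (s−1)·60°, reference_angle + s·60°). Ordering:
    1 anterior, 2 anteroseptal, 3 inferoseptal, 4 inferior,
    5 inferolateral, 6 anterolateral. Background is labelled 0.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty myocardium mask")
    H, W = mask.shape
    cr, cc = center
    rows, cols = np.mgrid[0:H, 0:W].astype(np.float64)
    # counterclockwise with y pointing up in image terms → negate the row offset
    ang = np.degrees(np.arctan2(-(rows - cr), cols - cc))
    sector = np.floor(((ang - reference_angle) % 360.0) / 60.0).astype(int) + 1
    return np.where(mask, sector, 0)


def segment_strain_table(ecc_map: np.ndarray, err_map: np.ndarray,
                         labels: np.ndarray, validity: np.ndarray | None = None,
                         frame: int = 0) -> pd.DataFrame:
    """Average per-pixel strains within each AHA segment, in percent.

    Rows: segments 1..6 plus segment 0 = global (pixel-count-weighted mean,
    equivalently the mean over all valid pixels). Segments with no valid
    pixel appear with NaN strain and n_pixels = 0.
    """
    labels = np.asarray(labels)
    valid = ~np.isnan(ecc_map)
    if validity is not None:
        valid = valid & np.asarray(validity, dtype=bool)
    rows = []
    total_n = 0
    for s in range(1, 7):
        sel = (labels == s) & valid
        n = int(sel.sum())
        total_n += n
        rows.append({
            "frame": frame, "segment": s, "n_pixels": n,
            "Ecc_percent": 100.0 * float(ecc_map[sel].mean()) if n else np.nan,
            "Err_percent": 100.0 * float(err_map[sel].mean()) if n else np.nan,
        })
    if total_n == 0:
        raise ValueError("no valid pixels in any segment")
    allsel = (labels > 0) & valid
    rows.append({"frame": frame, "segment": 0, "n_pixels": int(allsel.sum()),
                 "Ecc_percent": 100.0 * float(ecc_map[allsel].mean()),
                 "Err_percent": 100.0 * float(err_map[allsel].mean())})
    return pd.DataFrame(rows)


def sequence_strain_tables(disp: DisplacementSequence,
                           mask: np.ndarray | None = None,
                           reference_angle: float = 90.0,
                           center: tuple[float, float] | None = None) -> pd.DataFrame:
    """Strain tables for every frame of a displacement sequence.

    The reference-frame myocardium mask defaults to the sequence's
    foreground; the LV center defaults to the mask centroid.
    """
    mask = disp.foreground_mask if mask is None else np.asarray(mask).astype(bool)
    ctr = center or lv_center(mask)
    pf = polar_frame(mask.shape, ctr)
    labels = aha_segment_labels(mask, ctr, reference_angle)
    tables = []
    for t in range(disp.n):
        _, ecc, err = compute_strain_maps(disp.ux[t], disp.uy[t], mask, pf,
                                          disp.pixel_spacing)
        tables.append(segment_strain_table(ecc, err, labels, frame=t))
    return pd.concat(tables, ignore_index=True)


def peak_strain(tables: pd.DataFrame) -> pd.DataFrame:
    """Per-segment peak-magnitude strain over the cycle (sign preserved).

    For each segment and each of Ecc/Err, the value with maximal absolute
    magnitude across frames, with the frame index where it occurs.
    """
    if tables["frame"].nunique() < 2:
        raise ValueError("need at least 2 frames for a temporal peak")
    out = []
    for s, grp in tables.groupby("segment"):
        row = {"segment": s}
        for col in ("Ecc_percent", "Err_percent"):
            vals = grp[col].to_numpy()
            frames = grp["frame"].to_numpy()
            ok = ~np.isnan(vals)
            if not ok.any():
                row[col] = np.nan
                row[col.replace("_percent", "_peak_frame")] = -1
                continue
            k = np.nanargmax(np.abs(np.where(ok, vals, 0.0)))
            row[col] = float(vals[k])
            row[col.replace("_percent", "_peak_frame")] = int(frames[k])
        out.append(row)
    return pd.DataFrame(out)
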