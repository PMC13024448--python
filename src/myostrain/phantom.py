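"""Synthetic deforming-annulus phantom with analytic displacement and strain.

The phantom emulates a mid-ventricular short-axis slice: an annular left
ventricular myocardium mask deforming over the cardiac cycle.  The motion
is an analytic map applied to reference (frame-0) material points,

    phi_t(r, theta) = ( r - a(t) * g(r),  theta + beta(t) ),

a radial contraction composed with a rigid twist, both modulated by a
raised-cosine ramp that rises from 0 at frame 0 to 1 at ``peak_frame``
(peak systole) and falls back towards 0 at the final frame.  The radial
profile

    g(r) = Ri * cos^2( (pi/2) * (r - Ri) / (Ro - Ri) )

is smooth, maximal at the endocardium (so ``contraction_amplitude`` is the
peak fractional inward endocardial displacement) and vanishes with zero
slope at the epicardium.  Its stretches are closed-form:

    lambda_c(r) = r'(r)/r = 1 - a(t) g(r)/r          (circumferential)
    lambda_r(r) = dr'/dr  = 1 - a(t) g'(r)           (radial)

giving Green–Lagrange strains Ecc = (lambda_c^2 - 1)/2 <= 0 and
Err = (lambda_r^2 - 1)/2 >= 0 — the physiologic systolic signs
(circumferential shortening, wall thickening).  The twist is rigid and
contributes no strain.

The phantom plays the role of a tagging-derived reference standard: its
displacement fields are what a dense motion-estimation method would
measure, and its closed-form segment strains are the oracle the strain
pipeline is validated against.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import integrate

from .data_io import CineSequence, DisplacementSequence

__all__ = ["PhantomSpec", "PhantomTruth", "make_phantom", "analytic_segment_strain",
           "make_dataset"]


@dataclasses.dataclass
class PhantomSpec:
    """Geometry and motion parameters of the deforming annulus."""

    grid_size: int = 128
    n_frames: int = 20
    center: tuple[float, float] = (64.0, 64.0)    # (row, col) pixels
    inner_radius: float = 2.2                     # mm (endocardium)
    outer_radius: float = 3.8                     # mm (epicardium)
    pixel_spacing: float = 0.1                    # mm / pixel
    contraction_amplitude: float = 0.12           # peak fractional endo contraction
    twist_amplitude: float = 0.10                 # radians peak rotation
    peak_frame: int = 9
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError("need 0 < inner_radius < outer_radius")
        if not 0 <= self.peak_frame < self.n_frames:
            raise ValueError("peak_frame must lie in [0, n_frames)")
        if not 0 <= self.contraction_amplitude < 1:
            raise ValueError("contraction_amplitude must keep the inner radius positive")
        wall_px = (self.outer_radius - self.inner_radius) / self.pixel_spacing
        if wall_px < 2:
            raise ValueError(
                f"degenerate annulus: wall is {wall_px:.2f} px across (< 2 px)")


@dataclasses.dataclass
class PhantomTruth:
    """Analytic ground truth attached to a phantom sequence."""

    displacement: DisplacementSequence        # analytic field on the reference grid
    segment_table: pd.DataFrame               # frame, segment, Ecc, Err (fractions)
    ramp: np.ndarray                          # a(t)/A, the temporal modulation

    def segment_table_percent(self) -> pd.DataFrame:
        t = self.segment_table.copy()
        t["Ecc_percent"] = 100.0 * t.pop("Ecc")
        t["Err_percent"] = 100.0 * t.pop("Err")
        return t


def _ramp(n_frames: int, peak_frame: int) -> np.ndarray:
    """Raised-cosine 0 → 1 → 0 modulation, peaking at peak_frame."""
    t = np.arange(n_frames, dtype=np.float64)
    w = np.zeros(n_frames)
    p = peak_frame
    if p > 0:
        up = t <= p
        w[up] = 0.5 * (1.0 - np.cos(np.pi * t[up] / p))
    else:
        w[0] = 1.0
    tail = n_frames - 1 - p
    if tail > 0:
        down = t > p
        w[down] = 0.5 * (1.0 - np.cos(np.pi * (n_frames - 1 - t[down]) / tail))
    return w


def _g(spec: PhantomSpec, r: np.ndarray) -> np.ndarray:
    ri, ro = spec.inner_radius, spec.outer_radius
    u = (np.pi / 2.0) * (np.asarray(r) - ri) / (ro - ri)
    out = ri * np.cos(u) ** 2
    return np.where((r >= ri) & (r <= ro), out, 0.0)


def _g_prime(spec: PhantomSpec, r: np.ndarray) -> np.ndarray:
    ri, ro = spec.inner_radius, spec.outer_radius
    u = (np.pi / 2.0) * (np.asarray(r) - ri) / (ro - ri)
    out = -ri * (np.pi / (2.0 * (ro - ri))) * np.sin(2.0 * u)
    return np.where((r >= ri) & (r <= ro), out, 0.0)


def _amplitudes(spec: PhantomSpec, frame: int) -> tuple[float, float]:
    w = _ramp(spec.n_frames, spec.peak_frame)[frame]
    return spec.contraction_amplitude * w, spec.twist_amplitude * w


def make_phantom(spec: PhantomSpec):
    """Render the phantom: masks, analytic displacement fields, ground truth.

    Returns ``(cine, displacement, truth)``. Masks are rendered per frame
    by thresholding the signed distance of the deformed annulus at pixel
    centers; displacements live on the frame-0 reference grid (Lagrangian),
    zero at frame 0 and outside the reference myocardium.
    """
    n = spec.grid_size
    cr, cc = spec.center
    rows, cols = np.mgrid[0:n, 0:n].astype(np.float64)
    px = (cols - cc) * spec.pixel_spacing   # mm, column direction
    py = (rows - cr) * spec.pixel_spacing   # mm, row direction
    r = np.hypot(px, py)

    ri, ro = spec.inner_radius, spec.outer_radius
    ref_mask = (r >= ri) & (r <= ro)
    if ref_mask.sum() < 4:
        raise ValueError("degenerate annulus: fewer than 4 pixels in the wall")

    masks = np.zeros((spec.n_frames, n, n), dtype=np.uint8)
    ux = np.zeros((spec.n_frames, n, n), dtype=np.float64)
    uy = np.zeros_like(ux)
    for t in range(spec.n_frames):
        a, beta = _amplitudes(spec, t)
        # deformed annulus: radial map is monotone, so its image is the band
        # [r'(Ri), r'(Ro)]; the rigid twist maps the band onto itself
        ri_t = ri - a * _g(spec, np.array(ri))
        ro_t = ro - a * _g(spec, np.array(ro))
        signed_dist = np.maximum(ri_t - r, r - ro_t)
        masks[t] = (signed_dist <= 0).astype(np.uint8)

        rp = r - a * _g(spec, r)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(r > 0, rp / r, 1.0)
        cb, sb = np.cos(beta), np.sin(beta)
        new_x = scale * (cb * px - sb * py)
        new_y = scale * (sb * px + cb * py)
        ux[t] = np.where(ref_mask, new_x - px, 0.0)
        uy[t] = np.where(ref_mask, new_y - py, 0.0)

    cine = CineSequence(frames=masks, pixel_spacing=spec.pixel_spacing,
                        scan_id=f"phantom-{spec.seed}")
    disp = DisplacementSequence(ux=ux, uy=uy, foreground_mask=ref_mask,
                                pixel_spacing=spec.pixel_spacing,
                                scan_id=f"phantom-{spec.seed}")

    rows_out = []
    for t in range(spec.n_frames):
        seg = analytic_segment_strain(spec, t)
        for s in range(1, 7):
            rows_out.append({"frame": t, "segment": s,
                             "Ecc": seg[s][0], "Err": seg[s][1]})
    table = pd.DataFrame(rows_out)
    truth = PhantomTruth(displacement=disp, segment_table=table,
                         ramp=_ramp(spec.n_frames, spec.peak_frame))
    return cine, disp, truth


def analytic_segment_strain(spec: PhantomSpec, frame: int) -> dict[int, tuple[float, float]]:
    """Closed-form wall-averaged (Ecc, Err) per AHA segment at one frame.

    The motion is axisymmetric, so all six segments share the same value:
    the area-weighted average over the reference annulus,
    ``∫ E(r) r dr / ∫ r dr`` on [Ri, Ro], evaluated by adaptive quadrature.
    """
    if not 0 <= frame < spec.n_frames:
        raise ValueError(f"frame {frame} outside [0, {spec.n_frames})")
    a, _ = _amplitudes(spec, frame)
    ri, ro = spec.inner_radius, spec.outer_radius

    def ecc_r(r):
        lam_c = 1.0 - a * _g(spec, r) / r
        return 0.5 * (lam_c ** 2 - 1.0) * r

    def err_r(r):
        lam_r = 1.0 - a * _g_prime(spec, r)
        return 0.5 * (lam_r ** 2 - 1.0) * r

    area, _ = integrate.quad(lambda r: r, ri, ro)
    ecc, _ = integrate.quad(ecc_r, ri, ro, limit=200)
    err, _ = integrate.quad(err_r, ri, ro, limit=200)
    ecc /= area
    err /= area
    return {s: (ecc, err) for s in range(1, 7)}


def smoke_spec(grid_size: int = 32, n_frames: int = 8) -> PhantomSpec:
    """Reduced-scale base spec for desk-scale (CPU) validation runs.

    Keeps the default annulus in mm and rescales pixel spacing so the wall
    spans the smaller grid proportionally (0.3 mm/px at 32x32, ~5 px across
    the wall); the deformation peaks mid-sequence.
    """
    return PhantomSpec(
        grid_size=grid_size, n_frames=n_frames,
        center=(grid_size / 2.0, grid_size / 2.0),
        pixel_spacing=0.3 * 32 / grid_size,
        peak_frame=n_frames // 2)


def make_dataset(n_scans: int, seed: int, base: PhantomSpec | None = None,
                 slices_per_scan: int = 3):
    """Generate a cohort of phantom scans with per-scan geometry/motion jitter.

    Mirrors the structure of a multi-slice short-axis study (a few slices
    per scan, ~3 as in a 64-slices-from-22-scans cohort). Contraction and
    twist amplitudes, base radii and center vary scan-to-scan (±15–30%
    around the base spec); within a scan, slices differ mildly in radii and
    center (apex-to-base taper and slice obliquity) while sharing the
    scan's motion amplitudes. A network trained on the cohort must
    therefore infer motion from geometry rather than memorize one annulus.
    Deterministic for a fixed seed.
    """
    base = base or PhantomSpec()
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_scans):
        ri_scan = base.inner_radius * rng.uniform(0.85, 1.15)
        wall_scan = (base.outer_radius - base.inner_radius) * rng.uniform(0.8, 1.2)
        center_scan = (base.center[0] + rng.uniform(-2.0, 2.0),
                       base.center[1] + rng.uniform(-2.0, 2.0))
        contraction = base.contraction_amplitude * rng.uniform(0.7, 1.3)
        twist = base.twist_amplitude * rng.uniform(0.7, 1.3)
        for j in range(slices_per_scan):
            ri = ri_scan * rng.uniform(0.92, 1.08)
            wall = wall_scan * rng.uniform(0.9, 1.1)
            jit = rng.uniform(-1.0, 1.0, size=2)
            spec = dataclasses.replace(
                base,
                inner_radius=ri,
                outer_radius=ri + wall,
                center=(center_scan[0] + jit[0], center_scan[1] + jit[1]),
                contraction_amplitude=contraction,
                twist_amplitude=twist,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            cine, disp, truth = make_phantom(spec)
            scan_id = f"scan{k:03d}"
            slice_id = f"slice{j}"
            cine.scan_id = disp.scan_id = scan_id
            cine.slice_id = disp.slice_id = slice_id
            out.append({"spec": spec, "cine": cine, "displacement": disp,
                        "truth": truth, "scan_id": scan_id, "slice_id": slice_id})
    return out
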