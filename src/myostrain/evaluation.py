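"""Agreement statistics between predicted and reference measurements.

Displacement-field metrics: SSIM (Gaussian window 11, sigma 1.5) on the
normalized images, per-component RMSE and mean endpoint error (EPE) in mm
over the myocardium mask. Strain agreement: ICC(2,1) (two-way random
effects, absolute agreement, single measurement), Pearson r, per-method
coefficient of variation, Bland–Altman bias and 1.96-SD limits of
agreement, and per-segment paired t-tests with Bonferroni correction
(factor 6, the segments within one strain family).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = ["AgreementReport", "ssim", "rmse_epe", "icc", "pearson_cv",
           "bland_altman", "segment_ttests", "agreement_report"]


@dataclasses.dataclass
class AgreementReport:
    """Container for the full method-agreement suite (JSON-serializable)."""

    ssim_x: float | None = None
    ssim_y: float | None = None
    rmse_x_mm: float | None = None
    rmse_y_mm: float | None = None
    epe_mm: float | None = None
    strain: dict | None = None          # per family: icc, pearson, cv, bland-altman
    ttests: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.ttests is not None:
            d["ttests"] = self.ttests.to_dict(orient="records")
        return d


# ---------------------------------------------------------------------------
# Displacement-field metrics
# ---------------------------------------------------------------------------

def ssim(a: np.ndarray, b: np.ndarray, dynamic_range: float = 1.0) -> float:
    """Structural similarity index of two 2-D images.

    Gaussian weighting (window 11, sigma 1.5, filters truncated at 3.5
    sigma, reflect boundary), K1 = 0.01, K2 = 0.03; the local SSIM map is
    averaged after cropping the half-window border.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    sigma, truncate = 1.5, 3.5
    pad = int(truncate * sigma + 0.5)     # = 5 → 11-pixel window

    def f(im):
        return ndimage.gaussian_filter(im, sigma=sigma, truncate=truncate,
                                       mode="reflect")

    ua, ub = f(a), f(b)
    uaa, ubb, uab = f(a * a), f(b * b), f(a * b)
    va = uaa - ua * ua
    vb = ubb - ub * ub
    cov = uab - ua * ub
    c1 = (0.01 * dynamic_range) ** 2
    c2 = (0.03 * dynamic_range) ** 2
    s = ((2 * ua * ub + c1) * (2 * cov + c2)) / (
        (ua ** 2 + ub ** 2 + c1) * (va + vb + c2))
    return float(s[pad:-pad, pad:-pad].mean())


def rmse_epe(pred_ux, pred_uy, ref_ux, ref_uy, mask):
    """Per-component RMSE and mean endpoint error over mask pixels, in mm.

    Accepts per-frame (H, W) fields or stacks (T, H, W) with a (H, W) mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty evaluation mask")
    arrs = [np.asarray(x, dtype=np.float64) for x in (pred_ux, pred_uy, ref_ux, ref_uy)]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("displacement component shapes differ")
    m = np.broadcast_to(mask, arrs[0].shape)
    dx = (arrs[0] - arrs[2])[m]
    dy = (arrs[1] - arrs[3])[m]
    rmse_x = float(np.sqrt(np.mean(dx ** 2)))
    rmse_y = float(np.sqrt(np.mean(dy ** 2)))
    epe = float(np.mean(np.hypot(dx, dy)))
    return rmse_x, rmse_y, epe


# ---------------------------------------------------------------------------
# Strain agreement
# ---------------------------------------------------------------------------

def icc(x, y) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    From the two-way ANOVA decomposition with n targets and k = 2 raters:

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("icc expects two equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("icc needs at least 3 paired measurements")
    data = np.stack([x, y], axis=1)          # rows = targets, cols = raters
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("icc undefined: zero total variance")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse)))


def pearson_cv(x, y):
    """Pearson r plus each method's coefficient of variation (percent)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson undefined: zero variance")
    r = float(stats.pearsonr(x, y).statistic)

    def cv(v):
        if np.mean(v) == 0:
            return float("nan")
        return float(100.0 * np.std(v, ddof=1) / abs(np.mean(v)))

    return r, cv(x), cv(y)


def bland_altman(x, y):
    """Mean bias of x − y, SD of differences, and 1.96-SD limits of agreement."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def segment_ttests(tables_a, tables_b, family_size: int = 6) -> pd.DataFrame:
    """Paired Student t-tests per AHA segment, Bonferroni-corrected.

    ``tables_a``/``tables_b``: per-slice segment tables (DataFrames with
    ``segment``, ``Ecc_percent``, ``Err_percent``), the same slices in the
    same order. Pairing is across slices within each segment; the
    Bonferroni factor is the number of segments per strain family.
    Identical samples give t = 0, p = 1 by convention.
    """
    if len(tables_a) != len(tables_b):
        raise ValueError("mismatched slice sets")
    if len(tables_a) < 3:
        raise ValueError("need at least 3 slices per method")
    rows = []
    for fam, col in (("Ecc", "Ecc_percent"), ("Err", "Err_percent")):
        for s in range(1, family_size + 1):
            a = np.array([float(t.loc[t["segment"] == s, col].iloc[0])
                          for t in tables_a])
            b = np.array([float(t.loc[t["segment"] == s, col].iloc[0])
                          for t in tables_b])
            diff = a - b
            if np.allclose(diff, 0.0):
                t_stat, p = 0.0, 1.0
            elif np.std(diff, ddof=1) == 0:
                t_stat, p = np.inf * np.sign(diff.mean()), 0.0
            else:
                res = stats.ttest_rel(a, b)
                t_stat, p = float(res.statistic), float(res.pvalue)
            rows.append({"family": fam, "segment": s, "t": t_stat, "p_raw": p,
                         "p_adjusted": min(1.0, family_size * p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def agreement_report(pred_norm=None, ref_norm=None,
                     pred_disp=None, ref_disp=None, mask=None,
                     strain_pairs: dict | None = None,
                     tables_a=None, tables_b=None) -> AgreementReport:
    """Assemble the full agreement suite from whatever inputs are given.

    ``pred_norm``/``ref_norm``: normalized (2, T, H, W) images → SSIM per
    component (frame-averaged). ``pred_disp``/``ref_disp`` + ``mask``:
    signed mm fields → RMSE/EPE. ``strain_pairs``: {family: (pred, ref)}
    1-D percent values → ICC/Pearson/CV/Bland–Altman. ``tables_a/b``:
    per-slice tables → paired t-tests.
    """
    rep = AgreementReport()
    if pred_norm is not None and ref_norm is not None:
        pred_norm = np.asarray(pred_norm)
        ref_norm = np.asarray(ref_norm)
        rep.ssim_x = float(np.mean([ssim(pred_norm[0, t], ref_norm[0, t])
                                    for t in range(pred_norm.shape[1])]))
        rep.ssim_y = float(np.mean([ssim(pred_norm[1, t], ref_norm[1, t])
                                    for t in range(pred_norm.shape[1])]))
    if pred_disp is not None and ref_disp is not None and mask is not None:
        rep.rmse_x_mm, rep.rmse_y_mm, rep.epe_mm = rmse_epe(
            pred_disp[0], pred_disp[1], ref_disp[0], ref_disp[1], mask)
    if strain_pairs:
        rep.strain = {}
        for fam, (a, b) in strain_pairs.items():
            a = np.asarray(a, dtype=np.float64)
            b = np.asarray(b, dtype=np.float64)
            r, cv_a, cv_b = pearson_cv(a, b)
            bias, sd, lo, hi = bland_altman(a, b)
            rep.strain[fam] = {
                "icc": icc(a, b), "pearson_r": r,
                "cv_pred_percent": cv_a, "cv_ref_percent": cv_b,
                "bias": bias, "sd_diff": sd, "loa_low": lo, "loa_high": hi,
                "n": int(a.size),
            }
    if tables_a is not None and tables_b is not None:
        rep.ttests = segment_ttests(tables_a, tables_b)
    return rep
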