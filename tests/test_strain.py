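"""Green–Lagrange strain computation and AHA segment analysis."""

import numpy as np
import pandas as pd
import pytest

from myostrain import (PhantomSpec, aha_segment_labels, analytic_segment_strain,
                       compute_strain_maps, lv_center, make_phantom, peak_strain,
                       polar_frame, segment_strain_table)
from myostrain.strain import sequence_strain_tables


@pytest.fixture(scope="module")
def annulus():
    spec = PhantomSpec()
    cine, disp, truth = make_phantom(spec)
    return spec, disp.foreground_mask


def _coords(shape, center, spacing):
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return (cols - center[1]) * spacing, (rows - center[0]) * spacing


class TestCenter:
    def test_symmetric_annulus_centroid(self, annulus):
        spec, mask = annulus
        r, c = lv_center(mask)
        assert r == pytest.approx(spec.center[0], abs=0.01)
        assert c == pytest.approx(spec.center[1], abs=0.01)

    def test_translation_equivariance(self, annulus):
        _, mask = annulus
        shifted = np.roll(np.roll(mask, 5, axis=0), -3, axis=1)
        r0, c0 = lv_center(mask)
        r1, c1 = lv_center(shifted)
        assert (r1 - r0, c1 - c0) == (pytest.approx(5.0), pytest.approx(-3.0))

    def test_c_shaped_mask_warns_but_returns(self, annulus, caplog):
        _, mask = annulus
        broken = mask.copy()
        broken[:, 60:68] = False   # cut the ring into a C
        with caplog.at_level("WARNING", logger="myostrain"):
            lv_center(broken)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            lv_center(np.zeros((8, 8), bool))


class TestStrainMaps:
    def test_zero_displacement_zero_strain(self, annulus):
        spec, mask = annulus
        pf = polar_frame(mask.shape, spec.center)
        st, ecc, err = compute_strain_maps(np.zeros(mask.shape), np.zeros(mask.shape),
                                           mask, pf, spec.pixel_spacing)
        assert np.nanmax(np.abs(ecc)) == 0.0
        assert np.nanmax(np.abs(err)) == 0.0

    def test_uniform_scaling_gives_0p105_everywhere(self, annulus):
        spec, mask = annulus
        px, py = _coords(mask.shape, spec.center, spec.pixel_spacing)
        ux, uy = 0.1 * px, 0.1 * py
        pf = polar_frame(mask.shape, spec.center)
        _, ecc, err = compute_strain_maps(ux, uy, mask, pf, spec.pixel_spacing)
        np.testing.assert_allclose(ecc[~np.isnan(ecc)], 0.105, atol=1e-9)
        np.testing.assert_allclose(err[~np.isnan(err)], 0.105, atol=1e-9)

    def test_rigid_motion_strain_free(self, annulus):
        spec, mask = annulus
        px, py = _coords(mask.shape, spec.center, spec.pixel_spacing)
        th = np.deg2rad(10.0)
        ux = np.cos(th) * px - np.sin(th) * py - px + 0.8
        uy = np.sin(th) * px + np.cos(th) * py - py - 0.4
        pf = polar_frame(mask.shape, spec.center)
        st, ecc, err = compute_strain_maps(ux, uy, mask, pf, spec.pixel_spacing)
        assert np.abs(st.E[st.validity]).max() <= 1e-9

    def test_tensor_symmetric_for_random_fields(self, annulus):
        spec, mask = annulus
        rng = np.random.default_rng(0)
        pf = polar_frame(mask.shape, spec.center)
        st, _, _ = compute_strain_maps(rng.normal(0, 0.2, mask.shape),
                                       rng.normal(0, 0.2, mask.shape),
                                       mask, pf, spec.pixel_spacing)
        asym = np.abs(st.E - np.swapaxes(st.E, -1, -2))[st.validity]
        assert asym.max() < 1e-12

    def test_empty_and_thin_masks_rejected(self, annulus):
        spec, mask = annulus
        pf = polar_frame(mask.shape, spec.center)
        with pytest.raises(ValueError):
            compute_strain_maps(np.zeros(mask.shape), np.zeros(mask.shape),
                                np.zeros(mask.shape, bool), pf, spec.pixel_spacing)
        lone = np.zeros(mask.shape, bool)
        lone[5, 5] = True
        with pytest.raises(ValueError, match="thin"):
            compute_strain_maps(np.zeros(mask.shape), np.zeros(mask.shape),
                                lone, pf, spec.pixel_spacing)


class TestSegments:
    def test_sector_membership_and_rotation_equivariance(self, annulus):
        spec, mask = annulus
        labels = aha_segment_labels(mask, spec.center, reference_angle=90.0)
        # a pixel 30 degrees counterclockwise of the reference sits in sector 1
        ang = np.deg2rad(120.0)
        r_px = 30
        row = int(round(spec.center[0] - r_px * np.sin(ang)))
        col = int(round(spec.center[1] + r_px * np.cos(ang)))
        assert labels[row, col] == 1
        shifted = aha_segment_labels(mask, spec.center, reference_angle=150.0)
        sel = labels > 0
        np.testing.assert_array_equal(shifted[sel], (labels[sel] - 2) % 6 + 1)

    def test_segment_pixel_counts_balanced(self, annulus):
        spec, mask = annulus
        labels = aha_segment_labels(mask, spec.center)
        counts = np.array([(labels == s).sum() for s in range(1, 7)])
        assert np.abs(counts - counts.mean()).max() <= 0.02 * counts.mean() + 2

    def test_uniform_map_table(self, annulus):
        spec, mask = annulus
        labels = aha_segment_labels(mask, spec.center)
        ecc = np.where(mask, 0.105, np.nan)
        err = np.where(mask, 0.105, np.nan)
        t = segment_strain_table(ecc, err, labels)
        assert np.allclose(t["Ecc_percent"], 10.5)
        assert np.allclose(t["Err_percent"], 10.5)

    def test_invalid_segment_reported_missing_and_global_weighted(self, annulus):
        spec, mask = annulus
        labels = aha_segment_labels(mask, spec.center)
        ecc = np.where(mask, 0.1, np.nan).astype(float)
        ecc[labels == 3] = np.nan
        t = segment_strain_table(ecc, ecc, labels)
        assert np.isnan(t.loc[t.segment == 3, "Ecc_percent"].iloc[0])
        assert t.loc[t.segment == 3, "n_pixels"].iloc[0] == 0
        ns = t[t.segment > 0].dropna()
        w = (ns["n_pixels"] * ns["Ecc_percent"]).sum() / ns["n_pixels"].sum()
        assert t.loc[t.segment == 0, "Ecc_percent"].iloc[0] == pytest.approx(w)


class TestPeak:
    def test_ramp_peak_frame_recovered(self):
        rows = []
        for f, v in enumerate([0.0, -2.0, -5.0, -3.0]):
            rows.append({"frame": f, "segment": 1, "n_pixels": 10,
                         "Ecc_percent": v, "Err_percent": -v})
        t = pd.DataFrame(rows)
        p = peak_strain(t)
        assert p.loc[0, "Ecc_percent"] == -5.0
        assert p.loc[0, "Ecc_peak_frame"] == 2
        assert p.loc[0, "Err_percent"] == 5.0

    def test_phantom_peak_matches_spec(self, small_phantom):
        spec, (cine, disp, truth) = small_phantom
        tables = sequence_strain_tables(disp)
        p = peak_strain(tables[tables.segment > 0])
        assert set(p["Ecc_peak_frame"]) == {spec.peak_frame}
        assert set(p["Err_peak_frame"]) == {spec.peak_frame}


def test_segment_average_converges_to_analytic_with_resolution():
    """Pixel-averaged strain of the rendered phantom approaches the
    closed-form wall average as the grid is refined (observed order >= 1)."""
    errs = []
    for grid, spacing in ((64, 0.2), (128, 0.1)):
        spec = PhantomSpec(grid_size=grid, center=(grid / 2., grid / 2.),
                           pixel_spacing=spacing)
        _, disp, _ = make_phantom(spec)
        tables = sequence_strain_tables(disp)
        got = tables.query("frame == @spec.peak_frame and segment == 0")
        ecc_a, err_a = analytic_segment_strain(spec, spec.peak_frame)[1]
        errs.append(abs(got["Err_percent"].iloc[0] / 100.0 - err_a))
    assert errs[1] < errs[0]
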