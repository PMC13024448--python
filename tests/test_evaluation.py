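"""Agreement metrics against independent reference implementations."""

import numpy as np
import pandas as pd
import pytest

from myostrain import (bland_altman, icc, pearson_cv, rmse_epe, segment_ttests,
                       ssim)


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(2024)


class TestSsim:
    def test_self_similarity_is_one(self, rng):
        a = rng.random((40, 40))
        assert ssim(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_luminance_shift_penalized(self, rng):
        a = rng.random((40, 40))
        assert ssim(a, a + 0.5) < 1.0

    def test_symmetry(self, rng):
        a = rng.random((32, 32))
        b = rng.random((32, 32))
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)

    def test_matches_reference_implementation(self, rng):
        skimage = pytest.importorskip("skimage.metrics")
        a = rng.random((48, 48))
        b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1)
        ref = skimage.structural_similarity(
            a, b, data_range=1.0, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False)
        assert ssim(a, b) == pytest.approx(ref, abs=1e-6)


class TestRmseEpe:
    def test_perfect_agreement(self, rng):
        u = rng.random((3, 8, 8))
        m = np.ones((8, 8), bool)
        assert rmse_epe(u, u, u, u, m) == (0.0, 0.0, 0.0)

    def test_three_four_five(self):
        z = np.zeros((2, 6, 6))
        m = np.ones((6, 6), bool)
        rx, ry, epe = rmse_epe(z + 3, z + 4, z, z, m)
        assert (rx, ry, epe) == (pytest.approx(3.0), pytest.approx(4.0),
                                 pytest.approx(5.0))

    def test_matches_naive_loop(self, rng):
        px, py = rng.normal(size=(2, 2, 5, 5))
        tx, ty = rng.normal(size=(2, 2, 5, 5))
        m = rng.random((5, 5)) < 0.7
        rx, ry, epe = rmse_epe(px, py, tx, ty, m)
        sx = sy = se = n = 0.0
        for t in range(2):
            for r in range(5):
                for c in range(5):
                    if m[r, c]:
                        dx, dy = px[t, r, c] - tx[t, r, c], py[t, r, c] - ty[t, r, c]
                        sx += dx ** 2
                        sy += dy ** 2
                        se += np.hypot(dx, dy)
                        n += 1
        assert rx == pytest.approx(np.sqrt(sx / n), abs=1e-12)
        assert ry == pytest.approx(np.sqrt(sy / n), abs=1e-12)
        assert epe == pytest.approx(se / n, abs=1e-12)

    def test_empty_mask_rejected(self):
        z = np.zeros((1, 4, 4))
        with pytest.raises(ValueError):
            rmse_epe(z, z, z, z, np.zeros((4, 4), bool))


class TestIcc:
    def test_identity_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 9.0])
        assert icc(x, x) == pytest.approx(1.0)

    def test_constant_offset_vs_anova_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 1.0
        # two-way ANOVA by hand: MSR = 2*var(rows), MSC from the offset
        data = np.stack([x, y], 1)
        n, k = data.shape
        grand = data.mean()
        msr = k * ((data.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (((data - data.mean(1, keepdims=True) - data.mean(0) + grand) ** 2)
               .sum() / ((n - 1) * (k - 1)))
        expect = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        assert icc(x, y) == pytest.approx(expect, abs=1e-12)
        assert icc(x, y) < 1.0   # Pearson would be exactly 1 here

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(10, 3, 30)
        y = x + rng.normal(0.5, 1.0, 30)
        n = x.size
        df = pd.DataFrame({
            "targets": np.tile(np.arange(n), 2),
            "raters": np.repeat(["a", "b"], n),
            "score": np.concatenate([x, y])})
        ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="score")
        ref_icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc(x, y) == pytest.approx(ref_icc2, abs=1e-6)

    def test_independent_noise_near_zero(self, rng):
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        assert abs(icc(x, y)) < 0.1

    def test_offset_icc_below_pearson(self, rng):
        x = rng.normal(size=50)
        y = x + 2.0
        r, _, _ = pearson_cv(x, y)
        assert icc(x, y) < abs(r)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc(np.ones(5), np.ones(5))


class TestPearsonCv:
    def test_proportional_and_antiproportional(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert pearson_cv(x, 2 * x)[0] == pytest.approx(1.0)
        assert pearson_cv(x, -x)[0] == pytest.approx(-1.0)

    def test_cv_direct_arithmetic(self):
        x = np.array([10.0, 12.0, 8.0, 10.0])
        _, cv_x, _ = pearson_cv(x, x + 1)
        assert cv_x == pytest.approx(100 * np.std(x, ddof=1) / 10.0, abs=1e-12)

    def test_degenerate_inputs_flagged(self):
        with pytest.raises(ValueError):
            pearson_cv(np.ones(4), np.array([1.0, 2.0, 3.0, 4.0]))


class TestBlandAltman:
    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0])
        bias, sd, lo, hi = bland_altman(x, x + 1)
        assert (bias, sd, lo, hi) == (-1.0, 0.0, -1.0, -1.0)

    def test_identity(self):
        x = np.array([1.0, 2.0, 3.0])
        assert bland_altman(x, x) == (0.0, 0.0, 0.0, 0.0)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 40))
        b1 = bland_altman(x, y)
        b2 = bland_altman(y, x)
        assert b1[0] == pytest.approx(-b2[0], abs=1e-12)
        assert b1[1] == pytest.approx(b2[1], abs=1e-12)

    def test_gaussian_coverage_within_limits(self, rng):
        x = rng.normal(size=1000)
        y = x + rng.normal(0.2, 1.0, 1000)
        bias, sd, lo, hi = bland_altman(x, y)
        d = x - y
        inside = np.mean((d >= lo) & (d <= hi))
        assert inside >= 0.93


def _tables(values):
    """Per-slice tables with identical Err and the given per-slice Ecc."""
    out = []
    for v in values:
        rows = [{"segment": s, "Ecc_percent": v + 0.01 * s, "Err_percent": 1.0}
                for s in range(1, 7)]
        out.append(pd.DataFrame(rows))
    return out


class TestTtests:
    def test_identical_tables_give_null_convention(self):
        ta = _tables([1.0, 2.0, 3.0, 4.0])
        res = segment_ttests(ta, ta)
        assert np.all(res["t"] == 0.0)
        assert np.all(res["p_adjusted"] == 1.0)

    def test_matches_textbook_paired_t(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.5, 2.0, 3.5, 3.0])
        res = segment_ttests(_tables(a), _tables(b))
        d = a - b
        t_expect = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy import stats
        p_expect = 2 * stats.t.sf(abs(t_expect), len(d) - 1)
        row = res[(res.family == "Ecc") & (res.segment == 1)].iloc[0]
        assert row["t"] == pytest.approx(t_expect, abs=1e-9)
        assert row["p_raw"] == pytest.approx(p_expect, abs=1e-9)
        assert np.all(res["p_adjusted"] == np.minimum(1.0, 6 * res["p_raw"]))

    def test_mismatched_slice_sets_rejected(self):
        with pytest.raises(ValueError):
            segment_ttests(_tables([1, 2, 3]), _tables([1, 2, 3, 4]))
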