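"""Hemodynamic metrics: TAWSS, OSI, frame errors, agreement statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wallshear.flatmap import Flatmap
from wallshear.metrics import (
    WSSSeries,
    bland_altman,
    frame_errors,
    icc_a1,
    linreg,
    osi,
    tawss,
)


def _series(mags, times=None, axis=(0.0, 0.0, 1.0), shape=(4, 6)):
    """Constant-per-frame WSS series with given signed magnitudes."""
    axis = np.asarray(axis, float)
    mask = np.ones(shape, bool)
    frames = [
        Flatmap(np.broadcast_to(m * axis, shape + (3,)).copy(), mask) for m in mags
    ]
    if times is None:
        times = np.arange(len(mags), dtype=float) * 100.0
    return WSSSeries(frames, np.asarray(times, float))


class TestTAWSS:
    def test_constant_magnitude(self):
        s = _series([2.0, 2.0, 2.0, 2.0])
        assert np.allclose(tawss(s).values, 2.0)

    def test_two_equal_duration_plateaus_average(self):
        # 1 Pa then 3 Pa, symmetric switch: time average is exactly 2 Pa
        s = _series([1.0, 1.0, 1.0, 3.0, 3.0, 3.0])
        assert np.allclose(tawss(s).values, 2.0)

    def test_nonnegative_on_random_series(self, rng):
        mags = rng.normal(size=12)
        s = _series(mags)
        assert np.all(tawss(s).values >= 0)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            _series([1.0])


class TestOSI:
    def test_constant_direction_zero(self):
        s = _series([1.0, 2.5, 0.7, 1.8, 1.0])
        assert np.allclose(osi(s).values, 0.0)

    def test_full_reversal_half(self):
        # symmetric square wave: sign flip midway between frames
        s = _series([1.0, 1.0, 1.0, 1.0, -1.0, -1.0, -1.0, -1.0])
        assert np.allclose(osi(s).values, 0.5)

    def test_quarter_cycle_reversal(self):
        # +1 for 3T/4, -1 for T/4 along one axis -> 0.5 (1 - |T/2| / T) = 0.25
        s = _series([1.0, 1.0, 1.0, 1.0, 1.0, -1.0, -1.0])
        assert np.allclose(osi(s).values, 0.25)

    def test_zero_magnitude_nodes_masked(self):
        s = _series([0.0, 0.0, 0.0])
        out = osi(s)
        assert not out.mask.any()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_bounds_on_random_series(self, seed):
        r = np.random.default_rng(seed)
        w = r.normal(size=(6, 3, 4, 3))
        mask = np.ones((3, 4), bool)
        frames = [Flatmap(f, mask) for f in w]
        out = osi(WSSSeries(frames, np.linspace(0, 800, 6)))
        vals = out.values[out.mask]
        assert np.all(vals >= 0.0) and np.all(vals <= 0.5 + 1e-12)

    def test_time_reversal_invariance(self, rng):
        w = rng.normal(size=(7, 3, 4, 3))
        mask = np.ones((3, 4), bool)
        t = np.linspace(0, 800, 7)
        fwd = [Flatmap(f, mask) for f in w]
        rev = [Flatmap(f, mask) for f in w[::-1]]
        a = osi(WSSSeries(fwd, t)).values
        b = osi(WSSSeries(rev, t)).values
        assert np.allclose(a, b)
        assert np.allclose(
            tawss(WSSSeries(fwd, t)).values, tawss(WSSSeries(rev, t)).values
        )

    def test_masked_nodes_ignored(self, rng):
        w = rng.normal(size=(5, 3, 4, 3))
        mask = np.ones((3, 4), bool)
        mask[0, 0] = False
        t = np.linspace(0, 800, 5)
        a = osi(WSSSeries([Flatmap(f, mask) for f in w], t))
        w2 = w.copy()
        w2[:, 0, 0, :] += 77.0
        b = osi(WSSSeries([Flatmap(f, mask) for f in w2], t))
        assert np.array_equal(a.values[a.mask], b.values[b.mask])


class TestFrameErrors:
    def test_perfect_agreement(self, rng):
        v = np.abs(rng.normal(size=(4, 6, 3))) + 0.1
        mask = np.ones((4, 6), bool)
        out = frame_errors(Flatmap(v, mask), Flatmap(v, mask))
        assert out["mae"] == 0.0
        assert out["rel_error"] == 0.0
        assert out["pearson"] == pytest.approx(1.0)

    def test_uniform_magnitude_shift(self, rng):
        mag = np.abs(rng.normal(size=(4, 6))) + 1.0
        mask = np.ones((4, 6), bool)
        ref = np.zeros((4, 6, 3))
        ref[..., 0] = mag
        pred = ref.copy()
        pred[..., 0] += 1.0
        out = frame_errors(Flatmap(pred, mask), Flatmap(ref, mask))
        assert out["mae"] == pytest.approx(1.0)
        assert out["pearson"] == pytest.approx(1.0)

    def test_relative_error_uses_peak_reference(self):
        mask = np.ones((2, 2), bool)
        ref = np.zeros((2, 2, 3))
        ref[..., 0] = [[4.0, 2.0], [1.0, 3.0]]
        pred = ref.copy()
        pred[..., 0] += 1.0
        out = frame_errors(Flatmap(pred, mask), Flatmap(ref, mask))
        assert out["rel_error"] == pytest.approx(25.0)

    def test_constant_reference_flags_undefined_pearson(self):
        mask = np.ones((3, 3), bool)
        ref = np.full((3, 3, 3), 1.0)
        pred = np.random.default_rng(0).normal(size=(3, 3, 3))
        out = frame_errors(Flatmap(pred, mask), Flatmap(ref, mask))
        assert out["pearson"] is None


def _brute_force_icc_a1(x, y):
    """Two-way ANOVA mean squares written out longhand."""
    data = np.stack([x, y], axis=1)
    n, k = data.shape
    grand = sum(data[i][j] for i in range(n) for j in range(k)) / (n * k)
    ms_rows = sum((sum(data[i]) / k - grand) ** 2 for i in range(n)) * k / (n - 1)
    ms_cols = sum((sum(data[:, j]) / n - grand) ** 2 for j in range(k)) * n / (k - 1)
    sse = sum(
        (data[i][j] - sum(data[i]) / k - sum(data[:, j]) / n + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (ms_rows - mse) / (ms_rows + (k - 1) * mse + k * (ms_cols - mse) / n)


class TestICC:
    def test_perfect_agreement_is_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert icc_a1(x, x) == pytest.approx(1.0)

    def test_constant_offset_penalized_below_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = x + 10.0
        assert icc_a1(x, y) < 0.2  # Pearson would be exactly 1

    def test_matches_brute_force_anova_on_small_table(self, rng):
        x = rng.normal(size=6) * 2 + 5
        y = x + rng.normal(size=6) * 0.5 + 0.3
        assert icc_a1(x, y) == pytest.approx(_brute_force_icc_a1(x, y), abs=1e-12)

    def test_matches_pingouin_reference(self, rng):
        import pandas as pd
        import pingouin as pg

        x = rng.normal(size=8) + 3
        y = x + rng.normal(size=8) * 0.4
        df = pd.DataFrame(
            {
                "target": np.repeat(np.arange(8), 2),
                "rater": np.tile(["a", "b"], 8),
                "score": np.stack([x, y], axis=1).ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="target", raters="rater", ratings="score")
        ref_a1 = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].item()
        assert icc_a1(x, y) == pytest.approx(ref_a1, abs=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            icc_a1([1.0, 2.0], [1.0, 2.0])


class TestBlandAltman:
    def test_identical_data_zero_bias_and_limits(self):
        x = np.array([1.0, 2.0, 3.0])
        out = bland_altman(x, x)
        assert out["bias"] == 0.0 and out["loa_low"] == 0.0 and out["loa_high"] == 0.0

    def test_two_point_sample(self):
        # diffs {-1, 0}: bias -0.5, sd = 1/sqrt(2), limits -0.5 -+ 1.96/sqrt(2)
        out = bland_altman(np.array([1.0, 2.0]), np.array([0.0, 2.0]))
        assert out["bias"] == pytest.approx(-0.5)
        assert out["loa_low"] == pytest.approx(-0.5 - 1.96 / np.sqrt(2))
        assert out["loa_high"] == pytest.approx(-0.5 + 1.96 / np.sqrt(2))

    def test_bias_invariant_to_common_shift(self, rng):
        x = rng.normal(size=10)
        y = x + rng.normal(size=10) * 0.1
        a = bland_altman(x, y)
        b = bland_altman(x + 5.0, y + 5.0)
        assert a["bias"] == pytest.approx(b["bias"])


def _brute_force_ols(x, y):
    """Normal equations assembled entry by entry."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    ss_res = sum((yi - slope * xi - intercept) ** 2 for xi, yi in zip(x, y))
    ss_tot = sum((yi - sy / n) ** 2 for yi in y)
    return slope, intercept, 1 - ss_res / ss_tot


class TestLinreg:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        out = linreg(x, 2 * x)
        assert out["slope"] == pytest.approx(2.0)
        assert out["r_squared"] == pytest.approx(1.0)

    def test_matches_brute_force_on_small_table(self, rng):
        x = rng.normal(size=9)
        y = 1.7 * x + rng.normal(size=9) * 0.3
        k, b, r2 = _brute_force_ols(x, y)
        out = linreg(x, y)
        assert out["slope"] == pytest.approx(k, abs=1e-12)
        assert out["intercept"] == pytest.approx(b, abs=1e-12)
        assert out["r_squared"] == pytest.approx(r2, abs=1e-12)

    def test_slope_recovers_unity_under_noise(self):
        r = np.random.default_rng(42)
        x = r.normal(size=5000) * 2 + 3
        y = x + r.normal(size=5000) * 0.2
        out = linreg(x, y)
        assert out["slope"] == pytest.approx(1.0, abs=0.02)

    def test_r_squared_in_unit_interval(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        out = linreg(x, y)
        assert 0.0 <= out["r_squared"] <= 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            linreg(np.ones(5), np.arange(5.0))


class TestMaskContract:
    def test_frame_errors_ignore_masked_nodes(self, rng):
        mask = np.ones((4, 6), bool)
        mask[0, :2] = False
        ref = np.abs(rng.normal(size=(4, 6, 3)))
        pred = ref + rng.normal(size=(4, 6, 3)) * 0.1
        base = frame_errors(Flatmap(pred, mask), Flatmap(ref, mask))
        pred2 = pred.copy()
        pred2[0, :2] = 1e6
        again = frame_errors(Flatmap(pred2, mask), Flatmap(ref, mask))
        assert base == again
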