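import numpy as np
import pytest

from pelvigrf.errors import InvalidParameterError
from pelvigrf.metrics import (
    bland_altman,
    compare_grf,
    heading_error,
    nrmse,
    pearson_corr,
    rms_diff,
)
from pelvigrf.signalproc import UniformSeries

FS = 100.0
G = 9.81
MASS = 74.3


def vec_series(values):
    return UniformSeries(0.0, FS, np.asarray(values, dtype=float))


def pbw_to_n(x):
    return x * MASS * G / 100.0


class TestRmsDiff:
    def test_identical_series(self):
        a = vec_series(np.random.default_rng(0).normal(size=(50, 3)))
        per_axis, mag = rms_diff(a, a, MASS)
        assert np.allclose(per_axis, 0.0) and mag == 0.0

    def test_constant_vertical_offset(self):
        a = vec_series(np.tile([0.0, 0.0, 700.0], (50, 1)))
        b = vec_series(np.tile([0.0, 0.0, 700.0 + pbw_to_n(2.0)], (50, 1)))
        per_axis, _ = rms_diff(a, b, MASS)
        assert np.isclose(per_axis[2], 2.0)

    def test_sinusoidal_difference(self):
        t = np.arange(0, 10, 1 / FS)
        a = np.zeros((t.size, 3))
        b = a.copy()
        b[:, 0] = pbw_to_n(np.sin(2 * np.pi * 1.0 * t))
        per_axis, _ = rms_diff(vec_series(a), vec_series(b), MASS)
        assert np.isclose(per_axis[0], 1.0 / np.sqrt(2.0), atol=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = vec_series(rng.normal(size=(30, 3))), vec_series(
            rng.normal(size=(30, 3)))
        assert np.allclose(rms_diff(a, b, MASS)[0], rms_diff(b, a, MASS)[0])

    def test_length_mismatch(self):
        with pytest.raises(InvalidParameterError):
            rms_diff(vec_series(np.zeros((10, 3))),
                     vec_series(np.zeros((9, 3))), MASS)


class TestPearson:
    def test_self_and_negated(self):
        a = vec_series(np.random.default_rng(2).normal(size=(40, 3)))
        assert np.allclose(pearson_corr(a, a), 1.0)
        assert np.allclose(pearson_corr(a, a.with_values(-a.values)), -1.0)

    def test_textbook_ten_sample_pair(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10.0])
        y = np.array([2, 1, 4, 3, 7, 5, 8, 6, 10, 9.0])
        sx, sy = x - x.mean(), y - y.mean()
        expected = (sx * sy).sum() / np.sqrt((sx ** 2).sum() * (sy ** 2).sum())
        a = vec_series(np.column_stack([x, x, x]))
        b = vec_series(np.column_stack([y, y, y]))
        assert np.allclose(pearson_corr(a, b), expected, atol=1e-12)

    def test_zero_variance_flagged_not_numbered(self):
        a = vec_series(np.random.default_rng(3).normal(size=(20, 3)))
        const = vec_series(np.ones((20, 3)))
        r = pearson_corr(a, const)
        assert np.all(np.isnan(r))


class TestNrmse:
    def test_zero_for_identical(self):
        a = vec_series(np.random.default_rng(4).normal(size=(30, 3)))
        assert np.allclose(nrmse(a, a), 0.0)

    def test_arithmetic(self):
        # RMS 5 against range 50 -> 10 %
        n = 1000
        ref = np.zeros((n, 3))
        ref[0, :] = 25.0
        ref[1, :] = -25.0
        a = ref + 5.0
        out = nrmse(vec_series(a), vec_series(ref))
        assert np.allclose(out, 10.0)

    def test_reference_anchored_asymmetry(self):
        rng = np.random.default_rng(5)
        a = vec_series(rng.normal(size=(50, 3)))
        b = vec_series(2.0 * rng.normal(size=(50, 3)))
        assert not np.allclose(nrmse(a, b), nrmse(b, a))

    def test_zero_range_rejected(self):
        a = vec_series(np.random.default_rng(6).normal(size=(10, 3)))
        with pytest.raises(InvalidParameterError):
            nrmse(a, vec_series(np.ones((10, 3))))


class TestBlandAltman:
    def test_identical_inputs(self):
        a = vec_series(np.random.default_rng(7).normal(size=(50, 3)))
        out = bland_altman(a, a, "vertical")
        assert out == {"mean_diff": 0.0, "iqr_low": 0.0, "iqr_high": 0.0}

    def test_constant_vertical_offset(self):
        a = vec_series(np.tile([0.0, 0.0, 700.0], (50, 1)))
        b = a.with_values(a.values + [0.0, 0.0, pbw_to_n(2.0)])
        out = bland_altman(a, b, "vertical", mass=MASS)
        assert np.isclose(out["mean_diff"], -2.0)
        assert np.isclose(out["iqr_low"], out["iqr_high"])

    def test_uniform_difference_quartiles(self):
        rng = np.random.default_rng(8)
        n = 20000
        base = np.zeros((n, 3))
        d = rng.uniform(-1.0, 1.0, size=n)
        a = base.copy()
        a[:, 2] = d
        out = bland_altman(vec_series(a), vec_series(base), "vertical")
        assert np.isclose(out["iqr_low"], -0.5, atol=0.03)
        assert np.isclose(out["iqr_high"], 0.5, atol=0.03)

    def test_shear_plane_compares_horizontal_magnitudes(self):
        a = vec_series(np.tile([3.0, 4.0, 100.0], (10, 1)))
        b = vec_series(np.tile([5.0, 0.0, 50.0], (10, 1)))
        out = bland_altman(a, b, "shear")
        assert np.isclose(out["mean_diff"], 0.0)

    def test_percentile_convention_pinned(self):
        # golden 11-point vector: linear interpolation quartiles
        d = np.arange(11, dtype=float)  # 0..10
        a = np.zeros((11, 3))
        a[:, 2] = d
        out = bland_altman(vec_series(a), vec_series(np.zeros((11, 3))),
                           "vertical")
        assert out["iqr_low"] == 2.5 and out["iqr_high"] == 7.5


class TestHeadingError:
    def test_identical_headings(self):
        frames = [np.array([1.0, 0.0])] * 5
        assert heading_error(frames, frames) == [0.0, 0.0, 0.0]

    def test_orthogonal_headings(self):
        a = [np.array([1.0, 0.0])] * 3
        b = [np.array([0.0, 1.0])] * 3
        assert np.allclose(heading_error(a, b), [90.0])

    def test_arccos_of_dot_product(self):
        a = [np.array([1.0, 0.0])] * 3
        b = [np.array([0.6, 0.8])] * 3
        assert np.allclose(heading_error(a, b), [np.degrees(np.arccos(0.6))])

    def test_first_and_last_excluded(self):
        a = [np.array([0.0, 1.0])] + [np.array([1.0, 0.0])] * 3 \
            + [np.array([0.0, 1.0])]
        out = heading_error(a, [np.array([1.0, 0.0])] * 5)
        assert np.allclose(out, [0.0, 0.0, 0.0])

    def test_count_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            heading_error([np.array([1.0, 0.0])] * 3,
                          [np.array([1.0, 0.0])] * 4)


def test_compare_grf_full_report():
    rng = np.random.default_rng(9)
    t = np.arange(0, 5, 1 / FS)
    base = np.column_stack([
        np.sin(2 * np.pi * 1.8 * t),
        np.sin(np.pi * 1.8 * t),
        100.0 + 20 * np.sin(2 * np.pi * 1.8 * t),
    ]) * MASS * G / 100.0
    noisy = base + rng.normal(0, pbw_to_n(1.0), base.shape)
    rep = compare_grf(UniformSeries(0, FS, noisy),
                      UniformSeries(0, FS, base), MASS)
    # Y has unit signal amplitude against unit noise: corr ~ sqrt(1/3)
    assert all(0.4 < r <= 1.0 for r in rep.corr) and rep.corr[2] > 0.99
    assert all(0.9 < v < 1.1 for v in rep.rms_pbw)
    d = rep.to_dict()
    assert set(d) >= {"rms_pbw", "corr", "nrmse_pct", "bland_altman_shear",
                      "bland_altman_vertical"}
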