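import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from pelvigrf.errors import InvalidParameterError, TooShortError
from pelvigrf.signalproc import (
    UniformSeries,
    butter_zero_phase,
    detrend_mean,
    differentiate,
    find_peaks,
    integrate_cumulative,
    savgol_smooth,
)

FS = 100.0


def series(values, fs=FS, t0=0.0):
    return UniformSeries(t0, fs, np.asarray(values, dtype=float))


def prominence_oracle(v, min_prominence):
    """Exhaustive O(n^2) topographic prominence.

    'Higher terrain' stops the scan when strictly higher, or equal with a
    smaller index (the leftmost of equal summits is the parent)."""
    out = []
    n = len(v)
    for i in range(1, n - 1):
        if not (v[i] > v[i - 1] and v[i] > v[i + 1]):
            continue
        left = [v[j] for j in range(i - 1, -1, -1)]
        lbase = v[i]
        for x in left:
            if x >= v[i]:
                break
            lbase = min(lbase, x)
        rbase = v[i]
        for j in range(i + 1, n):
            if v[j] > v[i]:
                break
            rbase = min(rbase, v[j])
        if v[i] - max(lbase, rbase) >= min_prominence:
            out.append(i)
    return out


class TestButterZeroPhase:
    def test_dc_gains(self):
        const = series(np.full(300, 4.2))
        low = butter_zero_phase(const, "low", 10.0)
        assert np.allclose(low.values, 4.2, atol=1e-9)
        high = butter_zero_phase(const, "high", 2.0)
        assert np.allclose(high.values, 0.0, atol=1e-9)

    def test_cutoff_frequency_gain_matches_analytic_squared_response(self):
        # forward + backward pass squares the magnitude response: a 2 Hz
        # sinusoid through a 2nd-order low-pass at 2 Hz keeps (1/sqrt2)^2
        t = np.arange(0, 10, 1 / FS)
        x = series(np.sin(2 * np.pi * 2.0 * t))
        y = butter_zero_phase(x, "low", 2.0)
        amp = np.abs(y.values[200:-200]).max()
        b, a = sps.butter(2, 2.0, fs=FS)
        _, h = sps.freqz(b, a, worN=[2.0], fs=FS)
        assert np.isclose(amp, np.abs(h[0]) ** 2, atol=0.02)
        assert np.isclose(amp, 0.5, atol=0.02)

    def test_invalid_cutoffs_rejected(self):
        x = series(np.random.default_rng(0).normal(size=100))
        with pytest.raises(InvalidParameterError):
            butter_zero_phase(x, "low", 60.0)  # beyond Nyquist
        with pytest.raises(InvalidParameterError):
            butter_zero_phase(x, "band", (5.0, 2.0))
        with pytest.raises(InvalidParameterError):
            butter_zero_phase(x, "notch", 5.0)

    def test_too_short_series_raises_instead_of_truncating(self):
        with pytest.raises(TooShortError):
            butter_zero_phase(series(np.ones(5)), "low", 5.0)

    @pytest.mark.parametrize("kind,cut", [("low", 8.0), ("high", 2.0),
                                          ("band", (1.0, 10.0))])
    def test_time_reversal_symmetry_and_linearity(self, kind, cut):
        rng = np.random.default_rng(42)
        x, y = rng.normal(size=400), rng.normal(size=400)
        fx = butter_zero_phase(series(x), kind, cut).values
        frev = butter_zero_phase(series(x[::-1]), kind, cut).values
        assert np.allclose(fx[::-1], frev, atol=1e-9)
        combo = butter_zero_phase(series(2.0 * x - 3.0 * y), kind, cut).values
        fy = butter_zero_phase(series(y), kind, cut).values
        assert np.allclose(combo, 2.0 * fx - 3.0 * fy, atol=1e-9)

    def test_vector_series_filtered_per_axis(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(200, 3))
        out = butter_zero_phase(series(v), "low", 5.0).values
        for ax in range(3):
            col = butter_zero_phase(series(v[:, ax]), "low", 5.0).values
            assert np.allclose(out[:, ax], col)


class TestDetrendMean:
    @pytest.mark.parametrize("vals,expected", [
        ([5.0, 5.0, 5.0], [0.0, 0.0, 0.0]),
        ([1.0, 2.0, 3.0], [-1.0, 0.0, 1.0]),
    ])
    def test_examples(self, vals, expected):
        assert np.allclose(detrend_mean(series(vals)).values, expected)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_output_mean_negligible(self, seed):
        v = np.random.default_rng(seed).normal(3.0, 10.0, size=257)
        out = detrend_mean(series(v)).values
        assert abs(out.mean()) < 1e-9 * max(1.0, np.abs(v).max())


class TestFindPeaks:
    def test_constant_has_no_peaks(self):
        assert find_peaks(series(np.ones(50)), 0.1) == []

    def test_sinusoid_maxima(self):
        t = np.arange(0, 3, 1 / FS)
        x = series(np.sin(2 * np.pi * 1.8 * t))
        idx = find_peaks(x, 0.2)
        assert idx == prominence_oracle(x.values, 0.2)
        # maxima roughly every 1/1.8 s
        assert np.allclose(np.diff(idx), 1 / 1.8 * FS, atol=1.0)

    def test_equal_twin_summits_keep_one(self):
        # two 1.0 peaks with a 0.9 saddle: only the parent summit clears a
        # 0.2 prominence screen
        v = [0.0, 1.0, 0.9, 1.0, 0.0]
        assert find_peaks(series(v), 0.2) == [1]
        assert prominence_oracle(v, 0.2) == [1]

    @given(st.integers(0, 2 ** 31 - 1), st.integers(10, 500))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_agrees_with_exhaustive_oracle(self, seed, n):
        v = np.random.default_rng(seed).normal(size=n)
        x = series(v)
        for prom in (0.1, 0.5, 1.5):
            assert find_peaks(x, prom) == prominence_oracle(v, prom)


class TestSavgol:
    def test_cubic_reproduced_exactly(self):
        t = np.linspace(0, 1, 101)
        v = 2 * t ** 3 - t ** 2 + 0.5 * t - 3
        out = savgol_smooth(series(v), 11).values
        assert np.max(np.abs(out[5:-5] - v[5:-5])) < 1e-9

    def test_constant_preserved(self):
        out = savgol_smooth(series(np.full(31, 7.0)), 11).values
        assert np.allclose(out, 7.0)

    def test_spike_attenuated(self):
        t = np.linspace(0, 1, 101)
        clean = t ** 3
        spiked = clean.copy()
        spiked[50] += 2.0
        out = savgol_smooth(series(spiked), 11).values
        assert abs(out[50] - clean[50]) < 0.5 * 2.0

    def test_invalid_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            savgol_smooth(series(np.ones(20)), 10)  # even
        with pytest.raises(InvalidParameterError):
            savgol_smooth(series(np.ones(5)), 11)  # longer than series


class TestCalculus:
    def test_constant_integral_and_zero(self):
        n, a = 501, 2.5
        out = integrate_cumulative(series(np.full(n, a))).values
        assert np.isclose(out[-1], a * (n - 1) / FS, atol=1e-9)
        assert np.allclose(integrate_cumulative(series(np.zeros(n))).values, 0)

    def test_sinusoid_whole_periods(self):
        f = 2.0
        t = np.arange(0, 2.0, 1 / FS)  # 4 whole periods
        out = integrate_cumulative(series(np.sin(2 * np.pi * f * t))).values
        assert abs(out[-1]) <= (2 * np.pi * f / FS) ** 2

    def test_derivative_examples(self):
        t = np.arange(0, 2, 1 / FS)
        ramp = differentiate(series(3.0 * t)).values
        assert np.allclose(ramp, 3.0, atol=1e-9)
        assert np.allclose(differentiate(series(np.full(50, 1.0))).values, 0.0)
        quad = differentiate(series(0.5 * 0.7 * t ** 2)).values
        assert np.allclose(quad[1:-1], 0.7 * t[1:-1], atol=0.7 / FS ** 2 * 10)

    def test_derivative_inverts_integral_in_interior(self):
        t = np.arange(0, 2, 1 / FS)
        x = np.sin(2 * np.pi * 1.3 * t)
        back = differentiate(integrate_cumulative(series(x))).values
        assert np.max(np.abs(back[2:-2] - x[2:-2])) < (2 * np.pi * 1.3) ** 2 / FS ** 2


class TestUniformSeries:
    def test_rejects_non_finite(self):
        with pytest.raises(InvalidParameterError):
            series([1.0, np.nan, 2.0])

    def test_slice_time_half_open(self):
        x = series(np.arange(100))
        sl = x.slice_time(0.10, 0.20)
        assert sl.n == 10 and sl.values[0] == 10
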