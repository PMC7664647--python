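"""Deterministic signal-processing primitives shared by every pipeline stage.

All operations act on :class:`UniformSeries`, a uniformly sampled scalar or
3-vector time series.  Filtering is zero-phase (forward-backward Butterworth),
which is what makes the downstream gait-event timing and per-step frame
construction free of filter-induced delays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate, signal

from .errors import InvalidParameterError, TooShortError

__all__ = [
    "UniformSeries",
    "butter_zero_phase",
    "detrend_mean",
    "find_peaks",
    "savgol_smooth",
    "integrate_cumulative",
    "differentiate",
]


@dataclass
class UniformSeries:
    """A uniformly sampled time series.

    Parameters
    ----------
    t0 : float
        Time of the first sample, seconds.
    fs : float
        Sample rate, Hz (> 0). Sample spacing is exactly ``1/fs``.
    values : ndarray
        Shape ``(n,)`` for scalar series or ``(n, 3)`` for 3-vector series.
        Must be finite everywhere.
    """

    t0: float
    fs: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise InvalidParameterError(f"fs must be > 0, got {self.fs}")
        if self.values.ndim not in (1, 2) or (
            self.values.ndim == 2 and self.values.shape[1] != 3
        ):
            raise InvalidParameterError(
                f"values must have shape (n,) or (n, 3), got {self.values.shape}"
            )
        if self.values.shape[0] < 1:
            raise TooShortError("series must contain at least one sample")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("series contains non-finite values")

    # -- basic views -------------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    @property
    def is_vector(self) -> bool:
        return self.values.ndim == 2

    def with_values(self, values: np.ndarray) -> "UniformSeries":
        return replace(self, values=np.asarray(values, dtype=float))

    def slice_time(self, start: float, stop: float) -> "UniformSeries":
        """Samples with start <= t < stop (half-open window)."""
        i0 = int(np.ceil((start - self.t0) * self.fs - 1e-9))
        i1 = int(np.ceil((stop - self.t0) * self.fs - 1e-9))
        i0, i1 = max(i0, 0), min(i1, self.n)
        if i1 <= i0:
            raise TooShortError("time window contains no samples")
        return UniformSeries(self.t0 + i0 / self.fs, self.fs, self.values[i0:i1])

    def index_at(self, time_s: float) -> int:
        return int(round((time_s - self.t0) * self.fs))


def _butter_sos_ba(band_kind: str, cutoff_hz, order: int, fs: float):
    nyq = fs / 2.0
    cut = np.atleast_1d(np.asarray(cutoff_hz, dtype=float))
    if band_kind in ("low", "high"):
        if cut.size != 1:
            raise InvalidParameterError(f"{band_kind}-pass expects one cutoff")
        if not 0.0 < cut[0] < nyq:
            raise InvalidParameterError(
                f"cutoff {cut[0]} Hz outside (0, {nyq}) Hz"
            )
        wn = cut[0]
        btype = "lowpass" if band_kind == "low" else "highpass"
    elif band_kind == "band":
        if cut.size != 2 or not cut[0] < cut[1]:
            raise InvalidParameterError("band-pass expects cutoff pair low < high")
        if not (0.0 < cut[0] and cut[1] < nyq):
            raise InvalidParameterError(
                f"cutoffs {cut} Hz outside (0, {nyq}) Hz"
            )
        wn = cut
        btype = "bandpass"
    else:
        raise InvalidParameterError(f"unknown band kind {band_kind!r}")
    return signal.butter(order, wn, btype=btype, fs=fs)


def butter_zero_phase(
    x: UniformSeries, band_kind: str, cutoff_hz, order: int = 2,
    padlen: int | None = None,
) -> UniformSeries:
    """Zero-phase Butterworth filter (forward, then backward).

    The two passes square the magnitude response and cancel the phase, so a
    second-order design has an effective fourth-order roll-off and no time
    shift.  Edges are handled by reflective (even) signal extension before
    the forward-backward pass, which suppresses start/stop transients
    without inventing data.  By default the pad is sized to the filter's
    impulse-response length (slowest-pole decay to 1e-12, capped at the
    series length), which makes the operation time-reversal symmetric;
    ``padlen`` overrides it where a short, localised transient is preferable
    (sub-second windows whose mirrored content is not representative).
    Vector series are filtered per axis.
    """
    b, a = _butter_sos_ba(band_kind, cutoff_hz, order, x.fs)
    min_len = 3 * (max(len(a), len(b)) - 1)
    if x.n <= min_len:
        raise TooShortError(
            f"series of {x.n} samples too short for order-{order} "
            f"zero-phase filtering (needs > {min_len})"
        )
    if padlen is None:
        poles = np.abs(np.roots(a))
        pmax = poles.max() if poles.size else 0.0
        if 0.0 < pmax < 1.0:
            ir = int(np.ceil(np.log(1e-12) / np.log(pmax)))
        else:  # pragma: no cover - Butterworth designs are always stable
            ir = min_len
        padlen = max(min_len, ir)
    padlen = int(min(x.n - 1, padlen))
    y = signal.filtfilt(b, a, x.values, axis=0, padtype="even", padlen=padlen)
    return x.with_values(y)


def detrend_mean(x: UniformSeries) -> UniformSeries:
    """Remove the mean (per axis for vector series)."""
    return x.with_values(x.values - x.values.mean(axis=0))


def find_peaks(x: UniformSeries, min_prominence: float) -> list[int]:
    """Strict local maxima with topographic prominence >= ``min_prominence``.

    Prominence of a peak is its height above the highest saddle separating
    it from higher terrain.  The interval scan from a peak stops at a sample
    that is strictly higher, or equal in height with a smaller index — so of
    two equal summits the leftmost acts as the parent and keeps its full
    prominence while the other is measured against the connecting saddle.
    """
    if x.is_vector:
        raise InvalidParameterError("find_peaks expects a scalar series")
    v = x.values
    n = v.size
    out: list[int] = []
    for i in range(1, n - 1):
        if not (v[i] > v[i - 1] and v[i] > v[i + 1]):
            continue
        # left scan: any sample >= v[i] stops (equal height has smaller index)
        left_base = v[i]
        j = i - 1
        while j >= 0 and v[j] < v[i]:
            left_base = min(left_base, v[j])
            j -= 1
        # right scan: only strictly higher samples stop
        right_base = v[i]
        j = i + 1
        while j < n and v[j] <= v[i]:
            right_base = min(right_base, v[j])
            j += 1
        prominence = v[i] - max(left_base, right_base)
        if prominence >= min_prominence:
            out.append(i)
    return out


def savgol_smooth(x: UniformSeries, window_len: int, poly_order: int = 3) -> UniformSeries:
    """Savitzky–Golay smoothing: local least-squares polynomial fit."""
    if window_len % 2 == 0 or window_len <= poly_order:
        raise InvalidParameterError(
            f"window_len must be odd and > poly_order, got {window_len}"
        )
    if window_len > x.n:
        raise InvalidParameterError(
            f"window_len {window_len} exceeds series length {x.n}"
        )
    y = signal.savgol_filter(
        x.values, window_len, poly_order, axis=0, mode="interp"
    )
    return x.with_values(y)


def integrate_cumulative(x: UniformSeries) -> UniformSeries:
    """Cumulative trapezoidal integral, starting at zero."""
    if x.n < 2:
        raise TooShortError("integration needs at least two samples")
    y = integrate.cumulative_trapezoid(x.values, dx=x.dt, axis=0, initial=0.0)
    return x.with_values(y)


def differentiate(x: UniformSeries) -> UniformSeries:
    """Central differences in the interior, one-sided at the endpoints."""
    if x.n < 3:
        raise TooShortError("differentiation needs at least three samples")
    y = np.gradient(x.values, x.dt, axis=0, edge_order=1)
    return x.with_values(y)
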