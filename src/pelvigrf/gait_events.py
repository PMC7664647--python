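"""Initial-contact detection from pelvis-frame accelerations.

Foot strike produces a burst in the pelvis acceleration at every step.  The
detector low-pass filters the calibrated acceleration (2 Hz, order-2,
zero-phase), takes the vector magnitude, removes its mean, and screens the
remaining local maxima by topographic prominence (default 0.2 m/s^2).  The
surviving peaks lag the true foot strike by the loading response, so a
uniform offset (default 0.08 s) is subtracted from each peak time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TooShortError
from .signalproc import UniformSeries, butter_zero_phase, detrend_mean, find_peaks

__all__ = ["StepSegmentation", "detect_initial_contacts", "segment_steps"]


@dataclass
class StepSegmentation:
    """Ordered initial-contact times and the step windows between them."""

    ic_times: np.ndarray
    offset_applied: float = 0.0
    steps: list[tuple[float, float]] = field(init=False)

    def __post_init__(self):
        self.ic_times = np.asarray(self.ic_times, dtype=float)
        if self.ic_times.size > 1 and np.any(np.diff(self.ic_times) <= 0):
            raise ValueError("ic_times must be strictly increasing")
        self.steps = segment_steps(self.ic_times)

    @property
    def n_steps(self) -> int:
        return len(self.steps)


def segment_steps(ic_times) -> list[tuple[float, float]]:
    """Half-open windows [IC_{k-1}, IC_k) between consecutive contacts."""
    ic = np.asarray(ic_times, dtype=float)
    return [(float(ic[i]), float(ic[i + 1])) for i in range(ic.size - 1)]


def detect_initial_contacts(
    acc_p: UniformSeries,
    min_prominence: float = 0.2,
    lp_cutoff_hz: float = 2.0,
    ic_offset_s: float = 0.08,
    min_interval_s: float = 0.25,
) -> StepSegmentation:
    """Detect initial contacts in a pelvis-frame acceleration stream.

    ``ic_offset_s`` is subtracted from each detected peak time (the peak is
    assumed to lag the true contact); pass a negative value to shift the
    other way.  Peaks closer together than ``min_interval_s`` are resolved
    in favour of the higher peak — two physiological steps cannot be faster.
    Contacts that fall outside the recording after offsetting are dropped.
    An empty result is valid (e.g. a standing trial).
    """
    if acc_p.n == 0:
        raise TooShortError("empty acceleration input")
    lp = butter_zero_phase(acc_p, "low", lp_cutoff_hz, order=2)
    mag = UniformSeries(lp.t0, lp.fs, np.linalg.norm(lp.values, axis=1))
    dt_mag = detrend_mean(mag)
    idx = find_peaks(dt_mag, min_prominence)

    kept: list[int] = []
    for i in idx:
        if kept and (i - kept[-1]) / acc_p.fs < min_interval_s:
            if dt_mag.values[i] > dt_mag.values[kept[-1]]:
                kept[-1] = i
        else:
            kept.append(i)

    times = acc_p.t0 + np.asarray(kept, dtype=float) / acc_p.fs - ic_offset_s
    t_end = acc_p.t0 + (acc_p.n - 1) / acc_p.fs
    times = times[(times >= acc_p.t0) & (times <= t_end)]
    return StepSegmentation(ic_times=times, offset_applied=ic_offset_s)
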