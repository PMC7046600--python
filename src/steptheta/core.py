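"""Core time-series containers shared by every analysis stage.

Three lightweight containers cover everything the pipeline moves around:
uniformly sampled traces (paw displacement, LFP, speed), sorted event
timestamps (troughs, rewards, spikes), and an instantaneous-phase series
anchored so that phase is exactly 0 degrees at each cycle trough.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class UniformTimeSeries:
    """Evenly sampled trace.

    Parameters
    ----------
    values : array of float
        Samples, arbitrary units.
    rate_hz : float
        Sampling rate, Hz.
    t0_s : float
        Time of the first sample, seconds.
    """

    values: np.ndarray
    rate_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("need a 1-d trace of length >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n) / self.rate_hz

    @property
    def end_s(self) -> float:
        return self.t0_s + self.duration_s


@dataclass
class EventSeries:
    """Sorted event timestamps (troughs, spikes, rewards...)."""

    times_s: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.ndim != 1:
            raise ValueError("times_s must be 1-d")
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.times_s.size

    def between(self, start_s: float, end_s: float) -> "EventSeries":
        """Events in the half-open window [start_s, end_s)."""
        m = (self.times_s >= start_s) & (self.times_s < end_s)
        return EventSeries(self.times_s[m], self.label)


@dataclass
class PhaseSeries:
    """Instantaneous phase on a uniform grid, trough = 0 degrees.

    Phase increases linearly from 0 at one source trough to 360 at the
    next; outside the first/last trough the phase is undefined (NaN on
    the grid, events there are dropped downstream).  ``phase_at`` gives
    exact piecewise-linear interpolation at arbitrary times, which is
    what phase assignment uses — the sampled grid is for inspection and
    plotting.
    """

    phase_deg: np.ndarray
    rate_hz: float
    t0_s: float
    source_troughs: EventSeries = field(repr=False)

    def phase_at(self, times_s: np.ndarray) -> np.ndarray:
        """Phase (degrees in [0, 360)) at each query time; NaN outside span."""
        t = np.atleast_1d(np.asarray(times_s, dtype=float))
        tr = self.source_troughs.times_s
        out = np.full(t.shape, np.nan)
        if tr.size < 2:
            return out
        k = np.searchsorted(tr, t, side="right") - 1
        valid = (k >= 0) & (k < tr.size - 1)
        kv = k[valid]
        frac = (t[valid] - tr[kv]) / (tr[kv + 1] - tr[kv])
        out[valid] = (360.0 * frac) % 360.0
        return out

    @property
    def valid_span(self) -> tuple[float, float]:
        tr = self.source_troughs.times_s
        return float(tr[0]), float(tr[-1])
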