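"""Trace conditioning, trough detection, phase construction and spectra.

The analysis convention throughout is trough-anchored: the trough of a
cycle (LFP theta trough, or paw touching the ground) defines phase 0,
and phase advances linearly to 360 degrees at the next trough.  This
makes phase exactly zero at every detected trough by construction, at
the cost of a sawtooth instantaneous frequency; a Hilbert-based phase is
deliberately not the default because its phase at the waveform trough
depends on cycle asymmetry.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import EventSeries, PhaseSeries, UniformTimeSeries


def bandpass(ts: UniformTimeSeries, lo_hz: float, hi_hz: float,
             order: int = 4) -> UniformTimeSeries:
    """Zero-phase Butterworth band-pass.

    Forward-backward filtering (``sosfiltfilt``) so in-band components
    pass with no phase shift; trough times are therefore preserved.
    """
    nyq = ts.rate_hz / 2.0
    if not (0 < lo_hz < hi_hz < nyq):
        raise ValueError(
            f"band ({lo_hz}, {hi_hz}) Hz outside (0, Nyquist={nyq}) Hz")
    sos = sps.butter(order, [lo_hz, hi_hz], btype="bandpass",
                     fs=ts.rate_hz, output="sos")
    y = sps.sosfiltfilt(sos, ts.values)
    return UniformTimeSeries(y, ts.rate_hz, ts.t0_s)


def _robust_range(x: np.ndarray) -> float:
    lo, hi = np.percentile(x, [5.0, 95.0])
    return float(hi - lo)


def detect_troughs(ts: UniformTimeSeries, min_interval_s: float,
                   prominence_frac: float = 0.25,
                   label: str = "trough",
                   smooth_window_s: float | None = None) -> EventSeries:
    """Detect trace minima (cycle troughs) with sub-sample refinement.

    Minima must clear a prominence of ``prominence_frac`` times the
    robust (5th-95th percentile) range of the raw trace and be separated
    by at least ``min_interval_s``; when two candidates are closer than
    that, the deeper one wins.  Before detection the trace is smoothed
    with a centered moving average of ``smooth_window_s`` (default half
    the minimum interval — always well below a cycle, so symmetric cycle
    minima are not displaced; windows shorter than 3 samples are a
    no-op; pass 0 to disable).  This keeps broadband noise from
    clearing the prominence gate.  Trough times are refined by fitting a
    parabola through the three samples around each minimum.  A flat
    trace yields an empty series.
    """
    if min_interval_s <= 1.0 / ts.rate_hz:
        raise ValueError("min_interval_s must exceed one sample period")
    raw = ts.values
    rng = _robust_range(raw)
    if rng == 0.0:
        return EventSeries(np.empty(0), label)
    if smooth_window_s is None:
        smooth_window_s = min_interval_s / 2.0
    w = int(round(smooth_window_s * ts.rate_hz))
    if w >= 3:
        w += 1 - w % 2                      # odd, centered
        pad = w // 2
        xp = np.pad(raw, pad, mode="reflect")
        x = np.convolve(xp, np.ones(w) / w, mode="valid")
    else:
        x = raw
    distance = max(1, int(round(min_interval_s * ts.rate_hz)))
    idx, _ = sps.find_peaks(-x, distance=distance,
                            prominence=prominence_frac * rng)
    if idx.size == 0:
        return EventSeries(np.empty(0), label)
    # parabolic refinement: vertex of the parabola through (i-1, i, i+1)
    inner = (idx > 0) & (idx < x.size - 1)
    delta = np.zeros(idx.size)
    i = idx[inner]
    denom = x[i - 1] - 2.0 * x[i] + x[i + 1]
    ok = denom > 0
    d = np.zeros(i.size)
    d[ok] = 0.5 * (x[i - 1] - x[i + 1])[ok] / denom[ok]
    delta[inner] = np.clip(d, -0.5, 0.5)
    times = ts.t0_s + (idx + delta) / ts.rate_hz
    return EventSeries(np.sort(times), label)


def phase_from_troughs(troughs: EventSeries, rate_hz: float,
                       t0_s: float = 0.0,
                       duration_s: float | None = None) -> PhaseSeries:
    """Build a trough-anchored PhaseSeries on a uniform grid.

    Phase is 0 at each trough and ramps linearly to 360 at the next.
    Grid samples before the first or after the last trough are NaN and
    excluded from all downstream phase statistics (partial edge cycles
    carry no well-defined phase).
    """
    if troughs.n < 2:
        raise ValueError("need at least 2 troughs to define phase")
    if duration_s is None:
        duration_s = troughs.times_s[-1] - t0_s
    n = int(np.ceil(duration_s * rate_hz))
    ps = PhaseSeries(np.empty(0), rate_hz, t0_s, troughs)
    grid = t0_s + np.arange(n) / rate_hz
    ps.phase_deg = ps.phase_at(grid)
    return ps


def power_spectrum(ts: UniformTimeSeries, seg_len_s: float,
                   peak_band_hz: tuple[float, float] = (1.0, 20.0)
                   ) -> tuple[np.ndarray, np.ndarray, float]:
    """Welch spectrum normalized to its maximum, plus the peak frequency.

    Returns ``(freq_hz, power, peak_hz)`` where power is scaled so the
    largest bin equals 1 and ``peak_hz`` is the frequency of maximum
    power restricted to ``peak_band_hz`` (default 1-20 Hz, the
    locomotor/theta range).  Frequency resolution is ``1/seg_len_s``.
    """
    nperseg = int(round(seg_len_s * ts.rate_hz))
    if ts.n < 2 * nperseg:
        raise ValueError("trace must span at least two segments")
    f, p = sps.welch(ts.values, fs=ts.rate_hz, nperseg=nperseg,
                     detrend="constant")
    p = p / p.max() if p.max() > 0 else p
    band = (f >= peak_band_hz[0]) & (f <= peak_band_hz[1])
    peak_hz = float(f[band][np.argmax(p[band])])
    return f, p, peak_hz
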