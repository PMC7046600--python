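"""Step-theta coupling pipeline: phase assignment, shuffle significance,
behavioral and speed parcellation, segment classification.

The central quantity is the theta phase attributed to each step-cycle
trough (the moment the paw touches the ground).  Coupling depth is the
mean resultant length of those phases; its significance is assessed
against a time-offset shuffle null in which the continuous paw
displacement trace is circularly shifted by random 1-3 s offsets and
the whole trough-detection + phase-assignment chain is recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

from . import circstats
from .circstats import CouplingResult
from .core import EventSeries, PhaseSeries, UniformTimeSeries
from .signal import detect_troughs

MIN_EVENTS = 200                       # exclude parsed data below this
SPEED_BINS_CMS = [(2.0, 7.0), (7.0, 13.0), (13.0, 19.0)]
SEGMENT_CLASSES = ("step<theta", "step=theta", "step>theta")


# ---------------------------------------------------------------------------
# phase assignment and the basic coupling statistic

def assign_phases(events: EventSeries, phase: PhaseSeries
                  ) -> tuple[np.ndarray, int]:
    """Phase (degrees) at each event time; events outside the valid
    phase span are dropped and counted.  Returns (phases, n_dropped)."""
    ph = phase.phase_at(events.times_s)
    valid = np.isfinite(ph)
    n_dropped = int((~valid).sum())
    if valid.sum() == 0 and events.n > 0:
        raise ValueError("all events fall outside the valid phase span")
    return ph[valid], n_dropped


def coupling_analysis(events: EventSeries, phase: PhaseSeries,
                      min_events: int = MIN_EVENTS,
                      bin_deg: int = circstats.DEFAULT_BIN_DEG
                      ) -> CouplingResult:
    """Full coupling summary, or a below-threshold marker when fewer
    than ``min_events`` events carry a valid phase (the count filter is
    an exclusion rule, not an error)."""
    phases, n_dropped = assign_phases(events, phase)
    if phases.size < min_events:
        return CouplingResult.below_threshold(phases.size, n_dropped)
    return CouplingResult.from_phases(phases, bin_deg=bin_deg,
                                      n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# shuffle (time-offset) significance test

@dataclass
class ShuffleResult:
    observed_r: float
    shuffled_r: np.ndarray
    pct99: float
    significant: bool
    n_shuffles: int
    observed: CouplingResult | None = None

    def to_dict(self) -> dict:
        return {"observed_r": self.observed_r,
                "pct99": self.pct99,
                "significant": bool(self.significant),
                "n_shuffles": self.n_shuffles,
                "shuffled_r": self.shuffled_r.tolist()}


def _restrict(times: np.ndarray,
              intervals: list[tuple[float, float]] | None) -> np.ndarray:
    if intervals is None:
        return times
    keep = np.zeros(times.size, dtype=bool)
    for s, e in intervals:
        keep |= (times >= s) & (times < e)
    return times[keep]


def shuffle_test(paw_trace: UniformTimeSeries, theta_phase: PhaseSeries,
                 n_shuffles: int = 500,
                 offset_range_s: tuple[float, float] = (1.0, 3.0),
                 seed: int | np.random.Generator = 0,
                 min_interval_s: float = 0.06,
                 prominence_frac: float = 0.25,
                 run_intervals: list[tuple[float, float]] | None = None,
                 ) -> ShuffleResult:
    """Time-offset shuffle test of step-theta coupling.

    Each shuffle circularly shifts the continuous paw-displacement trace
    by an offset drawn uniformly from ``offset_range_s`` with random
    sign, re-detects step-cycle troughs on the shifted trace, assigns
    theta phases and recomputes the mean resultant length.  The observed
    coupling is significant when its r exceeds the 99th percentile of
    the shuffled distribution.  Circular shifting preserves the trough
    count, so the null matches the observed statistic's sample size.
    """
    import warnings
    if n_shuffles < 100:
        warnings.warn("fewer than 100 shuffles: 99th percentile unstable")
    if paw_trace.duration_s <= offset_range_s[1]:
        raise ValueError("trace shorter than the maximum shuffle offset")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    def r_of(trace: UniformTimeSeries) -> tuple[float, CouplingResult]:
        tr = detect_troughs(trace, min_interval_s, prominence_frac)
        times = _restrict(tr.times_s, run_intervals)
        if times.size == 0:
            return float("nan"), CouplingResult.below_threshold(0)
        res = coupling_analysis(EventSeries(times), theta_phase,
                                min_events=1)
        return res.r, res

    observed_r, observed = r_of(paw_trace)
    shuffled = np.empty(n_shuffles)
    for i in range(n_shuffles):
        off = rng.uniform(*offset_range_s) * rng.choice([-1.0, 1.0])
        shift = int(round(off * paw_trace.rate_hz))
        rolled = UniformTimeSeries(np.roll(paw_trace.values, shift),
                                   paw_trace.rate_hz, paw_trace.t0_s)
        shuffled[i], _ = r_of(rolled)
    pct99 = float(np.nanpercentile(shuffled, 99.0))
    return ShuffleResult(observed_r=float(observed_r), shuffled_r=shuffled,
                         pct99=pct99, significant=bool(observed_r > pct99),
                         n_shuffles=n_shuffles, observed=observed)


# ---------------------------------------------------------------------------
# behavioral parcellation (VRon / VRoff / VRrwd)

@dataclass
class EpochSet:
    """Behavioral epochs plus reward times; reward windows (VRrwd) are
    the +/- 1 s intervals around each reward delivery and take
    precedence over the VRon/VRoff epoch they sit inside."""
    intervals: list          # (start_s, end_s, label in {VRon, VRoff})
    reward_times_s: list = field(default_factory=list)
    reward_halfwidth_s: float = 1.0

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals)
        for s, e, lab in ivs:
            if not s < e:
                raise ValueError(f"epoch ({s}, {e}) has start >= end")
            if lab not in ("VRon", "VRoff"):
                raise ValueError(f"unknown epoch label {lab!r}")
        for (s1, e1, _), (s2, e2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError("VRon/VRoff intervals overlap")

    def rwd_intervals(self) -> list[tuple[float, float]]:
        h = self.reward_halfwidth_s
        return [(t - h, t + h) for t in sorted(self.reward_times_s)]

    def label_of(self, times: np.ndarray) -> np.ndarray:
        """Label per time: VRrwd within +/-1 s of a reward, else the
        covering VRon/VRoff epoch, else '' (unassigned)."""
        t = np.asarray(times, dtype=float)
        out = np.full(t.shape, "", dtype=object)
        for s, e, lab in self.intervals:
            out[(t >= s) & (t < e)] = lab
        for s, e in self.rwd_intervals():
            out[(t >= s) & (t <= e)] = "VRrwd"
        return out


def parse_behavior(events: EventSeries, phase: PhaseSeries,
                   epochs: EpochSet, min_events: int = MIN_EVENTS
                   ) -> dict:
    """Per-condition coupling of step troughs to theta.

    Returns ``{label: CouplingResult}`` for VRon/VRoff/VRrwd plus an
    ``n_unassigned`` count of events covered by no epoch.
    """
    labels = epochs.label_of(events.times_s)
    out: dict = {"n_unassigned": int((labels == "").sum())}
    for lab in ("VRon", "VRoff", "VRrwd"):
        sub = EventSeries(events.times_s[labels == lab])
        if sub.n == 0:
            out[lab] = CouplingResult.below_threshold(0)
        else:
            out[lab] = coupling_analysis(sub, phase, min_events=min_events)
    return out


# ---------------------------------------------------------------------------
# speed parcellation

def parse_speed(events: EventSeries, speed: UniformTimeSeries,
                phase: PhaseSeries | None = None,
                bins: list[tuple[float, float]] = None,
                min_events: int = MIN_EVENTS) -> dict:
    """Assign each event to the speed bin (half-open [lo, hi)) containing
    the instantaneous running speed at its time.

    Returns per-bin event sets (and CouplingResults when ``phase`` is
    given), the unassigned count, and the covered fraction.
    """
    if bins is None:
        bins = SPEED_BINS_CMS
    v = np.interp(events.times_s, speed.times_s, speed.values)
    out: dict = {"bins": bins}
    n_assigned = 0
    for lo, hi in bins:
        m = (v >= lo) & (v < hi)
        n_assigned += int(m.sum())
        sub = EventSeries(events.times_s[m])
        entry: dict = {"events": sub, "n": sub.n}
        if phase is not None:
            entry["coupling"] = (coupling_analysis(sub, phase,
                                                   min_events=min_events)
                                 if sub.n else
                                 CouplingResult.below_threshold(0))
        out[f"{lo:g}-{hi:g}"] = entry
    out["n_unassigned"] = events.n - n_assigned
    out["covered_fraction"] = (n_assigned / events.n) if events.n else 0.0
    return out


# ---------------------------------------------------------------------------
# 500-ms segment classification

@dataclass
class SegmentClassification:
    n_segments: int
    counts: dict
    proportions: dict
    coupling: dict            # per-class CouplingResult (pooled phases)

    def to_dict(self) -> dict:
        return {"n_segments": self.n_segments,
                "counts": self.counts,
                "proportions": self.proportions,
                "coupling": {k: v.to_dict()
                             for k, v in self.coupling.items()}}


def classify_segments(step_troughs: EventSeries, theta_troughs: EventSeries,
                      span: tuple[float, float], seg_len_s: float = 0.5,
                      phase: PhaseSeries | None = None,
                      min_events: int = MIN_EVENTS) -> SegmentClassification:
    """Divide ``span`` into consecutive non-overlapping segments and
    classify each by comparing its step-trough and theta-trough counts
    (half-open [t, t+seg_len) windows; no partial terminal segment).

    When ``phase`` is given, step-trough phases are pooled per class and
    summarized like any other coupling analysis.
    """
    t0, t1 = span
    if t1 - t0 < seg_len_s:
        raise ValueError("span shorter than one segment")
    n_seg = int(np.floor((t1 - t0) / seg_len_s))
    edges = t0 + np.arange(n_seg + 1) * seg_len_s
    sc = np.diff(np.searchsorted(step_troughs.times_s, edges))
    tc = np.diff(np.searchsorted(theta_troughs.times_s, edges))
    cls = np.where(sc < tc, "step<theta",
                   np.where(sc == tc, "step=theta", "step>theta"))
    counts = {c: int((cls == c).sum()) for c in SEGMENT_CLASSES}
    props = {c: counts[c] / n_seg for c in SEGMENT_CLASSES}
    coupling: dict = {}
    if phase is not None:
        seg_of_step = np.floor(
            (step_troughs.times_s - t0) / seg_len_s).astype(int)
        inside = (seg_of_step >= 0) & (seg_of_step < n_seg)
        for c in SEGMENT_CLASSES:
            m = inside & (cls[np.clip(seg_of_step, 0, n_seg - 1)] == c)
            sub = EventSeries(step_troughs.times_s[m])
            coupling[c] = (coupling_analysis(sub, phase,
                                             min_events=min_events)
                           if sub.n else CouplingResult.below_threshold(0))
    return SegmentClassification(n_segments=n_seg, counts=counts,
                                 proportions=props, coupling=coupling)


# ---------------------------------------------------------------------------
# step count vs running speed

def step_speed_correlation(step_troughs: EventSeries,
                           speed: UniformTimeSeries,
                           window_s: float = 1.0) -> dict:
    """Pearson correlation between per-window step counts and mean
    running speed (non-overlapping windows from the trace start)."""
    n_win = int(np.floor(speed.duration_s / window_s))
    if n_win < 10:
        raise ValueError("need at least 10 windows")
    edges = speed.t0_s + np.arange(n_win + 1) * window_s
    counts = np.diff(np.searchsorted(step_troughs.times_s, edges))
    per_win = int(round(window_s * speed.rate_hz))
    v = speed.values[:n_win * per_win].reshape(n_win, per_win).mean(axis=1)
    if counts.std() == 0 or v.std() == 0:
        return {"r": float("nan"), "p": float("nan"), "n_windows": n_win,
                "defined": False}
    r, p = spstats.pearsonr(counts, v)
    return {"r": float(r), "p": float(p), "n_windows": n_win,
            "defined": True}


def run_intervals_from_speed(speed: UniformTimeSeries,
                             min_speed_cms: float = 2.0,
                             min_duration_s: float = 0.5
                             ) -> list[tuple[float, float]]:
    """RUN periods: maximal intervals where speed >= ``min_speed_cms``
    lasting at least ``min_duration_s``."""
    above = speed.values >= min_speed_cms
    d = np.diff(above.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    out = []
    for s, e in zip(starts, ends):
        t_s = speed.t0_s + s / speed.rate_hz
        t_e = speed.t0_s + e / speed.rate_hz
        if t_e - t_s >= min_duration_s:
            out.append((t_s, t_e))
    return out
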