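"""Medial septal unit analyses.

Units below 300 spikes are discarded (too few events for stable phase
statistics), the survivors are tested for phase coupling to hippocampal
theta and to the step cycle, spike timing is visualized as trough-
triggered averages, and the coupling strengths to the two rhythms are
correlated across cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .circstats import CouplingResult
from .core import EventSeries, PhaseSeries
from .coupling import coupling_analysis

MIN_SPIKES = 300


@dataclass
class SpikeUnit:
    unit_id: int
    spike_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if (self.spike_times_s.size > 1
                and not np.all(np.diff(self.spike_times_s) > 0)):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return self.spike_times_s.size

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> list["SpikeUnit"]:
        """Units from a tidy (unit_id, time_s) table."""
        return [cls(int(uid), np.sort(g["time_s"].to_numpy()))
                for uid, g in df.groupby("unit_id")]


def filter_units(units: list[SpikeUnit],
                 min_spikes: int = MIN_SPIKES) -> list[SpikeUnit]:
    """Keep units with at least ``min_spikes`` spikes."""
    return [u for u in units if u.n_spikes >= min_spikes]


def spike_phase_coupling(unit: SpikeUnit, phase: PhaseSeries,
                         run_intervals: list[tuple[float, float]] | None = None
                         ) -> CouplingResult:
    """Coupling of a unit's spikes to a phase signal (theta or step).

    Same contract as the step-trough analysis but with no minimum-event
    filter here: the >= 300-spike cluster rule (``filter_units``)
    governs inclusion.  ``run_intervals`` optionally restricts spikes to
    the same RUN mask used for the step analyses.
    """
    times = unit.spike_times_s
    if run_intervals is not None:
        keep = np.zeros(times.size, dtype=bool)
        for s, e in run_intervals:
            keep |= (times >= s) & (times < e)
        times = times[keep]
    return coupling_analysis(EventSeries(times), phase, min_events=1)


@dataclass
class TriggeredAverage:
    """Peri-event firing rate around repeated trigger events."""
    lags_s: np.ndarray            # bin centers, symmetric around 0
    rate_hz: np.ndarray
    n_triggers: int
    bin_s: float

    @property
    def total_spikes(self) -> int:
        return int(round(self.rate_hz.sum() * self.n_triggers * self.bin_s))


def triggered_average(unit: SpikeUnit, triggers: EventSeries,
                      window_s: float = 0.5,
                      bin_s: float = 0.01) -> TriggeredAverage:
    """Trough-triggered spike average: histogram of spike lags relative
    to each trigger over [-window, +window), normalized to firing rate
    (count / (n_triggers * bin))."""
    if triggers.n == 0:
        raise ValueError("no trigger events")
    if triggers.n < 10:
        raise ValueError("need at least 10 triggers")
    nbins = 2 * int(round(window_s / bin_s))
    edges = -window_s + np.arange(nbins + 1) * bin_s
    spikes = unit.spike_times_s
    # spike count per (trigger, lag-bin) via one vectorized searchsorted
    cuts = np.searchsorted(spikes, triggers.times_s[:, None] + edges[None, :])
    counts = np.diff(cuts, axis=1).sum(axis=0).astype(float)
    rate = counts / (triggers.n * bin_s)
    centers = edges[:-1] + bin_s / 2.0
    return TriggeredAverage(lags_s=centers, rate_hz=rate,
                            n_triggers=triggers.n, bin_s=bin_s)


def coupling_strength_correlation(theta_r: np.ndarray, step_r: np.ndarray,
                                  n_perm: int = 10_000,
                                  seed: int = 0) -> tuple[float, float]:
    """Across-cell association between theta- and step-coupling depth.

    Spearman rank correlation with a permutation p value (two-sided):
    one coupling vector is permuted across cells ``n_perm`` times and
    the p value is the fraction of permutations with |rho| at least as
    large as observed (add-one corrected).
    """
    x = np.asarray(theta_r, dtype=float)
    y = np.asarray(step_r, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 units with both coupling values")
    rho = float(spstats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    rx = spstats.rankdata(x)
    ry = spstats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = x.size
    perm = np.empty(n_perm)
    for i in range(n_perm):
        perm[i] = np.dot(rx, rng.permutation(ry)) / n
    obs = np.dot(rx, ry) / n
    p = (1 + np.sum(np.abs(perm) >= abs(obs) - 1e-12)) / (n_perm + 1)
    return rho, float(p)
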