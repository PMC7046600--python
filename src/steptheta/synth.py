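"""Synthetic recording sessions with known injected phase coupling.

Real sessions of this kind contain a hippocampal LFP dominated by theta
(~8 Hz during running), front-paw displacement traces with alternating
left/right step cycles at ~3-8 Hz, a running-speed trace, behavioral
epochs (virtual-reality feedback on/off, rewards), and spike trains of
medial septal units that burst rhythmically at preferred theta and
step-cycle phases.  This module generates sessions with exactly that
statistical structure and records every injected parameter as ground
truth, so the analysis pipeline can be validated by parameter recovery.

Coupling is injected directly: each right-paw step-cycle trough is
placed at a theta phase drawn i.i.d. from a von Mises distribution with
the target mean direction and a concentration chosen so the population
mean resultant length equals the target (``kappa_for_resultant``).
This makes the injected resultant exactly known, which a pair of
coupled dynamical oscillators would not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, special

from .core import EventSeries, PhaseSeries, UniformTimeSeries

__all__ = [
    "OscSpec", "UnitSpec", "SynthSessionConfig", "GroundTruth",
    "SynthSession", "kappa_for_resultant", "generate_theta_lfp",
    "generate_stepping", "generate_speed", "generate_spikes",
    "generate_session", "default_units", "paw_trace_from_troughs",
]


# ---------------------------------------------------------------------------
# configuration

@dataclass
class OscSpec:
    """Cycle-frequency model: mean-reverting random walk, clipped to a band.

    The cycle-by-cycle frequency follows an Ornstein-Uhlenbeck-style
    walk whose stationary SD is ``drift_sd_hz`` and whose correlation
    time is ``tau_s`` (default 4 s): frequency wanders by ~drift_sd over
    seconds rather than jumping cycle to cycle, matching how theta and
    stepping frequencies drift in real recordings.
    """
    mean_hz: float
    drift_sd_hz: float = 0.0
    lo_hz: float | None = None
    hi_hz: float | None = None
    tau_s: float = 4.0

    def __post_init__(self) -> None:
        if self.mean_hz <= 0:
            raise ValueError("mean_hz must be positive")
        if self.drift_sd_hz < 0:
            raise ValueError("drift_sd_hz must be >= 0")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.lo_hz is None:
            self.lo_hz = self.mean_hz / 2.0
        if self.hi_hz is None:
            self.hi_hz = self.mean_hz * 1.5


@dataclass
class UnitSpec:
    """Generative phenotype of one medial septal unit.

    ``theta_mu_deg=0`` with high concentration emulates short-burst
    cells firing maximally at the theta trough; ``theta_mu_deg=180``
    emulates long-burst cells firing maximally at the theta peak.
    Step-cycle coupling is parameterized independently.
    """
    unit_id: int
    mean_rate_hz: float
    burst_len: int = 1
    theta_mu_deg: float = 0.0
    theta_kappa: float = 0.0
    step_mu_deg: float = 0.0
    step_kappa: float = 0.0
    burst_isi_s: float = 0.005

    def __post_init__(self) -> None:
        if self.mean_rate_hz <= 0:
            raise ValueError("mean_rate_hz must be positive")
        if self.theta_kappa < 0 or self.step_kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.burst_len < 1:
            raise ValueError("burst_len must be >= 1")


def default_units() -> list[UnitSpec]:
    """Twelve rhythmic units: half trough-preferring short-burst cells,
    half peak-preferring long-burst cells, with independently varied
    step-cycle coupling."""
    units = []
    step_mus = [40.0, 130.0, 220.0, 310.0, 85.0, 175.0]
    step_kappas = [0.3, 0.8, 1.5, 0.5, 1.0, 0.2]
    for i in range(6):
        units.append(UnitSpec(unit_id=i, mean_rate_hz=12.0, burst_len=2,
                              theta_mu_deg=0.0, theta_kappa=1.2 + 0.3 * i,
                              step_mu_deg=step_mus[i],
                              step_kappa=step_kappas[i]))
    for i in range(6):
        units.append(UnitSpec(unit_id=6 + i, mean_rate_hz=18.0, burst_len=5,
                              theta_mu_deg=180.0, theta_kappa=1.0 + 0.3 * i,
                              step_mu_deg=step_mus[5 - i],
                              step_kappa=step_kappas[5 - i]))
    return units


def _default_epochs(duration_s: float) -> list[tuple[float, float, str]]:
    # feedback off at the start and end of the session, on in the middle
    a = min(120.0, duration_s / 6.0)
    return [(0.0, a, "VRoff"),
            (a, duration_s - a, "VRon"),
            (duration_s - a, duration_s, "VRoff")]


def _default_rewards(duration_s: float) -> list[float]:
    a = min(120.0, duration_s / 6.0)
    return list(np.arange(a + 15.0, duration_s - a, 30.0))


@dataclass
class SynthSessionConfig:
    """All generative parameters of one synthetic session.

    Defaults mirror the study conditions: 20-min sessions, theta at 8 Hz
    with slow drift, stepping drifting across 3-8 Hz, step-trough theta
    coupling with resultant 0.10 at 226 degrees, and a 0.5 population
    correlation between per-second step counts and running speed.
    """
    duration_s: float = 1200.0
    lfp_rate_hz: float = 1000.0
    paw_rate_hz: float = 50.0
    theta: OscSpec = field(default_factory=lambda: OscSpec(8.0, 0.5, 6.0, 10.0))
    step: OscSpec = field(default_factory=lambda: OscSpec(5.5, 1.0, 3.0, 8.0))
    coupling_mu_deg: float = 226.0
    coupling_r: float = 0.10
    speed_step_corr: float = 0.5
    epochs: list = None
    reward_times_s: list = None
    units: list = field(default_factory=default_units)
    seed: int = 0
    lfp_noise_sd: float = 0.10        # additive, in units of theta amplitude
    lfp_amp_jitter: float = 0.10      # per-cycle amplitude SD
    paw_noise_frac: float = 0.05      # white noise SD as fraction of amplitude
    paw_amplitude: float = 1.0
    speed_mean_cms: float = 10.5      # affine map into the 2-19 cm/s range
    speed_sd_cms: float = 4.25

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not (0.0 <= self.coupling_r < 1.0):
            raise ValueError("coupling_r must be in [0, 1)")
        if not (-1.0 <= self.speed_step_corr <= 1.0):
            raise ValueError("speed_step_corr must be in [-1, 1]")
        if self.lfp_rate_hz <= 0 or self.paw_rate_hz <= 0:
            raise ValueError("sample rates must be positive")
        if self.epochs is None:
            self.epochs = _default_epochs(self.duration_s)
        if self.reward_times_s is None:
            self.reward_times_s = _default_rewards(self.duration_s)
        for s, e, lab in self.epochs:
            if not (0.0 <= s < e <= self.duration_s):
                raise ValueError(f"epoch ({s}, {e}) outside session")
            if lab not in ("VRon", "VRoff"):
                raise ValueError(f"epoch label {lab!r} not VRon/VRoff")


@dataclass
class GroundTruth:
    """Everything injected, for parameter-recovery validation."""
    theta_trough_times_s: np.ndarray
    right_trough_times_s: np.ndarray
    left_trough_times_s: np.ndarray
    right_trough_theta_phases_deg: np.ndarray
    coupling_mu_deg: float
    coupling_kappa: float
    coupling_r: float
    speed_step_corr: float
    unit_specs: list

    def to_dict(self) -> dict:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in self.__dict__.items() if k != "unit_specs"}
        d["unit_specs"] = [asdict(u) for u in self.unit_specs]
        return d


@dataclass
class SynthSession:
    config: SynthSessionConfig
    lfp: UniformTimeSeries
    paw_left: UniformTimeSeries
    paw_right: UniformTimeSeries
    speed: UniformTimeSeries
    spikes: pd.DataFrame            # columns: unit_id, time_s
    ground_truth: GroundTruth

    @property
    def epochs(self) -> list:
        return self.config.epochs

    @property
    def reward_times_s(self) -> list:
        return self.config.reward_times_s


# ---------------------------------------------------------------------------
# von Mises concentration for a target resultant

def vm_resultant(kappa: float) -> float:
    """Population mean resultant length A(kappa) = I1(kappa)/I0(kappa)."""
    return float(special.i1e(kappa) / special.i0e(kappa))


def kappa_for_resultant(r0: float) -> float:
    """Concentration kappa of a von Mises distribution whose population
    mean resultant length equals ``r0``, solved to |A(kappa)-r0| < 1e-8.
    """
    if not (0.0 <= r0 < 1.0):
        raise ValueError("target resultant must be in [0, 1)")
    if r0 == 0.0:
        return 0.0
    hi = 2.0
    while vm_resultant(hi) < r0:
        hi *= 2.0
        if hi > 1e12:       # pragma: no cover - r0 < 1 guarantees a root
            raise RuntimeError("failed to bracket kappa")
    return float(optimize.brentq(lambda k: vm_resultant(k) - r0, 0.0, hi,
                                 xtol=1e-12, rtol=8.9e-16))


# ---------------------------------------------------------------------------
# oscillation scaffolding

def _cycle_freqs(osc: OscSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Clipped mean-reverting walk of cycle-by-cycle frequency.

    Discretized OU process with one step per cycle: the step duration
    is approximated by 1/mean_hz, the stationary SD equals drift_sd_hz,
    and excursions are clipped into [lo_hz, hi_hz].
    """
    if osc.drift_sd_hz == 0.0:
        return np.full(n, osc.mean_hz)
    a = np.exp(-1.0 / (osc.mean_hz * osc.tau_s))     # per-cycle decay
    sd_step = osc.drift_sd_hz * np.sqrt(1.0 - a * a)
    steps = rng.normal(0.0, sd_step, n)
    f = np.empty(n)
    f[0] = np.clip(osc.mean_hz + rng.normal(0.0, osc.drift_sd_hz),
                   osc.lo_hz, osc.hi_hz)
    for i in range(1, n):
        f[i] = np.clip(osc.mean_hz + a * (f[i - 1] - osc.mean_hz) + steps[i],
                       osc.lo_hz, osc.hi_hz)
    return f


def _trough_times(osc: OscSpec, duration_s: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Trough times covering [0, duration] plus one extra cycle so the
    waveform can be evaluated up to the session end."""
    n_max = int(np.ceil(duration_s * osc.hi_hz)) + 3
    freqs = _cycle_freqs(osc, n_max, rng)
    times = np.concatenate([[0.0], np.cumsum(1.0 / freqs)])
    last = np.searchsorted(times, duration_s)
    return times[:min(last + 2, times.size)]


def _phase_on_grid(troughs: np.ndarray, rate_hz: float,
                   duration_s: float) -> np.ndarray:
    """Piecewise-linear unwrapped phase (radians) on a uniform grid;
    extrapolated at the edges with the adjacent cycle frequency."""
    t = np.arange(int(round(duration_s * rate_hz))) / rate_hz
    unwrapped = 2.0 * np.pi * np.arange(troughs.size)
    slope0 = (unwrapped[1] - unwrapped[0]) / (troughs[1] - troughs[0])
    slope1 = (unwrapped[-1] - unwrapped[-2]) / (troughs[-1] - troughs[-2])
    ph = np.interp(t, troughs, unwrapped,
                   left=unwrapped[0] + slope0 * (0.0 - 0.0),
                   right=unwrapped[-1])
    before = t < troughs[0]
    after = t > troughs[-1]
    ph[before] = unwrapped[0] + slope0 * (t[before] - troughs[0])
    ph[after] = unwrapped[-1] + slope1 * (t[after] - troughs[-1])
    return ph


def generate_theta_lfp(cfg: SynthSessionConfig, rng: np.random.Generator
                       ) -> tuple[UniformTimeSeries, EventSeries]:
    """Theta-band LFP with cycle-frequency drift; returns the trace and
    the generative trough times (waveform minima coincide with them).

    The waveform is -cos of the trough-anchored phase, scaled by a
    slowly varying per-cycle amplitude envelope, plus white noise.
    """
    troughs = _trough_times(cfg.theta, cfg.duration_s, rng)
    ph = _phase_on_grid(troughs, cfg.lfp_rate_hz, cfg.duration_s)
    amps = 1.0 + cfg.lfp_amp_jitter * rng.normal(0.0, 1.0, troughs.size)
    amps = np.clip(amps, 0.3, None)
    t = np.arange(ph.size) / cfg.lfp_rate_hz
    env = np.interp(t, troughs, amps)
    values = -np.cos(ph) * env
    if cfg.lfp_noise_sd > 0:
        values = values + rng.normal(0.0, cfg.lfp_noise_sd, values.size)
    ts = UniformTimeSeries(values, cfg.lfp_rate_hz, 0.0)
    keep = troughs[troughs < cfg.duration_s]
    return ts, EventSeries(keep, "theta_trough")


# ---------------------------------------------------------------------------
# stepping

def _phase_crossing_times(theta_troughs: np.ndarray, phase_deg: float,
                          k: int) -> float:
    """Time within theta cycle k at which theta phase equals phase_deg."""
    return theta_troughs[k] + (phase_deg / 360.0) * (
        theta_troughs[k + 1] - theta_troughs[k])


def _place_right_troughs(cfg: SynthSessionConfig,
                         theta_troughs: np.ndarray,
                         rng: np.random.Generator
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Place right-paw trough times at i.i.d. von Mises theta phases.

    Each step advances nominally by one step period (from the drifting
    step-frequency walk) and the trough is snapped to the nearest time
    at which the theta phase equals the drawn target phase, subject to a
    minimum inter-trough interval of half a step period.  Snapping never
    changes the drawn phase, so the injected phase distribution is exact
    by construction; when the nearest crossing would violate the minimum
    interval the next theta cycle's crossing is used instead.

    With ``coupling_r == 0`` no snapping happens at all: the step clock
    runs independently of theta, which is what "no coupling" means
    physically.  (Snapping troughs to i.i.d. uniform phases would still
    tie the step process to theta's cycle grid and, being exchangeable
    with nothing, would break time-shift surrogate calibration.)  The
    reported trough phases are then simply theta read out at the placed
    times.
    """
    if cfg.coupling_r == 0.0:
        return _independent_troughs(cfg, theta_troughs, rng)
    kappa = kappa_for_resultant(cfg.coupling_r)
    mu_rad = np.radians(cfg.coupling_mu_deg)
    n_max = int(np.ceil(cfg.duration_s * cfg.step.hi_hz)) + 3
    freqs = _cycle_freqs(cfg.step, n_max, rng)
    target_phases = np.degrees(rng.vonmises(mu_rad, kappa, n_max)) % 360.0

    t_end = theta_troughs[-1]
    times: list[float] = []
    phases: list[float] = []
    t_prev = rng.uniform(0.0, 1.0 / freqs[0])
    for j in range(n_max):
        period = 1.0 / freqs[j]
        nominal = t_prev + period if times else t_prev
        min_ok = (times[-1] + 0.5 * period) if times else 0.0
        phi = target_phases[j]
        k = int(np.searchsorted(theta_troughs, max(nominal, 0.0),
                                side="right")) - 1
        k = max(k, 0)
        placed = None
        for kk in range(max(k - 1, 0), theta_troughs.size - 1):
            cand = _phase_crossing_times(theta_troughs, phi, kk)
            if cand < min_ok:
                continue
            if placed is None or abs(cand - nominal) < abs(placed - nominal):
                placed = cand
            if cand > nominal + 1.0:    # no closer crossing will appear
                break
        if placed is None or placed >= min(t_end, cfg.duration_s):
            break
        times.append(placed)
        phases.append(phi)
        t_prev = placed
    return np.asarray(times), np.asarray(phases)


def _independent_troughs(cfg: SynthSessionConfig,
                         theta_troughs: np.ndarray,
                         rng: np.random.Generator
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Uncoupled stepping: troughs follow the step clock alone; the
    returned phases are theta evaluated at the placed times."""
    n_max = int(np.ceil(cfg.duration_s * cfg.step.hi_hz)) + 3
    freqs = _cycle_freqs(cfg.step, n_max, rng)
    start = rng.uniform(0.0, 1.0 / freqs[0])
    times = start + np.concatenate([[0.0], np.cumsum(1.0 / freqs[1:])])
    t_end = min(theta_troughs[-1], cfg.duration_s)
    times = times[times < t_end]
    k = np.searchsorted(theta_troughs, times, side="right") - 1
    k = np.clip(k, 0, theta_troughs.size - 2)
    frac = (times - theta_troughs[k]) / (theta_troughs[k + 1]
                                         - theta_troughs[k])
    phases = (360.0 * frac) % 360.0
    return times, phases


def paw_trace_from_troughs(trough_times: np.ndarray, cfg: SynthSessionConfig,
               rng: np.random.Generator) -> UniformTimeSeries:
    """Raised-cosine displacement cycles with minima at the troughs,
    plus white noise; flat baseline outside the stepped span."""
    n = int(round(cfg.duration_s * cfg.paw_rate_hz))
    t = np.arange(n) / cfg.paw_rate_hz
    values = np.zeros(n)
    if trough_times.size >= 2:
        unwrapped = 2.0 * np.pi * np.arange(trough_times.size)
        inside = (t >= trough_times[0]) & (t <= trough_times[-1])
        ph = np.interp(t[inside], trough_times, unwrapped)
        values[inside] = 0.5 * cfg.paw_amplitude * (1.0 - np.cos(ph))
    if cfg.paw_noise_frac > 0:
        values = values + rng.normal(
            0.0, cfg.paw_noise_frac * cfg.paw_amplitude, n)
    return UniformTimeSeries(values, cfg.paw_rate_hz, 0.0)


def generate_stepping(cfg: SynthSessionConfig, theta_troughs: EventSeries,
                      rng: np.random.Generator
                      ) -> tuple[UniformTimeSeries, UniformTimeSeries,
                                 GroundTruth]:
    """Left/right paw displacement traces with alternating step cycles.

    Right-paw troughs carry the injected theta-phase coupling; left-paw
    troughs are offset by half a step cycle (midpoints of consecutive
    right troughs), reproducing the alternating gait.
    """
    right, phases = _place_right_troughs(cfg, theta_troughs.times_s, rng)
    left = 0.5 * (right[:-1] + right[1:]) if right.size >= 2 else np.empty(0)
    right_ts = paw_trace_from_troughs(right, cfg, rng)
    left_ts = paw_trace_from_troughs(left, cfg, rng)
    gt = GroundTruth(
        theta_trough_times_s=theta_troughs.times_s,
        right_trough_times_s=right,
        left_trough_times_s=left,
        right_trough_theta_phases_deg=phases,
        coupling_mu_deg=cfg.coupling_mu_deg,
        coupling_kappa=kappa_for_resultant(cfg.coupling_r),
        coupling_r=cfg.coupling_r,
        speed_step_corr=cfg.speed_step_corr,
        unit_specs=list(cfg.units),
    )
    return left_ts, right_ts, gt


# ---------------------------------------------------------------------------
# speed

def generate_speed(cfg: SynthSessionConfig, step_troughs: np.ndarray,
                   rng: np.random.Generator,
                   window_s: float = 1.0) -> UniformTimeSeries:
    """Running-speed trace correlated with per-window step counts.

    Gaussian-copula construction: per 1-s window,
    speed_z = a * zscore(step count) + sqrt(1-a^2) * noise with
    a = ``speed_step_corr``, then affine-mapped so ~95% of speeds fall
    in the 2-19 cm/s range.  The trace interpolates window centers.
    """
    n_win = int(np.floor(cfg.duration_s / window_s))
    edges = np.arange(n_win + 1) * window_s
    counts = np.diff(np.searchsorted(step_troughs, edges)).astype(float)
    sd = counts.std()
    z = (counts - counts.mean()) / sd if sd > 0 else np.zeros(n_win)
    a = cfg.speed_step_corr
    noise = rng.normal(0.0, 1.0, n_win)
    mix = a * z + np.sqrt(max(0.0, 1.0 - a * a)) * noise
    speed_win = cfg.speed_mean_cms + cfg.speed_sd_cms * mix
    speed_win = np.clip(speed_win, 0.0, None)
    # zero-order hold: per-window mean of the trace equals the
    # constructed window value, so the injected correlation survives
    # the round trip through windowed re-analysis exactly
    rate = cfg.paw_rate_hz
    n = int(round(cfg.duration_s * rate))
    idx = np.minimum((np.arange(n) / (window_s * rate)).astype(int),
                     n_win - 1)
    return UniformTimeSeries(speed_win[idx], rate, 0.0)


# ---------------------------------------------------------------------------
# spikes

def generate_spikes(cfg: SynthSessionConfig, theta_phase: PhaseSeries,
                    step_phase: PhaseSeries,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Spike tables for all configured units.

    Each unit is an inhomogeneous point process of burst onsets whose
    log-intensity is baseline + theta_kappa*cos(phase_theta - theta_mu)
    + step_kappa*cos(phase_step - step_mu); each onset emits
    ``burst_len`` spikes at short intra-burst intervals.  Intensity is
    rescaled so the realized mean spike rate matches ``mean_rate_hz``.
    """
    rate = 1000.0
    n = int(round(cfg.duration_s * rate))
    t = np.arange(n) / rate
    phi_t = np.radians(theta_phase.phase_at(t))
    phi_s = np.radians(step_phase.phase_at(t))
    frames = []
    for u in cfg.units:
        mod = np.zeros(n)
        mt = np.isfinite(phi_t)
        ms = np.isfinite(phi_s)
        mod[mt] += u.theta_kappa * np.cos(phi_t[mt] - np.radians(u.theta_mu_deg))
        mod[ms] += u.step_kappa * np.cos(phi_s[ms] - np.radians(u.step_mu_deg))
        lam = np.exp(mod)
        lam *= (u.mean_rate_hz / u.burst_len) / lam.mean()
        counts = rng.poisson(lam / rate)
        onsets = np.repeat(t, counts) + rng.uniform(0.0, 1.0 / rate,
                                                    int(counts.sum()))
        if u.burst_len > 1:
            # bursts centered on the onset so the preferred phase of the
            # intensity model is preserved by the burst structure
            offs = (np.arange(u.burst_len)
                    - (u.burst_len - 1) / 2.0) * u.burst_isi_s
            spikes = (onsets[:, None] + offs[None, :]).ravel()
            spikes += rng.normal(0.0, 0.2e-3, spikes.size)
        else:
            spikes = onsets
        spikes = np.sort(spikes[(spikes >= 0) & (spikes < cfg.duration_s)])
        # enforce strictly increasing times (refractory-like nudge)
        d = np.diff(spikes)
        while np.any(d <= 0):
            spikes[1:][d <= 0] += 1e-6
            spikes = np.sort(spikes)
            d = np.diff(spikes)
        frames.append(pd.DataFrame({"unit_id": u.unit_id, "time_s": spikes}))
    if not frames:
        return pd.DataFrame({"unit_id": pd.Series(dtype=int),
                             "time_s": pd.Series(dtype=float)})
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# session orchestration

def generate_session(cfg: SynthSessionConfig) -> SynthSession:
    """Generate one full session; identical config (incl. seed) gives a
    bit-identical session.  One master seed spawns independent streams
    for LFP, stepping, speed and spikes so stages are individually
    reproducible."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_lfp, rng_step, rng_speed, rng_spk = (
        np.random.default_rng(s) for s in ss.spawn(4))
    lfp, theta_troughs = generate_theta_lfp(cfg, rng_lfp)
    left, right, gt = generate_stepping(cfg, theta_troughs, rng_step)
    speed = generate_speed(cfg, gt.right_trough_times_s, rng_speed)

    theta_phase = PhaseSeries(np.empty(0), cfg.lfp_rate_hz, 0.0,
                              EventSeries(gt.theta_trough_times_s))
    step_phase = PhaseSeries(np.empty(0), cfg.paw_rate_hz, 0.0,
                             EventSeries(gt.right_trough_times_s))
    spikes = generate_spikes(cfg, theta_phase, step_phase, rng_spk)
    return SynthSession(config=cfg, lfp=lfp, paw_left=left, paw_right=right,
                        speed=speed, spikes=spikes, ground_truth=gt)
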