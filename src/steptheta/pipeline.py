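"""End-to-end session analysis: simulate -> analyze -> report glue.

``run_pipeline`` takes a session (directory or in-memory) and a
:class:`~steptheta.config.PipelineConfig` and produces one JSON-ready
report aggregating every analysis: spectra, step-theta coupling with
the shuffle test, behavioral (VRon/VRoff/VRrwd) and speed parcellation,
500-ms segment classification, step-speed correlation, and per-unit
spike analyses.  The report is deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

from . import coupling as cp
from . import signal as sig
from . import spikes as spk
from .config import PipelineConfig
from .core import EventSeries
from .io import Session, read_session


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and np.isnan(x):
        return None
    return x


def extract_theta_phase(session: Session, cfg: PipelineConfig | None = None):
    """Band-pass the LFP, detect theta troughs, and return
    ``(theta_troughs, theta_phase)`` on the LFP grid."""
    cfg = cfg or PipelineConfig()
    theta = sig.bandpass(session.lfp, *cfg.theta_band_hz)
    theta_troughs = sig.detect_troughs(theta, cfg.theta_min_interval_s,
                                       cfg.theta_prominence_frac,
                                       label="theta_trough")
    theta_phase = sig.phase_from_troughs(theta_troughs, session.lfp.rate_hz,
                                         session.lfp.t0_s,
                                         session.lfp.duration_s)
    return theta_troughs, theta_phase


def extract_step_troughs(session: Session,
                         cfg: PipelineConfig | None = None,
                         paw: str = "right") -> EventSeries:
    """Detect step-cycle troughs on one paw's displacement trace."""
    cfg = cfg or PipelineConfig()
    trace = session.paw_right if paw == "right" else session.paw_left
    return sig.detect_troughs(trace, cfg.paw_min_interval_s,
                              cfg.paw_prominence_frac, label="step_trough")


def session_coupling(session: Session, cfg: PipelineConfig | None = None):
    """Step-trough/theta coupling of one session via the full chain
    (trough detection, trough-anchored phase, phase assignment, mean
    vector).  Returns a CouplingResult."""
    cfg = cfg or PipelineConfig()
    _, theta_phase = extract_theta_phase(session, cfg)
    right = extract_step_troughs(session, cfg, "right")
    return cp.coupling_analysis(right, theta_phase,
                                min_events=cfg.min_events,
                                bin_deg=cfg.bin_deg)


def analyze_session(session: Session, config: PipelineConfig | None = None
                    ) -> dict:
    """Run every analysis on one loaded session; see module docstring."""
    cfg = config or PipelineConfig()

    # --- theta phase from the LFP ------------------------------------
    theta_troughs, theta_phase = extract_theta_phase(session, cfg)

    # --- step-cycle troughs (right forepaw drives all analyses) ------
    right_troughs = extract_step_troughs(session, cfg, "right")
    left_troughs = extract_step_troughs(session, cfg, "left")
    run_iv = cp.run_intervals_from_speed(session.speed,
                                         cfg.run_min_speed_cms)
    run_right = EventSeries(cp._restrict(right_troughs.times_s, run_iv))

    # --- headline coupling + shuffle significance --------------------
    observed = cp.coupling_analysis(run_right, theta_phase,
                                    min_events=cfg.min_events,
                                    bin_deg=cfg.bin_deg)
    shuffle = cp.shuffle_test(session.paw_right, theta_phase,
                              n_shuffles=cfg.n_shuffles,
                              offset_range_s=cfg.offset_range_s,
                              seed=cfg.seed,
                              min_interval_s=cfg.paw_min_interval_s,
                              prominence_frac=cfg.paw_prominence_frac,
                              run_intervals=run_iv)

    # --- parcellations -----------------------------------------------
    epochs = cp.EpochSet(session.epochs, session.reward_times_s,
                         cfg.reward_halfwidth_s)
    behavior = cp.parse_behavior(run_right, theta_phase, epochs,
                                 min_events=cfg.min_events)
    speed_bins = cp.parse_speed(run_right, session.speed, theta_phase,
                                bins=list(cfg.speed_bins_cms),
                                min_events=cfg.min_events)
    span = (float(theta_troughs.times_s[0]), float(theta_troughs.times_s[-1]))
    segments = cp.classify_segments(right_troughs, theta_troughs, span,
                                    seg_len_s=cfg.seg_len_s,
                                    phase=theta_phase,
                                    min_events=cfg.min_events)
    stepspeed = {
        "right": cp.step_speed_correlation(right_troughs, session.speed,
                                           cfg.speed_window_s),
        "left": cp.step_speed_correlation(left_troughs, session.speed,
                                          cfg.speed_window_s),
    }

    # --- spectra ------------------------------------------------------
    f_paw, p_paw, peak_paw = sig.power_spectrum(session.paw_right,
                                                cfg.psd_seg_len_s)
    f_lfp, p_lfp, peak_lfp = sig.power_spectrum(session.lfp,
                                                cfg.psd_seg_len_s)

    # --- medial septal units -----------------------------------------
    step_phase = None
    units_block: dict = {"n_total": 0, "n_kept": 0, "units": {}}
    if right_troughs.n >= 2:
        step_phase = sig.phase_from_troughs(right_troughs,
                                            session.paw_right.rate_hz,
                                            session.paw_right.t0_s,
                                            session.paw_right.duration_s)
    units = spk.SpikeUnit.from_frame(session.spikes)
    kept = spk.filter_units(units, cfg.min_spikes)
    units_block["n_total"] = len(units)
    units_block["n_kept"] = len(kept)
    theta_rs, step_rs = [], []
    for u in kept:
        tres = spk.spike_phase_coupling(u, theta_phase, run_iv)
        sres = (spk.spike_phase_coupling(u, step_phase, run_iv)
                if step_phase is not None else None)
        peth_theta = spk.triggered_average(u, theta_troughs,
                                           cfg.peth_window_s, cfg.peth_bin_s)
        peth_step = spk.triggered_average(u, right_troughs,
                                          cfg.peth_window_s, cfg.peth_bin_s)
        units_block["units"][u.unit_id] = {
            "n_spikes": u.n_spikes,
            "theta": tres.to_dict(),
            "step": sres.to_dict() if sres else None,
            "peth_theta": {"lags_s": peth_theta.lags_s,
                           "rate_hz": peth_theta.rate_hz},
            "peth_step": {"lags_s": peth_step.lags_s,
                          "rate_hz": peth_step.rate_hz},
        }
        if sres is not None and not tres.excluded and not sres.excluded:
            theta_rs.append(tres.r)
            step_rs.append(sres.r)
    if len(theta_rs) >= 3:
        rho, p = spk.coupling_strength_correlation(
            np.array(theta_rs), np.array(step_rs),
            n_perm=cfg.n_perm, seed=cfg.seed)
        units_block["coupling_strength_correlation"] = {
            "rho": rho, "p": p, "n_cells": len(theta_rs)}

    report = {
        "config": cfg.to_dict(),
        "config_hash": cfg.hash(),
        "n_theta_troughs": theta_troughs.n,
        "n_step_troughs_right": right_troughs.n,
        "n_step_troughs_right_run": run_right.n,
        "n_step_troughs_left": left_troughs.n,
        "run_time_s": float(sum(e - s for s, e in run_iv)),
        "coupling": observed.to_dict(),
        "shuffle": shuffle.to_dict(),
        "behavior": {k: (v.to_dict() if hasattr(v, "to_dict") else v)
                     for k, v in behavior.items()},
        "speed_bins": {k: ({"n": v["n"],
                            "coupling": v["coupling"].to_dict()}
                           if isinstance(v, dict) and "events" in v else v)
                       for k, v in speed_bins.items()},
        "segments": segments.to_dict(),
        "step_speed": stepspeed,
        "spectra": {
            "paw_right": {"freq_hz": f_paw, "power": p_paw,
                          "peak_hz": peak_paw},
            "lfp": {"freq_hz": f_lfp, "power": p_lfp, "peak_hz": peak_lfp},
        },
        "units": units_block,
    }
    return _jsonable(report)


def run_pipeline(session_dir: str | Path,
                 config: PipelineConfig | None = None) -> dict:
    """Load a session directory, analyze it, and attach input provenance."""
    d = Path(session_dir)
    session = read_session(d)
    report = analyze_session(session, config)
    report["inputs"] = {p.name: _hash_file(p)
                        for p in sorted(d.iterdir()) if p.is_file()}
    return report
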