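"""Session file I/O.

A session directory contains:

* ``paw_left.csv`` / ``paw_right.csv`` — (time_s, displacement)
* ``lfp.f32`` + ``lfp.json`` — flat little-endian float32 samples with a
  JSON sidecar ``{"rate_hz": ..., "t0_s": ..., "units": ...}``
* ``speed.csv`` — (time_s, speed_cms)
* ``events.csv`` — (start_s, end_s, label); rewards are zero-length
  rows labelled ``reward``
* ``spikes.csv`` — (unit_id, time_s)
* ``ground_truth.json`` — present only for synthetic sessions
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import UniformTimeSeries


@dataclass
class Session:
    lfp: UniformTimeSeries
    paw_left: UniformTimeSeries
    paw_right: UniformTimeSeries
    speed: UniformTimeSeries
    epochs: list                     # (start_s, end_s, label)
    reward_times_s: list
    spikes: pd.DataFrame
    ground_truth: dict | None = None


def write_trace_csv(path: Path, ts: UniformTimeSeries,
                    value_col: str = "value") -> None:
    pd.DataFrame({"time_s": ts.times_s, value_col: ts.values}).to_csv(
        path, index=False)


def read_trace_csv(path: Path) -> UniformTimeSeries:
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy()
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: non-uniform sampling")
    return UniformTimeSeries(df.iloc[:, 1].to_numpy(), 1.0 / dt[0],
                             float(t[0]))


def write_trace_f32(path: Path, ts: UniformTimeSeries,
                    units: str = "a.u.") -> None:
    ts.values.astype("<f4").tofile(path)
    sidecar = {"rate_hz": ts.rate_hz, "t0_s": ts.t0_s, "units": units}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_trace_f32(path: Path) -> UniformTimeSeries:
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing JSON sidecar {sidecar_path} for binary trace {path}")
    meta = json.loads(sidecar_path.read_text())
    values = np.fromfile(path, dtype="<f4").astype(float)
    return UniformTimeSeries(values, meta["rate_hz"], meta.get("t0_s", 0.0))


def write_session(session, out_dir: str | Path) -> Path:
    """Write a (synthetic or loaded) session to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trace_csv(out / "paw_left.csv", session.paw_left, "displacement")
    write_trace_csv(out / "paw_right.csv", session.paw_right, "displacement")
    write_trace_f32(out / "lfp.f32", session.lfp, units="mV")
    write_trace_csv(out / "speed.csv", session.speed, "speed_cms")

    epochs = getattr(session, "epochs", None)
    rewards = getattr(session, "reward_times_s", None)
    if epochs is None:                      # synthetic session
        epochs = session.config.epochs
        rewards = session.config.reward_times_s
    rows = [{"start_s": s, "end_s": e, "label": lab} for s, e, lab in epochs]
    rows += [{"start_s": t, "end_s": t, "label": "reward"} for t in rewards]
    pd.DataFrame(rows).to_csv(out / "events.csv", index=False)

    session.spikes.to_csv(out / "spikes.csv", index=False)

    gt = getattr(session, "ground_truth", None)
    if gt is not None:
        payload = gt if isinstance(gt, dict) else gt.to_dict()
        (out / "ground_truth.json").write_text(json.dumps(payload))
    return out


def read_session(session_dir: str | Path) -> Session:
    d = Path(session_dir)
    for name in ("paw_left.csv", "paw_right.csv", "lfp.f32", "speed.csv",
                 "events.csv", "spikes.csv"):
        if not (d / name).exists():
            raise FileNotFoundError(f"session file missing: {d / name}")
    ev = pd.read_csv(d / "events.csv")
    epochs = [(r.start_s, r.end_s, r.label)
              for r in ev.itertuples() if r.label != "reward"]
    rewards = [r.start_s for r in ev.itertuples() if r.label == "reward"]
    gt_path = d / "ground_truth.json"
    return Session(
        lfp=read_trace_f32(d / "lfp.f32"),
        paw_left=read_trace_csv(d / "paw_left.csv"),
        paw_right=read_trace_csv(d / "paw_right.csv"),
        speed=read_trace_csv(d / "speed.csv"),
        epochs=epochs,
        reward_times_s=rewards,
        spikes=pd.read_csv(d / "spikes.csv"),
        ground_truth=(json.loads(gt_path.read_text())
                      if gt_path.exists() else None),
    )
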