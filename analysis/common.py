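"""Shared paths and session roster for the numbered analysis scripts.

Sessions live under scratch/sessions/ (large binary traces, regenerated
on demand by 01_simulate_sessions.py); tables go to results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SESSION_DIR = ROOT / "scratch" / "sessions"
RESULTS = ROOT / "results"

# 3 animals x 3 sessions, 20 min each, the study's coupling conditions
COUPLED_SEEDS = list(range(1, 10))
# sessions used for the step-speed correlation analysis
SPEED_SEEDS = [11, 12, 13]
# uncoupled control session
NULL_SEED = 101


def session_path(name: str) -> Path:
    return SESSION_DIR / name


def coupled_names():
    return [f"coupled_{i:02d}" for i in COUPLED_SEEDS]


def require_sessions(names):
    missing = [n for n in names if not session_path(n).exists()]
    if missing:
        raise SystemExit(
            f"missing sessions {missing}: run 01_simulate_sessions.py first")
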