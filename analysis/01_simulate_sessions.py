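"""Generate the synthetic session roster.

Nine 20-min sessions (3 animals x 3 sessions) carry the study's
injected conditions — theta ~8 Hz, stepping 3-8 Hz, right-paw troughs
coupled to theta at resultant 0.10 / 226 deg, step-speed correlation
0.5 — plus three sessions reserved for the speed analysis and one
uncoupled control.  Sessions are written under scratch/sessions/; a
roster with injected ground truth goes to results/sessions.csv.
"""

import pandas as pd

from steptheta.io import write_session
from steptheta.synth import SynthSessionConfig, generate_session

from common import (COUPLED_SEEDS, NULL_SEED, RESULTS, SESSION_DIR,
                    SPEED_SEEDS, session_path)


def main() -> None:
    SESSION_DIR.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    rows = []
    roster = ([(f"coupled_{i:02d}", i, 0.10) for i in COUPLED_SEEDS]
              + [(f"speed_{i}", i, 0.10) for i in SPEED_SEEDS]
              + [(f"null_{NULL_SEED}", NULL_SEED, 0.0)])
    for name, seed, r in roster:
        cfg = SynthSessionConfig(seed=seed, coupling_r=r)
        session = generate_session(cfg)
        write_session(session, session_path(name))
        gt = session.ground_truth
        rows.append({
            "session": name, "seed": seed, "duration_s": cfg.duration_s,
            "injected_r": r, "injected_mu_deg": cfg.coupling_mu_deg,
            "n_right_troughs": gt.right_trough_times_s.size,
            "n_theta_troughs": gt.theta_trough_times_s.size,
            "n_spikes": len(session.spikes),
        })
        print(f"{name}: {rows[-1]['n_right_troughs']} step troughs, "
              f"{rows[-1]['n_theta_troughs']} theta troughs")
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "sessions.csv", index=False)
    print(f"\nwrote {len(rows)} sessions to {SESSION_DIR}")
    print(f"roster -> {RESULTS / 'sessions.csv'}")


if __name__ == "__main__":
    main()
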