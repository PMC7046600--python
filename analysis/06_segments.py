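"""500-ms segment classification: step vs theta trough counts.

The session span is cut into consecutive 500-ms segments; each is
tagged by whether it contains fewer, equally many, or more step troughs
than theta troughs, and coupling is summarized per segment class.
Writes results/segments.csv with per-session proportions and the
pooled averages.
"""

import numpy as np
import pandas as pd

from steptheta.circstats import kruskal_wallis
from steptheta.config import PipelineConfig
from steptheta.coupling import classify_segments
from steptheta.io import read_session
from steptheta.pipeline import (extract_step_troughs, extract_theta_phase)

from common import RESULTS, coupled_names, require_sessions, session_path


def main() -> None:
    names = coupled_names()
    require_sessions(names)
    cfg = PipelineConfig()
    rows = []
    by_class: dict = {}
    for name in names:
        s = read_session(session_path(name))
        theta_troughs, phase = extract_theta_phase(s, cfg)
        steps = extract_step_troughs(s, cfg)
        span = (float(theta_troughs.times_s[0]),
                float(theta_troughs.times_s[-1]))
        seg = classify_segments(steps, theta_troughs, span, cfg.seg_len_s,
                                phase, cfg.min_events)
        row = {"session": name, "n_segments": seg.n_segments}
        for c, p in seg.proportions.items():
            row[c] = p
            res = seg.coupling[c]
            if not res.excluded:
                by_class.setdefault(c, []).append(res.r)
        rows.append(row)
        print(f"{name}: " + "  ".join(
            f"{c} {100 * p:.0f}%" for c, p in seg.proportions.items()))
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "segments.csv", index=False)
    mean_props = df[["step<theta", "step=theta", "step>theta"]].mean()
    print("\npooled: " + "  ".join(f"{c} {100 * v:.0f}%"
                                   for c, v in mean_props.items()))
    groups = [np.array(v) for v in by_class.values() if len(v) >= 2]
    if len(groups) >= 2:
        h, p = kruskal_wallis(groups)
        print(f"coupling across segment classes: Kruskal-Wallis "
              f"H={h:.2f} p={p:.3f}")


if __name__ == "__main__":
    main()
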