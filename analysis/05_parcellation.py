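"""Behavioral-state and running-speed parcellation of the coupling.

Step troughs are split by condition (VRon / VRoff / VRrwd, reward
windows taking precedence) and independently by speed bin (2-7, 7-13,
13-19 cm/s); coupling is summarized per subset (>= 200 troughs) and
compared across groups with Kruskal-Wallis on per-session r values.
Writes results/parcellation.csv.
"""

import numpy as np
import pandas as pd

from steptheta.circstats import kruskal_wallis
from steptheta.config import PipelineConfig
from steptheta.coupling import EpochSet, parse_behavior, parse_speed
from steptheta.io import read_session
from steptheta.pipeline import extract_step_troughs, extract_theta_phase

from common import RESULTS, coupled_names, require_sessions, session_path


def main() -> None:
    names = coupled_names()
    require_sessions(names)
    cfg = PipelineConfig()
    rows = []
    by_label: dict = {}
    for name in names:
        s = read_session(session_path(name))
        _, phase = extract_theta_phase(s, cfg)
        troughs = extract_step_troughs(s, cfg)
        ep = EpochSet(s.epochs, s.reward_times_s, cfg.reward_halfwidth_s)
        beh = parse_behavior(troughs, phase, ep, cfg.min_events)
        spd = parse_speed(troughs, s.speed, phase,
                          list(cfg.speed_bins_cms), cfg.min_events)
        results = {lab: beh[lab] for lab in ("VRon", "VRoff", "VRrwd")}
        results.update({f"{lo:g}-{hi:g} cm/s": spd[f"{lo:g}-{hi:g}"]["coupling"]
                        for lo, hi in cfg.speed_bins_cms})
        for lab, res in results.items():
            rows.append({"session": name, "condition": lab, "n": res.n,
                         "r": res.r, "mean_angle_deg": res.mean_angle_deg,
                         "rayleigh_p": res.rayleigh_p,
                         "excluded": res.excluded})
            if not res.excluded:
                by_label.setdefault(lab, []).append(res.r)
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "parcellation.csv", index=False)

    beh_groups = [np.array(by_label[k]) for k in ("VRon", "VRoff", "VRrwd")
                  if k in by_label and len(by_label[k]) >= 2]
    if len(beh_groups) >= 2:
        h, p = kruskal_wallis(beh_groups)
        print(f"behavioral conditions: Kruskal-Wallis H={h:.2f} p={p:.3f} "
              f"({'no ' if p > 0.05 else ''}detectable difference)")
    spd_groups = [np.array(v) for k, v in by_label.items()
                  if k.endswith("cm/s") and len(v) >= 2]
    if len(spd_groups) >= 2:
        h, p = kruskal_wallis(spd_groups)
        print(f"speed bins: Kruskal-Wallis H={h:.2f} p={p:.3f} "
              f"({'no ' if p > 0.05 else ''}detectable difference)")
    print(f"\nper-condition table -> {RESULTS / 'parcellation.csv'}")


if __name__ == "__main__":
    main()
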