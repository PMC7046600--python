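# steptheta

Phase relationships between the stepping rhythm of running rodents,
hippocampal theta oscillations, and medial septal neuron spiking.

During locomotion, head-fixed mice step at ~3–8 Hz — a range that
overlaps hippocampal theta (~6–10 Hz). This package implements the
analysis chain used to ask whether the two rhythms are coupled: it
detects step-cycle troughs (the moments a paw touches the ground) on
paw-displacement traces, attributes a theta phase to each trough, and
quantifies coupling with circular statistics, guarding significance
with a time-offset shuffle test. Because no recordings of this kind
are publicly deposited, the package also contains a first-class
synthetic-session generator that injects known coupling, so every
stage can be validated by parameter recovery.

## The statistics at the core

For event phases φ₁…φₙ (degrees, theta trough = 0) the depth of
modulation is the mean resultant length

    r = | Σₖ e^{iφₖ} | / n,   r ∈ [0, 1],

with the preferred phase given by the argument of the sum (Zar's
mean-vector method). Uniformity is tested with the Rayleigh statistic
z = n·r², using the exponential approximation of the p value.
Significance of the observed coupling is assessed against a surrogate
null: the continuous paw-displacement trace is circularly shifted by a
random 1–3 s offset, troughs are re-detected, and r is recomputed; the
observed r is significant when it exceeds the 99th percentile of 500
such shuffles. Further analyses parcel the data by behavioral state
(virtual-reality feedback on/off and ±1 s reward windows), by running
speed (2–7, 7–13, 13–19 cm/s), and by 500-ms segments classified on
step- vs theta-trough counts; medial septal units (≥ 300 spikes) are
tested for spike-phase coupling to both rhythms and summarized with
trough-triggered averages.

## Worked example

```python
from steptheta import SynthSessionConfig, generate_session
from steptheta.pipeline import session_coupling, extract_theta_phase
from steptheta.coupling import shuffle_test

session = generate_session(SynthSessionConfig(seed=3))   # 20-min session
res = session_coupling(session)
print(f"n={res.n} r={res.r:.3f} angle={res.mean_angle_deg:.0f} deg "
      f"p={res.rayleigh_p:.2e}")

_, theta_phase = extract_theta_phase(session)
sh = shuffle_test(session.paw_right, theta_phase, seed=3)
print(f"observed r={sh.observed_r:.4f} vs shuffled 99th pct "
      f"{sh.pct99:.4f} -> significant={sh.significant}")
```

prints

```
n=6418 r=0.100 angle=225 deg p=8.40e-29
observed r=0.1002 vs shuffled 99th pct 0.0292 -> significant=True
```

The session was generated with step troughs coupled to theta at
resultant 0.10 and mean direction 226°; the pipeline recovers a weak
but highly non-uniform phase distribution (r ≈ 0.10 near 226°) that
clearly exceeds its shuffle null — the same signature reported for
real recordings.

## Analysis scripts

`analysis/01_simulate_sessions.py` … `07_septal_units.py` run the full
study narrative on a roster of synthetic sessions (9 coupled sessions
plus controls): spectra and step–speed correlation, per-session
coupling, shuffle significance, behavioral/speed parcellation, 500-ms
segment classification, and the septal-unit analyses. Session data are
written under `scratch/sessions/` and tables under `results/`.

There is also a CLI for single sessions:

```bash
steptheta simulate --config cfg.json --out session_dir/
steptheta analyze --session session_dir/ --out report.json
steptheta report --report report.json --out figures/
```

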