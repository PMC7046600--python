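# Methods

## Problem setting

Running rodents step rhythmically at roughly 3–8 Hz while the
hippocampal local field potential (LFP) expresses theta oscillations at
roughly 6–10 Hz. The analyses here quantify whether step-cycle troughs
— the moments a paw touches the ground — occur at preferred phases of
theta, whether that preference survives a surrogate-data significance
test, whether it depends on behavioral state or running speed, and
whether medial septal neurons are phase-coupled to both rhythms
simultaneously. Since no public recordings exist for this paradigm,
every analysis is exercised on synthetic sessions with known injected
structure; passing tests demonstrate parameter recovery under the
generator's assumptions, not properties of any real dataset.

## Phase convention

All phases are in degrees with the cycle trough at 0°. Instantaneous
phase is constructed by trough-to-trough linear interpolation: phase is
exactly 0 at each detected trough and ramps linearly to 360° at the
next. This matches the trough-anchored convention of the analyses and
avoids the waveform-asymmetry sensitivity of Hilbert phase (for an
asymmetric cycle the Hilbert analytic phase at the waveform minimum is
not a fixed value; the two conventions agree only for symmetric
cycles). Samples before the first and after the last trough carry no
phase; events there are dropped and counted. Degrees are used on every
interface; radians appear only inside computations.

## Trough detection

Troughs are local minima of the (optionally band-passed) trace that
clear a prominence threshold of `prominence_frac` (default 0.25) times
the robust trace range (5th–95th percentile), separated by at least
`min_interval_s`; of two closer candidates the deeper wins. Before
detection the trace is smoothed with a centered moving average of half
the minimum interval (a no-op below 3 samples), which keeps broadband
noise from clearing the prominence gate while displacing symmetric
cycle minima by nothing; detection thresholds are always computed from
the raw trace. Trough times are refined to sub-sample precision by a
parabolic fit through the three samples around each minimum. Partial
cycles at the trace edges are excluded from all phase analyses. The
theta band for LFP trough detection defaults to 4–12 Hz (zero-phase
Butterworth, forward–backward), `min_interval_s` = 65 ms; paw traces
use 60 ms and no band-pass.

## Circular statistics

Depth of modulation is the mean resultant length r = |Σ e^{iφ}|/n;
its direction is the preferred phase, reported as undefined when
r < 1e-12. Uniformity uses the Rayleigh statistic z = n r² with the
exponential approximation p = exp(√(1+4n+4(n²−R²)) − (1+2n)), R = n r
(a higher-order series variant is available behind the same flag); a
Monte-Carlo test in the suite checks the approximation against
brute-force simulation at n = 10. Phase histograms use 18° half-open
bins. Group comparisons use Kruskal–Wallis with tie correction
(delegated to scipy); the all-identical-input corner returns H = 0,
p = 1. No multiple-testing correction is applied anywhere.

## Shuffle (time-offset) significance test

The continuous paw-displacement trace is circularly shifted by an
offset drawn uniformly from 1–3 s with random sign, troughs are
re-detected on the shifted trace, theta phases are re-assigned, and r
is recomputed; 500 shuffles form the null and the observed r is
significant when it exceeds their 99th percentile. Circular shifting
preserves the trough count, so the null matches the observed sample
size.

A property of this surrogate worth knowing: all 500 shuffled
statistics are computed from the same trough set, and because offsets
are confined to ±1–3 s, two shuffles can sit arbitrarily close to one
another in offset while every shuffle is at least 1 s from the
observed data. The shuffled distribution is therefore slightly
under-dispersed relative to the observed statistic, and the realized
false-positive level of the test on truly uncoupled sessions is about
3–4% rather than the nominal 1% (measured here over hundreds of
seeded 20-minute null sessions and reproduced with a stripped-down
reimplementation free of detection and noise). Detection of genuinely
coupled sessions is unaffected: with the injected effect size the
observed r exceeds the shuffled 99th percentile by a factor of ~3.

## Parcellation rules

Behavioral conditions: VRrwd is the ±1 s window around each reward and
takes precedence over the VRon/VRoff epoch containing it; overlapping
VRon/VRoff epochs are an error; events in no epoch are counted as
unassigned. Speed bins are half-open [2,7), [7,13), [13,19) cm/s on
the instantaneous speed at each event. Any parsed event set with fewer
than 200 events is excluded from phase statistics (reported as a
below-threshold marker); spike analyses instead require ≥ 300 spikes
per unit. Segment classification cuts the analysis span into
consecutive 500-ms half-open windows anchored at the span start (no
partial terminal segment) and compares step- and theta-trough counts
per window. RUN periods default to speed ≥ 2 cm/s (the lower edge of
the slow bin) for at least 0.5 s; the step–speed correlation is
Pearson's r between non-overlapping 1-s window counts and mean speed.
The right forepaw drives all step analyses; the left is generated and
analyzed only for alternation and its own step–speed correlation.

## Synthetic sessions

The generator produces, per session: an LFP whose cycle frequency
follows a clipped mean-reverting random walk (stationary SD
`drift_sd`, correlation time 4 s — frequencies wander over seconds,
as in real recordings, rather than jumping cycle-to-cycle) rendered as
−cos(phase) with a smooth per-cycle amplitude envelope plus white
noise; paw displacement traces built as raised-cosine cycles with
unambiguous minima plus white noise (SD 5% of amplitude); a speed
trace; spike trains; behavioral epochs and reward times. Defaults
encode the study conditions: 20-min sessions, LFP at 1 kHz, paw
tracking at 50 Hz, theta 8 ± 0.5 Hz (clipped 6–10), stepping
5.5 ± 1 Hz (clipped 3–8), coupling r = 0.10 at 226°, step–speed
correlation 0.5, twelve bursting units. One master seed spawns
independent streams per stage, so identical configs give bit-identical
sessions.

**Coupling injection.** Right-paw troughs are placed at theta phases
drawn i.i.d. from a von Mises distribution with mean 226° and
concentration κ solving A(κ) = I₁(κ)/I₀(κ) = r₀ (bisection to 1e-8);
each trough is snapped to the nearest time at which theta actually
crosses the drawn phase, subject to a minimum inter-trough interval of
half a step period (snapping to the following cycle when needed, which
never alters the drawn phase). The injected resultant is therefore
exactly known — the reason for preferring direct phase placement over
coupled dynamical oscillators. Left-paw troughs sit at the midpoints
of consecutive right troughs (gait alternation).

**The uncoupled case is different in kind.** With `coupling_r = 0` the
step clock runs independently of theta and no snapping occurs. This is
deliberate: snapping troughs to i.i.d. *uniform* phases would still
tie the step process to theta's cycle grid, and such a process is not
statistically exchangeable with its own time-shifted copies — the
shuffle test then misfires at 8–9% instead of its realized ~3–4%.
Physically independent oscillators produce marginally uniform (indeed
slightly super-uniform, lattice-like) relative phases and are the
correct model of "no coupling".

**Speed.** Per 1-s window, speed is a·zscore(step count) + √(1−a²)·
noise with a the target correlation, affine-mapped so ~95% of values
fall in 2–19 cm/s, clipped at 0, and rendered as a zero-order-hold
trace so windowed re-analysis recovers the constructed values exactly.

**Spikes.** Each unit is an inhomogeneous Poisson process of burst
onsets with log-intensity θκ·cos(φθ−θμ) + sκ·cos(φs−sμ), rescaled to
the unit's mean rate; each onset emits `burst_len` spikes at 5-ms
intervals centered on the onset (centering preserves the preferred
phase). Trough-preferring short-burst and peak-preferring long-burst
phenotypes are the defaults.

**What the generator does not emulate.** Video-tracking artifacts,
non-sinusoidal theta harmonics, theta amplitude–speed covariation,
grooming/immobility bouts, spike sorting noise, and any
cross-frequency structure beyond the injected phase couplings. Tests
passing on these sessions show the pipeline recovers what was
injected; they cannot show robustness to artifacts the generator
omits.

## Numerical choices

Zero-phase 4th-order Butterworth band-passes; Welch spectra with
10-s segments, power normalized to the maximum, peak reported over
1–20 Hz; percentile-based (5–95%) robust ranges; ties between equal
minima broken by earlier time; permutation p-values with add-one
correction ((1+k)/(N+1)); the across-cell coupling-strength
correlation is Spearman's ρ with a seeded 10⁴-permutation two-sided
p. Problem sizes in the test suite are chosen so the full run takes a
few minutes: 20-minute sessions where the study conditions demand
them, 1–7-minute sessions for structural checks.

## Known limitations

- The shuffle surrogate's realized type-I level (~3–4% at nominal 1%)
  is a property of the published 1–3 s offset procedure, as analyzed
  above; widening the offset range would fix it but would no longer be
  the same test.
- Trough-anchored linear phase is exact at troughs but piecewise-
  uniform in between; estimates of preferred phase away from the
  trough inherit a small cycle-shape bias relative to Hilbert phase.
- The ≥ 200-event filter makes VRrwd coupling estimates unavailable in
  short sessions (few rewards), which the reports mark as excluded
  rather than zero.
- Paw traces are sampled at 50 Hz; trough timing is parabolic-refined
  but phase jitter of a few degrees at 8-Hz theta remains and
  attenuates recovered resultants by roughly 3–5% relative to the
  injected value.
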