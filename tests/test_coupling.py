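"""Coupling pipeline: phase assignment, filters, shuffle, parcellation."""

import numpy as np
import pytest

from steptheta.circstats import kruskal_wallis, mean_vector
from steptheta.core import EventSeries, PhaseSeries, UniformTimeSeries
from steptheta.coupling import (EpochSet, assign_phases, classify_segments,
                                coupling_analysis, parse_behavior,
                                parse_speed, shuffle_test,
                                step_speed_correlation)
from steptheta.pipeline import extract_theta_phase
from steptheta.synth import SynthSessionConfig, generate_session, \
    kappa_for_resultant


def uniform_phase(cycle_s=0.125, n_cycles=200):
    """PhaseSeries from perfectly regular troughs."""
    troughs = EventSeries(np.arange(n_cycles + 1) * cycle_s)
    return PhaseSeries(np.empty(0), 1000.0, 0.0, troughs)


class TestAssignPhases:
    def test_trough_and_midpoint(self):
        ph = uniform_phase()
        got, dropped = assign_phases(EventSeries([0.125, 0.125 * 1.5]), ph)
        assert got[0] == 0.0
        assert got[1] == pytest.approx(180.0)
        assert dropped == 0

    def test_out_of_span_dropped_and_counted(self):
        ph = uniform_phase(n_cycles=10)
        got, dropped = assign_phases(EventSeries([0.5, 99.0]), ph)
        assert got.size == 1 and dropped == 1

    def test_all_outside_errors(self):
        with pytest.raises(ValueError):
            assign_phases(EventSeries([99.0]), uniform_phase(n_cycles=10))

    def test_generator_round_trip_at_known_phases(self, rng):
        """Events placed at exact von Mises phases along regular theta
        cycles come back with the injected mean direction."""
        troughs = np.arange(0, 401) * 0.125
        ph = PhaseSeries(np.empty(0), 1000.0, 0.0, EventSeries(troughs))
        kappa = kappa_for_resultant(0.6)
        draws = np.degrees(rng.vonmises(np.radians(226), kappa, 100)) % 360
        cycles = rng.choice(399, 100, replace=False)
        times = np.sort(troughs[cycles] + draws / 360.0 * 0.125)
        got, _ = assign_phases(EventSeries(times), ph)
        _, ang = mean_vector(got)
        assert min(abs(ang - 226), 360 - abs(ang - 226)) < 10.0


class TestCouplingAnalysis:
    def test_below_threshold_marker(self, rng):
        ph = uniform_phase(n_cycles=500)
        times = np.sort(rng.uniform(1, 60, 199))
        res = coupling_analysis(EventSeries(times), ph)
        assert res.excluded and res.n == 199
        assert np.isnan(res.r)

    def test_uniform_null_expectation(self):
        """Random events on a regular phase grid: r is near its uniform-
        null expectation sqrt(pi)/2/sqrt(n) and the Rayleigh test only
        rejects at its nominal rate (fixed seed battery)."""
        ph = uniform_phase(n_cycles=500)
        n = 200
        expect = np.sqrt(np.pi) / 2.0 / np.sqrt(n)
        rs, rejects = [], 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            times = np.sort(rng.uniform(1, 60, n))
            res = coupling_analysis(EventSeries(times), ph)
            assert not res.excluded
            rs.append(res.r)
            rejects += res.rayleigh_p <= 0.05
        assert np.mean(rs) == pytest.approx(expect, rel=0.35)
        assert rejects <= 3        # >= 90% of runs keep p > 0.05

    def test_injected_session_recovery(self, medium_session):
        """Full chain on a synthetic session recovers the injected weak
        coupling (within 3 SE) and the 226-degree preferred phase."""
        from steptheta.pipeline import session_coupling
        res = session_coupling(medium_session)
        se = np.sqrt((1 - 0.1 ** 2) / (2 * res.n))
        assert abs(res.r - 0.10) <= 3 * se
        d = abs(res.mean_angle_deg - 226.0)
        assert min(d, 360 - d) <= 20.0
        assert res.histogram.sum() == res.n


class TestShuffleTest:
    def test_deterministic_given_seed(self, short_session, pcfg):
        _, ph = extract_theta_phase(short_session, pcfg)
        a = shuffle_test(short_session.paw_right, ph, n_shuffles=100,
                         seed=5)
        b = shuffle_test(short_session.paw_right, ph, n_shuffles=100,
                         seed=5)
        assert a.observed_r == b.observed_r
        assert np.array_equal(a.shuffled_r, b.shuffled_r)
        assert a.significant == b.significant

    def test_coupled_session_significant(self, short_session, pcfg):
        _, ph = extract_theta_phase(short_session, pcfg)
        res = shuffle_test(short_session.paw_right, ph, seed=1)
        assert res.significant
        assert res.observed_r > res.pct99

    def test_few_shuffles_warn(self, short_session, pcfg):
        _, ph = extract_theta_phase(short_session, pcfg)
        with pytest.warns(UserWarning):
            shuffle_test(short_session.paw_right, ph, n_shuffles=20, seed=0)

    def test_short_trace_errors(self):
        ts = UniformTimeSeries(np.zeros(100), 50.0)
        with pytest.raises(ValueError):
            shuffle_test(ts, uniform_phase(), seed=0)

    def test_joint_time_shift_leaves_r_unchanged(self, short_session, pcfg):
        """Shifting paw trace and theta troughs by the same offset
        leaves the observed coupling unchanged (up to edge troughs)."""
        from steptheta.pipeline import extract_step_troughs, session_coupling
        from steptheta import signal as sig
        delta_n = 250                    # 5 s at 50 Hz
        base = session_coupling(short_session, pcfg)
        paw = short_session.paw_right
        shifted_paw = UniformTimeSeries(np.roll(paw.values, delta_n),
                                        paw.rate_hz)
        ttr, _ = extract_theta_phase(short_session, pcfg)
        delta_s = delta_n / paw.rate_hz
        shifted_troughs = EventSeries(ttr.times_s + delta_s)
        ph = PhaseSeries(np.empty(0), 1000.0, 0.0, shifted_troughs)
        tr = sig.detect_troughs(shifted_paw, pcfg.paw_min_interval_s,
                                pcfg.paw_prominence_frac)
        inner = EventSeries(tr.times_s[(tr.times_s > delta_s + 1)])
        res = coupling_analysis(inner, ph)
        assert res.r == pytest.approx(base.r, abs=0.01)


class TestParseBehavior:
    def epochs(self):
        return EpochSet(intervals=[(0.0, 60.0, "VRoff"),
                                   (60.0, 240.0, "VRon"),
                                   (240.0, 300.0, "VRoff")],
                        reward_times_s=[100.0, 200.0])

    def test_reward_precedence_inside_vron(self):
        labels = self.epochs().label_of(np.array([100.5, 150.0, 30.0,
                                                  350.0]))
        assert list(labels) == ["VRrwd", "VRon", "VRoff", ""]

    def test_overlapping_epochs_error(self):
        with pytest.raises(ValueError):
            EpochSet(intervals=[(0.0, 100.0, "VRon"),
                                (50.0, 150.0, "VRoff")])

    def test_per_label_results_and_unassigned(self):
        ph = uniform_phase(cycle_s=0.125, n_cycles=2600)
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 320, 600))
        out = parse_behavior(EventSeries(times), ph, self.epochs(),
                             min_events=20)
        assert set(out) == {"VRon", "VRoff", "VRrwd", "n_unassigned"}
        assert out["n_unassigned"] > 0
        assert not out["VRon"].excluded

    def test_same_coupling_across_conditions(self):
        """Sessions with one injected coupling level: the per-condition
        resultants do not differ (Kruskal-Wallis on per-session r)."""
        from steptheta.pipeline import extract_step_troughs, \
            extract_theta_phase
        groups = {"VRon": [], "VRoff": [], "VRrwd": []}
        for seed in (41, 42, 43, 44):
            s = generate_session(SynthSessionConfig(duration_s=300.0,
                                                    seed=seed))
            _, ph = extract_theta_phase(s)
            troughs = extract_step_troughs(s)
            ep = EpochSet(s.epochs, s.reward_times_s)
            out = parse_behavior(troughs, ph, ep, min_events=30)
            for lab in groups:
                if not out[lab].excluded:
                    groups[lab].append(out[lab].r)
        _, p = kruskal_wallis([np.array(v) for v in groups.values()])
        assert p > 0.05


class TestParseSpeed:
    def constant_speed(self, value, dur=100.0):
        n = int(dur * 50)
        return UniformTimeSeries(np.full(n, float(value)), 50.0)

    def test_half_open_bin_edges(self):
        ev = EventSeries([50.0])
        out = parse_speed(ev, self.constant_speed(7.0))
        assert out["7-13"]["n"] == 1 and out["2-7"]["n"] == 0

    def test_out_of_range_unassigned(self):
        ev = EventSeries([50.0])
        out = parse_speed(ev, self.constant_speed(25.0))
        assert out["n_unassigned"] == 1
        assert out["covered_fraction"] == 0.0

    def test_default_synth_mostly_covered(self, short_session):
        from steptheta.pipeline import extract_step_troughs
        troughs = extract_step_troughs(short_session)
        out = parse_speed(troughs, short_session.speed)
        assert out["covered_fraction"] >= 0.90


class TestClassifySegments:
    def test_count_comparisons(self):
        steps = EventSeries([0.1, 0.3])
        theta = EventSeries([0.05, 0.15, 0.25, 0.35])
        out = classify_segments(steps, theta, (0.0, 0.5), phase=None)
        assert out.counts["step<theta"] == 1 and out.n_segments == 1

    def test_equal_counts(self):
        steps = EventSeries([0.1, 0.2, 0.3])
        theta = EventSeries([0.15, 0.25, 0.35])
        out = classify_segments(steps, theta, (0.0, 0.5))
        assert out.counts["step=theta"] == 1

    def test_theta_faster_everywhere(self):
        """8 Hz theta vs 4 Hz stepping: every 500-ms segment has more
        theta troughs (counting oracle: 4 vs 2 per segment)."""
        theta = EventSeries(np.arange(0, 60, 0.125))
        steps = EventSeries(np.arange(0.03, 60, 0.25))
        out = classify_segments(steps, theta, (0.0, 60.0))
        assert out.proportions["step<theta"] == 1.0

    def test_partition_and_merge_consistency(self, rng):
        """Classes partition all segments; 0.25-s counts merged in pairs
        reproduce the 0.5-s counts when no trough hits a boundary."""
        steps = EventSeries(np.sort(rng.uniform(0, 60, 300)) + 1e-4)
        theta = EventSeries(np.arange(0.0612, 60, 0.125))
        half = classify_segments(steps, theta, (0.0, 60.0), seg_len_s=0.5)
        assert sum(half.counts.values()) == half.n_segments
        q_edges = np.arange(0, 60.0001, 0.25)
        sc = np.diff(np.searchsorted(steps.times_s, q_edges))
        tc = np.diff(np.searchsorted(theta.times_s, q_edges))
        sc2 = sc.reshape(-1, 2).sum(1)
        tc2 = tc.reshape(-1, 2).sum(1)
        assert half.counts["step=theta"] == int((sc2 == tc2).sum())
        assert half.counts["step<theta"] == int((sc2 < tc2).sum())

    def test_span_too_short_errors(self):
        with pytest.raises(ValueError):
            classify_segments(EventSeries([0.1]), EventSeries([0.2]),
                              (0.0, 0.3))


class TestStepSpeedCorrelation:
    def test_proportional_noiseless(self):
        """Speed built proportional to per-window counts gives r = 1."""
        rng = np.random.default_rng(0)
        counts = rng.integers(2, 9, 60)
        times = np.concatenate([w + np.linspace(0.05, 0.95, c)
                                for w, c in enumerate(counts)])
        speed_vals = np.repeat(counts.astype(float), 50)
        out = step_speed_correlation(EventSeries(times),
                                     UniformTimeSeries(speed_vals, 50.0))
        assert out["r"] == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_flagged(self):
        times = np.arange(0.5, 60, 1.0)      # exactly 1 per window
        speed = UniformTimeSeries(np.full(3000, 10.0), 50.0)
        out = step_speed_correlation(EventSeries(times), speed)
        assert not out["defined"]

    def test_too_few_windows_errors(self):
        with pytest.raises(ValueError):
            step_speed_correlation(
                EventSeries([0.1]), UniformTimeSeries(np.zeros(100), 50.0))


def test_monotone_recovery_in_injected_coupling():
    """Mean estimated resultant rises strictly with injected coupling
    across r in {0, 0.1, 0.3, 0.6} (120-s sessions, 6 seeds each)."""
    from steptheta.pipeline import session_coupling
    means = []
    for r0 in (0.0, 0.1, 0.3, 0.6):
        vals = []
        for seed in range(6):
            s = generate_session(SynthSessionConfig(
                duration_s=120.0, seed=700 + seed, coupling_r=r0))
            res = session_coupling(s)
            vals.append(res.r)
        means.append(np.mean(vals))
    assert all(b > a for a, b in zip(means, means[1:]))
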