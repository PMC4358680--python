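import numpy as np
import pytest

from conftest import naive_event_scan

from cortisim import (Event, burstiness_factor, classify_event, detect_events,
                      estimate_baseline, summarise_block)
from cortisim.events import analyse_trace


def const_baseline(trace, level):
    return np.full(len(trace.voltages), float(level))


class TestDetection:
    def test_flat_trace_has_no_events(self, trace_factory):
        tr = trace_factory(np.full(20_000, -55.0))
        assert detect_events(tr, const_baseline(tr, -55.0)) == []

    def test_rectangular_pulse(self, trace_factory):
        v = np.full(20_000, -55.0)
        v[10_000:10_500] = -10.0  # 50 ms pulse
        tr = trace_factory(v)
        events = detect_events(tr, const_baseline(tr, -55.0))
        assert len(events) == 1
        e = events[0]
        assert e.duration == pytest.approx(50.0, abs=0.1)
        assert e.kind == "spike"
        assert e.peak == pytest.approx(-10.0)
        assert not e.truncated

    def test_subthreshold_pulse_ignored(self, trace_factory):
        v = np.full(10_000, -55.0)
        v[4000:5000] = -35.0  # Delta 20 mV < 25 mV threshold
        tr = trace_factory(v)
        assert detect_events(tr, const_baseline(tr, -55.0)) == []

    def test_rearm_semantics(self, trace_factory):
        # a dip below baseline + 5 closes the event and re-arms the detector;
        # a dip that stays at/above it does not
        def pattern(dip):
            v = np.full(12_000, -55.0)
            v[2000:4000] = -10.0
            v[4000:5000] = dip
            v[5000:7000] = -10.0
            return trace_factory(v)

        closing = detect_events(pattern(-51.0), const_baseline(pattern(-51.0),
                                                               -55.0))
        holding = detect_events(pattern(-49.0), const_baseline(pattern(-49.0),
                                                               -55.0))
        assert len(closing) == 2
        assert len(holding) == 1
        assert holding[0].duration == pytest.approx(500.0, abs=0.1)

    def test_event_open_at_end_is_truncated(self, trace_factory):
        v = np.full(10_000, -55.0)
        v[8000:] = -10.0
        tr = trace_factory(v)
        events = detect_events(tr, const_baseline(tr, -55.0))
        assert len(events) == 1
        assert events[0].truncated
        assert events[0].t_end == pytest.approx(tr.duration_ms + tr.dt,
                                                abs=0.1)

    def test_parameter_validation(self, trace_factory):
        tr = trace_factory(np.full(100, -55.0))
        base = const_baseline(tr, -55.0)
        with pytest.raises(ValueError):
            detect_events(tr, base, threshold_delta=5.0, rearm_delta=5.0)
        with pytest.raises(ValueError):
            detect_events(tr, base[:-1])

    def test_matches_independent_naive_scan(self, trace_factory):
        """Kernel detector equals a sample-by-sample reference on random
        traces with random baselines (the full 1000-trace sweep runs in the
        acceptance suite)."""
        rng = np.random.default_rng(123)
        for _ in range(150):
            n = 3000
            v = -55.0 + np.cumsum(rng.normal(0, 1.2, n))
            knots = rng.normal(-55.0, 4.0, 6)
            base = np.interp(np.arange(n), np.linspace(0, n - 1, 6), knots)
            tr = trace_factory(v)
            got = [(int(round(e.t_start / tr.dt)),
                    int(round(e.t_end / tr.dt)), e.peak, e.truncated)
                   for e in detect_events(tr, base)]
            assert got == naive_event_scan(v, base, 25.0, 5.0)


class TestClassification:
    @pytest.mark.parametrize("duration, kind", [
        (50.0, "spike"),
        (99.9, "spike"),
        (100.0, "burst"),   # tie broken toward burst
        (500.0, "burst"),
    ])
    def test_duration_cutoff(self, duration, kind):
        assert classify_event(duration) == kind

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            classify_event(0.0)

    def test_burstiness_factor_counts_bursts(self):
        def ev(dur):
            return Event(0.0, dur, 0.0, classify_event(dur))

        assert burstiness_factor([ev(50), ev(60), ev(200), ev(300)]) == 0.5
        assert burstiness_factor([ev(50), ev(60)]) == 0.0
        assert burstiness_factor([]) is None  # undefined, never 0

    def test_bf_monotone_under_relabelling(self):
        # promoting any spike to a burst can only raise the fraction
        durations = [20.0, 40.0, 60.0, 250.0, 400.0]
        events = [Event(0, d, 0.0, classify_event(d)) for d in durations]
        bf0 = burstiness_factor(events)
        for i, d in enumerate(durations):
            if d < 100.0:
                promoted = list(events)
                promoted[i] = Event(0, 150.0, 0.0, "burst")
                assert burstiness_factor(promoted) >= bf0


class TestBaseline:
    def test_constant_trace(self, trace_factory):
        tr = trace_factory(np.full(50_000, -55.0))
        np.testing.assert_allclose(estimate_baseline(tr), -55.0)

    def test_tracks_subthreshold_step_within_one_window(self, trace_factory):
        v = np.concatenate([np.full(60_000, -55.0), np.full(60_000, -45.0)])
        tr = trace_factory(v)
        base = estimate_baseline(tr, window_ms=2000.0)
        # two windows after the step the old level has left the window
        assert base[60_000 + 40_000:].max() == pytest.approx(-45.0, abs=0.01)
        assert base[:60_000].min() == pytest.approx(-55.0, abs=0.01)

    def test_ignores_regular_spikes(self, trace_factory):
        from cortisim.synthetic import (GroundTruthSpec, ScheduledEvent,
                                        generate_trace)
        spec = GroundTruthSpec(
            baseline_mv=-55.0,
            events=tuple(ScheduledEvent(1000.0 * k, 20.0, "spike")
                         for k in range(1, 30)))
        tr, _ = generate_trace(spec)
        base = estimate_baseline(tr)
        assert np.abs(base + 55.0).max() < 1.0

    def test_window_validation(self, trace_factory):
        tr = trace_factory(np.full(1000, -55.0))
        with pytest.raises(ValueError):
            estimate_baseline(tr, window_ms=0.0)
        with pytest.raises(ValueError):
            estimate_baseline(tr, window_ms=500.0)  # longer than 100 ms trace
        with pytest.raises(ValueError):
            estimate_baseline(trace_factory([]))

    def test_slow_drift_does_not_change_classification(self):
        from cortisim.synthetic import (GroundTruthSpec, generate_trace,
                                        periodic_schedule)
        schedule = periodic_schedule(6, 3, gap_ms=3000.0)
        flat_spec = GroundTruthSpec(events=schedule, noise_sigma_mv=1.0,
                                    seed=5)
        drift_spec = GroundTruthSpec(events=schedule, noise_sigma_mv=1.0,
                                     seed=5, drift_mv_per_min=5.0)
        kinds = []
        for spec in (flat_spec, drift_spec):
            tr, _ = generate_trace(spec)
            _, events, _ = analyse_trace(
                tr, [(0.0, tr.duration_ms / 60_000.0)])
            kinds.append([e.kind for e in events if not e.truncated])
        assert kinds[0] == kinds[1]
        assert kinds[0].count("burst") == 3


class TestBlockSummary:
    def test_single_pulse_whole_trace(self, trace_factory):
        v = np.full(100_000, -55.0)  # 100 s at dt = 1 ms
        v[50_000:50_050] = -10.0     # one 50 ms pulse
        tr = trace_factory(v, dt=1.0)
        base = const_baseline(tr, -55.0)
        events = detect_events(tr, base)
        s = summarise_block(tr, base, events, (0.0, 100.0 / 60.0))
        assert s.frequency_hz == pytest.approx(0.01, rel=1e-3)
        assert s.mean_duration_ms == pytest.approx(50.0, abs=1.0)
        assert s.burstiness == 0.0
        assert s.baseline_mv == pytest.approx(-55.0)

    def test_event_counting_frequency(self, trace_factory):
        # 62 events starting inside a 3-minute block -> 0.344 Hz
        v = np.full(200_000, -55.0)  # 200 s at dt = 1 ms
        for k in range(62):
            i = 1000 + k * 2800
            v[i:i + 40] = -10.0
        tr = trace_factory(v, dt=1.0)
        base = const_baseline(tr, -55.0)
        events = detect_events(tr, base)
        s = summarise_block(tr, base, events, (0.0, 3.0))
        assert s.n_events == 62
        assert s.frequency_hz == pytest.approx(62 / 180.0)

    def test_empty_block_is_flagged_undefined(self, trace_factory):
        tr = trace_factory(np.full(120_000, -55.0), dt=1.0)
        base = const_baseline(tr, -55.0)
        s = summarise_block(tr, base, [], (0.0, 2.0))
        assert s.frequency_hz == 0.0
        assert s.mean_duration_ms is None
        assert s.burstiness is None

    def test_truncated_events_count_for_frequency_only(self, trace_factory):
        v = np.full(60_000, -55.0, dtype=float)  # 60 s at dt = 1 ms
        v[59_000:] = -10.0
        tr = trace_factory(v, dt=1.0)
        base = const_baseline(tr, -55.0)
        events = detect_events(tr, base)
        s = summarise_block(tr, base, events, (0.0, 1.0))
        assert s.n_events == 1
        assert s.mean_duration_ms is None   # unknown true duration
        assert s.burstiness is None
        s_incl = summarise_block(tr, base, events, (0.0, 1.0),
                                 include_truncated=True)
        assert s_incl.mean_duration_ms is not None

    def test_interval_validation(self, trace_factory):
        tr = trace_factory(np.full(1000, -55.0), dt=1.0)
        base = const_baseline(tr, -55.0)
        with pytest.raises(ValueError):
            summarise_block(tr, base, [], (0.5, 0.5))
        with pytest.raises(ValueError):
            summarise_block(tr, base, [], (0.0, 2.0))  # beyond 1 s trace
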