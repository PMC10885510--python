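import numpy as np
import pytest

from fiberphot import (Event, FilterStep, IntervalSpec, Recording,
                       apply_condition, apply_filters, detect_binary,
                       detect_binned, detect_peaks, detect_timestamps,
                       resolve_intervals)
from fiberphot.events import PredicateError
from oracles import as_pairs, brute_binary, brute_binned, brute_peaks


def rec(rate=1.0, **channels):
    n = len(next(iter(channels.values())))
    return Recording("r", np.arange(n) / rate,
                     {k: np.asarray(v, dtype=float) for k, v in channels.items()}, rate)


def ev(pairs):
    return [Event(float(s), float(e), i) for i, (s, e) in enumerate(pairs)]


class TestDetectBinary:
    def test_manual_edge_enumeration(self):
        r = rec(ttl=[0, 0, 1, 1, 0, 1, 0])
        assert as_pairs(detect_binary(r, "ttl")) == [(2.0, 4.0), (5.0, 6.0)]

    def test_all_zeros_empty_and_inverted_full_span(self):
        r = rec(ttl=[0, 0, 0, 0])
        assert detect_binary(r, "ttl") == []
        assert as_pairs(detect_binary(r, "ttl", inverted=True)) == [(0.0, 3.0)]

    def test_leading_run_opens_at_first_sample(self):
        r = rec(ttl=[1, 1, 0])
        assert as_pairs(detect_binary(r, "ttl")) == [(0.0, 2.0)]

    def test_run_active_at_end_closes_at_last_timestamp(self):
        r = rec(ttl=[0, 1, 1])
        assert as_pairs(detect_binary(r, "ttl")) == [(1.0, 2.0)]

    def test_non_binary_values_rejected(self):
        r = rec(ttl=[0, 1, 2, 1])
        with pytest.raises(ValueError, match="2"):
            detect_binary(r, "ttl")

    def test_complement_tiles_span(self, rng):
        """binary(x) union binary(x, inverted) tile [t0, t_last) exactly."""
        for _ in range(50):
            n = int(rng.integers(3, 60))
            x = rng.integers(0, 2, n).astype(float)
            r = rec(ttl=x)
            both = sorted(as_pairs(detect_binary(r, "ttl"))
                          + as_pairs(detect_binary(r, "ttl", inverted=True)))
            cursor = r.time[0]
            for start, end in both:
                assert start == cursor  # no gap, no overlap
                cursor = end
            assert cursor == r.time[-1]


class TestDetectBinned:
    def test_even_division(self):
        r = rec(x=np.zeros(11))  # span 0..10 s
        assert len(detect_binned(r, 0.0, 2.0)) == 5

    def test_offset_start_hand_enumeration(self):
        r = rec(x=np.zeros(11))
        assert as_pairs(detect_binned(r, 1.0, 3.0)) == [(1.0, 4.0), (4.0, 7.0), (7.0, 10.0)]

    def test_bin_longer_than_span_empty(self):
        r = rec(x=np.zeros(11))
        assert detect_binned(r, 0.0, 99.0) == []

    def test_partial_trailing_bin_dropped(self):
        r = rec(x=np.zeros(11))
        assert as_pairs(detect_binned(r, 0.0, 4.0)) == [(0.0, 4.0), (4.0, 8.0)]


class TestDetectPeaks:
    def test_constant_signal_no_events(self):
        r = rec(rate=10.0, x=np.full(100, 5.0))
        assert detect_peaks(r, "x", L=1.0, k=1.0) == []

    def test_single_impulse_on_bounded_noise_floor(self, rng):
        # uniform noise is bounded: nothing but the impulse can cross 3 local SDs
        x = rng.uniform(-1.0, 1.0, 150)
        x[75] += 10.0 * x.std()
        r = rec(rate=10.0, x=x)
        events = detect_peaks(r, "x", L=5.0, k=3.0)
        assert len(events) == 1
        assert events[0].start_s <= r.time[75] < events[0].end_s

    def test_k_zero_flags_above_local_mean_on_sine(self):
        t = np.arange(400) / 10.0
        x = np.sin(2 * np.pi * 0.5 * t)
        r = rec(rate=10.0, x=x)
        events = detect_peaks(r, "x", L=2.0, k=0.0)
        flagged = sum(int(round((e.end_s - e.start_s) * 10)) for e in events)
        assert flagged == pytest.approx(200, abs=30)  # about half the samples

    def test_window_under_three_samples_rejected(self):
        r = rec(rate=1.0, x=np.zeros(50))
        with pytest.raises(ValueError, match="3 samples"):
            detect_peaks(r, "x", L=2.0, k=1.0)


class TestDetectTimestamps:
    def test_empty(self):
        assert detect_timestamps([]) == []

    def test_unsorted_input_sorted(self):
        out = detect_timestamps([(5.0, 6.0), (1.0, 2.0)])
        assert as_pairs(out) == [(1.0, 2.0), (5.0, 6.0)]
        assert [e.index for e in out] == [0, 1]

    def test_start_after_end_rejected(self):
        with pytest.raises(ValueError, match="row 2"):
            detect_timestamps([(1.0, 2.0), (4.0, 3.0)])


class TestBruteForceOracles:
    """Detectors agree with direct per-sample enumeration on random recordings."""

    def test_binary_and_binned_and_peaks(self, rng):
        for _ in range(60):
            n = int(rng.integers(10, 200))
            rate = float(rng.choice([1.0, 5.0, 10.0]))
            t = np.arange(n) / rate
            ttl = rng.integers(0, 2, n).astype(float)
            sig = rng.normal(size=n)
            r = Recording("r", t, {"ttl": ttl, "sig": sig}, rate)
            inv = bool(rng.integers(0, 2))
            assert as_pairs(detect_binary(r, "ttl", inv)) == brute_binary(t, ttl, inv)
            t0 = float(rng.uniform(0, t[-1] / 2))
            L = float(rng.uniform(0.5, t[-1]))
            assert as_pairs(detect_binned(r, t0, L)) == brute_binned(t, t0, L)
            Lw = float(rng.uniform(3.5, 20.0)) / rate
            k = float(rng.uniform(0.0, 3.0))
            got = as_pairs(detect_peaks(r, "sig", Lw, k))
            expected = brute_peaks(t, sig, Lw, k)
            assert got == pytest.approx(expected)


class TestConditions:
    def test_all_vs_any_on_time_predicate(self):
        n = 500
        r = Recording("r", np.arange(n, dtype=float), {"x": np.zeros(n)}, 1.0)
        events = ev([(350.0, 370.0)])
        assert apply_condition(events, r, "time < 360", mode="any") != []
        assert apply_condition(events, r, "time < 360", mode="all") == []

    def test_tautology_is_identity(self):
        r = rec(x=np.arange(10.0))
        events = ev([(1.0, 3.0), (5.0, 8.0)])
        out = apply_condition(events, r, "time >= 0", mode="all")
        assert as_pairs(out) == as_pairs(events)

    def test_missing_values_count_as_failing(self):
        x = np.array([1.0, np.nan, 1.0, 1.0])
        r = rec(x=x)
        events = ev([(0.0, 3.0)])
        assert apply_condition(events, r, "x > 0", mode="all") == []
        assert apply_condition(events, r, "x > 0", mode="any") != []

    def test_unknown_identifier_named(self):
        r = rec(x=np.zeros(5))
        with pytest.raises(PredicateError, match="bogus"):
            apply_condition(ev([(0.0, 2.0)]), r, "bogus > 1")

    def test_function_calls_rejected(self):
        r = rec(x=np.zeros(5))
        with pytest.raises(PredicateError):
            apply_condition(ev([(0.0, 2.0)]), r, "abs(x) > 1")

    def test_boolean_combinations(self):
        r = rec(x=np.array([0.0, 1.0, 2.0, 3.0, 4.0]))
        events = ev([(0.0, 4.0)])
        kept = apply_condition(events, r, "(x > 0 and x < 5) or time == 0", mode="all")
        assert as_pairs(kept) == [(0.0, 4.0)]


SPAN = (0.0, 100.0)


class TestFilterCatalogue:
    def test_empty_chain_is_identity(self):
        events = ev([(1.0, 2.0), (5.0, 7.0)])
        assert as_pairs(apply_filters(events, [], SPAN)) == as_pairs(events)

    @pytest.mark.parametrize("kind,params,expected", [
        ("keep_first", {}, [(1.0, 2.0)]),
        ("drop_first", {}, [(3.0, 4.0), (6.0, 9.0)]),
        ("keep_last", {}, [(6.0, 9.0)]),
        ("drop_last", {}, [(1.0, 2.0), (3.0, 4.0)]),
        ("shift", {"dt_s": 0.5}, [(1.5, 2.5), (3.5, 4.5), (6.5, 9.5)]),
        ("pad_min_length", {"min_s": 2.0}, [(1.0, 3.0), (3.0, 5.0), (6.0, 9.0)]),
        ("truncate_max", {"max_s": 1.5}, [(1.0, 2.0), (3.0, 4.0), (6.0, 7.5)]),
        ("drop_shorter", {"min_s": 1.0}, [(1.0, 2.0), (3.0, 4.0), (6.0, 9.0)]),
        ("drop_shorter", {"min_s": 2.0}, [(6.0, 9.0)]),
        ("drop_longer", {"max_s": 1.0}, [(1.0, 2.0), (3.0, 4.0)]),
        ("before", {"t_s": 5.0}, [(1.0, 2.0), (3.0, 4.0)]),
        ("before", {"t_s": 5.0, "action": "exclude"}, [(6.0, 9.0)]),
        ("after", {"t_s": 5.0}, [(6.0, 9.0)]),
        ("after", {"t_s": 5.0, "action": "exclude"}, [(1.0, 2.0), (3.0, 4.0)]),
    ])
    def test_single_step_fixtures(self, kind, params, expected):
        events = ev([(1.0, 2.0), (3.0, 4.0), (6.0, 9.0)])
        out = apply_filters(events, [FilterStep(kind, params)], SPAN)
        assert as_pairs(out) == expected

    def test_aggregate_within_hand_merge(self):
        events = ev([(1.0, 2.0), (2.5, 3.0), (10.0, 11.0)])
        out = apply_filters(events, [FilterStep("aggregate_within", {"gap_s": 1.0})], SPAN)
        assert as_pairs(out) == [(1.0, 3.0), (10.0, 11.0)]

    def test_pad_extends_end_only(self):
        out = apply_filters(ev([(5.0, 6.0)]),
                            [FilterStep("pad_min_length", {"min_s": 3.0})], SPAN)
        assert as_pairs(out) == [(5.0, 8.0)]

    def test_drop_shorter_inclusive_boundary(self):
        events = ev([(0.0, 1.0), (2.0, 4.0), (5.0, 8.0)])  # lengths 1, 2, 3
        out = apply_filters(events, [FilterStep("drop_shorter", {"min_s": 2.0})], SPAN)
        assert [e.length_s for e in out] == [2.0, 3.0]

    def test_shift_then_truncate_composition(self):
        out = apply_filters(
            ev([(1.0, 3.0)]),
            [FilterStep("shift", {"dt_s": 0.5}), FilterStep("truncate_max", {"max_s": 1.0})],
            SPAN,
        )
        assert as_pairs(out) == [(1.5, 2.5)]

    def test_coalesce_merges_overlaps_and_is_idempotent(self):
        events = ev([(1.0, 4.0), (3.0, 5.0), (7.0, 8.0)])
        once = apply_filters(events, [FilterStep("coalesce")], SPAN)
        assert as_pairs(once) == [(1.0, 5.0), (7.0, 8.0)]
        twice = apply_filters(once, [FilterStep("coalesce")], SPAN)
        assert as_pairs(twice) == as_pairs(once)

    def test_min_rate_all_or_nothing(self):
        events = ev([(1.0, 2.0), (3.0, 4.0)])  # 2 events over 100 s span
        keep = apply_filters(events, [FilterStep("min_rate", {"rate_per_s": 0.02})], SPAN)
        drop = apply_filters(events, [FilterStep("min_rate", {"rate_per_s": 0.021})], SPAN)
        assert as_pairs(keep) == as_pairs(events)
        assert drop == []

    def test_drop_successive_within_gap(self):
        events = ev([(1.0, 2.0), (2.5, 3.0), (10.0, 11.0), (11.5, 12.0)])
        out = apply_filters(events, [FilterStep("drop_successive_within", {"gap_s": 1.0})], SPAN)
        assert as_pairs(out) == [(1.0, 2.0), (10.0, 11.0)]

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown filter"):
            FilterStep("explode", {})

    def test_output_reindexed_chronologically(self):
        events = ev([(1.0, 2.0), (3.0, 4.0), (6.0, 9.0)])
        out = apply_filters(events, [FilterStep("drop_first", {})], SPAN)
        assert [e.index for e in out] == [0, 1]


class TestBuildEventSeries:
    def test_declarative_definition_runs_full_chain(self):
        from fiberphot import EventSeriesDef, build_event_series
        r = rec(ttl=[0, 1, 1, 0, 1, 0, 1, 1, 1, 0],
                x=[0, 5, 5, 0, 5, 0, 1, 1, 1, 0])
        definition = EventSeriesDef(
            name="bouts",
            source={"kind": "binary", "channel": "ttl"},
            condition="x > 2", condition_mode="all",
            filters=[FilterStep("drop_shorter", {"min_s": 2.0})],
        )
        out = build_event_series(r, definition)
        # three raw runs; the [6,9) run fails x > 2; of the rest only [1,3) is >= 2 s
        assert as_pairs(out) == [(1.0, 3.0)]

    def test_unknown_source_kind_rejected(self):
        from fiberphot import EventSeriesDef, build_event_series
        r = rec(ttl=[0, 1, 0])
        with pytest.raises(ValueError, match="source kind"):
            build_event_series(r, EventSeriesDef("s", {"kind": "telepathy"}))


class TestResolveIntervals:
    def test_baseline_and_post_windows(self):
        # a 3 s pre-event baseline and 5 s after the end of the event signal
        event = Event(10.0, 15.0, 0)
        specs = [IntervalSpec("baseline", "event_start", -3.0, 0.0),
                 IntervalSpec("event", "event_signal"),
                 IntervalSpec("post", "event_end", 0.0, 5.0)]
        windows = resolve_intervals(event, specs)
        assert windows["baseline"] == (7.0, 10.0)
        assert windows["event"] == (10.0, 15.0)
        assert windows["post"] == (15.0, 20.0)

    def test_nonoverlap_clips_to_previous_event_end(self):
        event = Event(10.0, 15.0, 1)
        spec = [IntervalSpec("baseline", "event_start_nonoverlap", -3.0, 0.0)]
        windows = resolve_intervals(event, spec, prev_event_end=8.0)
        assert windows["baseline"] == (8.0, 10.0)

    def test_nonoverlap_without_previous_event_unclipped(self):
        event = Event(10.0, 15.0, 0)
        spec = [IntervalSpec("baseline", "event_start_nonoverlap", -3.0, 0.0)]
        assert resolve_intervals(event, spec, prev_event_end=None)["baseline"] == (7.0, 10.0)

    def test_collapsed_window_dropped_with_warning(self, caplog):
        event = Event(10.0, 15.0, 1)
        spec = [IntervalSpec("baseline", "event_start_nonoverlap", -3.0, 0.0)]
        with caplog.at_level("WARNING", logger="fiberphot.events"):
            windows = resolve_intervals(event, spec, prev_event_end=12.0)
        assert windows == {}
        assert "collapsed" in caplog.text

    def test_duplicate_names_rejected(self):
        event = Event(0.0, 1.0, 0)
        specs = [IntervalSpec("a", "event_start", -1, 0), IntervalSpec("a", "event_end", 0, 1)]
        with pytest.raises(ValueError, match="unique"):
            resolve_intervals(event, specs)

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            IntervalSpec("a", "event_middle", 0, 1)
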