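"""Windowed rates, circular shifting, the shuffle null, and cell calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ofcalc as oc
from ofcalc import SpikeTrain
from ofcalc.synthetic import default_truth


def brute_force_null_rates(event_times, shifts, windows, session_length):
    """Independent oracle: shift and recount every event with plain loops."""
    total = sum(e - s for s, e in windows)
    rates = []
    for delta in shifts:
        shifted = [(t + delta) % session_length for t in event_times]
        n = sum(1 for t in shifted for (s, e) in windows if s <= t < e)
        rates.append(n / total)
    return rates


def percentile_oracle(values, q):
    """Sort-and-index linear interpolation between order statistics."""
    s = sorted(values)
    pos = (len(s) - 1) * q / 100.0
    lo = math.floor(pos)
    frac = pos - lo
    if frac == 0:
        return s[lo]
    return s[lo] * (1 - frac) + s[lo + 1] * frac


class TestWindowSpikeRate:
    def test_no_events_zero_rate(self):
        windows = [(10.0, 12.0), (20.0, 22.0)]
        assert oc.window_spike_rate(SpikeTrain("c", np.empty(0)), windows) == 0.0

    def test_manual_count(self):
        windows = [(10.0 * k, 10.0 * k + 2.0) for k in range(1, 11)]
        events = np.array([10.5, 11.9, 30.0, 50.5, 90.1])  # 5 inside 10 x 2 s
        rate = oc.window_spike_rate(SpikeTrain("c", events), windows)
        assert rate == pytest.approx(5 / 20.0)

    def test_half_open_boundaries(self):
        windows = [(10.0, 12.0)]
        at_start = oc.window_spike_rate(SpikeTrain("c", np.array([10.0])), windows)
        at_end = oc.window_spike_rate(SpikeTrain("c", np.array([12.0])), windows)
        assert at_start == pytest.approx(0.5)  # start inclusive
        assert at_end == 0.0                   # end exclusive

    def test_zero_duration_errors(self):
        with pytest.raises(oc.AnalysisError):
            oc.window_spike_rate(SpikeTrain("c", np.empty(0)), [])


class TestCircularShift:
    def test_full_period_is_identity(self):
        events = np.array([3.0, 100.0, 900.0])
        out = oc.circular_shift(SpikeTrain("c", events), 1200.0, 1200.0)
        np.testing.assert_allclose(out.event_times, events)

    def test_wrap_example(self):
        out = oc.circular_shift(SpikeTrain("c", np.array([100.0, 1190.0])), 20.0, 1200.0)
        np.testing.assert_allclose(out.event_times, [10.0, 120.0])

    @settings(deadline=None)
    @given(
        events=st.lists(st.floats(0.0, 999.9), min_size=1, max_size=8),
        delta=st.floats(0.0, 5000.0),
    )
    def test_count_conserved_and_intervals_preserved(self, events, delta):
        train = SpikeTrain("c", np.sort(events))
        out = oc.circular_shift(train, delta, 1000.0)
        assert out.n_events == train.n_events
        # circular inter-event gaps (including the wrap-around gap) are a
        # multiset invariant of rotation
        def circular_gaps(t):
            t = np.sort(t)
            if t.size < 2:
                return np.empty(0)
            return np.sort(np.diff(np.concatenate((t, [t[0] + 1000.0]))))
        np.testing.assert_allclose(
            circular_gaps(out.event_times),
            circular_gaps(train.event_times % 1000.0),
            atol=1e-9,
        )


class TestShuffleNull:
    def test_empty_train_null_is_zero(self, schedule):
        res = oc.shuffle_null(
            SpikeTrain("c", np.empty(0)),
            schedule.condition_windows("OFF"),
            schedule.session_length,
            n_shuffles=100,
            seed=1,
        )
        assert res.observed_rate == 0.0
        assert np.all(res.null_rates == 0.0)
        assert res.p95 == 0.0 and res.p5 == 0.0

    def test_single_event_geometric_probability(self):
        # one event, window [0, 2) of a 10 s session, shifts uniform(0, 10):
        # the shifted event lands in the window with probability 2/10
        res = oc.shuffle_null(
            SpikeTrain("c", np.array([5.0])),
            [(0.0, 2.0)],
            10.0,
            n_shuffles=4000,
            shift_range=(0.0, 10.0),
            seed=11,
        )
        frac_hit = float(np.mean(res.null_rates > 0))
        assert frac_hit == pytest.approx(0.2, abs=3 * math.sqrt(0.2 * 0.8 / 4000))

    def test_same_seed_identical(self, schedule):
        train = SpikeTrain("c", np.linspace(5.0, 1200.0, 40))
        kwargs = dict(n_shuffles=50, seed=99)
        a = oc.shuffle_null(train, schedule.condition_windows("OFF"),
                            schedule.session_length, **kwargs)
        b = oc.shuffle_null(train, schedule.condition_windows("OFF"),
                            schedule.session_length, **kwargs)
        np.testing.assert_array_equal(a.null_rates, b.null_rates)

    def test_matches_brute_force_on_grid_shifts(self, schedule):
        rng = np.random.default_rng(3)
        train = SpikeTrain("c", np.sort(rng.uniform(0, schedule.session_length, 30)))
        windows = schedule.condition_windows("OFF")
        shifts = np.arange(20.0, 1200.0, 24.0)  # 50 grid shifts
        res = oc.shuffle_null(
            train, windows, schedule.session_length, shifts=shifts
        )
        oracle = brute_force_null_rates(
            list(train.event_times), list(shifts), windows, schedule.session_length
        )
        np.testing.assert_allclose(res.null_rates, oracle, atol=1e-12)
        assert res.p95 == pytest.approx(percentile_oracle(oracle, 95))
        assert res.p5 == pytest.approx(percentile_oracle(oracle, 5))

    def test_negative_shift_range_rejected(self, schedule):
        with pytest.raises(oc.AnalysisError):
            oc.shuffle_null(
                SpikeTrain("c", np.array([1.0])),
                schedule.condition_windows("OFF"),
                schedule.session_length,
                shift_range=(-5.0, 100.0),
            )


class TestPercentileConvention:
    def test_linear_interpolation_matches_oracle(self):
        values = np.arange(1, 1001) / 1000.0
        assert float(np.percentile(values, 95)) == pytest.approx(
            percentile_oracle(values, 95)
        )
        # the oracle value itself: position 0.95*(1000-1) = 949.05 between
        # order statistics 0.950 and 0.951
        assert percentile_oracle(values, 95) == pytest.approx(0.95005)

    @settings(deadline=None)
    @given(st.lists(st.floats(0.0, 10.0), min_size=2, max_size=40))
    def test_oracle_agreement_random_vectors(self, values):
        for q in (5, 95):
            assert float(np.percentile(values, q)) == pytest.approx(
                percentile_oracle(values, q), abs=1e-9
            )


class TestClassifyCell:
    def test_planted_suppressed_src(self, schedule):
        truth = default_truth("SRC_SUPPRESSED", "c", baseline_rate=0.05, shock_rate=2.0)
        train = oc.generate_spike_train(truth, schedule, seed=5)
        report = oc.classify_cell(train, schedule, seed=6)
        assert report.is_src and report.suppressed is True
        assert not report.is_ssc and not report.on_only_src

    def test_planted_on_only_src(self, schedule):
        truth = default_truth("SRC_ON_ONLY", "c", baseline_rate=0.05, shock_rate=2.0)
        train = oc.generate_spike_train(truth, schedule, seed=7)
        report = oc.classify_cell(train, schedule, seed=8)
        assert report.on_only_src and not report.is_src
        assert report.suppressed is None  # defined only for SRCs

    def test_empty_train_never_significant(self, schedule):
        report = oc.classify_cell(SpikeTrain("c", np.empty(0)), schedule, seed=1)
        assert not report.is_src and not report.is_ssc and not report.on_only_src

    def test_off_only_session(self, schedule):
        train = SpikeTrain("c", np.array([400.0, 500.0]))
        report = oc.classify_cell(train, schedule, conditions=("OFF",), seed=1)
        assert report.on_result is None and report.suppressed is None

    def test_shuffle_conserves_event_count(self, schedule):
        rng = np.random.default_rng(12)
        events = np.sort(rng.uniform(0, schedule.session_length, 25))
        for delta in rng.uniform(20, 1200, 20):
            out = oc.circular_shift(SpikeTrain("c", events), delta,
                                    schedule.session_length)
            assert out.n_events == 25


class TestSessionSummary:
    def test_worked_example_percentages(self):
        reports = [
            oc.CellReport(f"c{i}", is_src=(i < 27), suppressed=(True if i < 26 else False) if i < 27 else None)
            for i in range(391)
        ]
        summary = oc.session_summary(reports)
        assert summary["n_cells"] == 391 and summary["n_src"] == 27
        assert summary["pct_src"] == 6.9
        assert summary["n_suppressed"] == 26
        assert summary["pct_suppressed"] == 96.3  # 26/27 = 96.296...

    def test_no_src(self):
        summary = oc.session_summary([oc.CellReport(f"c{i}") for i in range(10)])
        assert summary["pct_src"] == 0.0 and summary["pct_suppressed"] == 0.0

    def test_empty_errors(self):
        with pytest.raises(oc.AnalysisError):
            oc.session_summary([])

    def test_percentages_recompute_from_counts(self, schedule):
        truths = [default_truth("SRC_SUPPRESSED" if i < 3 else "NULL", f"c{i}")
                  for i in range(10)]
        trains = [oc.generate_spike_train(t, schedule, seed=i) for i, t in enumerate(truths)]
        summary = oc.session_summary(oc.classify_session(trains, schedule, seed=2, n_shuffles=200))
        assert summary["pct_src"] == round(100.0 * summary["n_src"] / summary["n_cells"], 1)
        if summary["n_src"]:
            assert summary["pct_suppressed"] == round(
                100.0 * summary["n_suppressed"] / summary["n_src"], 1
            )
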