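"""Schedule construction, GPIO alignment, and file round trips."""

import numpy as np
import pytest

import ofcalc as oc
from ofcalc.behavior import BehaviorEvent, BehaviorEventLog
from ofcalc.io import (
    find_trigger_time,
    infer_sampling_rate,
    read_behavior_csv,
    write_behavior_csv,
)
from ofcalc.schedule import default_condition_split


class TestScheduleGeneration:
    def test_default_protocol_invariants(self, schedule):
        assert schedule.n_shocks == 20
        onsets = np.array(schedule.shock_onsets)
        assert np.all(np.diff(onsets) > 0)
        # ITI = shock offset to next onset, uniform in [30, 60]
        itis = np.diff(onsets) - schedule.shock_duration
        assert np.all((itis >= 30.0) & (itis <= 60.0))
        assert onsets[0] >= 330.0
        assert schedule.off_trial_indices == frozenset(range(1, 11))
        assert schedule.on_trial_indices == frozenset(range(11, 21))
        # LED spans onset-1 .. onset+shock_duration+1 for exactly the ON trials
        expected_led = {
            (schedule.shock_onsets[i - 1] - 1.0, schedule.shock_onsets[i - 1] + 3.0)
            for i in schedule.on_trial_indices
        }
        assert set(schedule.led_windows) == expected_led
        assert all(b - a == pytest.approx(4.0) for a, b in schedule.led_windows)
        for start, end in schedule.all_windows():
            assert 0.0 <= start < end <= schedule.session_length

    def test_shock_phase_duration_matches_protocol(self):
        # sum(ITI) + 20 * 2 s; ~940 s at the mean ITI of 45 s
        for seed in range(5):
            s = oc.generate_schedule(seed=seed)
            phase = s.shock_onsets[-1] + s.shock_duration - 300.0
            assert 640.0 <= phase <= 1240.0

    def test_degenerate_iti_closed_form(self):
        s = oc.generate_schedule(iti_range=(45.0, 45.0), seed=0)
        for k, onset in enumerate(s.shock_onsets, start=1):
            assert onset == pytest.approx(300.0 + 45.0 * k + 2.0 * (k - 1))

    def test_single_shock_split_is_off_only(self):
        off, on = default_condition_split(1)
        assert off == frozenset({1}) and on == frozenset()
        s = oc.generate_schedule(n_shocks=1, seed=3)
        assert s.led_windows == ()
        with pytest.raises(oc.ScheduleError):
            s.condition_windows("ON")

    def test_inverted_iti_range_rejected(self):
        with pytest.raises(oc.ConfigError):
            oc.generate_schedule(iti_range=(60.0, 30.0), seed=0)

    def test_yaml_round_trip(self, schedule, tmp_path):
        path = tmp_path / "schedule.yaml"
        schedule.to_yaml(path)
        back = oc.ExperimentSchedule.from_yaml(path)
        assert back == schedule


class TestAlignment:
    def _traces(self, t_end=1212.0, fs=20.0):
        times = np.arange(int(t_end * fs)) / fs
        values = np.outer(times, [1.0, 2.0])
        return oc.TraceMatrix(times, values, ["a", "b"], fs)

    def _gpio(self, trigger):
        return oc.GpioRecord(
            channel=np.array(["trigger"] * 3),
            timestamps=np.array([0.0, trigger, trigger + 100.0]),
            values=np.array([0.0, 1.0, 1.0]),
        )

    def test_offset_subtraction(self):
        aligned = oc.align_to_experiment_start(
            self._traces(), self._gpio(12.0), session_length=1200.0
        )
        assert aligned.aligned
        assert aligned.times[0] == pytest.approx(0.0)
        assert aligned.times[-1] < 1200.0
        # the first retained sample carried original time 12.0 s
        assert aligned.values[0, 0] == pytest.approx(12.0)

    def test_zero_trigger_is_identity(self):
        traces = self._traces(t_end=10.0)
        gpio = oc.GpioRecord(
            channel=np.array(["trigger"] * 2),
            timestamps=np.array([0.0, 5.0]),
            values=np.array([1.0, 1.0]),
        )
        aligned = oc.align_to_experiment_start(traces, gpio)
        np.testing.assert_allclose(aligned.times, traces.times)
        np.testing.assert_allclose(aligned.values, traces.values)

    def test_first_retained_index_brute_force(self):
        # oracle: scan for the first sample time >= the trigger time
        traces = self._traces()
        trigger = 3.35
        first = next(i for i, t in enumerate(traces.times) if t >= trigger)
        assert first == 67
        aligned = oc.align_to_experiment_start(traces, self._gpio(trigger))
        assert aligned.times.size == traces.times.size - first
        assert aligned.values[0, 0] == pytest.approx(traces.values[first, 0])

    def test_alignment_is_rigid_shift(self):
        traces = self._traces()
        aligned = oc.align_to_experiment_start(traces, self._gpio(12.0))
        kept = traces.times >= 12.0
        np.testing.assert_allclose(
            np.diff(aligned.times), np.diff(traces.times[kept]), atol=1e-12
        )

    def test_missing_channel_errors(self):
        gpio = self._gpio(1.0)
        with pytest.raises(oc.AlignmentError):
            oc.align_to_experiment_start(self._traces(), gpio, trigger_channel="sync")

    def test_trigger_after_last_sample_errors(self):
        with pytest.raises(oc.AlignmentError):
            oc.align_to_experiment_start(self._traces(t_end=10.0), self._gpio(50.0))

    def test_flat_gpio_has_no_trigger(self):
        gpio = oc.GpioRecord(
            channel=np.array(["trigger"] * 3),
            timestamps=np.array([0.0, 1.0, 2.0]),
            values=np.array([0.0, 0.0, 0.0]),
        )
        with pytest.raises(oc.AlignmentError):
            find_trigger_time(gpio, "trigger")


class TestTraceCsv:
    def test_round_trip_lossless(self, tmp_path):
        rng = np.random.default_rng(5)
        traces = oc.TraceMatrix(
            times=np.arange(200) / 20.0,
            values=rng.normal(size=(200, 3)),
            cell_ids=["c0", "c1", "c2"],
            sampling_rate=20.0,
        )
        path = tmp_path / "traces.csv"
        oc.write_trace_csv(traces, path)
        back = oc.read_trace_csv(path)
        assert back.cell_ids == traces.cell_ids
        assert back.sampling_rate == pytest.approx(20.0)
        np.testing.assert_allclose(back.values, traces.values, atol=1e-9)
        np.testing.assert_allclose(back.times, traces.times, atol=1e-9)

    def test_rejected_cells_dropped(self, tmp_path):
        path = tmp_path / "traces.csv"
        path.write_text(
            "time_s,c0,c1,c2\n"
            ",accepted,rejected,accepted\n"
            "0.0,1.0,9.0,3.0\n"
            "0.05,1.5,9.0,3.5\n"
        )
        traces = oc.read_trace_csv(path)
        assert traces.cell_ids == ["c0", "c2"]
        assert traces.sampling_rate == pytest.approx(20.0)
        np.testing.assert_allclose(traces.values[:, 0], [1.0, 1.5])

    def test_non_monotonic_time_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,c0\n0.0,1.0\n0.10,1.0\n0.05,1.0\n")
        with pytest.raises(oc.FormatError):
            oc.read_trace_csv(path)

    def test_excess_jitter_rejected(self):
        with pytest.raises(oc.FormatError):
            infer_sampling_rate(np.array([0.0, 0.05, 0.10, 0.20]))


class TestBehaviorCsv:
    def test_start_stop_pairing(self, tmp_path):
        path = tmp_path / "behavior.csv"
        path.write_text(
            "time,subject,behavior,status\n"
            "10.0,observer,freezing,START\n"
            "14.5,observer,freezing,STOP\n"
        )
        log = read_behavior_csv(path)
        assert log.epochs() == [(10.0, 14.5)]

    def test_empty_log(self):
        assert BehaviorEventLog([]).epochs() == []

    def test_unmatched_start_names_row(self, tmp_path):
        path = tmp_path / "behavior.csv"
        path.write_text("time,subject,behavior,status\n10.0,observer,freezing,START\n")
        with pytest.raises(oc.FormatError, match="10.0"):
            read_behavior_csv(path)

    def test_round_trip(self, tmp_path):
        log = BehaviorEventLog([
            BehaviorEvent(3.0, "freezing", "START"),
            BehaviorEvent(8.5, "freezing", "STOP"),
            BehaviorEvent(20.0, "freezing", "START"),
            BehaviorEvent(21.25, "freezing", "STOP"),
        ])
        path = tmp_path / "behavior.csv"
        write_behavior_csv(log, path)
        assert read_behavior_csv(path).epochs() == [(3.0, 8.5), (20.0, 21.25)]


class TestReportOutput:
    def test_report_tsv_and_summary(self, tmp_path):
        reports = [
            oc.CellReport("c0", n_spikes=12, is_src=True, suppressed=True),
            oc.CellReport("c1", n_spikes=3),
        ]
        summary = oc.session_summary(reports)
        tsv, js = tmp_path / "report.tsv", tmp_path / "summary.json"
        oc.write_report(reports, summary, tsv, js)
        lines = tsv.read_text().strip().split("\n")
        assert len(lines) == 3  # header + one row per cell
        assert lines[0].split("\t")[0] == "cell_id"
        import json
        loaded = json.loads(js.read_text())
        assert loaded["n_cells"] == 2 and loaded["n_src"] == 1
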