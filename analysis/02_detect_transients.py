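#!/usr/bin/env python
"""Align traces to the GPIO trigger and detect calcium transients.

Reads the session written by 01_simulate_session.py, shifts trace times so
the experiment starts at 0, drops pre-trigger samples, and applies the
2-SD-above-baseline peak rule per cell.  Writes one row per detected event
(cell_id, event_time_s, peak_value) to results/spikes.csv.
"""

import argparse
from pathlib import Path

import ofcalc as oc


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--session", type=Path, default=Path("results/session"))
    parser.add_argument("--out", type=Path, default=Path("results/spikes.csv"))
    parser.add_argument("--baseline-method", choices=("full", "habituation"),
                        default="full")
    args = parser.parse_args()

    traces = oc.read_trace_csv(args.session / "traces.csv")
    gpio = oc.read_gpio_csv(args.session / "gpio.csv")
    schedule = oc.ExperimentSchedule.from_yaml(args.session / "schedule.yaml")

    aligned = oc.align_to_experiment_start(
        traces, gpio, session_length=schedule.session_length
    )
    dropped = traces.times.size - aligned.times.size
    print(f"aligned {aligned.times.size} samples "
          f"(dropped {dropped} pre-trigger/post-session samples)")

    trains = oc.detect_session(aligned, baseline_method=args.baseline_method)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    with open(args.out, "w") as fh:
        fh.write("cell_id,event_time_s,peak_value\n")
        for train in trains:
            for t, v in zip(train.event_times, train.peak_values):
                fh.write(f"{train.cell_id},{t:.6g},{v:.6g}\n")

    counts = [t.n_events for t in trains]
    print(f"detected {sum(counts)} events over {len(trains)} cells "
          f"(median {sorted(counts)[len(counts) // 2]} events/cell)")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
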