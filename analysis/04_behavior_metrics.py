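#!/usr/bin/env python
"""Freezing-bout metrics of the observer, split by light-OFF/ON condition.

Reads the scored freezing log and the schedule, keeps bouts strictly
longer than 2 s, and reports — per condition period — total freezing time,
percent freezing, bout count, mean bout duration, and the mean duration of
bouts beginning inside a 2-s shock window.  Writes results/behavior.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

import ofcalc as oc


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--session", type=Path, default=Path("results/session"))
    parser.add_argument("--out", type=Path, default=Path("results/behavior.tsv"))
    args = parser.parse_args()

    schedule = oc.ExperimentSchedule.from_yaml(args.session / "schedule.yaml")
    log = oc.read_behavior_csv(args.session / "behavior.csv")
    bouts = oc.extract_bouts(log)
    print(f"{len(log.epochs())} scored freezing epochs, "
          f"{len(bouts)} accepted bouts (> 2 s)")

    rows = []
    for cond in ("OFF", "ON"):
        m = oc.condition_metrics(
            bouts, schedule.condition_period(cond), schedule.shock_windows(),
            condition=cond,
        )
        rows.append(vars(m))
        print(f"{cond}: {m.pct_freeze:.1f}% freezing over "
              f"[{m.period[0]:.1f}, {m.period[1]:.1f}) s, "
              f"{m.n_bouts} bouts, mean {m.mean_bout_s:.2f} s, "
              f"shock-onset bout mean {m.shock_onset_bout_mean_s:.2f} s "
              f"({m.n_shock_onset_bouts} bouts)")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, sep="\t", index=False, float_format="%.6g")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
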