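#!/usr/bin/env python
"""Classify cells as shock-responding / shock-suppressed via the shuffle null.

For every cell, the mean event rate over the light-OFF shock windows is
compared with the 95th/5th percentile of 1000 circularly shifted rates
(shifts uniform on 20-1200 s); SRCs are then re-tested on the light-ON
trials to assess optogenetic suppression.  Writes the per-cell report, the
session summary, and a peri-shock raster table for the identified SRCs,
and compares the calls against the planted ground truth.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import ofcalc as oc


def read_spike_trains(path) -> list[oc.SpikeTrain]:
    df = pd.read_csv(path)
    trains = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        trains.append(oc.SpikeTrain(
            cell_id=str(cell_id),
            event_times=np.sort(grp["event_time_s"].to_numpy(dtype=float)),
        ))
    return trains


def raster_rows(trains, schedule, reports, half_width=5.0):
    """Peri-shock event times (s, relative to onset) for SRCs, per OFF trial."""
    src_ids = {r.cell_id for r in reports if r.is_src}
    for train in trains:
        if train.cell_id not in src_ids:
            continue
        for trial in sorted(schedule.off_trial_indices):
            onset = schedule.shock_onsets[trial - 1]
            rel = train.event_times - onset
            for t in rel[(rel >= -half_width) & (rel < half_width)]:
                yield train.cell_id, trial, float(t)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--spikes", type=Path, default=Path("results/spikes.csv"))
    parser.add_argument("--session", type=Path, default=Path("results/session"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--n-shuffles", type=int, default=1000)
    args = parser.parse_args()

    schedule = oc.ExperimentSchedule.from_yaml(args.session / "schedule.yaml")
    trains = read_spike_trains(args.spikes)
    reports = oc.classify_session(
        trains, schedule, n_shuffles=args.n_shuffles, seed=args.seed
    )
    summary = oc.session_summary(reports)
    oc.write_report(reports, summary,
                    args.out / "report.tsv", args.out / "summary.json")

    print(f"{summary['n_src']} cells ({summary['pct_src']}%) of the total "
          f"{summary['n_cells']} cells were identified as SRCs")
    if summary["n_src"]:
        print(f"{summary['n_suppressed']} of {summary['n_src']} SRCs "
              f"({summary['pct_suppressed']}%) were suppressed during light-ON")
    print(f"{summary['n_ssc']} SSCs, {summary['n_on_only']} ON-only SRCs")

    with open(args.out / "src_raster.tsv", "w") as fh:
        fh.write("cell_id\ttrial\tt_rel_s\n")
        for cell_id, trial, t in raster_rows(trains, schedule, reports):
            fh.write(f"{cell_id}\t{trial}\t{t:.4f}\n")

    truth_path = args.session / "ground_truth.tsv"
    if truth_path.exists():
        # keep_default_na: the planted class "NULL" is a label, not missing data
        truth = pd.read_csv(truth_path, sep="\t", keep_default_na=False) \
            .set_index("cell_id")["klass"]
        confusion = {}
        for r in reports:
            called = ("SRC_SUPPRESSED" if r.is_src and r.suppressed
                      else "SRC_NOT_SUPPRESSED" if r.is_src
                      else "SSC" if r.is_ssc
                      else "SRC_ON_ONLY" if r.on_only_src
                      else "NULL")
            confusion[(truth[r.cell_id], called)] = \
                confusion.get((truth[r.cell_id], called), 0) + 1
        rows = [{"planted": p, "called": c, "n": n}
                for (p, c), n in sorted(confusion.items())]
        pd.DataFrame(rows).to_csv(args.out / "confusion.tsv", sep="\t", index=False)
        agree = sum(n for (p, c), n in confusion.items() if p == c)
        print(f"ground truth: {agree}/{summary['n_cells']} cells "
              f"called exactly as planted (results/confusion.tsv)")

    with open(args.out / "summary.json") as fh:
        print("summary:", json.dumps(json.load(fh), indent=2))


if __name__ == "__main__":
    main()
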