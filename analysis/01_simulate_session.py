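#!/usr/bin/env python
"""Generate one study-shaped observational-fear session with known truth.

65 cells — 10 SRC_SUPPRESSED, 5 SRC_NOT_SUPPRESSED, 5 SRC_ON_ONLY, 5 SSC
and 40 NULL (a minority of responders, as in the recorded data) — on the
standard protocol: 5 min habituation, 20 foot shocks of 2 s with 30-60 s
random intervals, LED on for shocks 11-20.  Writes raw traces (20 Hz,
starting 5 s before the GPIO trigger), the GPIO table, the freezing log,
the schedule and the ground-truth table under results/session/.
"""

import argparse
from pathlib import Path

import ofcalc as oc

CLASSES = {
    "SRC_SUPPRESSED": 10,
    "SRC_NOT_SUPPRESSED": 5,
    "SRC_ON_ONLY": 5,
    "SSC": 5,
    "NULL": 40,
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--out", type=Path, default=Path("results/session"))
    args = parser.parse_args()

    session = oc.generate_session(CLASSES, seed=args.seed)
    paths = oc.write_session(session, args.out)

    sched = session.schedule
    n_events = sum(t.n_events for t in session.true_trains)
    print(f"session: {session.traces.n_cells} cells, "
          f"{session.traces.times.size} samples at "
          f"{session.traces.sampling_rate:g} Hz, "
          f"session length {sched.session_length:.1f} s")
    print(f"schedule: {sched.n_shocks} shocks, first at {sched.shock_onsets[0]:.1f} s, "
          f"{len(sched.led_windows)} LED windows")
    print(f"planted events: {n_events} across all cells")
    for name, path in paths.items():
        print(f"wrote {name}: {path}")


if __name__ == "__main__":
    main()
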