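#!/usr/bin/env python
"""Session-level statistics: suppression chi-square and paired freezing tests.

Two analyses: (1) a two-sided chi-square goodness-of-fit on the
suppressed/not-suppressed split of the SRCs found by 03_classify_cells.py
(equal expected proportions, no continuity correction); (2) two-tailed
paired t-tests (df = n_sessions - 1) comparing OFF vs ON freezing metrics
across several simulated observer sessions.  Writes results/stats.json.
"""

import argparse
import json
from pathlib import Path

import ofcalc as oc

METRICS = ("pct_freeze", "n_bouts", "mean_bout_s", "shock_onset_bout_mean_s")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--summary", type=Path, default=Path("results/summary.json"))
    parser.add_argument("--out", type=Path, default=Path("results/stats.json"))
    parser.add_argument("--n-sessions", type=int, default=5)
    parser.add_argument("--seed", type=int, default=11)
    args = parser.parse_args()

    out: dict = {}
    with open(args.summary) as fh:
        summary = json.load(fh)
    if summary["n_src"]:
        chi = oc.chisq_goodness_of_fit(
            (summary["n_suppressed"], summary["n_src"] - summary["n_suppressed"])
        )
        out["suppression_chi_square"] = {
            "observed": list(chi.observed),
            "statistic": round(chi.statistic, 3),
            "df": chi.df,
            "p": oc.format_p(chi.p),
        }
        print(f"suppression: {summary['pct_suppressed']}% of SRCs "
              f"(X2 = {chi.statistic:.3f}, df = {chi.df}, p {oc.format_p(chi.p)})")

    import numpy as np
    rng = np.random.default_rng(args.seed)
    pairs = []
    for _ in range(args.n_sessions):
        sched = oc.generate_schedule(seed=np.random.default_rng(rng.integers(2**31)))
        log = oc.generate_behavior_log(
            sched, seed=np.random.default_rng(rng.integers(2**31))
        )
        bouts = oc.extract_bouts(log)
        pairs.append(tuple(
            oc.condition_metrics(bouts, sched.condition_period(c),
                                 sched.shock_windows(), condition=c)
            for c in ("OFF", "ON")
        ))
    out["freezing_paired_tests"] = {}
    for metric in METRICS:
        res = oc.compare_conditions(pairs, metric)
        out["freezing_paired_tests"][metric] = {
            "t": None if res.undefined else round(res.t, 4),
            "df": res.df,
            "p": None if res.undefined else oc.format_p(res.p),
            "undefined": res.undefined,
        }
        shown = "undefined" if res.undefined else \
            f"t = {res.t:.4f}, df = {res.df}, p = {oc.format_p(res.p)}"
        print(f"{metric} OFF vs ON over {args.n_sessions} sessions: {shown}")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    with open(args.out, "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
        fh.write("\n")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
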