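"""On-disk formats and GPIO time alignment.

Formats (all plain text):

* **Trace CSV** — ROI-extraction export: first column time in seconds,
  one column per accepted cell.  An optional second header row carries a
  per-cell ``accepted``/``rejected`` status (cells marked rejected are
  dropped on read); the dialect is a simplified version of the exports
  produced by one-photon processing suites.
* **GPIO CSV** — columns ``channel,time,value``: hardware digital lines
  sampled on the acquisition clock; the experiment-start trigger is a
  rising edge on one channel.
* **Behavior CSV** — BORIS-export-like columns
  ``time,subject,behavior,status`` with status START/STOP.
* **Report TSV/JSON** — one row per classified cell plus a summary of
  session-level counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .behavior import BehaviorEvent, BehaviorEventLog
from .errors import AlignmentError, FormatError


@dataclass
class TraceMatrix:
    """Uniformly sampled fluorescence traces of all accepted cells.

    ``values`` has shape (n_samples, n_cells); ``times`` is in seconds on
    the acquisition clock until ``aligned`` is set by
    :func:`align_to_experiment_start`, after which time 0 is experiment
    start.
    """

    times: np.ndarray
    values: np.ndarray
    cell_ids: list[str]
    sampling_rate: float
    aligned: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.times.size:
            raise FormatError("values must be (n_samples, n_cells)")
        if len(self.cell_ids) != self.values.shape[1]:
            raise FormatError("one cell id per column required")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("cell ids must be unique")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def trace(self, cell_id: str) -> np.ndarray:
        return self.values[:, self.cell_ids.index(cell_id)]


@dataclass
class GpioRecord:
    """Digital line samples on the acquisition clock, per channel."""

    channel: np.ndarray  # labels, one per sample
    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.channel = np.asarray(self.channel)

    def channel_samples(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.channel == name
        t, v = self.timestamps[mask], self.values[mask]
        if np.any(np.diff(t) < 0):
            raise FormatError(f"GPIO timestamps on {name!r} not sorted")
        return t, v


def infer_sampling_rate(times: np.ndarray, jitter_tol: float = 0.01) -> float:
    """Sampling rate from the median time step; errors beyond 1% jitter."""
    dt = np.diff(np.asarray(times, dtype=float))
    if dt.size == 0:
        raise FormatError("need at least two samples to infer a sampling rate")
    if np.any(dt <= 0):
        raise FormatError("time column is not strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > jitter_tol * med:
        raise FormatError(
            f"time step jitter exceeds {100 * jitter_tol:.0f}% of the median step"
        )
    return 1.0 / med


# ---------------------------------------------------------------------------
# trace CSV

_STATUS_WORDS = {"accepted", "rejected", "undecided"}


def read_trace_csv(path) -> TraceMatrix:
    """Read a trace CSV, honoring an optional accepted/rejected status row."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a time column and at least one cell")
    cell_ids = [str(c).strip() for c in df.columns[1:]]
    first = [str(x).strip().lower() for x in df.iloc[0, 1:]]
    if set(first) <= _STATUS_WORDS:
        keep = [s == "accepted" for s in first]
        df = df.iloc[1:]  # status row's time field may be blank
    else:
        keep = [True] * len(cell_ids)
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged rows or missing fields")
    try:
        times = df.iloc[:, 0].astype(float).to_numpy()
        values = df.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric data row ({exc})") from exc
    cols = [i for i, k in enumerate(keep) if k]
    return TraceMatrix(
        times=times,
        values=values[:, cols],
        cell_ids=[cell_ids[i] for i in cols],
        sampling_rate=infer_sampling_rate(times),
    )


def write_trace_csv(traces: TraceMatrix, path, status_row: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write("time_s," + ",".join(traces.cell_ids) + "\n")
        if status_row:
            fh.write("," + ",".join(["accepted"] * traces.n_cells) + "\n")
        for t, row in zip(traces.times, traces.values):
            fh.write(f"{t:.9g}," + ",".join(f"{v:.9g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# GPIO CSV

def read_gpio_csv(path) -> GpioRecord:
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"channel", "time", "value"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: GPIO CSV needs columns {sorted(required)}")
    return GpioRecord(
        channel=df["channel"].astype(str).to_numpy(),
        timestamps=df["time"].astype(float).to_numpy(),
        values=df["value"].astype(float).to_numpy(),
    )


def write_gpio_csv(gpio: GpioRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write("channel,time,value\n")
        for c, t, v in zip(gpio.channel, gpio.timestamps, gpio.values):
            fh.write(f"{c},{t:.9g},{v:.9g}\n")


# ---------------------------------------------------------------------------
# behavior CSV

def read_behavior_csv(path) -> BehaviorEventLog:
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"time", "behavior", "status"} <= set(df.columns):
        raise FormatError(f"{path}: behavior CSV needs time, behavior, status")
    events = [
        BehaviorEvent(
            time=float(row["time"]),
            behavior=str(row["behavior"]).strip(),
            status=str(row["status"]).strip().upper(),
            subject=str(row.get("subject", "observer")).strip(),
        )
        for _, row in df.iterrows()
    ]
    log = BehaviorEventLog(events)
    log.epochs()  # validate START/STOP pairing eagerly, naming the bad row
    return log


def write_behavior_csv(log: BehaviorEventLog, path) -> None:
    with open(path, "w") as fh:
        fh.write("time,subject,behavior,status\n")
        for ev in sorted(log.events, key=lambda e: (e.time, e.status)):
            fh.write(f"{ev.time:.9g},{ev.subject},{ev.behavior},{ev.status}\n")


# ---------------------------------------------------------------------------
# alignment

def find_trigger_time(
    gpio: GpioRecord, trigger_channel: str, threshold: float | None = None
) -> float:
    """Time of the first rising edge on the trigger channel.

    The line is binarized at ``threshold`` (default: midpoint of the
    channel's range); the trigger is the first sample at which the line is
    high, provided it was low before (a line that is high from the first
    sample counts as rising at that sample).
    """
    t, v = gpio.channel_samples(trigger_channel)
    if t.size == 0:
        raise AlignmentError(f"no samples on GPIO channel {trigger_channel!r}")
    if threshold is None:
        # midpoint of the line's range; a constant-high line (trigger up
        # before recording of the channel began) is high throughout
        lo, hi = float(v.min()), float(v.max())
        threshold = 0.5 * hi if lo == hi else 0.5 * (lo + hi)
    high = v > threshold
    if not high.any():
        raise AlignmentError(f"no trigger event on channel {trigger_channel!r}")
    rising = np.flatnonzero(high & ~np.concatenate(([False], high[:-1])))
    if rising.size == 0:
        raise AlignmentError(f"no rising edge on channel {trigger_channel!r}")
    return float(t[rising[0]])


def align_to_experiment_start(
    traces: TraceMatrix,
    gpio: GpioRecord,
    trigger_channel: str = "trigger",
    session_length: float | None = None,
) -> TraceMatrix:
    """Shift trace times so the GPIO trigger is time 0.

    Samples before the trigger are discarded; if ``session_length`` is
    given, samples at or beyond it are discarded too.
    """
    t0 = find_trigger_time(gpio, trigger_channel)
    new_times = traces.times - t0
    keep = new_times >= 0.0
    if session_length is not None:
        keep &= new_times < session_length
    if not keep.any():
        raise AlignmentError(
            f"trigger at t={t0} s leaves no trace samples in the session"
        )
    return replace(
        traces,
        times=new_times[keep],
        values=traces.values[keep],
        cell_ids=list(traces.cell_ids),
        aligned=True,
    )


# ---------------------------------------------------------------------------
# report

REPORT_COLUMNS = [
    "cell_id", "n_spikes", "off_rate", "off_p95", "is_src", "is_ssc",
    "on_rate", "on_p95", "suppressed", "on_only_src",
]


def report_frame(reports) -> pd.DataFrame:
    """Per-cell classification table (one row per CellReport)."""
    rows = []
    for r in reports:
        rows.append({
            "cell_id": r.cell_id,
            "n_spikes": r.n_spikes,
            "off_rate": r.off_result.observed_rate if r.off_result else np.nan,
            "off_p95": r.off_result.p95 if r.off_result else np.nan,
            "is_src": r.is_src,
            "is_ssc": r.is_ssc,
            "on_rate": r.on_result.observed_rate if r.on_result else np.nan,
            "on_p95": r.on_result.p95 if r.on_result else np.nan,
            "suppressed": "" if r.suppressed is None else r.suppressed,
            "on_only_src": r.on_only_src,
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(reports, summary: dict, tsv_path, json_path) -> None:
    """Write the per-cell TSV and the session-summary JSON."""
    frame = report_frame(reports)
    frame.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
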