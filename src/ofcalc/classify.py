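"""Shuffle-null classification of shock-responding and shock-suppressed cells.

For each cell the mean event rate over the shock windows of a condition is
compared with a null distribution obtained by circularly shifting the
cell's whole event train by random increments (uniform on 20–1200 s by
default, wrapped modulo the session length) and recomputing the same
windowed rate; 1000 shifts form the null.  A cell is

* **SRC** (shock-responding) if its observed light-OFF shock-window rate
  strictly exceeds the null's 95th percentile;
* **SSC** (shock-suppressed) if that rate is strictly below the 5th
  percentile;
* **suppressed** (among SRCs) if, re-running the same test on the
  light-ON trials' shock windows, the ON-condition rate is no longer
  significant against its own null;
* **ON-only SRC** if it is not an SRC but its ON-condition rate exceeds
  the ON null's 95th percentile.

Circular shifting conserves the event count and every inter-event
interval, so the null preserves each cell's overall rate and burstiness
while breaking any alignment with the shock schedule.  Percentiles use
linear interpolation between order statistics.  An empty train is never
significant in either direction (0 cannot strictly exceed or fall below a
null that is identically 0).

No multiple-testing correction is applied across cells; calls are raw
per-cell tests at the 5% level, reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import SpikeTrain
from .errors import AnalysisError
from .schedule import ExperimentSchedule

Window = tuple[float, float]

DEFAULT_N_SHUFFLES = 1000
DEFAULT_SHIFT_RANGE = (20.0, 1200.0)


def _window_edges(windows: list[Window]) -> np.ndarray:
    if not windows:
        raise AnalysisError("no windows given")
    wins = sorted(windows)
    for (a0, a1), (b0, b1) in zip(wins, wins[1:]):
        if b0 < a1:
            raise AnalysisError(f"overlapping windows {(a0, a1)} and {(b0, b1)}")
    edges = np.asarray([e for w in wins for e in w], dtype=float)
    return edges


def count_in_windows(times: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Events per row of ``times`` falling in any half-open window.

    ``edges`` is the flattened sorted window boundary array; a time t is
    inside a window iff searchsorted(edges, t, 'right') is odd, which
    implements start-inclusive / end-exclusive membership.
    """
    idx = np.searchsorted(edges, times, side="right")
    return np.sum(idx % 2 == 1, axis=-1)


def window_spike_rate(train: SpikeTrain, windows: list[Window]) -> float:
    """Mean event rate (events/s) over the union of half-open windows."""
    edges = _window_edges(windows)
    total = float(np.sum(edges[1::2] - edges[0::2]))
    if total <= 0:
        raise AnalysisError("zero total window duration")
    n = int(count_in_windows(train.event_times, edges))
    return n / total


def circular_shift(
    train: SpikeTrain, delta: float, session_length: float
) -> SpikeTrain:
    """Shift every event by ``delta`` seconds, wrapping at session length."""
    if delta < 0:
        raise AnalysisError("shift must be non-negative")
    shifted = np.sort((train.event_times + delta) % session_length)
    return SpikeTrain(cell_id=train.cell_id, event_times=shifted)


@dataclass
class ShuffleResult:
    """Observed windowed rate and its circular-shift null for one condition."""

    cell_id: str
    condition: str  # OFF | ON
    observed_rate: float
    null_rates: np.ndarray
    p95: float
    p5: float
    n_shuffles: int
    shift_range: tuple[float, float]

    @property
    def significant_high(self) -> bool:
        return self.observed_rate > self.p95

    @property
    def significant_low(self) -> bool:
        return self.observed_rate < self.p5


def shuffle_null(
    train: SpikeTrain,
    windows: list[Window],
    session_length: float,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    shift_range: tuple[float, float] = DEFAULT_SHIFT_RANGE,
    seed=None,
    condition: str = "",
    shifts: np.ndarray | None = None,
) -> ShuffleResult:
    """Windowed rate vs. its circular-shift null.

    Shifts are drawn Uniform(*shift_range*) and applied modulo
    ``session_length``; ``shifts`` overrides the random draw with an
    explicit array (used for grid-based cross-checks).  Deterministic for
    a fixed ``seed``.
    """
    lo, hi = shift_range
    if lo < 0 or hi < lo:
        raise AnalysisError(f"bad shift range {shift_range}")
    edges = _window_edges(windows)
    if edges[-1] > session_length:
        raise AnalysisError("windows extend past session end")
    total = float(np.sum(edges[1::2] - edges[0::2]))
    if total <= 0:
        raise AnalysisError("zero total window duration")

    if shifts is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        shifts = rng.uniform(lo, hi, size=n_shuffles)
    else:
        shifts = np.asarray(shifts, dtype=float)
        n_shuffles = shifts.size

    observed = int(count_in_windows(train.event_times, edges)) / total
    if train.n_events:
        shifted = (train.event_times[None, :] + shifts[:, None]) % session_length
        null = count_in_windows(shifted, edges).astype(float) / total
    else:
        null = np.zeros(n_shuffles)
    return ShuffleResult(
        cell_id=train.cell_id,
        condition=condition,
        observed_rate=observed,
        null_rates=null,
        p95=float(np.percentile(null, 95)),
        p5=float(np.percentile(null, 5)),
        n_shuffles=n_shuffles,
        shift_range=(lo, hi),
    )


@dataclass
class CellReport:
    """Classification of one cell across the OFF and ON conditions.

    ``suppressed`` is None unless the cell is an SRC and the schedule has
    ON trials.
    """

    cell_id: str
    n_spikes: int = 0
    is_src: bool = False
    is_ssc: bool = False
    suppressed: bool | None = None
    on_only_src: bool = False
    off_result: ShuffleResult | None = None
    on_result: ShuffleResult | None = None


def classify_cell(
    train: SpikeTrain,
    schedule: ExperimentSchedule,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    shift_range: tuple[float, float] = DEFAULT_SHIFT_RANGE,
    seed=None,
    conditions: tuple[str, ...] = ("OFF", "ON"),
    use_led_windows: bool = False,
) -> CellReport:
    """Full per-cell classification: SRC/SSC on OFF trials, suppression on ON.

    Raises if a requested condition has no trials in the schedule; pass
    ``conditions=("OFF",)`` for a light-OFF-only session.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    report = CellReport(cell_id=train.cell_id, n_spikes=train.n_events)

    if "OFF" in conditions:
        off = shuffle_null(
            train,
            schedule.condition_windows("OFF"),
            schedule.session_length,
            n_shuffles=n_shuffles,
            shift_range=shift_range,
            seed=rng,
            condition="OFF",
        )
        report.off_result = off
        report.is_src = off.significant_high
        report.is_ssc = off.significant_low

    if "ON" in conditions:
        on = shuffle_null(
            train,
            schedule.condition_windows("ON", use_led=use_led_windows),
            schedule.session_length,
            n_shuffles=n_shuffles,
            shift_range=shift_range,
            seed=rng,
            condition="ON",
        )
        report.on_result = on
        if report.is_src:
            report.suppressed = not on.significant_high
        report.on_only_src = (not report.is_src) and on.significant_high
    return report


def classify_session(
    trains: list[SpikeTrain],
    schedule: ExperimentSchedule,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    shift_range: tuple[float, float] = DEFAULT_SHIFT_RANGE,
    seed=None,
    conditions: tuple[str, ...] = ("OFF", "ON"),
    use_led_windows: bool = False,
) -> list[CellReport]:
    """Classify every cell, with per-cell seeds spawned from one master seed."""
    root = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [
        classify_cell(
            train, schedule,
            n_shuffles=n_shuffles,
            shift_range=shift_range,
            seed=np.random.default_rng(root.integers(2**31)),
            conditions=conditions,
            use_led_windows=use_led_windows,
        )
        for train in trains
    ]


def session_summary(reports: list[CellReport]) -> dict:
    """Session-level counts and percentages (percent to one decimal).

    Percentages are recomputed from the counts in the same dict:
    ``pct_src`` of all cells, ``pct_suppressed`` of SRCs.
    """
    if not reports:
        raise AnalysisError("no cell reports to summarize")
    n_cells = len(reports)
    n_src = sum(r.is_src for r in reports)
    n_suppressed = sum(bool(r.suppressed) for r in reports if r.is_src)
    n_ssc = sum(r.is_ssc for r in reports)
    n_on_only = sum(r.on_only_src for r in reports)
    return {
        "n_cells": n_cells,
        "n_src": n_src,
        "pct_src": round(100.0 * n_src / n_cells, 1),
        "n_suppressed": n_suppressed,
        "pct_suppressed": round(100.0 * n_suppressed / n_src, 1) if n_src else 0.0,
        "n_ssc": n_ssc,
        "n_on_only": n_on_only,
    }
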