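"""Freezing-bout metrics from a manually scored behavioral event log.

The observer's behavior is scored externally (BORIS-style event logging)
into START/STOP rows per behavior.  Here freezing epochs are paired up,
abutting epochs merged, short epochs discarded (an accepted freezing bout
must last strictly more than 2 s), and per-condition summary metrics
computed: total freezing time, percent freezing, bout count, mean bout
duration, and the mean duration of bouts that begin inside a shock window.

A bout belongs to the period in which it *begins*; its full duration is
credited there even if it extends past the period boundary (no clipping by
default — ``clip_to_period`` opts in).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AnalysisError, FormatError

Window = tuple[float, float]

FREEZING = "freezing"


@dataclass(frozen=True)
class BehaviorEvent:
    time: float
    behavior: str
    status: str  # START | STOP
    subject: str = "observer"


@dataclass
class BehaviorEventLog:
    """Ordered START/STOP rows; every START must have a later matching STOP."""

    events: list[BehaviorEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.time < 0:
                raise FormatError(f"negative event time {ev.time}")
            if ev.status not in ("START", "STOP"):
                raise FormatError(f"bad status {ev.status!r} at t={ev.time}")

    def epochs(self, behavior: str = FREEZING) -> list[Window]:
        """Pair START/STOP rows of one behavior into (start, stop) epochs."""
        rows = sorted(
            (ev for ev in self.events if ev.behavior == behavior),
            key=lambda ev: (ev.time, ev.status == "START"),
        )
        out: list[Window] = []
        open_start: float | None = None
        for ev in rows:
            if ev.status == "START":
                if open_start is not None:
                    raise FormatError(
                        f"START {behavior!r} at t={ev.time} while epoch opened "
                        f"at t={open_start} is still open"
                    )
                open_start = ev.time
            else:
                if open_start is None:
                    raise FormatError(f"STOP {behavior!r} at t={ev.time} without START")
                if ev.time <= open_start:
                    raise FormatError(
                        f"STOP at t={ev.time} not after START at t={open_start}"
                    )
                out.append((open_start, ev.time))
                open_start = None
        if open_start is not None:
            raise FormatError(f"unmatched START {behavior!r} at t={open_start}")
        return out


@dataclass(frozen=True)
class FreezingBout:
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class ConditionBehavior:
    """Freezing metrics of one optogenetic condition period."""

    condition: str
    period: Window
    total_freeze_s: float
    pct_freeze: float
    n_bouts: int
    mean_bout_s: float
    shock_onset_bout_mean_s: float
    n_shock_onset_bouts: int
    mean_defined: bool


def merge_abutting(epochs: list[Window]) -> list[Window]:
    """Union epochs whose boundaries touch or overlap (gap = 0 merges)."""
    merged: list[list[float]] = []
    for start, end in sorted(epochs):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(a, b) for a, b in merged]


def extract_bouts(
    log: BehaviorEventLog,
    min_duration: float = 2.0,
    behavior: str = FREEZING,
) -> list[FreezingBout]:
    """Accepted freezing bouts: merged epochs with duration strictly > 2 s."""
    epochs = merge_abutting(log.epochs(behavior))
    return [
        FreezingBout(start, end)
        for start, end in epochs
        if end - start > min_duration
    ]


def condition_metrics(
    bouts: list[FreezingBout],
    period: Window,
    shock_windows: list[Window],
    condition: str = "",
    clip_to_period: bool = False,
) -> ConditionBehavior:
    """Summarize freezing within one condition period.

    Membership is by bout start time (half-open period); only shock windows
    that begin inside the period contribute to the shock-onset bout metric.
    """
    start, end = period
    if end <= start:
        raise AnalysisError(f"empty condition period {period}")
    selected = [b for b in bouts if start <= b.start < end]
    if clip_to_period:
        durations = [min(b.end, end) - b.start for b in selected]
    else:
        durations = [b.duration for b in selected]
    total = float(sum(durations))
    n = len(selected)
    period_windows = [w for w in shock_windows if start <= w[0] < end]
    shock_bouts = [
        d for b, d in zip(selected, durations)
        if any(w0 <= b.start < w1 for w0, w1 in period_windows)
    ]
    return ConditionBehavior(
        condition=condition,
        period=period,
        total_freeze_s=total,
        pct_freeze=100.0 * total / (end - start),
        n_bouts=n,
        mean_bout_s=total / n if n else 0.0,
        shock_onset_bout_mean_s=(
            float(sum(shock_bouts)) / len(shock_bouts) if shock_bouts else 0.0
        ),
        n_shock_onset_bouts=len(shock_bouts),
        mean_defined=n > 0,
    )


def compare_conditions(sessions, metric: str):
    """Two-tailed paired t-test of one metric across sessions (OFF vs ON).

    ``sessions`` is a list of ``(off, on)`` :class:`ConditionBehavior`
    pairs; ``metric`` names one of their numeric fields.  Returns the
    :class:`ofcalc.stats.PairedTResult` with df = n_sessions - 1.
    """
    from .stats import paired_t

    if len(sessions) < 2:
        raise AnalysisError("paired comparison needs at least 2 sessions")
    x = [getattr(off, metric) for off, _ in sessions]
    y = [getattr(on, metric) for _, on in sessions]
    return paired_t(x, y)
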