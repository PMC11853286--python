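"""Calcium-transient ("spike") detection by baseline thresholding.

An event is a local maximum of the fluorescence trace that strictly
exceeds ``baseline_mean + k * baseline_sd`` (k = 2 by default).  One
contiguous supra-threshold excursion contributes one event, timestamped at
its peak sample, so a single slow GCaMP transient cannot be counted many
times; peaks closer together than ``min_separation`` are merged onto the
larger one.

The baseline is either the whole trace (default) or the habituation
segment only; both are defensible readings of a "baseline mean" for a
session that is mostly quiescent, and the choice is exposed in the
configuration.  The standard deviation is the sample (n-1) estimate; NaN
samples (dropped frames) are excluded from the baseline and can never be
peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError

BASELINE_METHODS = ("full", "habituation")


@dataclass
class SpikeTrain:
    """Detected calcium-transient timestamps of one cell."""

    cell_id: str
    event_times: np.ndarray
    peak_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    threshold_used: float = np.nan
    baseline_mean: float = np.nan
    baseline_sd: float = np.nan

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.peak_values = np.asarray(self.peak_values, dtype=float)
        if np.any(np.diff(self.event_times) < 0):
            raise AnalysisError("event times must be sorted")

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)


def estimate_baseline(
    values: np.ndarray,
    times: np.ndarray | None = None,
    method: str = "full",
    habituation_end: float = 300.0,
) -> tuple[float, float]:
    """Baseline mean and sample SD of a trace.

    ``method="full"`` uses every finite sample; ``method="habituation"``
    restricts to samples with time < ``habituation_end`` (requires
    ``times``).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise AnalysisError("empty trace")
    if method not in BASELINE_METHODS:
        raise AnalysisError(f"unknown baseline method {method!r}")
    if method == "habituation":
        if times is None:
            raise AnalysisError("habituation baseline needs sample times")
        values = values[np.asarray(times, dtype=float) < habituation_end]
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise AnalysisError("no finite samples in baseline segment")
    mean = float(np.mean(finite))
    sd = float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0
    return mean, sd


def detect_spikes(
    values: np.ndarray,
    times: np.ndarray,
    baseline: tuple[float, float],
    sd_multiplier: float = 2.0,
    min_separation: float = 0.25,
    cell_id: str = "",
) -> SpikeTrain:
    """Detect transients strictly above ``mean + sd_multiplier * sd``.

    Returns one event per supra-threshold excursion, at the excursion's
    maximum sample; nearby peaks within ``min_separation`` seconds are
    merged to the larger peak.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    mean, sd = baseline
    threshold = mean + sd_multiplier * sd

    above = np.zeros(values.size, dtype=bool)
    finite = np.isfinite(values)
    above[finite] = values[finite] > threshold

    # contiguous supra-threshold runs -> one candidate peak each
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above.size and above[0]:
        starts = np.concatenate(([0], starts))
    if above.size and above[-1]:
        ends = np.concatenate((ends, [above.size]))
    peak_idx = [int(s + np.nanargmax(values[s:e])) for s, e in zip(starts, ends)]

    # greedy merge of peaks closer than min_separation, larger peak wins
    kept: list[int] = []
    for idx in peak_idx:
        if kept and times[idx] - times[kept[-1]] < min_separation:
            if values[idx] > values[kept[-1]]:
                kept[-1] = idx
        else:
            kept.append(idx)

    kept_arr = np.asarray(kept, dtype=int)
    return SpikeTrain(
        cell_id=cell_id,
        event_times=times[kept_arr] if kept_arr.size else np.empty(0),
        peak_values=values[kept_arr] if kept_arr.size else np.empty(0),
        threshold_used=threshold,
        baseline_mean=mean,
        baseline_sd=sd,
    )


def detect_session(
    traces,
    baseline_method: str = "full",
    sd_multiplier: float = 2.0,
    min_separation: float = 0.25,
    habituation_end: float = 300.0,
) -> list[SpikeTrain]:
    """Run baseline estimation + detection on every cell of a TraceMatrix."""
    trains = []
    for j, cell_id in enumerate(traces.cell_ids):
        v = traces.values[:, j]
        baseline = estimate_baseline(
            v, traces.times, method=baseline_method, habituation_end=habituation_end
        )
        trains.append(
            detect_spikes(
                v, traces.times, baseline,
                sd_multiplier=sd_multiplier,
                min_separation=min_separation,
                cell_id=cell_id,
            )
        )
    return trains
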