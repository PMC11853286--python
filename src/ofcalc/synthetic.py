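"""Synthetic observational-fear sessions with known ground truth.

Real sessions are 20-minute one-photon recordings: 5 min habituation, then
20 foot shocks (2 s each, 30-60 s apart) delivered to the demonstrator,
with the inhibitory red LED off for shocks 1-10 and on for shocks 11-20.
This module generates sessions of that shape end to end — schedule, event
trains, fluorescence traces, GPIO trigger, freezing log — so every
downstream stage can be tested against planted truth without any
recording.

Event trains are inhomogeneous Poisson processes whose rate switches from
a cell's baseline rate to a class-specific rate inside shock windows:

==================  ======================  =====================
planted class        rate in OFF windows     rate in ON windows
==================  ======================  =====================
SRC_SUPPRESSED       high                    baseline
SRC_NOT_SUPPRESSED   high                    high
SRC_ON_ONLY          baseline                high
SSC                  ~0 (below baseline)     ~0
NULL                 baseline                baseline
==================  ======================  =====================

Defaults: baseline 0.1 events/s (sparse GCaMP6f-like event rates), "high"
= 2.0 events/s (20x baseline, a strong effect), and the SSC baseline is
raised to 0.5 events/s — suppression is only detectable against a
non-trivial baseline.  Traces are rendered by dropping a
difference-of-exponentials GCaMP6f-like kernel (rise 0.08 s, decay 0.5 s)
at each event time on a 20 Hz grid, plus Gaussian noise at 1/6 of the
transient amplitude.

The freezing log is an alternating move/freeze renewal process with an
extra probability of a freeze bout starting inside each shock window; it
exists to exercise the bout metrics, not to model real freezing dynamics.

All randomness flows from one master seed: the same seed reproduces a
bit-identical session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .behavior import BehaviorEvent, BehaviorEventLog, FREEZING
from .detection import SpikeTrain
from .errors import ConfigError
from .io import GpioRecord, TraceMatrix, write_behavior_csv, write_gpio_csv, write_trace_csv
from .schedule import ExperimentSchedule, default_condition_split

CLASSES = ("SRC_SUPPRESSED", "SRC_NOT_SUPPRESSED", "SRC_ON_ONLY", "SSC", "NULL")

DEFAULT_BASELINE_RATE = 0.1   # events/s
DEFAULT_SHOCK_RATE = 2.0      # events/s, 20x baseline
SSC_BASELINE_RATE = 0.5       # events/s


@dataclass(frozen=True)
class CellGroundTruth:
    """Planted class and event rates of one simulated cell."""

    cell_id: str
    klass: str
    baseline_rate: float
    shock_rate_off: float
    shock_rate_on: float

    def __post_init__(self) -> None:
        if self.klass not in CLASSES:
            raise ConfigError(f"unknown cell class {self.klass!r}")
        if min(self.baseline_rate, self.shock_rate_off, self.shock_rate_on) < 0:
            raise ConfigError("rates must be non-negative")


def default_truth(
    klass: str,
    cell_id: str,
    baseline_rate: float = DEFAULT_BASELINE_RATE,
    shock_rate: float = DEFAULT_SHOCK_RATE,
) -> CellGroundTruth:
    """Ground truth for one cell under the default rate scheme."""
    if klass == "SRC_SUPPRESSED":
        rates = (baseline_rate, shock_rate, baseline_rate)
    elif klass == "SRC_NOT_SUPPRESSED":
        rates = (baseline_rate, shock_rate, shock_rate)
    elif klass == "SRC_ON_ONLY":
        rates = (baseline_rate, baseline_rate, shock_rate)
    elif klass == "SSC":
        rates = (SSC_BASELINE_RATE, 0.0, 0.0)
    elif klass == "NULL":
        rates = (baseline_rate, baseline_rate, baseline_rate)
    else:
        raise ConfigError(f"unknown cell class {klass!r}")
    return CellGroundTruth(cell_id, klass, *rates)


@dataclass(frozen=True)
class KernelParams:
    """GCaMP6f-like transient shape and trace noise model."""

    rise_tau: float = 0.08        # s
    decay_tau: float = 0.5        # s
    amplitude: float = 1.0        # fluorescence units (peak height)
    noise_sd: float = 1.0 / 6.0   # amplitude/noise defaults to 6
    baseline_level: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.rise_tau < self.decay_tau:
            raise ConfigError("need 0 < rise_tau < decay_tau")

    @property
    def peak_delay(self) -> float:
        """Time from event to kernel peak (closed form for the kernel)."""
        r, d = self.rise_tau, self.decay_tau
        return r * d / (d - r) * math.log(d / r)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Unit-peak difference-of-exponentials kernel, zero for t < 0."""
        t = np.asarray(t, dtype=float)
        raw = np.where(t >= 0, np.exp(-t / self.decay_tau) - np.exp(-t / self.rise_tau), 0.0)
        tp = self.peak_delay
        peak = math.exp(-tp / self.decay_tau) - math.exp(-tp / self.rise_tau)
        return self.amplitude * raw / peak


# ---------------------------------------------------------------------------
# schedule

def generate_schedule(
    n_shocks: int = 20,
    iti_range: tuple[float, float] = (30.0, 60.0),
    shock_duration: float = 2.0,
    habituation_duration: float = 300.0,
    tail: float = 60.0,
    seed=None,
) -> ExperimentSchedule:
    """Random protocol schedule: habituation, then shocks with uniform ITIs.

    The inter-trial interval (shock offset to next onset) is drawn uniform
    from ``iti_range``; LED windows (onset-1 to onset+shock_duration+1)
    are attached to the second half of the shocks.  ``tail`` seconds of
    recording follow the last shock.
    """
    if n_shocks < 1:
        raise ConfigError("need at least one shock")
    lo, hi = iti_range
    if hi < lo or lo < 0:
        raise ConfigError(f"bad ITI range {iti_range}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    itis = rng.uniform(lo, hi, size=n_shocks)
    onsets = habituation_duration + np.cumsum(itis) + shock_duration * np.arange(n_shocks)
    off_idx, on_idx = default_condition_split(n_shocks)
    led = tuple(
        (onsets[i - 1] - 1.0, onsets[i - 1] + shock_duration + 1.0)
        for i in sorted(on_idx)
    )
    return ExperimentSchedule(
        shock_onsets=tuple(float(t) for t in onsets),
        shock_duration=shock_duration,
        habituation_start=0.0,
        habituation_duration=habituation_duration,
        led_windows=led,
        off_trial_indices=off_idx,
        on_trial_indices=on_idx,
        session_length=float(onsets[-1] + shock_duration + tail),
    )


# ---------------------------------------------------------------------------
# event trains

def _rate_segments(
    truth: CellGroundTruth, schedule: ExperimentSchedule
) -> list[tuple[float, float, float]]:
    """Piecewise-constant (start, end, rate) covering [0, session_length)."""
    windows = []
    for i in sorted(schedule.off_trial_indices):
        windows.append((*schedule.shock_window(i), truth.shock_rate_off))
    for i in sorted(schedule.on_trial_indices):
        windows.append((*schedule.shock_window(i), truth.shock_rate_on))
    windows.sort()
    segments = []
    t = 0.0
    for start, end, rate in windows:
        if start > t:
            segments.append((t, start, truth.baseline_rate))
        segments.append((start, end, rate))
        t = end
    if t < schedule.session_length:
        segments.append((t, schedule.session_length, truth.baseline_rate))
    return segments


def generate_spike_train(
    truth: CellGroundTruth, schedule: ExperimentSchedule, seed=None
) -> SpikeTrain:
    """Inhomogeneous Poisson event train with rate switching in shock windows."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = []
    for start, end, rate in _rate_segments(truth, schedule):
        n = rng.poisson(rate * (end - start))
        if n:
            times.append(rng.uniform(start, end, size=n))
    events = np.sort(np.concatenate(times)) if times else np.empty(0)
    return SpikeTrain(cell_id=truth.cell_id, event_times=events)


# ---------------------------------------------------------------------------
# trace rendering

def render_trace(
    train: SpikeTrain,
    kernel: KernelParams,
    sampling_rate: float = 20.0,
    duration: float | None = None,
    t_start: float = 0.0,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a fluorescence series from an event train.

    Returns ``(times, values)`` on a uniform grid of ``duration`` seconds
    beginning at ``t_start`` (event times are on the same clock).  Each
    event contributes one kernel; the rendered peak lags the event by the
    kernel's rise (≈0.17 s for the defaults, always < 0.25 s).
    """
    if sampling_rate <= 0:
        raise ConfigError("sampling rate must be positive")
    if duration is None:
        duration = (float(train.event_times[-1]) + 5 * kernel.decay_tau - t_start
                    if train.n_events else 1.0)
    n = int(round(duration * sampling_rate))
    times = t_start + np.arange(n) / sampling_rate
    values = np.full(n, kernel.baseline_level, dtype=float)

    # kernel support truncated at 8 decay constants (<0.04% of peak left)
    support = int(math.ceil((8 * kernel.decay_tau) * sampling_rate))
    for t_ev in train.event_times:
        i0 = int(math.ceil((t_ev - times[0]) * sampling_rate))
        i0 = max(i0, 0)
        i1 = min(i0 + support, n)
        if i0 >= n:
            continue
        values[i0:i1] += kernel.evaluate(times[i0:i1] - t_ev)

    if kernel.noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        values += rng.normal(0.0, kernel.noise_sd, size=n)
    return times, values


# ---------------------------------------------------------------------------
# behavior log

def generate_behavior_log(
    schedule: ExperimentSchedule,
    mean_move_s: float = 20.0,
    mean_freeze_s: float = 6.0,
    shock_freeze_prob: float = 0.5,
    seed=None,
) -> BehaviorEventLog:
    """Alternating move/freeze renewal process with shock-triggered bouts.

    Freeze bouts additionally start inside each 2-s shock window with
    probability ``shock_freeze_prob``; overlapping freezing epochs are
    merged before the log is emitted.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = schedule.session_length
    epochs: list[tuple[float, float]] = []
    t = float(rng.exponential(mean_move_s))
    while t < L:
        dur = float(rng.exponential(mean_freeze_s))
        end = min(t + dur, L)
        if end > t:
            epochs.append((t, end))
        t = end + float(rng.exponential(mean_move_s))
    for i in range(1, schedule.n_shocks + 1):
        if rng.uniform() < shock_freeze_prob:
            w0, w1 = schedule.shock_window(i)
            start = float(rng.uniform(w0, w1))
            dur = 2.5 + float(rng.exponential(mean_freeze_s))
            epochs.append((start, min(start + dur, L)))
    # merge overlaps so the log satisfies START/STOP pairing
    merged: list[list[float]] = []
    for start, end in sorted(epochs):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    events = []
    for start, end in merged:
        events.append(BehaviorEvent(time=start, behavior=FREEZING, status="START"))
        events.append(BehaviorEvent(time=end, behavior=FREEZING, status="STOP"))
    return BehaviorEventLog(events)


# ---------------------------------------------------------------------------
# full session

@dataclass
class SyntheticSession:
    """One generated session: raw (unaligned) data plus planted truth."""

    traces: TraceMatrix            # acquisition clock; trigger at gpio_offset
    gpio: GpioRecord
    schedule: ExperimentSchedule   # experiment clock (0 = trigger)
    behavior: BehaviorEventLog     # experiment clock
    ground_truth: list[CellGroundTruth]
    true_trains: list[SpikeTrain]  # experiment clock
    gpio_offset: float


def generate_session(
    n_cells_per_class: dict[str, int],
    kernel: KernelParams | None = None,
    schedule: ExperimentSchedule | None = None,
    sampling_rate: float = 20.0,
    gpio_offset: float = 5.0,
    mean_move_s: float = 20.0,
    mean_freeze_s: float = 6.0,
    shock_freeze_prob: float = 0.5,
    seed=None,
) -> SyntheticSession:
    """Generate a mutually consistent session from one master seed.

    Trace times are on the acquisition clock, which starts ``gpio_offset``
    seconds before the experiment; the GPIO trigger rises at that offset,
    so aligning the traces brings planted events and schedule into
    register.
    """
    if not n_cells_per_class:
        raise ConfigError("empty cell-class map")
    kernel = kernel or KernelParams()
    master = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if schedule is None:
        schedule = generate_schedule(seed=master)

    truths: list[CellGroundTruth] = []
    k = 0
    for klass, count in n_cells_per_class.items():
        for _ in range(count):
            truths.append(default_truth(klass, f"cell_{k:03d}"))
            k += 1

    duration = gpio_offset + schedule.session_length
    trains, columns = [], []
    for truth in truths:
        train = generate_spike_train(
            truth, schedule, seed=np.random.default_rng(master.integers(2**31))
        )
        trains.append(train)
        # render on the acquisition clock: event at t happens at t + offset
        acq_train = SpikeTrain(
            cell_id=truth.cell_id, event_times=train.event_times + gpio_offset
        )
        _, values = render_trace(
            acq_train, kernel,
            sampling_rate=sampling_rate,
            duration=duration,
            t_start=0.0,
            seed=np.random.default_rng(master.integers(2**31)),
        )
        columns.append(values)

    n_samples = int(round(duration * sampling_rate))
    traces = TraceMatrix(
        times=np.arange(n_samples) / sampling_rate,
        values=np.column_stack(columns),
        cell_ids=[t.cell_id for t in truths],
        sampling_rate=sampling_rate,
        aligned=False,
    )
    gpio = GpioRecord(
        channel=np.array(["trigger"] * 3),
        timestamps=np.array([0.0, gpio_offset, duration]),
        values=np.array([0.0, 1.0, 1.0]),
    )
    behavior = generate_behavior_log(
        schedule,
        mean_move_s=mean_move_s,
        mean_freeze_s=mean_freeze_s,
        shock_freeze_prob=shock_freeze_prob,
        seed=np.random.default_rng(master.integers(2**31)),
    )
    return SyntheticSession(
        traces=traces,
        gpio=gpio,
        schedule=schedule,
        behavior=behavior,
        ground_truth=truths,
        true_trains=trains,
        gpio_offset=gpio_offset,
    )


def write_session(session: SyntheticSession, outdir) -> dict[str, Path]:
    """Write a session's files: traces, GPIO, behavior, schedule, truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "traces": outdir / "traces.csv",
        "gpio": outdir / "gpio.csv",
        "behavior": outdir / "behavior.csv",
        "schedule": outdir / "schedule.yaml",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    write_trace_csv(session.traces, paths["traces"])
    write_gpio_csv(session.gpio, paths["gpio"])
    write_behavior_csv(session.behavior, paths["behavior"])
    session.schedule.to_yaml(paths["schedule"])
    with open(paths["ground_truth"], "w") as fh:
        fh.write("cell_id\tklass\tbaseline_rate\tshock_rate_off\tshock_rate_on\tn_true_events\n")
        for truth, train in zip(session.ground_truth, session.true_trains):
            fh.write(
                f"{truth.cell_id}\t{truth.klass}\t{truth.baseline_rate:.6g}\t"
                f"{truth.shock_rate_off:.6g}\t{truth.shock_rate_on:.6g}\t{train.n_events}\n"
            )
    return paths
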