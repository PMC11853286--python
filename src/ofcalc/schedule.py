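"""Experiment timeline: habituation, shock train, LED windows, OFF/ON split.

Time is measured in seconds from experiment start (the GPIO trigger), and
every window is half-open ``[start, end)`` so that an event falling exactly
on a shared boundary is counted once.

Shock trials are numbered from 1.  With the default 20-shock protocol the
first 10 shocks are delivered with the inhibitory LED off ("light-OFF"
condition) and the last 10 with it on ("light-ON"); the LED window spans
from one second before each ON-trial shock onset to one second after shock
offset (4 s total for a 2 s shock).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

from .errors import ScheduleError

Window = tuple[float, float]


def default_condition_split(n_shocks: int) -> tuple[frozenset[int], frozenset[int]]:
    """OFF/ON partition of 1-based trial indices: first ceil(n/2) trials OFF.

    Matches the 10/10 split of the default 20-shock protocol and degrades
    sensibly for odd or single-shock schedules (1 shock -> OFF={1}, ON={}).
    """
    n_off = math.ceil(n_shocks / 2)
    off = frozenset(range(1, n_off + 1))
    on = frozenset(range(n_off + 1, n_shocks + 1))
    return off, on


@dataclass(frozen=True)
class ExperimentSchedule:
    """Timeline of one observational-fear session.

    Parameters
    ----------
    shock_onsets
        Onset of each foot shock, seconds from experiment start, strictly
        increasing.
    shock_duration
        Length of each shock in seconds (2.0 in the standard protocol).
    habituation_start, habituation_duration
        The no-shock habituation period (default the first 300 s).
    led_windows
        ``(start, end)`` of each inhibitory-LED illumination.
    off_trial_indices, on_trial_indices
        Disjoint 1-based shock indices covering all shocks.
    session_length
        Total session duration in seconds; all windows must fit inside
        ``[0, session_length]``.
    """

    shock_onsets: tuple[float, ...]
    session_length: float
    shock_duration: float = 2.0
    habituation_start: float = 0.0
    habituation_duration: float = 300.0
    led_windows: tuple[Window, ...] = ()
    off_trial_indices: frozenset[int] = field(default_factory=frozenset)
    on_trial_indices: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        n = len(self.shock_onsets)
        if any(b <= a for a, b in zip(self.shock_onsets, self.shock_onsets[1:])):
            raise ScheduleError("shock onsets must be strictly increasing")
        if self.shock_duration <= 0:
            raise ScheduleError("shock duration must be positive")
        all_idx = set(range(1, n + 1))
        if self.off_trial_indices | self.on_trial_indices != all_idx:
            raise ScheduleError("OFF/ON indices must cover all shocks")
        if self.off_trial_indices & self.on_trial_indices:
            raise ScheduleError("OFF/ON indices must be disjoint")
        for start, end in self.all_windows():
            if not (0.0 <= start < end <= self.session_length):
                raise ScheduleError(
                    f"window ({start}, {end}) outside [0, {self.session_length}]"
                )

    # ---- window accessors -------------------------------------------------

    @property
    def n_shocks(self) -> int:
        return len(self.shock_onsets)

    def shock_window(self, index: int) -> Window:
        """Half-open shock window of 1-based trial ``index``."""
        onset = self.shock_onsets[index - 1]
        return (onset, onset + self.shock_duration)

    def shock_windows(self, indices=None) -> list[Window]:
        idx = sorted(indices) if indices is not None else range(1, self.n_shocks + 1)
        return [self.shock_window(i) for i in idx]

    def condition_windows(self, condition: str, use_led: bool = False) -> list[Window]:
        """Shock (or LED) windows of one optogenetic condition.

        ``condition`` is ``"OFF"`` or ``"ON"``.  By default the 2-s shock
        windows are returned for both conditions — rates are computed "during
        the shock moment"; ``use_led=True`` substitutes the 4-s LED windows
        for the ON condition.
        """
        cond = condition.upper()
        if cond == "OFF":
            indices = self.off_trial_indices
        elif cond == "ON":
            indices = self.on_trial_indices
        else:
            raise ScheduleError(f"unknown condition {condition!r}")
        if not indices:
            raise ScheduleError(f"schedule has no {cond}-condition trials")
        if cond == "ON" and use_led:
            return sorted(self.led_windows)
        return self.shock_windows(indices)

    def habituation_window(self) -> Window:
        return (self.habituation_start,
                self.habituation_start + self.habituation_duration)

    def condition_period(self, condition: str) -> Window:
        """Behavioral comparison period for one condition.

        OFF runs from the first OFF-trial shock onset to the first LED
        onset; ON runs from the first LED onset to session end.  (With no
        ON trials, OFF extends to session end.)
        """
        cond = condition.upper()
        if cond == "OFF":
            start = min(self.shock_window(i)[0] for i in self.off_trial_indices)
            end = (min(w[0] for w in self.led_windows) if self.led_windows
                   else self.session_length)
            return (start, end)
        if cond == "ON":
            if not self.led_windows:
                raise ScheduleError("schedule has no LED windows")
            return (min(w[0] for w in self.led_windows), self.session_length)
        raise ScheduleError(f"unknown condition {condition!r}")

    def all_windows(self) -> list[Window]:
        wins = [self.habituation_window()]
        wins += self.shock_windows()
        wins += list(self.led_windows)
        return wins

    # ---- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "shock_onsets": [float(t) for t in self.shock_onsets],
            "shock_duration": float(self.shock_duration),
            "habituation_start": float(self.habituation_start),
            "habituation_duration": float(self.habituation_duration),
            "led_windows": [[float(a), float(b)] for a, b in self.led_windows],
            "off_trial_indices": sorted(self.off_trial_indices),
            "on_trial_indices": sorted(self.on_trial_indices),
            "session_length": float(self.session_length),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentSchedule":
        return cls(
            shock_onsets=tuple(float(t) for t in d["shock_onsets"]),
            shock_duration=float(d.get("shock_duration", 2.0)),
            habituation_start=float(d.get("habituation_start", 0.0)),
            habituation_duration=float(d.get("habituation_duration", 300.0)),
            led_windows=tuple((float(a), float(b)) for a, b in d.get("led_windows", [])),
            off_trial_indices=frozenset(int(i) for i in d["off_trial_indices"]),
            on_trial_indices=frozenset(int(i) for i in d["on_trial_indices"]),
            session_length=float(d["session_length"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentSchedule":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
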