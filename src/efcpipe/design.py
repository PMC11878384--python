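"""Block-design stimulus timing on a TR grid."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._validation import ValidationError, require

CONDITIONS = ("heat", "heat_fus", "fus")

__all__ = ["CONDITIONS", "StimulusEvent", "StimulusDesign"]


@dataclass(frozen=True)
class StimulusEvent:
    onset: float  # seconds
    duration: float  # seconds
    condition: str

    def __post_init__(self) -> None:
        require(self.onset >= 0, "event onset must be >= 0")
        require(self.duration > 0, "event duration must be > 0")
        require(self.condition in CONDITIONS, f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class StimulusDesign:
    """Timing of stimulation blocks for one run.

    Events are kept sorted by onset, must not overlap and must fit inside the
    acquired span ``tr * n_volumes``.
    """

    tr: float
    n_volumes: int
    events: tuple[StimulusEvent, ...]
    baseline_temperature: float | None = None
    stim_temperature: float | None = None

    def __post_init__(self) -> None:
        require(self.tr > 0, "tr must be > 0")
        require(self.n_volumes > 0, "n_volumes must be > 0")
        events = tuple(sorted(self.events, key=lambda e: e.onset))
        object.__setattr__(self, "events", events)
        span = self.tr * self.n_volumes
        prev_end = -np.inf
        for ev in events:
            if ev.onset < prev_end:
                raise ValidationError(f"events overlap at onset {ev.onset} s")
            if ev.onset + ev.duration > span + 1e-9:
                raise ValidationError(
                    f"event at {ev.onset} s runs past the acquired span ({span} s)"
                )
            prev_end = ev.onset + ev.duration

    def total_duration(self) -> float:
        return self.tr * self.n_volumes

    def frame_times(self) -> np.ndarray:
        """Acquisition times of the volume onsets (0, tr, 2*tr, ...)."""
        return np.arange(self.n_volumes) * self.tr

    def conditions(self) -> list[str]:
        """Conditions present, in canonical order."""
        present = {ev.condition for ev in self.events}
        return [c for c in CONDITIONS if c in present]

    def events_of(self, condition: str) -> list[StimulusEvent]:
        return [ev for ev in self.events if ev.condition == condition]

    def boxcar(self, condition: str, times: np.ndarray | None = None) -> np.ndarray:
        """1 during the condition's blocks, 0 elsewhere, on the given time grid."""
        if times is None:
            times = self.frame_times()
        times = np.asarray(times, float)
        box = np.zeros(len(times))
        for ev in self.events_of(condition):
            box[(times >= ev.onset) & (times < ev.onset + ev.duration)] = 1.0
        return box

    def cycle_mask(self, condition: str, times: np.ndarray | None = None,
                   cycle_s: float | None = None) -> np.ndarray:
        """Boolean mask of the condition's full cycles (block + following rest).

        ``cycle_s`` defaults to block duration plus the gap to the next event;
        trailing cycles that do not fit inside the series are dropped.
        """
        if times is None:
            times = self.frame_times()
        times = np.asarray(times, float)
        tr = float(times[1] - times[0]) if len(times) > 1 else self.tr
        span = float(times[-1]) + tr
        mask = np.zeros(len(times), dtype=bool)
        onsets = [ev.onset for ev in self.events]
        for i, ev in enumerate(self.events):
            if ev.condition != condition:
                continue
            if cycle_s is None:
                end = onsets[i + 1] if i + 1 < len(onsets) else ev.onset + ev.duration
                if i + 1 >= len(onsets):
                    end = min(span, ev.onset + ev.duration + 30.0)
            else:
                end = ev.onset + cycle_s
            if end > span + 1e-9:
                continue  # partial trailing cycle dropped
            mask |= (times >= ev.onset) & (times < end)
        return mask

    def shifted(self, shift_s: float) -> "StimulusDesign":
        """Shift all onsets earlier by ``shift_s`` (after discarding volumes).

        Events that would start before time zero are dropped.
        """
        n_shift = int(round(shift_s / self.tr))
        events = tuple(
            StimulusEvent(ev.onset - shift_s, ev.duration, ev.condition)
            for ev in self.events
            if ev.onset - shift_s >= 0
        )
        return StimulusDesign(
            tr=self.tr,
            n_volumes=self.n_volumes - n_shift,
            events=events,
            baseline_temperature=self.baseline_temperature,
            stim_temperature=self.stim_temperature,
        )
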