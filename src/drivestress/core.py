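"""Core containers shared across the pipeline.

Conventions used everywhere in this package:

* time is in seconds from session start,
* sample indices are 0-based,
* intervals are half-open ``[start, end)``,
* signal amplitudes are in mV unless a channel declares otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SCENARIOS = ("manual", "autonomous", "warmup")


@dataclass
class Channel:
    """One uniformly sampled physiological signal."""

    name: str
    unit: str
    fs_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be > 0, got {self.fs_hz}")
        if self.samples.size == 0:
            raise ValueError("channel has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"channel {self.name!r} contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    @property
    def t_s(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return np.arange(self.samples.size) / self.fs_hz

    def copy_with(self, samples: np.ndarray, name: str | None = None) -> "Channel":
        return Channel(name or self.name, self.unit, self.fs_hz, np.asarray(samples, float))


@dataclass(frozen=True)
class TrackEvent:
    """One stress-inducing task, located by its position on the track."""

    name: str
    start_km: float
    end_km: float


@dataclass
class EventSchedule:
    """Track geometry: total length, constant cruise speed and task positions.

    The constant speed makes the position -> time mapping linear:
    ``t(x) = x / speed_kmh * 3600`` seconds.
    """

    track_length_km: float
    speed_kmh: float
    events: list[TrackEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.track_length_km <= 0 or self.speed_kmh <= 0:
            raise ValueError("track length and speed must be positive")
        self.events = sorted(self.events, key=lambda e: e.start_km)
        prev_end = 0.0
        for ev in self.events:
            if not (0.0 <= ev.start_km < ev.end_km <= self.track_length_km):
                raise ValueError(f"event {ev.name!r} outside track bounds")
            if ev.start_km < prev_end:
                raise ValueError(f"event {ev.name!r} overlaps the previous event")
            prev_end = ev.end_km

    def km_to_s(self, x_km: float) -> float:
        return x_km / self.speed_kmh * 3600.0

    @property
    def duration_s(self) -> float:
        return self.km_to_s(self.track_length_km)

    @property
    def total_event_km(self) -> float:
        return sum(ev.end_km - ev.start_km for ev in self.events)

    @property
    def event_fraction(self) -> float:
        """Fraction of the track length covered by tasks."""
        return self.total_event_km / self.track_length_km

    def task_intervals_s(self) -> list[tuple[str, float, float]]:
        """Task intervals as half-open ``[start_s, end_s)`` triples."""
        return [(ev.name, self.km_to_s(ev.start_km), self.km_to_s(ev.end_km)) for ev in self.events]

    def in_task(self, t_s: np.ndarray) -> np.ndarray:
        """Boolean mask: which of the given times fall inside any task."""
        t_s = np.asarray(t_s, dtype=float)
        mask = np.zeros(t_s.shape, dtype=bool)
        for _, a, b in self.task_intervals_s():
            mask |= (t_s >= a) & (t_s < b)
        return mask

    def to_dict(self) -> dict:
        return {
            "track_length_km": self.track_length_km,
            "speed_kmh": self.speed_kmh,
            "events": [
                {"name": e.name, "start_km": e.start_km, "end_km": e.end_km} for e in self.events
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventSchedule":
        return cls(
            track_length_km=float(d["track_length_km"]),
            speed_kmh=float(d["speed_kmh"]),
            events=[TrackEvent(e["name"], float(e["start_km"]), float(e["end_km"])) for e in d["events"]],
        )


@dataclass
class SessionRecording:
    """One subject x one scenario: two hand SPR channels, up to three ECG
    channels and the track schedule the session was driven on."""

    subject_id: str
    scenario: str
    spr_left: Channel
    spr_right: Channel
    ecg: list[Channel]
    schedule: EventSchedule

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario tag {self.scenario!r}")
        if len(self.ecg) > 3:
            raise ValueError("at most 3 ECG channels are supported")
        chans = [self.spr_left, self.spr_right, *self.ecg]
        n = {c.samples.size for c in chans}
        fs = {c.fs_hz for c in chans}
        if len(n) != 1:
            raise ValueError("inconsistent channel lengths")
        if len(fs) != 1:
            raise ValueError("inconsistent channel sampling rates")

    @property
    def fs_hz(self) -> float:
        return self.spr_left.fs_hz

    @property
    def duration_s(self) -> float:
        return self.spr_left.duration_s

    @property
    def channels(self) -> list[Channel]:
        return [self.spr_left, self.spr_right, *self.ecg]


@dataclass
class SessionTruth:
    """Synthetic ground truth attached to a generated session: the
    artifact-free SPR reference, artifact intervals per hand, evoked-response
    onset times and true heart-beat times."""

    clean_spr: Channel
    artifact_intervals_left: list[tuple[float, float]]
    artifact_intervals_right: list[tuple[float, float]]
    evoked_times_s: np.ndarray
    beat_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.evoked_times_s = np.asarray(self.evoked_times_s, dtype=float)
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if self.beat_times_s.size > 1 and not np.all(np.diff(self.beat_times_s) > 0):
            raise ValueError("beat times must be strictly increasing")
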