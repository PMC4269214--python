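"""Core domain types of the day/night stress pipeline.

Every record that crosses a module boundary is one of the dataclasses below.
Validation happens at construction time: readers reject malformed inputs
instead of coercing them, so downstream code can rely on the invariants.

Missing values are represented by ``None`` throughout (never silently zero);
:class:`FeatureVector` carries them explicitly into the modeling layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date
from datetime import datetime
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "InsufficientDataError",
    "Modality",
    "CallDirection",
    "RRSession",
    "CallEvent",
    "CalendarEvent",
    "ContactsSnapshot",
    "BatterySample",
    "AccelWindow",
    "GPSSample",
    "AudioResponse",
    "PhoneDayLog",
    "SelfReport",
    "FeatureVector",
]


class ValidationError(ValueError):
    """An input violates a type invariant or operation precondition."""


class InsufficientDataError(ValidationError):
    """A series is too short for the requested statistic."""


class Modality(str, Enum):
    PHONE = "phone"
    HRV = "hrv"


class CallDirection(str, Enum):
    INCOMING = "incoming"
    OUTGOING = "outgoing"


def _require_tzaware(ts: datetime, what: str) -> None:
    if not isinstance(ts, datetime) or ts.tzinfo is None:
        raise ValidationError(f"{what} must be a timezone-aware datetime, got {ts!r}")


@dataclass(frozen=True)
class RRSession:
    """One night of beat-to-beat (RR) intervals from a chest belt.

    Parameters
    ----------
    subject_id : str
        Stable identifier of the wearer.
    start_time : datetime
        Timezone-aware timestamp of the first beat.
    rr_ms : ndarray
        Ordered RR intervals in milliseconds, all strictly positive.
    """

    subject_id: str
    start_time: datetime
    rr_ms: np.ndarray

    def __post_init__(self) -> None:
        _require_tzaware(self.start_time, "RRSession.start_time")
        rr = np.asarray(self.rr_ms, dtype=float)
        if rr.ndim != 1 or rr.size < 1:
            raise ValidationError("rr_ms must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(rr)) or np.any(rr <= 0):
            raise ValidationError("all RR intervals must be finite and > 0 ms")
        object.__setattr__(self, "rr_ms", rr)

    @property
    def duration_s(self) -> float:
        return float(self.rr_ms.sum() / 1000.0)

    @property
    def end_time(self) -> datetime:
        from datetime import timedelta

        return self.start_time + timedelta(seconds=self.duration_s)


@dataclass(frozen=True)
class CallEvent:
    timestamp: datetime
    direction: CallDirection
    duration_s: float

    def __post_init__(self) -> None:
        _require_tzaware(self.timestamp, "CallEvent.timestamp")
        object.__setattr__(self, "direction", CallDirection(self.direction))
        if self.duration_s < 0:
            raise ValidationError("call duration must be >= 0 s")


@dataclass(frozen=True)
class CalendarEvent:
    start: datetime
    end: datetime
    note_size: int = 0

    def __post_init__(self) -> None:
        _require_tzaware(self.start, "CalendarEvent.start")
        _require_tzaware(self.end, "CalendarEvent.end")
        if self.end < self.start:
            raise ValidationError("calendar event end precedes start")
        if self.note_size < 0:
            raise ValidationError("note_size must be >= 0")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass(frozen=True)
class ContactsSnapshot:
    timestamp: datetime
    n_contacts: int
    n_phone_numbers: int
    n_emails: int

    def __post_init__(self) -> None:
        _require_tzaware(self.timestamp, "ContactsSnapshot.timestamp")
        for name in ("n_contacts", "n_phone_numbers", "n_emails"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class BatterySample:
    timestamp: datetime
    level: float
    charging: bool

    def __post_init__(self) -> None:
        _require_tzaware(self.timestamp, "BatterySample.timestamp")
        if not 0.0 <= self.level <= 1.0:
            raise ValidationError("battery level must lie in [0, 1]")


@dataclass(frozen=True)
class AccelWindow:
    """A short burst of 3-axis accelerometer samples, in units of g."""

    timestamp: datetime
    samples: np.ndarray

    def __post_init__(self) -> None:
        _require_tzaware(self.timestamp, "AccelWindow.timestamp")
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] != 3:
            raise ValidationError("accel samples must be a non-empty (n, 3) array")
        object.__setattr__(self, "samples", arr)


@dataclass(frozen=True)
class GPSSample:
    timestamp: datetime
    lat: float
    lon: float

    def __post_init__(self) -> None:
        _require_tzaware(self.timestamp, "GPSSample.timestamp")
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"longitude {self.lon} outside [-180, 180]")


@dataclass(frozen=True)
class AudioResponse:
    """A voice-message recording, mono float samples in [-1, 1]."""

    timestamp: datetime
    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        _require_tzaware(self.timestamp, "AudioResponse.timestamp")
        if int(self.sample_rate) <= 0:
            raise ValidationError("sample_rate must be a positive integer")
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1:
            raise ValidationError("audio samples must be 1-D")
        if arr.size and (np.nanmax(np.abs(arr)) > 1.0 + 1e-9):
            raise ValidationError("audio samples must lie in [-1, 1]")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class PhoneDayLog:
    """All smartphone events logged for one subject on one civil day.

    Event lists are kept sorted by timestamp. Timestamps must fall on the
    stated local date, except contacts snapshots, which include the previous
    day's snapshot so that day-over-day deltas can be computed.
    """

    subject_id: str
    date: _date
    calls: list[CallEvent] = field(default_factory=list)
    calendar: list[CalendarEvent] = field(default_factory=list)
    contacts: list[ContactsSnapshot] = field(default_factory=list)
    battery: list[BatterySample] = field(default_factory=list)
    accel: list[AccelWindow] = field(default_factory=list)
    gps: list[GPSSample] = field(default_factory=list)
    audio: list[AudioResponse] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = sorted(self.calls, key=lambda e: e.timestamp)
        self.calendar = sorted(self.calendar, key=lambda e: e.start)
        self.contacts = sorted(self.contacts, key=lambda e: e.timestamp)
        self.battery = sorted(self.battery, key=lambda e: e.timestamp)
        self.accel = sorted(self.accel, key=lambda e: e.timestamp)
        self.gps = sorted(self.gps, key=lambda e: e.timestamp)
        self.audio = sorted(self.audio, key=lambda e: e.timestamp)
        # timestamps carry the subject's own UTC offset, so the local civil
        # date is simply the date of the timestamp as written
        for name in ("calls", "battery", "accel", "gps", "audio"):
            for ev in getattr(self, name):
                if ev.timestamp.date() != self.date:
                    raise ValidationError(
                        f"{name} event at {ev.timestamp.isoformat()} outside "
                        f"log date {self.date.isoformat()}"
                    )


@dataclass(frozen=True)
class SelfReport:
    """End-of-day self-assessed stress in [0, 1], optional relative sliders."""

    subject_id: str
    date: _date
    stress_score: float
    rel_yesterday: float | None = None
    rel_lastweek: float | None = None

    def __post_init__(self) -> None:
        for name in ("stress_score", "rel_yesterday", "rel_lastweek"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")


@dataclass
class FeatureVector:
    """Named feature → value mapping with a modality tag.

    Missing features are stored as ``None`` and are never replaced by zero;
    the modeling layer decides how to handle them (rows with missing selected
    features are dropped per model).
    """

    modality: Modality
    values: dict[str, float | None]

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        clean: dict[str, float | None] = {}
        for k, v in self.values.items():
            if k in clean:
                raise ValidationError(f"duplicate feature name {k!r}")
            if v is None or (isinstance(v, float) and np.isnan(v)):
                clean[k] = None
            else:
                clean[k] = float(v)
        self.values = clean

    def __getitem__(self, name: str) -> float | None:
        return self.values[name]

    def names(self) -> list[str]:
        return list(self.values)

    def present(self) -> dict[str, float]:
        return {k: v for k, v in self.values.items() if v is not None}


def sorted_by_time(events: Sequence, key: str = "timestamp") -> list:
    """Return events sorted non-decreasingly by their timestamp attribute."""
    return sorted(events, key=lambda e: getattr(e, key))
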