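"""Readers and writers for every external format the pipeline touches.

* RR sessions: plain text, one interval in milliseconds per line, ``#``
  comments; subject and start time come from a JSON sidecar or the caller.
* Phone-day logs: one JSON document per subject-day (audio entries
  reference WAV files relative to the document).
* Audio: 16-bit PCM mono WAV via the stdlib ``wave`` module.
* GPS: also importable from CSV with columns timestamp,lat,lon.
* Feature tables: CSV with one row per subject-day; missing values are
  written as empty fields, never as zeros, and values round-trip to 12
  significant digits.
* Self-reports: CSV with subject_id,date,stress_score.
* Fitted models: JSON (see ``StressLogitResults.to_dict``).

Readers validate rather than coerce: a malformed line or an
invariant-violating value raises with the offending location.
"""

from __future__ import annotations

import json
import logging
import wave
from datetime import date as _date
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    AccelWindow,
    AudioResponse,
    BatterySample,
    CalendarEvent,
    CallEvent,
    ContactsSnapshot,
    FeatureVector,
    GPSSample,
    PhoneDayLog,
    RRSession,
    SelfReport,
    ValidationError,
)

__all__ = [
    "read_rr_session",
    "write_rr_session",
    "read_phone_day",
    "write_phone_day",
    "read_wav",
    "write_wav",
    "read_gps_csv",
    "write_feature_table",
    "read_feature_table",
    "read_self_reports",
    "write_self_reports",
]

logger = logging.getLogger("stresspipe")

_PHONE_DAY_KEYS = {
    "subject_id",
    "date",
    "calls",
    "calendar",
    "contacts",
    "battery",
    "accel",
    "gps",
    "audio",
}


def _parse_ts(value: str, where: str) -> datetime:
    try:
        ts = datetime.fromisoformat(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"malformed timestamp {value!r} in {where}") from exc
    if ts.tzinfo is None:
        raise ValidationError(f"timestamp {value!r} in {where} lacks a timezone")
    return ts


# --------------------------------------------------------------------------
# RR sessions
# --------------------------------------------------------------------------
def read_rr_session(
    path: str | Path,
    subject_id: str | None = None,
    start_time: datetime | None = None,
) -> RRSession:
    """Read a plain-text RR file (one ms value per line, '#' comments).

    Subject and start time default to a JSON sidecar ``<path>.json`` with
    keys ``subject_id`` and ``start_time`` (ISO-8601 with timezone).
    """
    path = Path(path)
    if subject_id is None or start_time is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValidationError(
                f"no metadata: pass subject_id/start_time or provide {sidecar}"
            )
        meta = json.loads(sidecar.read_text())
        subject_id = subject_id or meta["subject_id"]
        start_time = start_time or _parse_ts(meta["start_time"], str(sidecar))
    rr: list[float] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        try:
            value = float(stripped)
        except ValueError as exc:
            raise ValidationError(
                f"{path}:{lineno}: non-numeric RR value {stripped!r}"
            ) from exc
        if value <= 0:
            raise ValidationError(f"{path}:{lineno}: non-positive RR interval {value}")
        rr.append(value)
    if not rr:
        raise ValidationError(f"{path}: no RR intervals found")
    return RRSession(subject_id=subject_id, start_time=start_time, rr_ms=np.array(rr))


def write_rr_session(session: RRSession, path: str | Path) -> None:
    """Write the RR text file plus its metadata sidecar."""
    path = Path(path)
    lines = [f"# subject: {session.subject_id}"]
    lines += [format(v, ".12g") for v in session.rr_ms]
    path.write_text("\n".join(lines) + "\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "subject_id": session.subject_id,
                "start_time": session.start_time.isoformat(),
            },
            indent=2,
        )
    )


# --------------------------------------------------------------------------
# WAV audio
# --------------------------------------------------------------------------
def read_wav(path: str | Path, timestamp: datetime) -> AudioResponse:
    """Read 16-bit PCM mono WAV into float samples in [-1, 1]."""
    with wave.open(str(path), "rb") as wf:
        if wf.getnchannels() != 1 or wf.getsampwidth() != 2:
            raise ValidationError(f"{path}: expected 16-bit PCM mono WAV")
        sr = wf.getframerate()
        raw = wf.readframes(wf.getnframes())
    samples = np.frombuffer(raw, dtype="<i2").astype(float) / 32768.0
    return AudioResponse(timestamp=timestamp, samples=samples, sample_rate=sr)


def write_wav(audio: AudioResponse, path: str | Path) -> None:
    """Write float samples in [-1, 1] as 16-bit PCM mono WAV."""
    ints = np.clip(np.round(audio.samples * 32768.0), -32768, 32767).astype("<i2")
    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(1)
        wf.setsampwidth(2)
        wf.setframerate(audio.sample_rate)
        wf.writeframes(ints.tobytes())


# --------------------------------------------------------------------------
# phone-day JSON
# --------------------------------------------------------------------------
def read_phone_day(path: str | Path) -> PhoneDayLog:
    """Read one subject-day of phone events from a JSON document.

    Unknown top-level keys are ignored with a logged warning; missing
    required keys raise. Event lists come back sorted by timestamp.
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    missing = {"subject_id", "date"} - set(doc)
    if missing:
        raise ValidationError(f"{path}: missing required keys {sorted(missing)}")
    unknown = set(doc) - _PHONE_DAY_KEYS
    if unknown:
        logger.warning("%s: ignoring unknown keys %s", path, sorted(unknown))
    day = _date.fromisoformat(doc["date"])
    where = str(path)

    calls = [
        CallEvent(
            timestamp=_parse_ts(e["timestamp"], where),
            direction=e["direction"],
            duration_s=float(e["duration_s"]),
        )
        for e in doc.get("calls", [])
    ]
    calendar = [
        CalendarEvent(
            start=_parse_ts(e["start"], where),
            end=_parse_ts(e["end"], where),
            note_size=int(e.get("note_size", 0)),
        )
        for e in doc.get("calendar", [])
    ]
    contacts = [
        ContactsSnapshot(
            timestamp=_parse_ts(e["timestamp"], where),
            n_contacts=int(e["n_contacts"]),
            n_phone_numbers=int(e["n_phone_numbers"]),
            n_emails=int(e["n_emails"]),
        )
        for e in doc.get("contacts", [])
    ]
    battery = [
        BatterySample(
            timestamp=_parse_ts(e["timestamp"], where),
            level=float(e["level"]),
            charging=bool(e["charging"]),
        )
        for e in doc.get("battery", [])
    ]
    accel = [
        AccelWindow(
            timestamp=_parse_ts(e["timestamp"], where),
            samples=np.asarray(e["samples"], float),
        )
        for e in doc.get("accel", [])
    ]
    gps = [
        GPSSample(
            timestamp=_parse_ts(e["timestamp"], where),
            lat=float(e["lat"]),
            lon=float(e["lon"]),
        )
        for e in doc.get("gps", [])
    ]
    audio = [
        read_wav(path.parent / e["wav"], _parse_ts(e["timestamp"], where))
        for e in doc.get("audio", [])
    ]
    return PhoneDayLog(
        subject_id=doc["subject_id"],
        date=day,
        calls=calls,
        calendar=calendar,
        contacts=contacts,
        battery=battery,
        accel=accel,
        gps=gps,
        audio=audio,
    )


def write_phone_day(log: PhoneDayLog, path: str | Path, audio_dir: str = "audio") -> None:
    """Write a phone-day log as JSON; audio goes to WAV files alongside."""
    path = Path(path)
    doc: dict = {"subject_id": log.subject_id, "date": log.date.isoformat()}
    doc["calls"] = [
        {
            "timestamp": c.timestamp.isoformat(),
            "direction": c.direction.value,
            "duration_s": c.duration_s,
        }
        for c in log.calls
    ]
    doc["calendar"] = [
        {"start": e.start.isoformat(), "end": e.end.isoformat(), "note_size": e.note_size}
        for e in log.calendar
    ]
    doc["contacts"] = [
        {
            "timestamp": s.timestamp.isoformat(),
            "n_contacts": s.n_contacts,
            "n_phone_numbers": s.n_phone_numbers,
            "n_emails": s.n_emails,
        }
        for s in log.contacts
    ]
    doc["battery"] = [
        {"timestamp": b.timestamp.isoformat(), "level": b.level, "charging": b.charging}
        for b in log.battery
    ]
    doc["accel"] = [
        {"timestamp": w.timestamp.isoformat(), "samples": w.samples.tolist()}
        for w in log.accel
    ]
    doc["gps"] = [
        {"timestamp": p.timestamp.isoformat(), "lat": p.lat, "lon": p.lon}
        for p in log.gps
    ]
    doc["audio"] = []
    if log.audio:
        adir = path.parent / audio_dir
        adir.mkdir(parents=True, exist_ok=True)
        for i, a in enumerate(log.audio):
            wav_rel = f"{audio_dir}/{log.subject_id}_{log.date.isoformat()}_{i}.wav"
            write_wav(a, path.parent / wav_rel)
            doc["audio"].append({"timestamp": a.timestamp.isoformat(), "wav": wav_rel})
    path.write_text(json.dumps(doc, indent=1))


def read_gps_csv(path: str | Path) -> list[GPSSample]:
    """Read a GPS track from CSV with columns timestamp,lat,lon."""
    df = pd.read_csv(path)
    required = {"timestamp", "lat", "lon"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: GPS CSV needs columns {sorted(required)}")
    return [
        GPSSample(
            timestamp=_parse_ts(str(row.timestamp), str(path)),
            lat=float(row.lat),
            lon=float(row.lon),
        )
        for row in df.itertuples()
    ]


# --------------------------------------------------------------------------
# feature tables and reports
# --------------------------------------------------------------------------
def write_feature_table(rows, path: str | Path) -> None:
    """Write (subject_id, date, FeatureVector, label) rows as CSV.

    All rows must share one feature-name set per modality; missing values
    become empty fields. Values survive a round-trip to 12 significant
    digits.
    """
    rows = list(rows)
    if not rows:
        raise ValidationError("no rows to write")
    names_by_modality: dict = {}
    for _, _, fv, _ in rows:
        ref = names_by_modality.setdefault(fv.modality, fv.names())
        if fv.names() != ref:
            raise ValidationError(
                f"inconsistent feature names for modality {fv.modality}"
            )
    all_names: list[str] = []
    for names in names_by_modality.values():
        all_names.extend(names)
    with open(path, "w") as fh:
        fh.write("subject_id,date," + ",".join(all_names) + ",stress_score\n")
        for subject_id, day, fv, label in rows:
            cells = [subject_id, day.isoformat() if hasattr(day, "isoformat") else str(day)]
            for name in all_names:
                v = fv.values.get(name)
                cells.append("" if v is None else format(v, ".12g"))
            cells.append("" if label is None else format(float(label), ".12g"))
            fh.write(",".join(cells) + "\n")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV into a DataFrame (NaN marks missing)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "subject_id" not in df.columns or "date" not in df.columns:
        raise ValidationError(f"{path}: feature table needs subject_id and date")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def read_self_reports(path: str | Path) -> list[SelfReport]:
    """Read self-report CSV (subject_id,date,stress_score[,rel_yesterday,rel_lastweek])."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    out = []
    for row in df.itertuples():
        out.append(
            SelfReport(
                subject_id=row.subject_id,
                date=_date.fromisoformat(str(row.date)),
                stress_score=float(row.stress_score),
                rel_yesterday=float(row.rel_yesterday)
                if hasattr(row, "rel_yesterday") and pd.notna(row.rel_yesterday)
                else None,
                rel_lastweek=float(row.rel_lastweek)
                if hasattr(row, "rel_lastweek") and pd.notna(row.rel_lastweek)
                else None,
            )
        )
    return out


def write_self_reports(reports: list[SelfReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("subject_id,date,stress_score\n")
        for r in reports:
            fh.write(f"{r.subject_id},{r.date.isoformat()},{r.stress_score:.12g}\n")
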