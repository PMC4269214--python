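"""Daytime smartphone behavioral features.

One :class:`~stresspipe.types.PhoneDayLog` is reduced to 19 named features
covering social interaction (calls, calendar, address-book deltas, battery
usage), physical activity (accelerometer magnitude, GPS distance, number of
visited locations via DBSCAN) and the voice responses (length and RMS
energy). Two anonymization procedures mirror what the collection app does
before upload: audio chunks are permuted within each second (destroys
intelligibility, preserves energy) and GPS tracks are shifted so the
centroid of the visited locations becomes the origin.

All aggregates that would divide by zero yield explicit missing values
(``None``) rather than exceptions; an empty log is a valid input.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import DBSCAN

from .config import PipelineConfig
from .types import (
    AudioResponse,
    BatterySample,
    CalendarEvent,
    CallDirection,
    CallEvent,
    ContactsSnapshot,
    FeatureVector,
    GPSSample,
    Modality,
    PhoneDayLog,
    ValidationError,
)

__all__ = [
    "PHONE_FEATURES",
    "EARTH_RADIUS_M",
    "anonymize_audio",
    "audio_basic_features",
    "call_features",
    "calendar_features",
    "contacts_delta",
    "battery_ratio",
    "accel_features",
    "gps_distance",
    "cluster_locations",
    "anonymize_gps",
    "extract_phone_features",
]

#: canonical order of the 19 phone features
PHONE_FEATURES = [
    "n_calls",
    "sum_call_s",
    "mean_call_s",
    "var_call_s",
    "in_out_ratio",
    "n_cal_events",
    "cal_total_s",
    "cal_mean_s",
    "cal_note_mean_chars",
    "d_contacts",
    "d_phone_numbers",
    "d_emails",
    "battery_ratio",
    "accel_mag_mean_g",
    "accel_mag_var_g2",
    "gps_distance_m",
    "n_locations",
    "audio_length_s",
    "speech_energy",
]

EARTH_RADIUS_M = 6_371_000.0


# --------------------------------------------------------------------------
# audio
# --------------------------------------------------------------------------
def anonymize_audio(audio: AudioResponse, chunk_ms: int = 50, seed: int = 0) -> AudioResponse:
    """Permute fixed-size chunks within every 1-second window.

    ``chunk_ms`` must divide 1000. The permutation is drawn per window from
    a seeded generator, so the output is deterministic; the sample multiset,
    total length and RMS energy are conserved exactly. A trailing partial
    chunk stays in place.
    """
    if 1000 % chunk_ms != 0:
        raise ValidationError(f"chunk_ms={chunk_ms} must divide 1000")
    rng = np.random.default_rng(seed)
    sr = audio.sample_rate
    chunk_n = max(1, sr * chunk_ms // 1000)
    out = audio.samples.copy()
    for w0 in range(0, out.size, sr):
        window = out[w0 : w0 + sr]
        n_full = window.size // chunk_n
        if n_full > 1:
            chunks = window[: n_full * chunk_n].reshape(n_full, chunk_n)
            window[: n_full * chunk_n] = chunks[rng.permutation(n_full)].ravel()
    return AudioResponse(timestamp=audio.timestamp, samples=out, sample_rate=sr)


def audio_basic_features(audio: AudioResponse) -> tuple[float, float]:
    """(length in seconds, RMS speech energy) of one recording."""
    length = audio.samples.size / audio.sample_rate
    energy = float(np.sqrt(np.mean(audio.samples**2))) if audio.samples.size else 0.0
    return length, energy


# --------------------------------------------------------------------------
# social interaction
# --------------------------------------------------------------------------
def call_features(calls: list[CallEvent]) -> dict[str, float | None]:
    """Count, total/mean/variance of duration, and incoming/outgoing ratio.

    Variance is the population variance. With no calls the mean, variance
    and ratio are missing; with no outgoing calls the ratio is missing.
    """
    n = len(calls)
    if n == 0:
        return {
            "n_calls": 0.0,
            "sum_call_s": 0.0,
            "mean_call_s": None,
            "var_call_s": None,
            "in_out_ratio": None,
        }
    durations = np.array([c.duration_s for c in calls], float)
    n_in = sum(c.direction is CallDirection.INCOMING for c in calls)
    n_out = n - n_in
    return {
        "n_calls": float(n),
        "sum_call_s": float(durations.sum()),
        "mean_call_s": float(durations.mean()),
        "var_call_s": float(durations.var()),
        "in_out_ratio": n_in / n_out if n_out > 0 else None,
    }


def calendar_features(events: list[CalendarEvent]) -> dict[str, float | None]:
    """Count, total and mean event time, mean note size in characters.

    Overlapping events are counted independently (no merging)."""
    n = len(events)
    if n == 0:
        return {
            "n_cal_events": 0.0,
            "cal_total_s": 0.0,
            "cal_mean_s": None,
            "cal_note_mean_chars": None,
        }
    durations = np.array([e.duration_s for e in events], float)
    notes = np.array([e.note_size for e in events], float)
    return {
        "n_cal_events": float(n),
        "cal_total_s": float(durations.sum()),
        "cal_mean_s": float(durations.mean()),
        "cal_note_mean_chars": float(notes.mean()),
    }


def contacts_delta(
    today: ContactsSnapshot | None, previous: ContactsSnapshot | None
) -> dict[str, float | None]:
    """Relative day-over-day change of contacts / phone numbers / e-mails.

    Each delta is (today - previous) / previous; a zero previous count (or a
    missing snapshot) makes the corresponding feature missing."""
    out: dict[str, float | None] = {
        "d_contacts": None,
        "d_phone_numbers": None,
        "d_emails": None,
    }
    if today is None or previous is None:
        return out
    for key, attr in (
        ("d_contacts", "n_contacts"),
        ("d_phone_numbers", "n_phone_numbers"),
        ("d_emails", "n_emails"),
    ):
        prev = getattr(previous, attr)
        if prev > 0:
            out[key] = (getattr(today, attr) - prev) / prev
    return out


def battery_ratio(samples: list[BatterySample]) -> float | None:
    """Seconds not charging / seconds charging, from a piecewise-constant
    reconstruction of the charging state between samples.

    Missing with fewer than two samples or zero charging time; 0.0 when the
    phone charged the whole time."""
    if len(samples) < 2:
        return None
    samples = sorted(samples, key=lambda s: s.timestamp)
    charging_s = 0.0
    idle_s = 0.0
    for a, b in zip(samples[:-1], samples[1:]):
        dt = (b.timestamp - a.timestamp).total_seconds()
        if a.charging:
            charging_s += dt
        else:
            idle_s += dt
    if charging_s <= 0:
        return None
    return idle_s / charging_s


# --------------------------------------------------------------------------
# physical activity
# --------------------------------------------------------------------------
def accel_features(windows: list) -> tuple[float | None, float | None]:
    """Mean and population variance of the acceleration magnitude, pooled
    over all windows of the day."""
    if not windows:
        return None, None
    mags = np.concatenate([np.linalg.norm(w.samples, axis=1) for w in windows])
    return float(mags.mean()), float(mags.var())


def _haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


def gps_distance(track: list[GPSSample]) -> float:
    """Total haversine distance (m) along the time-sorted track."""
    if len(track) < 2:
        return 0.0
    lat = np.array([p.lat for p in track])
    lon = np.array([p.lon for p in track])
    return float(np.sum(_haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])))


def cluster_locations(
    track: list[GPSSample], eps_m: float = 100.0, min_pts: int = 5
) -> int:
    """Number of visited locations: DBSCAN clusters under haversine distance
    (noise points excluded)."""
    if eps_m <= 0 or min_pts < 1:
        raise ValidationError("eps_m must be > 0 and min_pts >= 1")
    if not track:
        return 0
    coords = np.radians([[p.lat, p.lon] for p in track])
    labels = DBSCAN(
        eps=eps_m / EARTH_RADIUS_M, min_samples=min_pts, metric="haversine"
    ).fit_predict(coords)
    return int(len(set(labels) - {-1}))


def _cluster_centroids(
    track: list[GPSSample], eps_m: float, min_pts: int
) -> np.ndarray:
    if not track:
        return np.empty((0, 2))
    coords = np.array([[p.lat, p.lon] for p in track])
    labels = DBSCAN(
        eps=eps_m / EARTH_RADIUS_M, min_samples=min_pts, metric="haversine"
    ).fit_predict(np.radians(coords))
    cents = [coords[labels == k].mean(axis=0) for k in sorted(set(labels) - {-1})]
    return np.array(cents) if cents else np.empty((0, 2))


def anonymize_gps(
    track: list[GPSSample], cluster_centroids: np.ndarray | None = None,
    eps_m: float = 100.0, min_pts: int = 5,
) -> list[GPSSample]:
    """Shift the track so the centroid of the visited-location centroids is
    the coordinate origin (track centroid when no cluster exists).

    Latitude is translated; longitude offsets are additionally scaled by
    cos(centroid latitude) into the local equirectangular frame, so that
    near the new origin the pairwise haversine distances of a day-scale
    track are preserved to first order (a plain translation toward the
    equator would stretch east-west distances by 1/cos(lat))."""
    if not track:
        return []
    if cluster_centroids is None:
        cluster_centroids = _cluster_centroids(track, eps_m, min_pts)
    cents = np.asarray(cluster_centroids, float)
    if cents.size:
        ref = cents.mean(axis=0)
    else:
        ref = np.array([[p.lat, p.lon] for p in track]).mean(axis=0)
    coslat = np.cos(np.radians(ref[0]))
    return [
        GPSSample(
            timestamp=p.timestamp,
            lat=p.lat - ref[0],
            lon=(p.lon - ref[1]) * coslat,
        )
        for p in track
    ]


# --------------------------------------------------------------------------
# full battery
# --------------------------------------------------------------------------
def extract_phone_features(
    daylog: PhoneDayLog, config: PipelineConfig | None = None
) -> FeatureVector:
    """All 19 phone features for one subject-day.

    Audio features are the mean over the day's (up to four) voice responses;
    the contacts deltas compare the last snapshot of the day against the
    most recent earlier snapshot. Undefined features are marked missing.
    """
    cfg = config or PipelineConfig()
    values: dict[str, float | None] = dict.fromkeys(PHONE_FEATURES)
    values.update(call_features(daylog.calls))
    values.update(calendar_features(daylog.calendar))

    today_snap = prev_snap = None
    if daylog.contacts:
        snaps = sorted(daylog.contacts, key=lambda s: s.timestamp)
        today_snap = snaps[-1]
        earlier = [s for s in snaps if s.timestamp < today_snap.timestamp]
        prev_snap = earlier[-1] if earlier else None
    values.update(contacts_delta(today_snap, prev_snap))

    values["battery_ratio"] = battery_ratio(daylog.battery)
    mean_g, var_g2 = accel_features(daylog.accel)
    values["accel_mag_mean_g"] = mean_g
    values["accel_mag_var_g2"] = var_g2
    values["gps_distance_m"] = gps_distance(daylog.gps)
    values["n_locations"] = float(
        cluster_locations(daylog.gps, cfg.dbscan_eps_m, cfg.dbscan_min_pts)
    )
    if daylog.audio:
        pairs = [audio_basic_features(a) for a in daylog.audio]
        values["audio_length_s"] = float(np.mean([p[0] for p in pairs]))
        values["speech_energy"] = float(np.mean([p[1] for p in pairs]))
    return FeatureVector(modality=Modality.PHONE, values=values)
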