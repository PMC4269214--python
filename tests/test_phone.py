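"""Smartphone feature extraction and the anonymization procedures."""

from datetime import date, datetime, timedelta, timezone

import numpy as np
import pytest

from stresspipe.phone import (
    EARTH_RADIUS_M,
    PHONE_FEATURES,
    accel_features,
    anonymize_audio,
    anonymize_gps,
    audio_basic_features,
    battery_ratio,
    calendar_features,
    call_features,
    cluster_locations,
    contacts_delta,
    extract_phone_features,
    gps_distance,
)
from stresspipe.synth import DayParams, generate_phone_day
from stresspipe.types import (
    AccelWindow,
    AudioResponse,
    BatterySample,
    CalendarEvent,
    CallDirection,
    CallEvent,
    ContactsSnapshot,
    GPSSample,
    PhoneDayLog,
    ValidationError,
)

from .oracles import dbscan_direct

TZ = timezone(timedelta(hours=2))
T0 = datetime(2012, 6, 4, 9, 0, tzinfo=TZ)


def _audio(samples, sr=8000):
    return AudioResponse(timestamp=T0, samples=np.asarray(samples, float), sample_rate=sr)


class TestAudio:
    def test_permutation_conserves_multiset(self, rng):
        a = _audio(rng.uniform(-1, 1, 3 * 8000))
        out = anonymize_audio(a, chunk_ms=50, seed=4)
        assert out.samples.size == a.samples.size
        assert np.array_equal(np.sort(out.samples), np.sort(a.samples))

    def test_single_chunk_is_identity(self, rng):
        a = _audio(rng.uniform(-1, 1, 8000))
        out = anonymize_audio(a, chunk_ms=1000, seed=1)
        assert np.array_equal(out.samples, a.samples)

    def test_deterministic_and_energy_preserving(self, rng):
        a = _audio(rng.uniform(-1, 1, 2 * 8000))
        out1 = anonymize_audio(a, chunk_ms=250, seed=9)
        out2 = anonymize_audio(a, chunk_ms=250, seed=9)
        assert np.array_equal(out1.samples, out2.samples)
        rms = lambda s: np.sqrt(np.mean(s**2))
        assert rms(out1.samples) == pytest.approx(rms(a.samples), abs=1e-12)
        assert not np.array_equal(out1.samples, a.samples)

    def test_bad_chunk_size(self):
        with pytest.raises(ValidationError):
            anonymize_audio(_audio(np.zeros(8000)), chunk_ms=300)

    @pytest.mark.parametrize(
        "samples, sr, length, energy",
        [
            (np.zeros(16000), 16000, 1.0, 0.0),
            (np.full(8000, 0.25), 8000, 1.0, 0.25),
        ],
    )
    def test_basic_features(self, samples, sr, length, energy):
        got = audio_basic_features(_audio(samples, sr))
        assert got == (pytest.approx(length), pytest.approx(energy))


class TestCalls:
    def _call(self, direction, dur, minute=0):
        return CallEvent(T0 + timedelta(minutes=minute), direction, dur)

    def test_worked_example(self):
        calls = [
            self._call(CallDirection.INCOMING, 60, 0),
            self._call(CallDirection.OUTGOING, 120, 1),
            self._call(CallDirection.INCOMING, 300, 2),
        ]
        f = call_features(calls)
        assert f["n_calls"] == 3
        assert f["sum_call_s"] == 480
        assert f["mean_call_s"] == 160
        assert f["in_out_ratio"] == 2.0
        assert f["var_call_s"] == pytest.approx(np.var([60, 120, 300]))

    def test_empty(self):
        f = call_features([])
        assert f["n_calls"] == 0 and f["sum_call_s"] == 0
        assert f["mean_call_s"] is None and f["in_out_ratio"] is None

    def test_equal_durations_zero_variance(self):
        calls = [self._call(CallDirection.OUTGOING, 90, m) for m in range(4)]
        assert call_features(calls)["var_call_s"] == 0.0

    def test_no_outgoing_ratio_missing(self):
        assert call_features([self._call(CallDirection.INCOMING, 10)])["in_out_ratio"] is None


class TestCalendarContacts:
    def test_calendar_example(self):
        evs = [
            CalendarEvent(T0, T0 + timedelta(seconds=1800), note_size=0),
            CalendarEvent(T0, T0 + timedelta(seconds=1800), note_size=100),
        ]
        f = calendar_features(evs)
        assert f["cal_total_s"] == 3600 and f["cal_mean_s"] == 1800
        assert f["cal_note_mean_chars"] == 50

    def test_calendar_empty(self):
        f = calendar_features([])
        assert (f["n_cal_events"], f["cal_total_s"]) == (0, 0)
        assert f["cal_mean_s"] is None and f["cal_note_mean_chars"] is None

    def test_contacts_delta(self):
        prev = ContactsSnapshot(T0 - timedelta(days=1), 100, 120, 80)
        today = ContactsSnapshot(T0, 110, 120, 80)
        d = contacts_delta(today, prev)
        assert d["d_contacts"] == pytest.approx(0.10)
        assert d["d_phone_numbers"] == 0.0 and d["d_emails"] == 0.0

    def test_contacts_zero_previous_missing(self):
        prev = ContactsSnapshot(T0 - timedelta(days=1), 0, 10, 10)
        today = ContactsSnapshot(T0, 5, 10, 10)
        assert contacts_delta(today, prev)["d_contacts"] is None

    def test_contacts_missing_previous(self):
        today = ContactsSnapshot(T0, 5, 10, 10)
        assert all(v is None for v in contacts_delta(today, None).values())


class TestBattery:
    def _samples(self, pattern):
        # pattern: list of (hours_from_start, charging)
        return [
            BatterySample(T0 + timedelta(hours=h), 0.5, charging) for h, charging in pattern
        ]

    def test_worked_example(self):
        # 8 h not charging then 2 h charging
        s = self._samples([(0, False), (8, True), (10, True)])
        assert battery_ratio(s) == pytest.approx(4.0)

    def test_all_charging(self):
        s = self._samples([(0, True), (1, True), (2, True)])
        assert battery_ratio(s) == 0.0

    def test_never_charging_missing(self):
        s = self._samples([(0, False), (5, False)])
        assert battery_ratio(s) is None

    def test_single_sample_missing(self):
        assert battery_ratio(self._samples([(0, True)])) is None


class TestActivity:
    def test_accel_gravity_only(self):
        w = AccelWindow(T0, np.tile([0.0, 0.0, 1.0], (10, 1)))
        assert accel_features([w]) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_accel_example_and_order_invariance(self):
        w1 = AccelWindow(T0, np.array([[0.0, 0.0, 1.0]]))
        w2 = AccelWindow(T0 + timedelta(minutes=5), np.array([[0.0, 0.0, 3.0]]))
        assert accel_features([w1, w2]) == (pytest.approx(2.0), pytest.approx(1.0))
        assert accel_features([w2, w1]) == accel_features([w1, w2])

    def test_gps_distance_closed_form(self):
        a = GPSSample(T0, 47.00, 8.50)
        b = GPSSample(T0 + timedelta(minutes=1), 47.01, 8.50)
        # 0.01 degree of latitude = R * 0.01 * pi/180 = 1111.9 m
        assert gps_distance([a, b]) == pytest.approx(1111.9, abs=0.5)

    def test_gps_identical_points_and_symmetry(self):
        pts = [GPSSample(T0 + timedelta(minutes=i), 47.0 + 0.001 * i, 8.5) for i in range(5)]
        pts.insert(2, GPSSample(pts[1].timestamp + timedelta(seconds=1), pts[1].lat, pts[1].lon))
        fwd = gps_distance(pts)
        assert gps_distance(list(reversed(pts))) == pytest.approx(fwd)

    def test_dbscan_two_clusters_matches_oracle(self, rng):
        base = []
        truth_pts = []
        for center in ((47.37, 8.54), (47.415, 8.54)):  # ~5 km apart
            for i in range(6):
                dlat = rng.normal(0, 10 / 111_000)
                dlon = rng.normal(0, 10 / 111_000)
                base.append(
                    GPSSample(T0 + timedelta(minutes=len(base)), center[0] + dlat, center[1] + dlon)
                )
                truth_pts.append(
                    [
                        (center[0] + dlat) * np.pi / 180 * EARTH_RADIUS_M,
                        (center[1] + dlon) * np.pi / 180 * EARTH_RADIUS_M * np.cos(np.radians(47.4)),
                    ]
                )
        n = cluster_locations(base, eps_m=100, min_pts=5)
        assert n == 2
        assert n == dbscan_direct(truth_pts, eps=100, min_pts=5)

    def test_dbscan_degenerate_cases(self):
        tight = [GPSSample(T0 + timedelta(minutes=i), 47.0, 8.5) for i in range(6)]
        assert cluster_locations(tight, 100, 5) == 1
        scattered = [
            GPSSample(T0 + timedelta(minutes=i), 47.0 + 0.1 * i, 8.5) for i in range(3)
        ]
        assert cluster_locations(scattered, 100, 5) == 0
        assert cluster_locations([], 100, 5) == 0

    def test_anonymize_gps_zero_centroid_and_distance(self, rng):
        pts = [
            GPSSample(T0 + timedelta(minutes=i), 47.37 + rng.normal(0, 1e-4), 8.55 + rng.normal(0, 1e-4))
            for i in range(8)
        ]
        shifted = anonymize_gps(pts, eps_m=100, min_pts=5)
        lat0 = np.mean([p.lat for p in shifted])
        assert abs(lat0) < 1e-4  # single cluster centred at origin
        d0, d1 = gps_distance(pts), gps_distance(shifted)
        assert abs(d1 - d0) / d0 < 1e-3


class TestExtract:
    def test_empty_log(self):
        log = PhoneDayLog(subject_id="s", date=date(2012, 6, 4))
        fv = extract_phone_features(log)
        assert list(fv.values) == PHONE_FEATURES
        assert fv.values["n_calls"] == 0.0
        assert fv.values["gps_distance_m"] == 0.0
        assert fv.values["mean_call_s"] is None
        assert fv.values["audio_length_s"] is None

    def test_audio_only_log(self, rng):
        log = PhoneDayLog(
            subject_id="s",
            date=date(2012, 6, 4),
            audio=[_audio(rng.uniform(-0.5, 0.5, 8000))],
        )
        fv = extract_phone_features(log)
        assert fv.values["audio_length_s"] == pytest.approx(1.0)
        assert fv.values["speech_energy"] is not None
        assert fv.values["battery_ratio"] is None

    def test_generator_counts_reproduced(self):
        log = generate_phone_day(DayParams(audio_count=2, audio_len_s=5.0), seed=11)
        fv = extract_phone_features(log)
        assert fv.values["n_calls"] == len(log.calls)
        assert fv.values["n_cal_events"] == len(log.calendar)
        assert fv.values["audio_length_s"] == pytest.approx(5.0)
        assert fv.values["n_locations"] == 2.0  # two configured dwell centers
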