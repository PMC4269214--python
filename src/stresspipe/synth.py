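"""Seeded generators for RR nights, phone-day logs and self-reports.

The generators stand in for the field study the pipeline was designed
around: ~35 office workers wearing a chest belt at night and carrying an
instrumented phone by day. Every piece of randomness derives from one seed
through ``numpy.random.SeedSequence`` spawning, so a cohort is reproducible
byte for byte.

RR nights superimpose a low-frequency and a high-frequency sinusoidal
modulation (sympathetic/parasympathetic surrogates) plus white noise on a
constant mean interval, with ectopic beats injected as +/-40 % spikes at a
configurable rate; modulation rides on beat time rather than wall time,
which is adequate for band-dominance checks but is not a physiological
model of sleep architecture.

Cohorts carry a known multinomial-logit dependence of the stress class on
a small set of features the extraction chain recovers faithfully (sleep
duration, mean RR, call count, audio length). The self-report is drawn
uniformly inside the band of the sampled class, so the mapped label equals
the generated class exactly; label noise stays a separate knob.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date as _date
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

from .hrv import HRV_FEATURES
from .phone import PHONE_FEATURES
from .types import (
    AccelWindow,
    AudioResponse,
    BatterySample,
    CalendarEvent,
    CallDirection,
    CallEvent,
    ContactsSnapshot,
    GPSSample,
    PhoneDayLog,
    RRSession,
    SelfReport,
    ValidationError,
)

__all__ = [
    "NightParams",
    "DayParams",
    "EffectSpec",
    "CohortSpec",
    "DayRecord",
    "generate_rr_night",
    "generate_phone_day",
    "generate_cohort",
    "write_dataset",
]

TZ = timezone(timedelta(hours=2))  # central European summer time


@dataclass(frozen=True)
class NightParams:
    """Parameters of one synthetic night of RR intervals."""

    duration_h: float = 7.0
    mean_rr_ms: float = 1000.0
    lf_amp_ms: float = 20.0
    hf_amp_ms: float = 10.0
    lf_freq_hz: float = 0.1
    hf_freq_hz: float = 0.25
    noise_ms: float = 15.0
    ectopic_rate: float = 0.01

    def __post_init__(self) -> None:
        if not 4.0 <= self.duration_h <= 10.0:
            raise ValidationError("night duration must lie in [4, 10] h")
        if not 600.0 <= self.mean_rr_ms <= 1200.0:
            raise ValidationError("mean RR must lie in [600, 1200] ms")
        if self.lf_amp_ms and not 0.04 <= self.lf_freq_hz <= 0.15:
            raise ValidationError("LF modulation frequency outside [0.04, 0.15] Hz")
        if self.hf_amp_ms and not 0.15 <= self.hf_freq_hz <= 0.4:
            raise ValidationError("HF modulation frequency outside [0.15, 0.4] Hz")
        if min(self.lf_amp_ms, self.hf_amp_ms, self.noise_ms, self.ectopic_rate) < 0:
            raise ValidationError("amplitudes, noise and ectopic rate must be >= 0")


def generate_rr_night(
    params: NightParams,
    seed: int | np.random.Generator = 0,
    subject_id: str = "synthetic",
    start_time: datetime | None = None,
    return_truth: bool = False,
):
    """One night of RR intervals with known spectral content.

    RR_k = mean + A_LF sin(2 pi f_LF t_k) + A_HF sin(2 pi f_HF t_k) + noise,
    with t_k the cumulative beat time; each beat is independently replaced
    by a +/-40 % ectopic spike with probability ``ectopic_rate``. With
    ``return_truth`` the indices of the injected spikes are returned too.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if start_time is None:
        start_time = datetime(2012, 6, 1, 23, 0, tzinfo=TZ)
    duration_s = params.duration_h * 3600.0
    n_max = int(duration_s / (params.mean_rr_ms / 1000.0) * 1.3) + 10
    noise = rng.normal(0.0, params.noise_ms, n_max)
    spike_u = rng.random(n_max)
    spike_sign = rng.choice([-1.0, 1.0], n_max)
    rr = np.empty(n_max)
    is_spike = np.zeros(n_max, bool)
    t = 0.0
    k = 0
    two_pi = 2.0 * np.pi
    while t < duration_s and k < n_max:
        val = (
            params.mean_rr_ms
            + params.lf_amp_ms * np.sin(two_pi * params.lf_freq_hz * t)
            + params.hf_amp_ms * np.sin(two_pi * params.hf_freq_hz * t)
            + noise[k]
        )
        val = max(val, 200.0)  # physiological floor
        if spike_u[k] < params.ectopic_rate:
            val *= 1.0 + 0.4 * spike_sign[k]
            is_spike[k] = True
        rr[k] = val
        t += val / 1000.0
        k += 1
    session = RRSession(subject_id=subject_id, start_time=start_time, rr_ms=rr[:k])
    if return_truth:
        return session, np.flatnonzero(is_spike[:k])
    return session


@dataclass(frozen=True)
class DayParams:
    """Behavioral rates of one synthetic phone day (8:00-20:00)."""

    call_rate: float = 6.0
    call_dur_median_s: float = 90.0
    call_dur_sigma: float = 1.0
    p_incoming: float = 0.55
    calendar_rate: float = 2.0
    cal_dur_mean_s: float = 2400.0
    note_chars_mean: float = 40.0
    n_contacts: int = 200
    contact_drift: float = 0.01
    gps_centers: tuple = ((47.3769, 8.5417), (47.3952, 8.4920))
    gps_noise_m: float = 10.0
    accel_activity_g: float = 0.08
    accel_rate_hz: float = 5.0
    audio_count: int = 4
    audio_len_s: float = 20.0
    audio_rms: float = 0.1
    audio_sr: int = 8000

    def __post_init__(self) -> None:
        if min(self.call_rate, self.calendar_rate, self.audio_count) < 0:
            raise ValidationError("rates must be >= 0")


def generate_phone_day(
    params: DayParams,
    subject_id: str = "synthetic",
    day: _date = _date(2012, 6, 1),
    seed: int | np.random.Generator = 0,
) -> PhoneDayLog:
    """One subject-day of phone events.

    Calls: Poisson count, log-normal durations, Bernoulli direction.
    GPS: dwell points around the configured cluster centers, sampled on the
    5-minute duty cycle; accelerometer: 30-s windows every 5 minutes around
    1 g; battery: monotone discharge with one charging block; audio: white
    noise of the requested RMS and length.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    day_start = datetime(day.year, day.month, day.day, 8, 0, tzinfo=TZ)
    day_s = 12 * 3600

    def at(sec: float) -> datetime:
        return day_start + timedelta(seconds=float(sec))

    calls = []
    for _ in range(rng.poisson(params.call_rate)):
        calls.append(
            CallEvent(
                timestamp=at(rng.uniform(0, day_s - 1)),
                direction=CallDirection.INCOMING
                if rng.random() < params.p_incoming
                else CallDirection.OUTGOING,
                duration_s=float(
                    rng.lognormal(np.log(params.call_dur_median_s), params.call_dur_sigma)
                ),
            )
        )

    calendar = []
    for _ in range(rng.poisson(params.calendar_rate)):
        start_s = rng.uniform(0, day_s - 3600)
        dur = rng.exponential(params.cal_dur_mean_s)
        calendar.append(
            CalendarEvent(
                start=at(start_s),
                end=at(min(start_s + dur, day_s - 1)),
                note_size=int(rng.poisson(params.note_chars_mean)),
            )
        )

    n0 = params.n_contacts
    drift = rng.normal(0, params.contact_drift)
    contacts = [
        ContactsSnapshot(
            timestamp=datetime(day.year, day.month, day.day, 20, 0, tzinfo=TZ)
            - timedelta(days=1),
            n_contacts=n0,
            n_phone_numbers=int(n0 * 1.2),
            n_emails=int(n0 * 0.8),
        ),
        ContactsSnapshot(
            timestamp=at(11 * 3600),
            n_contacts=max(0, int(round(n0 * (1 + drift)))),
            n_phone_numbers=max(0, int(round(n0 * 1.2 * (1 + drift)))),
            n_emails=max(0, int(round(n0 * 0.8 * (1 + drift)))),
        ),
    ]

    battery = []
    level = 0.95
    for hour in range(13):
        charging = hour in (4, 5)  # noon charge
        battery.append(BatterySample(timestamp=at(hour * 3600), level=level, charging=charging))
        level = min(1.0, level + 0.15) if charging else max(0.05, level - 0.06)

    accel = []
    n_win = int(round(params.accel_rate_hz * 30))
    for slot in range(0, day_s, 600):  # every 10 minutes, 30 s windows
        g = np.zeros((n_win, 3))
        g[:, 2] = 1.0
        g += rng.normal(0, params.accel_activity_g, (n_win, 3))
        accel.append(AccelWindow(timestamp=at(slot), samples=g))

    gps = []
    centers = np.asarray(params.gps_centers, float)
    deg_noise = params.gps_noise_m / 111_000.0
    for slot in range(0, day_s, 300):
        c = centers[min(len(centers) - 1, int(slot / day_s * len(centers)))]
        gps.append(
            GPSSample(
                timestamp=at(slot),
                lat=float(c[0] + rng.normal(0, deg_noise)),
                lon=float(c[1] + rng.normal(0, deg_noise)),
            )
        )

    audio = []
    n_samp = int(round(params.audio_len_s * params.audio_sr))
    for i in range(params.audio_count):
        raw = rng.normal(0, params.audio_rms, n_samp)
        raw = np.clip(raw, -1.0, 1.0)
        audio.append(
            AudioResponse(
                timestamp=at((2 + 3 * i) * 3600 + 120),
                samples=raw,
                sample_rate=params.audio_sr,
            )
        )

    return PhoneDayLog(
        subject_id=subject_id,
        date=day,
        calls=calls,
        calendar=calendar,
        contacts=contacts,
        battery=battery,
        accel=accel,
        gps=gps,
        audio=audio,
    )


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth dependence of the stress class on named features.

    Class probabilities follow the reference-class multinomial logit on the
    standardised feature values: eta_i = intercept_i + beta_i . z. The
    default direction encodes higher stress with shorter sleep, faster
    heart rate, more calls and shorter voice answers; the default magnitude
    is strong (within-cohort Bayes accuracy around 0.8). ``zero()`` gives
    the no-effect (intercept-only) cohort.
    """

    feature_names: tuple = ("sleep_duration_h", "mean_rr_ms", "n_calls", "audio_length_s")
    beta_class1: tuple = (-2.5, -2.5, 2.5, -2.5)
    beta_class2: tuple = (-5.0, -5.0, 5.0, -5.0)
    intercept_class1: float = 0.0
    intercept_class2: float = -4.0
    #: nominal mean/sd used to standardise each feature before the logit
    feature_loc: tuple = (6.0, 950.0, 6.0, 20.0)
    feature_scale: tuple = (0.8, 70.0, 2.449, 6.0)

    @classmethod
    def zero(cls) -> "EffectSpec":
        return cls(beta_class1=(0.0,) * 4, beta_class2=(0.0,) * 4,
                   intercept_class1=0.0, intercept_class2=-0.2)


@dataclass(frozen=True)
class CohortSpec:
    """Study-shaped cohort: n_users x n_days with a known effect structure."""

    n_users: int = 10
    n_days: int = 30
    seed: int = 0
    night: NightParams = field(default_factory=NightParams)
    day: DayParams = field(default_factory=DayParams)
    effect: EffectSpec = field(default_factory=EffectSpec)
    #: fraction of days with an HRV night recording
    hrv_coverage: float = 1.0
    start_date: _date = _date(2012, 6, 1)


@dataclass
class DayRecord:
    """One generated subject-day: raw inputs plus the self-report."""

    subject_id: str
    date: _date
    rr: RRSession | None
    phone: PhoneDayLog | None
    report: SelfReport


def _softmax3(eta1: float, eta2: float) -> np.ndarray:
    e = np.array([0.0, eta1, eta2])
    e -= e.max()
    p = np.exp(e)
    return p / p.sum()


def generate_cohort(spec: CohortSpec, features_only: bool = False):
    """Generate a full cohort with known class structure.

    Per user-day the generator draws the driving feature values (sleep
    duration, mean RR, Poisson call count, audio length), standardises them
    with the effect spec's nominal location/scale, computes the three class
    probabilities through the ground-truth logit, samples the class and
    sets the self-report uniformly inside that class's score band.

    Returns ``(records, ground_truth)`` where ground_truth carries the
    effect spec, the latent feature table, the sampled classes and the
    ectopic-spike positions per night. With ``features_only=True`` the
    records are replaced by the latent feature DataFrame (no raw files are
    synthesised), which exercises the modeling chain without extraction.
    """
    eff = spec.effect
    ss = np.random.SeedSequence(spec.seed)
    user_seeds = ss.spawn(spec.n_users)
    records: list[DayRecord] = []
    latent_rows = []
    spikes: dict[tuple[str, str], np.ndarray] = {}
    band_eps = 0.005
    for ui in range(spec.n_users):
        subject = f"user{ui:02d}"
        urng = np.random.default_rng(user_seeds[ui])
        for di in range(spec.n_days):
            day = spec.start_date + timedelta(days=di)
            duration = float(np.clip(urng.normal(eff.feature_loc[0], eff.feature_scale[0]), 4.2, 9.5))
            mean_rr = float(np.clip(urng.normal(eff.feature_loc[1], eff.feature_scale[1]), 650.0, 1190.0))
            n_calls = int(urng.poisson(eff.feature_loc[2]))
            audio_len = float(np.clip(urng.normal(eff.feature_loc[3], eff.feature_scale[3]), 3.0, 45.0))
            x = np.array([duration, mean_rr, float(n_calls), audio_len])
            z = (x - np.asarray(eff.feature_loc)) / np.asarray(eff.feature_scale)
            eta1 = eff.intercept_class1 + float(np.dot(eff.beta_class1, z))
            eta2 = eff.intercept_class2 + float(np.dot(eff.beta_class2, z))
            probs = _softmax3(eta1, eta2)
            cls = int(urng.choice(3, p=probs))
            if cls == 0:
                score = float(urng.uniform(0.02, 0.3))
            elif cls == 1:
                score = float(urng.uniform(0.3 + band_eps, 0.7 - band_eps))
            else:
                score = float(urng.uniform(0.7, 0.98))
            latent_rows.append(
                {
                    "subject_id": subject,
                    "date": day,
                    "sleep_duration_h": duration,
                    "mean_rr_ms": mean_rr,
                    "n_calls": float(n_calls),
                    "audio_length_s": audio_len,
                    "class": cls,
                    "p0": probs[0],
                    "p1": probs[1],
                    "p2": probs[2],
                    "stress_score": score,
                }
            )
            if not features_only:
                has_hrv = urng.random() < spec.hrv_coverage
                rr = None
                if has_hrv:
                    night = dataclasses.replace(
                        spec.night, duration_h=duration, mean_rr_ms=mean_rr
                    )
                    rr, spike_idx = generate_rr_night(
                        night,
                        seed=urng,
                        subject_id=subject,
                        start_time=datetime(day.year, day.month, day.day, 23, 0, tzinfo=TZ),
                        return_truth=True,
                    )
                    spikes[(subject, day.isoformat())] = spike_idx
                dayp = dataclasses.replace(
                    spec.day, call_rate=0.0, audio_len_s=audio_len
                )
                phone = generate_phone_day(dayp, subject, day, seed=urng)
                # the call count is a latent driver: inject exactly n_calls
                calls = [
                    CallEvent(
                        timestamp=datetime(day.year, day.month, day.day, 9, 0, tzinfo=TZ)
                        + timedelta(seconds=float(s)),
                        direction=CallDirection.INCOMING
                        if urng.random() < spec.day.p_incoming
                        else CallDirection.OUTGOING,
                        duration_s=float(
                            urng.lognormal(
                                np.log(spec.day.call_dur_median_s), spec.day.call_dur_sigma
                            )
                        ),
                    )
                    for s in np.sort(urng.uniform(0, 10 * 3600, n_calls))
                ]
                phone.calls = sorted(calls, key=lambda c: c.timestamp)
                report = SelfReport(subject_id=subject, date=day, stress_score=score)
                records.append(DayRecord(subject, day, rr, phone, report))
    latents = pd.DataFrame(latent_rows)
    ground_truth = {
        "effect": eff,
        "latents": latents,
        "classes": latents[["subject_id", "date", "class"]],
        "spikes": spikes,
    }
    if features_only:
        return latents, ground_truth
    return records, ground_truth


def write_dataset(records: list[DayRecord], out_dir) -> None:
    """Write a cohort in the on-disk layout the pipeline consumes:
    ``rr/`` (text + sidecars), ``days/`` (JSON + WAV), ``reports/reports.csv``."""
    from pathlib import Path

    from .io import write_phone_day, write_rr_session, write_self_reports

    out = Path(out_dir)
    (out / "rr").mkdir(parents=True, exist_ok=True)
    (out / "days").mkdir(parents=True, exist_ok=True)
    (out / "reports").mkdir(parents=True, exist_ok=True)
    reports = []
    for rec in records:
        stem = f"{rec.subject_id}_{rec.date.isoformat()}"
        if rec.rr is not None:
            write_rr_session(rec.rr, out / "rr" / f"{stem}.txt")
        if rec.phone is not None:
            write_phone_day(rec.phone, out / "days" / f"{stem}.json")
        reports.append(rec.report)
    write_self_reports(reports, out / "reports" / "reports.csv")
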