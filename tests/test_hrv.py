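"""HRV feature extraction: worked examples, brute-force oracles, invariants."""

from datetime import datetime, timezone

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stresspipe.hrv import (
    HRV_FEATURES,
    approximate_entropy,
    band_powers,
    extract_hrv_features,
    filter_rr_artifacts,
    hrv_histogram,
    lomb_scargle_psd,
    poincare,
    time_domain_features,
    tinn,
)
from stresspipe.synth import NightParams, generate_rr_night
from stresspipe.types import InsufficientDataError, RRSession, ValidationError

from .oracles import (
    apen_direct,
    hrv_index_direct,
    lombscargle_direct,
    pnn50_direct,
    poincare_direct,
    rmssd_direct,
    sdnn_direct,
    tinn_direct,
)

UTC = timezone.utc


class TestArtifactFilter:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ((800, 1000, 810, 805), (800, 810, 805)),  # 1000 deviates 25 %
            ((900, 900, 900), (900, 900, 900)),
            ((1000, 1100), (1000, 1100)),  # 10 % passes
        ],
    )
    def test_worked_examples(self, series, expected):
        assert filter_rr_artifacts(np.array(series, float)).tolist() == list(expected)

    def test_comparison_is_against_last_retained(self):
        # the spike is dropped; its successor is compared to the pre-spike beat
        out = filter_rr_artifacts(np.array([800.0, 1200.0, 820.0, 830.0]))
        assert out.tolist() == [800.0, 820.0, 830.0]

    def test_idempotent(self, rng):
        rr = 1000 + 200 * rng.standard_normal(500).cumsum() * 0.01
        rr = np.clip(rr, 400, 2000)
        once = filter_rr_artifacts(rr)
        assert np.array_equal(filter_rr_artifacts(once), once)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            filter_rr_artifacts(np.array([]))


class TestTimeDomain:
    def test_worked_example(self):
        feats = time_domain_features(np.array([800.0, 860.0, 870.0, 800.0]))
        assert feats["pnn50_pct"] == pytest.approx(200.0 / 3.0, abs=1e-9)
        assert feats["rmssd_ms"] == pytest.approx(53.5413, abs=1e-3)

    def test_constant_series(self):
        feats = time_domain_features(np.full(10, 900.0))
        assert feats["sdnn_ms"] == 0.0
        assert feats["rmssd_ms"] == 0.0
        assert feats["pnn50_pct"] == 0.0

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            time_domain_features(np.array([800.0, 810.0]))

    def test_sleep_duration_is_sum_of_intervals(self):
        rr = np.full(25_200, 1000.0)
        assert time_domain_features(rr)["sleep_duration_h"] == pytest.approx(7.0)


class TestHistogram:
    def test_bin_alignment(self):
        edges, counts = hrv_histogram(np.array([800.0, 800.0, 810.0]))
        # 800 / 7.8125 = 102.4 -> bin 102 spans [796.875, 804.6875)
        i = int(np.floor(800.0 / 7.8125) - np.floor(edges[0] / 7.8125))
        assert edges[i] == pytest.approx(796.875)
        assert counts[i] == 2

    def test_single_interval(self):
        edges, counts = hrv_histogram(np.array([900.0]))
        assert counts.sum() == 1
        assert time_domain_features(np.full(3, 900.0))["hrv_index"] == 1.0

    def test_count_conservation(self, rng):
        rr = rng.uniform(500, 1500, 400)
        _, counts = hrv_histogram(rr)
        assert counts.sum() == rr.size


class TestTinn:
    def test_single_bin_degenerate(self):
        edges, counts = hrv_histogram(np.full(5, 900.0))
        assert tinn(edges, counts) == pytest.approx(7.8125)

    def test_recovers_triangle_width(self):
        # symmetric triangular histogram over 9 bins
        bw = 7.8125
        edges = bw * np.arange(100, 110)
        counts = np.array([1, 2, 3, 4, 5, 4, 3, 2, 1], float)
        width = tinn(edges, counts)
        assert abs(width - (edges[-1] - edges[0])) <= bw

    def test_monotone_in_histogram_width(self):
        bw = 7.8125
        edges = bw * np.arange(100, 112)
        narrow = np.array([0, 0, 2, 6, 2, 0, 0, 0, 0, 0, 0], float)
        wide = np.array([0, 1, 2, 6, 2, 1, 1, 0, 0, 0, 0], float)
        assert tinn(edges, wide) >= tinn(edges, narrow)

    def test_matches_exhaustive_search(self, rng):
        for _ in range(10):
            rr = rng.normal(900, 40, 60)
            edges, counts = hrv_histogram(rr)
            assert tinn(edges, counts) == pytest.approx(
                tinn_direct(edges, counts), abs=1e-9
            )


class TestApEn:
    def test_constant_is_perfectly_regular(self):
        assert approximate_entropy(np.full(50, 800.0)) == 0.0

    def test_periodic_below_shuffled(self, rng):
        periodic = np.tile([800.0, 900.0], 100)
        shuffled = rng.permutation(periodic)
        r = 0.2 * periodic.std(ddof=1)
        assert approximate_entropy(periodic, r=r) < approximate_entropy(shuffled, r=r)

    def test_matches_double_loop(self, rng):
        for _ in range(10):
            x = rng.normal(900, 30, rng.integers(10, 50))
            assert approximate_entropy(x) == pytest.approx(apen_direct(x), abs=1e-10)

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            approximate_entropy(np.array([800.0, 810.0, 820.0]), m=2)


class TestPoincare:
    def test_worked_example(self):
        sd1, sd2, ratio = poincare(np.array([800.0, 860.0, 870.0, 800.0]))
        # signed successive differences (60, 10, -70): sqrt(Var/2) = 37.86
        assert sd1 == pytest.approx(37.8594, abs=1e-3)
        assert ratio == pytest.approx(sd1 / sd2)

    def test_sd1_bounded_by_rmssd(self, rng):
        for _ in range(20):
            rr = rng.normal(900, 50, rng.integers(5, 80))
            sd1, _, _ = poincare(rr)
            rmssd = rmssd_direct(rr)
            assert sd1 <= rmssd / np.sqrt(2) + 1e-9

    def test_equality_when_mean_diff_zero(self):
        rr = np.array([800.0, 860.0, 870.0, 800.0])  # diffs sum to zero
        sd1, _, _ = poincare(rr)
        assert sd1 == pytest.approx(rmssd_direct(rr) / np.sqrt(2), abs=1e-9)

    def test_constant_series_ratio_missing(self):
        sd1, sd2, ratio = poincare(np.full(10, 900.0))
        assert sd1 == 0.0 and sd2 == 0.0 and ratio is None

    def test_matches_direct(self, rng):
        rr = rng.normal(900, 40, 30)
        sd1, sd2, _ = poincare(rr)
        o1, o2 = poincare_direct(rr)
        assert sd1 == pytest.approx(o1, abs=1e-9)
        assert sd2 == pytest.approx(o2, abs=1e-9)


class TestLombScargle:
    def test_pure_tone_peak(self):
        t = np.arange(400, dtype=float)  # 1 Hz sampling
        x = np.sin(2 * np.pi * 0.1 * t)
        psd = lomb_scargle_psd(t, x)
        peak = psd.frequencies[np.argmax(psd.power)]
        step = np.diff(psd.frequencies).max()
        assert abs(peak - 0.1) <= step

    def test_matches_classical_periodogram_when_even(self, rng):
        n = 512
        t = np.arange(n, dtype=float)
        x = np.sin(2 * np.pi * 0.1 * t) + 0.3 * rng.standard_normal(n)
        xc = x - x.mean()
        k = np.arange(1, n // 2)
        f = k / n
        sel = (f >= 0.01) & (f <= 0.4)
        p_dft = (np.abs(np.fft.rfft(xc)) ** 2 / n)[k][sel]
        psd = lomb_scargle_psd(t, x, freq_grid=f[sel])
        assert np.max(np.abs(psd.power - p_dft) / p_dft) < 1e-6

    def test_fast_and_exact_routes_agree_with_direct_sums(self, rng):
        rr = 950 + 25 * rng.standard_normal(300)
        t = np.cumsum(rr) / 1000.0
        fast = lomb_scargle_psd(t, rr, method="fft")
        exact = lomb_scargle_psd(t, rr, method="exact")
        assert np.allclose(fast.power, exact.power, rtol=0, atol=1e-6 * exact.power.max())
        # spot-check a handful of frequencies against the plain-sum oracle
        idx = rng.choice(exact.frequencies.size, 8, replace=False)
        direct = lombscargle_direct(t, rr - rr.mean(), exact.frequencies[idx])
        assert np.allclose(exact.power[idx], direct, rtol=1e-9)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValidationError):
            lomb_scargle_psd(np.array([0.0, 2.0, 1.0] + list(range(3, 13))), np.ones(13))

    def test_power_nonnegative(self, rng):
        x = rng.standard_normal(200)
        t = np.sort(rng.uniform(0, 200, 200))
        psd = lomb_scargle_psd(t, x)
        assert np.all(psd.power >= 0)


class TestBandPowers:
    def _psd_for(self, f_mod, rng, amp=30.0, noise=3.0):
        params = NightParams(
            duration_h=4.0,
            lf_amp_ms=amp if f_mod < 0.15 else 0.0,
            hf_amp_ms=amp if f_mod >= 0.15 else 0.0,
            lf_freq_hz=f_mod if f_mod < 0.15 else 0.1,
            hf_freq_hz=f_mod if f_mod >= 0.15 else 0.25,
            noise_ms=noise,
            ectopic_rate=0.0,
        )
        s = generate_rr_night(params, seed=int(rng.integers(2**31)))
        rr = s.rr_ms
        return lomb_scargle_psd(np.cumsum(rr) / 1000.0, rr)

    def test_hf_modulation_dominates(self, rng):
        bands = band_powers(self._psd_for(0.25, rng))
        assert bands["hf_nu"] > 0.7

    def test_normalised_units_sum_to_one(self, rng):
        bands = band_powers(self._psd_for(0.1, rng))
        assert bands["lf_nu"] + bands["hf_nu"] == pytest.approx(1.0)

    def test_ratio_scale_invariant(self, rng):
        psd = self._psd_for(0.1, rng)
        from stresspipe.hrv import PSD

        doubled = PSD(psd.frequencies, 2.0 * psd.power)
        assert band_powers(doubled)["lf_hf"] == pytest.approx(
            band_powers(psd)["lf_hf"]
        )


class TestExtract:
    def _session(self, rr):
        return RRSession("s1", datetime(2012, 6, 1, 23, 0, tzinfo=UTC), rr)

    def test_six_hour_night_duration(self):
        s = generate_rr_night(
            NightParams(duration_h=6.0, mean_rr_ms=1000.0, ectopic_rate=0.0), seed=7
        )
        fv = extract_hrv_features(s)
        assert fv.values["sleep_duration_h"] == pytest.approx(6.0, abs=0.01)

    def test_emits_all_14_features(self):
        s = generate_rr_night(NightParams(duration_h=4.0), seed=3)
        fv = extract_hrv_features(s)
        assert list(fv.values) == HRV_FEATURES
        assert len(fv.values) == 14

    def test_short_session_rejected(self):
        with pytest.raises(InsufficientDataError):
            extract_hrv_features(self._session(np.array([800.0, 810.0])))

    def test_start_time_shift_leaves_features_unchanged(self):
        s = generate_rr_night(NightParams(duration_h=4.0), seed=9)
        shifted = RRSession(s.subject_id, s.start_time.replace(hour=2), s.rr_ms)
        assert extract_hrv_features(s).values == extract_hrv_features(shifted).values


@given(
    st.lists(st.floats(min_value=400, max_value=1800), min_size=12, max_size=50).map(
        np.array
    )
)
def test_statistics_match_oracles_property(rr):
    """SDNN/RMSSD/pNN50/HRV-index on arbitrary short series equal the
    direct-formula implementations."""
    feats = time_domain_features(rr)
    assert feats["sdnn_ms"] == pytest.approx(sdnn_direct(rr), abs=1e-9)
    assert feats["rmssd_ms"] == pytest.approx(rmssd_direct(rr), abs=1e-9)
    assert feats["pnn50_pct"] == pytest.approx(pnn50_direct(rr), abs=1e-9)
    assert feats["hrv_index"] == pytest.approx(hrv_index_direct(rr), abs=1e-9)
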