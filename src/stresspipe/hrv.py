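"""Nocturnal heart-rate-variability features.

From one night of RR intervals the module derives, after a 20 % artifact
filter, the 14-feature HRV battery used by the stress models:

* time domain -- sleep duration, mean RR, SDNN, RMSSD, pNN50, and the two
  geometric measures built on the 1/128-s RR histogram (HRV triangular
  index and TINN);
* nonlinear -- approximate entropy (ApEn) and the Poincare-plot axes SD1,
  SD2 and their ratio;
* frequency domain -- normalized LF and HF power and LF/HF from a
  Lomb-Scargle periodogram of the unevenly sampled beat series
  (VLF 0.01-0.04 Hz, LF 0.04-0.15 Hz, HF 0.15-0.4 Hz).

Conventions (fixed here so independent oracles are unambiguous): SDNN uses
the n-1 denominator; the Poincare axes use population variance; pNN50 is a
percentage of the number of successive differences; ApEn defaults to m = 2,
r = 0.2 * SDNN with self-matches included; normalized band powers exclude
VLF from the denominator (LF_nu = LF / (LF + HF)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._lombscargle import default_grid, lombscargle_exact, lombscargle_fft
from .config import PipelineConfig
from .types import (
    FeatureVector,
    InsufficientDataError,
    Modality,
    RRSession,
    ValidationError,
)

__all__ = [
    "HRV_FEATURES",
    "PSD",
    "filter_rr_artifacts",
    "artifact_mask",
    "time_domain_features",
    "hrv_histogram",
    "tinn",
    "approximate_entropy",
    "poincare",
    "lomb_scargle_psd",
    "band_powers",
    "extract_hrv_features",
]

#: canonical order of the 14 HRV features
HRV_FEATURES = [
    "sleep_duration_h",
    "mean_rr_ms",
    "sdnn_ms",
    "rmssd_ms",
    "pnn50_pct",
    "hrv_index",
    "tinn_ms",
    "apen",
    "sd1_ms",
    "sd2_ms",
    "sd1_sd2",
    "lf_nu",
    "hf_nu",
    "lf_hf",
]


@dataclass(frozen=True)
class PSD:
    """A one-sided power spectral density estimate on a frequency grid."""

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, float)
        p = np.asarray(self.power, float)
        if f.ndim != 1 or f.size != p.size:
            raise ValidationError("frequencies and power must be same-length 1-D")
        if f.size and np.any(np.diff(f) <= 0):
            raise ValidationError("frequencies must be strictly increasing")
        if np.any(p < 0):
            raise ValidationError("power must be non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "power", p)


def filter_rr_artifacts(rr_ms: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Drop RR intervals deviating more than ``threshold`` (fractionally)
    from the previously *retained* interval.

    Comparing against the last retained beat (rather than the raw
    predecessor) stops an isolated ectopic spike from cascading into the
    deletion of the normal beats that follow it. The first interval is
    retained and anchors the comparison chain; if that anchor is itself an
    artifact the chain would reject nearly the whole night, so when fewer
    than half the beats survive, the filter re-runs anchored on the first
    beat within ``threshold`` of the series median (beats before it are
    dropped). The operation is idempotent.
    """
    rr = np.asarray(rr_ms, float)
    return rr[artifact_mask(rr, threshold)]


def artifact_mask(rr_ms: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Boolean retention mask of :func:`filter_rr_artifacts`."""
    rr = np.asarray(rr_ms, float)
    if rr.ndim != 1 or rr.size == 0:
        raise ValidationError("rr_ms must be a non-empty 1-D sequence")
    if np.any(rr <= 0):
        raise ValidationError("RR intervals must be positive")

    def chain(start: int) -> np.ndarray:
        keep = np.zeros(rr.size, dtype=bool)
        keep[start] = True
        last = rr[start]
        for i in range(start + 1, rr.size):
            if abs(rr[i] - last) <= threshold * last:
                keep[i] = True
                last = rr[i]
        return keep

    keep = chain(0)
    if keep.sum() < 0.5 * rr.size:
        med = np.median(rr)
        anchors = np.flatnonzero(np.abs(rr - med) <= threshold * med)
        if anchors.size:
            rescued = chain(int(anchors[0]))
            if rescued.sum() > keep.sum():
                keep = rescued
    return keep


def hrv_histogram(
    rr_ms: np.ndarray, bin_ms: float = 1000.0 / 128.0
) -> tuple[np.ndarray, np.ndarray]:
    """RR histogram on the canonical 1/128-s grid.

    Bin k spans ``[k*bin_ms, (k+1)*bin_ms)``; edges are aligned to zero so
    the same interval always lands in the same bin regardless of the series.
    Returns ``(bin_edges, counts)`` with ``sum(counts) == len(rr_ms)``.
    """
    rr = np.asarray(rr_ms, float)
    if rr.size == 0:
        raise ValidationError("empty series")
    k0 = int(np.floor(rr.min() / bin_ms))
    k1 = int(np.floor(rr.max() / bin_ms))
    edges = bin_ms * np.arange(k0, k1 + 2)
    idx = np.floor(rr / bin_ms).astype(int) - k0
    counts = np.bincount(idx, minlength=k1 - k0 + 1)
    return edges, counts


def tinn(bin_edges: np.ndarray, counts: np.ndarray) -> float:
    """Base width (ms) of the best-fit triangle to the RR histogram.

    The triangle is zero outside [N, M], rises linearly to the modal height
    at the modal bin and falls back to zero; (N, M) range over the bin edges
    left/right of the mode and minimize the summed squared error against the
    histogram evaluated at bin centers. A single-bin histogram degenerates
    to one bin width.
    """
    edges = np.asarray(bin_edges, float)
    counts = np.asarray(counts, float)
    if counts.size == 0 or counts.max() <= 0:
        raise ValidationError("histogram must have at least one nonzero bin")
    centers = 0.5 * (edges[:-1] + edges[1:])
    k_star = int(np.argmax(counts))  # ties -> lower bin
    x_peak = centers[k_star]
    y_peak = counts[k_star]
    left_edges = edges[: k_star + 1]  # candidates for N (<= left edge of mode)
    right_edges = edges[k_star + 1 :]  # candidates for M (>= right edge of mode)

    best = (np.inf, edges[k_star], edges[k_star + 1])
    for n_edge in left_edges:
        rise_den = x_peak - n_edge
        asc = np.where(
            (centers >= n_edge) & (centers <= x_peak),
            y_peak * (centers - n_edge) / rise_den if rise_den > 0 else y_peak,
            0.0,
        )
        for m_edge in right_edges:
            fall_den = m_edge - x_peak
            desc = np.where(
                (centers > x_peak) & (centers <= m_edge),
                y_peak * (m_edge - centers) / fall_den if fall_den > 0 else 0.0,
                0.0,
            )
            err = float(np.sum((counts - asc - desc) ** 2))
            if err < best[0] - 1e-12:
                best = (err, n_edge, m_edge)
    return float(best[2] - best[1])


def time_domain_features(
    rr_ms: np.ndarray, bin_ms: float = 1000.0 / 128.0
) -> dict[str, float]:
    """Time-domain battery from a filtered series (needs >= 3 intervals)."""
    rr = np.asarray(rr_ms, float)
    if rr.size < 3:
        raise InsufficientDataError("need at least 3 intervals (2 differences)")
    diffs = np.diff(rr)
    edges, counts = hrv_histogram(rr, bin_ms)
    return {
        "sleep_duration_h": float(rr.sum() / 3.6e6),
        "mean_rr_ms": float(rr.mean()),
        "sdnn_ms": float(rr.std(ddof=1)),
        "rmssd_ms": float(np.sqrt(np.mean(diffs**2))),
        "pnn50_pct": float(100.0 * np.mean(np.abs(diffs) > 50.0)),
        "hrv_index": float(rr.size / counts.max()),
        "tinn_ms": tinn(edges, counts),
    }


def approximate_entropy(
    rr_ms: np.ndarray, m: int = 2, r: float | None = None
) -> float:
    """Approximate entropy ApEn(m, r) under the Chebyshev distance.

    Phi_m is the mean log fraction of templates (self-matches included)
    within tolerance ``r`` of each length-m template; ApEn = Phi_m -
    Phi_{m+1}. ``r`` defaults to 0.2 * sample standard deviation; a constant
    series (r = 0) is perfectly regular and returns 0. Exact counts come
    from a KD-tree, which matches the brute-force double loop while scaling
    to full-night series.
    """
    x = np.asarray(rr_ms, float)
    if x.size <= m + 1:
        raise InsufficientDataError(f"series of length {x.size} too short for m={m}")
    if r is None:
        r = 0.2 * float(x.std(ddof=1))
    if r <= 0:
        return 0.0

    def phi(mm: int) -> float:
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        tree = cKDTree(emb)
        # KD-tree balls are closed, matching the <= r convention
        cnt = tree.query_ball_point(emb, r, p=np.inf, return_length=True)
        return float(np.mean(np.log(cnt / emb.shape[0])))

    return max(phi(m) - phi(m + 1), 0.0)


def poincare(rr_ms: np.ndarray) -> tuple[float, float, float | None]:
    """Poincare-plot axes (population-variance convention).

    With x the series lagged by one beat and y the series itself,
    SD1 = sqrt(Var(y - x)/2) captures beat-to-beat variability and
    SD2 = sqrt(Var(y + x)/2) the long-range variability. The ratio is
    ``None`` (missing) when SD2 = 0.
    """
    rr = np.asarray(rr_ms, float)
    if rr.size < 3:
        raise InsufficientDataError("need at least 3 intervals")
    x, y = rr[:-1], rr[1:]
    sd1 = float(np.sqrt(np.var(y - x) / 2.0))
    sd2 = float(np.sqrt(np.var(y + x) / 2.0))
    ratio = sd1 / sd2 if sd2 > 0 else None
    return sd1, sd2, ratio


def lomb_scargle_psd(
    times_s: np.ndarray,
    values_ms: np.ndarray,
    freq_grid: np.ndarray | None = None,
    f_min: float = 0.01,
    f_max: float = 0.4,
    oversampling: int = 4,
    method: str = "auto",
) -> PSD:
    """Classical Lomb-Scargle periodogram of the beat series.

    ``times_s`` are the cumulative beat times of the filtered intervals;
    values are mean-subtracted internally. With no explicit grid, the grid
    spans [f_min, f_max] at spacing 1/(oversampling * span). ``method`` is
    ``"exact"`` (direct sums via scipy), ``"fft"`` (Press-Rybicki, identical
    to ~1e-12) or ``"auto"`` (fft on the default grid for large problems).
    """
    t = np.asarray(times_s, float)
    x = np.asarray(values_ms, float)
    if t.ndim != 1 or t.size != x.size:
        raise ValidationError("times and values must be same-length 1-D")
    if t.size < 10:
        raise InsufficientDataError("need at least 10 samples for a spectrum")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    x = x - x.mean()
    span = t[-1] - t[0]

    if freq_grid is not None:
        f = np.asarray(freq_grid, float)
        return PSD(f, np.maximum(lombscargle_exact(t, x, f), 0.0))

    if method not in ("auto", "exact", "fft"):
        raise ValidationError(f"unknown method {method!r}")
    if method == "auto":
        grid_n = f_max * oversampling * span
        method = "fft" if t.size * grid_n > 2e6 else "exact"
    if method == "fft":
        f, p = lombscargle_fft(t, x, f_max=f_max, oversampling=oversampling)
        mask = f >= f_min
        return PSD(f[mask], np.maximum(p[mask], 0.0))
    f = default_grid(span, f_min, f_max, oversampling)
    return PSD(f, np.maximum(lombscargle_exact(t, x, f), 0.0))


def band_powers(
    psd: PSD,
    vlf: tuple[float, float] = (0.01, 0.04),
    lf: tuple[float, float] = (0.04, 0.15),
    hf: tuple[float, float] = (0.15, 0.4),
) -> dict[str, float | None]:
    """Trapezoidal band integrals and the normalized LF/HF quantities.

    Normalized units exclude VLF: lf_nu = LF/(LF+HF), hf_nu = HF/(LF+HF).
    lf_hf is missing (None) when HF power is zero.
    """

    def integrate(lo: float, hi: float) -> float:
        f, p = psd.frequencies, psd.power
        pts = f[(f > lo) & (f < hi)]
        grid = np.concatenate(([lo], pts, [hi]))
        vals = np.interp(grid, f, p, left=0.0, right=0.0)
        return float(np.trapezoid(vals, grid))

    p_vlf = integrate(*vlf)
    p_lf = integrate(*lf)
    p_hf = integrate(*hf)
    tot = p_lf + p_hf
    return {
        "vlf": p_vlf,
        "lf": p_lf,
        "hf": p_hf,
        "lf_nu": p_lf / tot if tot > 0 else None,
        "hf_nu": p_hf / tot if tot > 0 else None,
        "lf_hf": p_lf / p_hf if p_hf > 0 else None,
    }


def extract_hrv_features(
    session: RRSession, config: PipelineConfig | None = None
) -> FeatureVector:
    """All 14 HRV features for one night, after artifact rejection.

    Features that are undefined on the input (e.g. SD1/SD2 on a constant
    series, LF/HF with zero HF power) are marked missing. Sessions shorter
    than the configured minimum (default 5 minutes of beats) raise
    :class:`InsufficientDataError`.
    """
    cfg = config or PipelineConfig()
    rr = filter_rr_artifacts(session.rr_ms, cfg.artifact_threshold)
    if rr.sum() / 1000.0 < cfg.min_session_s or rr.size < 10:
        raise InsufficientDataError(
            f"session has only {rr.sum() / 1000.0:.1f} s of beats after filtering"
        )
    values: dict[str, float | None] = dict.fromkeys(HRV_FEATURES)
    values.update(time_domain_features(rr, cfg.hist_bin_ms))
    sdnn = values["sdnn_ms"]
    values["apen"] = approximate_entropy(rr, cfg.apen_m, cfg.apen_r_factor * sdnn if sdnn else None)
    sd1, sd2, ratio = poincare(rr)
    values.update({"sd1_ms": sd1, "sd2_ms": sd2, "sd1_sd2": ratio})
    t = np.cumsum(rr) / 1000.0
    psd = lomb_scargle_psd(
        t, rr, f_min=cfg.f_min_hz, f_max=cfg.f_max_hz, oversampling=cfg.oversampling
    )
    bands = band_powers(psd, cfg.vlf_band, cfg.lf_band, cfg.hf_band)
    values.update({k: bands[k] for k in ("lf_nu", "hf_nu", "lf_hf")})
    return FeatureVector(modality=Modality.HRV, values=values)
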