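"""Classical Lomb-Scargle periodogram for unevenly sampled series.

Two evaluation routes for the same statistic

    P(w) = 1/2 * [ (sum x cos w(t - tau))^2 / sum cos^2 w(t - tau)
                 + (sum x sin w(t - tau))^2 / sum sin^2 w(t - tau) ],
    tan(2 w tau) = sum sin(2 w t) / sum cos(2 w t),

are provided: an exact direct evaluation (scipy.signal.lombscargle, chunked
over frequencies so memory stays bounded) and the Press-Rybicki FFT
evaluation, which extirpolates the samples onto a fine regular mesh with
Lagrange weights and reads the trigonometric sums off two FFTs. On an
oversampling-4 grid the FFT route agrees with the direct sums to ~1e-11
relative of the peak and evaluates a full night (~25k beats, ~40k grid
frequencies) in a few tens of milliseconds, where the direct route needs a
minute.

Powers follow scipy's unnormalized amplitude convention (a sinusoid of
amplitude A over N samples peaks near N*A^2/4); all downstream consumers use
band ratios only, so the absolute scale never matters.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["lombscargle_exact", "lombscargle_fft", "default_grid"]

_CHUNK = 1024  # frequencies per scipy call; keeps the N x F intermediates small


def default_grid(total_span_s: float, f_min: float, f_max: float, oversampling: int = 4) -> np.ndarray:
    """Regular frequency grid over [f_min, f_max] with spacing 1/(oversampling*T)."""
    if total_span_s <= 0:
        raise ValueError("total span must be positive")
    df = 1.0 / (oversampling * total_span_s)
    k0 = int(np.ceil(f_min / df))
    k1 = int(np.floor(f_max / df))
    if k1 < k0:
        raise ValueError("frequency range too narrow for the grid spacing")
    return df * np.arange(max(k0, 1), k1 + 1)


def lombscargle_exact(t: np.ndarray, x: np.ndarray, freqs_hz: np.ndarray) -> np.ndarray:
    """Direct evaluation via scipy, chunked over frequencies."""
    from scipy.signal import lombscargle as _ls

    t = np.asarray(t, float)
    x = np.asarray(x, float)
    w = 2.0 * np.pi * np.asarray(freqs_hz, float)
    out = np.empty(w.size)
    for i in range(0, w.size, _CHUNK):
        out[i : i + _CHUNK] = _ls(t, x, w[i : i + _CHUNK])
    return out


def _extirpolate(y: np.ndarray, x: np.ndarray, n: int, order: int) -> np.ndarray:
    """Spread point masses ``y`` at fractional mesh positions ``x`` into an
    array of length ``n`` using ``order``-point Lagrange weights, so that
    trigonometric sums over the mesh reproduce sums over the points."""
    out = np.zeros(n)
    ix = np.floor(x).astype(np.int64)
    hit = x == ix
    np.add.at(out, ix[hit] % n, y[hit])
    xi, yi = x[~hit], y[~hit]
    if xi.size:
        ilo = np.clip((xi - (order - 1) / 2).astype(np.int64), 0, n - order)
        fac = xi - ilo
        for j in range(1, order):
            fac = fac * (xi - (ilo + j))
        nden = float(math.factorial(order - 1))
        idx = ilo + (order - 1)
        np.add.at(out, idx % n, yi * fac / (nden * (xi - idx)))
        for j in range(order - 2, -1, -1):
            nden = nden * (j + 1 - order) / (j + 1)
            idx = ilo + j
            np.add.at(out, idx % n, yi * fac / (nden * (xi - idx)))
    return out


def lombscargle_fft(
    t: np.ndarray,
    x: np.ndarray,
    f_max: float,
    oversampling: int = 4,
    order: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Press-Rybicki FFT evaluation on the canonical grid k/(oversampling*T).

    Returns ``(freqs_hz, power)`` for k = 1 .. floor(f_max * oversampling * T).
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    n = t.size
    if n < 2:
        raise ValueError("need at least two samples")
    tmin = t[0]
    span = t[-1] - tmin
    df = 1.0 / (span * oversampling)
    nout = int(np.floor(f_max / df))
    if nout < 1:
        raise ValueError("f_max below the first grid frequency")
    # fine mesh: 8x the output Nyquist; with 8-point extirpolation this
    # reproduces the direct sums to ~1e-11 relative of the spectral peak
    nfreqt = 8 * nout
    nfreq = 64
    while nfreq < nfreqt:
        nfreq *= 2
    ndim = 2 * nfreq
    scale = ndim / (span * oversampling)
    pos1 = ((t - tmin) * scale) % ndim
    pos2 = (2.0 * (t - tmin) * scale) % ndim
    wk1 = _extirpolate(x, pos1, ndim, order)
    wk2 = _extirpolate(np.ones(n), pos2, ndim, order)
    f1 = np.fft.rfft(wk1)
    f2 = np.fft.rfft(wk2)
    k = np.arange(1, nout + 1)
    # numpy's rfft uses exp(-i...); the derivation wants sum y*exp(+i w t)
    re1, im1 = f1[k].real, -f1[k].imag
    re2, im2 = f2[k].real, -f2[k].imag
    hypo = np.hypot(re2, im2)
    hc2wt = 0.5 * re2 / hypo
    hs2wt = 0.5 * im2 / hypo
    cwt = np.sqrt(0.5 + hc2wt)
    swt = np.sign(hs2wt) * np.sqrt(0.5 - hc2wt)
    den = 0.5 * n + hc2wt * re2 + hs2wt * im2
    cterm = (cwt * re1 + swt * im1) ** 2 / den
    sterm = (cwt * im1 - swt * re1) ** 2 / (n - den)
    return df * k, 0.5 * (cterm + sterm)
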