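"""Independent brute-force reference implementations.

Every statistic here is written as directly as possible from its defining
formula (double loops, exhaustive searches, direct trigonometric sums) so
the package implementations can be checked against a second, structurally
different route.
"""

import math

import numpy as np


def sdnn_direct(rr):
    rr = np.asarray(rr, float)
    m = sum(rr) / len(rr)
    return math.sqrt(sum((v - m) ** 2 for v in rr) / (len(rr) - 1))


def rmssd_direct(rr):
    diffs = [b - a for a, b in zip(rr[:-1], rr[1:])]
    return math.sqrt(sum(d * d for d in diffs) / len(diffs))


def pnn50_direct(rr):
    diffs = [abs(b - a) for a, b in zip(rr[:-1], rr[1:])]
    return 100.0 * sum(d > 50.0 for d in diffs) / len(diffs)


def hrv_index_direct(rr, bin_ms=1000.0 / 128.0):
    idx = [math.floor(v / bin_ms) for v in rr]
    counts = {}
    for i in idx:
        counts[i] = counts.get(i, 0) + 1
    return len(rr) / max(counts.values())


def tinn_direct(edges, counts):
    """Exhaustive search over all (N, M) edge pairs around the modal bin."""
    edges = np.asarray(edges, float)
    counts = np.asarray(counts, float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    k = int(np.argmax(counts))
    x_peak, y_peak = centers[k], counts[k]
    best_err, best = np.inf, (edges[k], edges[k + 1])
    for n_edge in edges[: k + 1]:
        for m_edge in edges[k + 1 :]:
            err = 0.0
            for c, d in zip(centers, counts):
                if n_edge <= c <= x_peak:
                    q = y_peak * (c - n_edge) / (x_peak - n_edge) if x_peak > n_edge else y_peak
                elif x_peak < c <= m_edge:
                    q = y_peak * (m_edge - c) / (m_edge - x_peak)
                else:
                    q = 0.0
                err += (d - q) ** 2
            if err < best_err - 1e-12:
                best_err, best = err, (n_edge, m_edge)
    return best[1] - best[0]


def apen_direct(x, m=2, r=None):
    """Double-loop template counting, Chebyshev distance, self-matches in."""
    x = np.asarray(x, float)
    n = len(x)
    if r is None:
        r = 0.2 * x.std(ddof=1)
    if r <= 0:
        return 0.0

    def phi(mm):
        count = n - mm + 1
        total = 0.0
        for i in range(count):
            matches = 0
            for j in range(count):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    matches += 1
            total += math.log(matches / count)
        return total / count

    return max(phi(m) - phi(m + 1), 0.0)


def poincare_direct(rr):
    rr = np.asarray(rr, float)
    d = rr[1:] - rr[:-1]
    s = rr[1:] + rr[:-1]
    sd1 = math.sqrt(np.var(d) / 2.0)
    sd2 = math.sqrt(np.var(s) / 2.0)
    return sd1, sd2


def lombscargle_direct(t, x, freqs_hz):
    """Classical Lomb-Scargle with the per-frequency tau offset, plain sums."""
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    out = []
    for f in np.atleast_1d(freqs_hz):
        w = 2.0 * math.pi * f
        tau = math.atan2(np.sum(np.sin(2 * w * t)), np.sum(np.cos(2 * w * t))) / (2 * w)
        c = np.cos(w * (t - tau))
        s = np.sin(w * (t - tau))
        out.append(0.5 * ((x @ c) ** 2 / (c @ c) + (x @ s) ** 2 / (s @ s)))
    return np.array(out)


def dbscan_direct(points_m, eps, min_pts):
    """Textbook DBSCAN on pre-computed metric coordinates (meters).

    Returns the number of clusters (noise excluded)."""
    pts = np.asarray(points_m, float)
    n = len(pts)
    dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    neighbors = [set(np.flatnonzero(dist[i] <= eps)) for i in range(n)]
    labels = [None] * n
    cluster = -1
    for i in range(n):
        if labels[i] is not None:
            continue
        if len(neighbors[i]) < min_pts:
            labels[i] = -1
            continue
        cluster += 1
        labels[i] = cluster
        frontier = list(neighbors[i] - {i})
        while frontier:
            j = frontier.pop()
            if labels[j] == -1:
                labels[j] = cluster
            if labels[j] is not None:
                continue
            labels[j] = cluster
            if len(neighbors[j]) >= min_pts:
                frontier.extend(neighbors[j] - {j})
    return cluster + 1
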