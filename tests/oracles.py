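"""Independent brute-force reference implementations used only by tests.

Each oracle is written as a plain, loop-based transcription of the
definition it checks, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def apen_bruteforce(x, m=2, r=None):
    """ApEn via explicit template loops (Chebyshev, self-matches included)."""
    x = list(map(float, x))
    n = len(x)
    if r is None:
        r = 0.2 * float(np.std(x))

    def phi(mm):
        templates = [x[i:i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for a in templates:
            count = 0
            for b in templates:
                if max(abs(u - v) for u, v in zip(a, b)) <= r:
                    count += 1
            total += math.log(count / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def recurrence_matrix_bruteforce(x, dim, delay, eps_frac=0.2):
    """Recurrence matrix via double loops over embedded vectors."""
    x = list(map(float, x))
    n_vec = len(x) - (dim - 1) * delay
    emb = [[x[i + k * delay] for k in range(dim)] for i in range(n_vec)]
    dmax = 0.0
    for i in range(n_vec):
        for j in range(i + 1, n_vec):
            d = math.sqrt(sum((a - b) ** 2 for a, b in zip(emb[i], emb[j])))
            dmax = max(dmax, d)
    eps = eps_frac * dmax
    rm = np.zeros((n_vec, n_vec), dtype=bool)
    for i in range(n_vec):
        for j in range(n_vec):
            d = math.sqrt(sum((a - b) ** 2 for a, b in zip(emb[i], emb[j])))
            rm[i, j] = d <= eps
    return rm


def extrema_scan(x, guard_frac=0.02):
    """Exhaustive extremum scan with the same prominence-pruning rule."""
    x = list(map(float, x))
    signs = []
    prev = 0
    for i in range(len(x) - 1):
        s = (x[i + 1] > x[i]) - (x[i + 1] < x[i])
        if s == 0:
            s = prev
        signs.append(s)
        prev = s
    idx = [i + 1 for i in range(len(signs) - 1) if signs[i + 1] != signs[i]]
    q75, q25 = np.percentile(x, [75, 25])
    guard = guard_frac * (q75 - q25)
    if guard > 0:
        while len(idx) >= 2:
            swings = [abs(x[idx[k + 1]] - x[idx[k]]) for k in range(len(idx) - 1)]
            k = min(range(len(swings)), key=swings.__getitem__)
            if swings[k] >= guard:
                break
            del idx[k:k + 2]
    return idx


def sparc_arc_bruteforce(x, fs, threshold_pct, fmax=20.0, grid=0.05):
    """Spectral arc length by explicit per-bin summation."""
    x = np.asarray(x, dtype=float)
    nfft = 1
    while nfft < max(len(x), fs / grid):
        nfft *= 2
    spectrum = np.fft.rfft(x, n=nfft)
    arc = 0.0
    freqs, mags = [], []
    for k in range(len(spectrum)):
        f = k * fs / nfft
        if f > fmax:
            break
        freqs.append(f)
        mags.append(abs(spectrum[k]))
    peak = max(mags)
    mhat = [v / peak for v in mags]
    cutoff_idx = 0
    for k, v in enumerate(mhat):
        if v >= threshold_pct / 100.0:
            cutoff_idx = k
    if cutoff_idx == 0:
        return float("nan")
    wc = freqs[cutoff_idx]
    for k in range(cutoff_idx):
        df = (freqs[k + 1] - freqs[k]) / wc
        dm = mhat[k + 1] - mhat[k]
        arc += math.sqrt(df * df + dm * dm)
    return -arc


def welch_band_power_bruteforce(x, fs, lo, hi, nperseg=500):
    """Band power by explicit Hann-windowed periodogram averaging."""
    x = np.asarray(x, dtype=float)
    nperseg = min(nperseg, len(x))
    nfft = max(nperseg, int(round(fs / 0.1)))
    step = nperseg // 2
    win = np.hanning(nperseg + 1)[:-1]  # periodic Hann
    segs = []
    start = 0
    while start + nperseg <= len(x):
        seg = x[start:start + nperseg]
        seg = (seg - seg.mean()) * win
        p = np.abs(np.fft.rfft(seg, n=nfft)) ** 2
        segs.append(p)
        start += step
    psd = np.mean(segs, axis=0) / (fs * np.sum(win ** 2))
    psd[1:-1] *= 2  # one-sided
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    # trapezoid over the half-open grid selection lo <= f < hi
    total = 0.0
    for k in range(len(freqs) - 1):
        f0, f1 = freqs[k], freqs[k + 1]
        if f0 >= lo and f1 < hi:
            total += 0.5 * (psd[k] + psd[k + 1]) * (f1 - f0)
    return total


def stroke_count_scan(force, enter, leave, min_samples):
    """Stroke count by a plain hysteresis state machine."""
    count = 0
    on = False
    start = 0
    intervals = []
    for i, f in enumerate(force):
        if not on and f > enter:
            on, start = True, i
        elif on and f < leave:
            intervals.append((start, i))
            on = False
    if on:
        intervals.append((start, len(force)))
    for a, b in intervals:
        if b - a >= min_samples:
            count += 1
    return count
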