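"""Independent brute-force recomputation of every per-step statistic.

Everything here is written from the textbook definitions in (mostly) pure
Python — explicit loops, a naive O(n^2) DFT — deliberately avoiding the
vectorized numpy/scipy paths the implementation uses, so agreement is a real
cross-check and not the same code run twice.
"""

import cmath
import math
from statistics import median


def _mean(x):
    return sum(x) / len(x)


def _percentile_linear(xs, q):
    """Linear-interpolation percentile (the standard 'linear' definition)."""
    s = sorted(xs)
    pos = (len(s) - 1) * q / 100.0
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    return s[lo] + (s[hi] - s[lo]) * (pos - lo)


def _pearson(a, b):
    n = len(a)
    ma, mb = _mean(a), _mean(b)
    va = sum((v - ma) ** 2 for v in a)
    vb = sum((v - mb) ** 2 for v in b)
    if va == 0.0 or vb == 0.0:
        return 0.0
    cov = sum((a[i] - ma) * (b[i] - mb) for i in range(n))
    return cov / math.sqrt(va * vb)


def _dft_power(x):
    """One-sided power spectrum by direct DFT summation, DC bin removed."""
    n = len(x)
    n_bins = n // 2 + 1
    p = []
    for k in range(1, n_bins):
        c = sum(x[j] * cmath.exp(-2j * math.pi * k * j / n) for j in range(n))
        p.append(abs(c) ** 2)
    return p


def naive_stat(x, stat, fs):
    x = [float(v) for v in x]
    n = len(x)
    m = _mean(x)
    if stat == "mean":
        return m
    if stat == "median":
        return median(x)
    if stat == "var":
        return sum((v - m) ** 2 for v in x) / (n - 1)
    if stat == "std":
        return math.sqrt(naive_stat(x, "var", fs))
    if stat == "min":
        return min(x)
    if stat == "max":
        return max(x)
    if stat == "range":
        return max(x) - min(x)
    if stat == "rms":
        return math.sqrt(sum(v * v for v in x) / n)
    if stat == "iqr":
        return _percentile_linear(x, 75) - _percentile_linear(x, 25)
    if stat == "mad":
        md = median(x)
        return median([abs(v - md) for v in x])
    if stat == "skewness":
        if max(x) == min(x):
            return 0.0
        m2 = sum((v - m) ** 2 for v in x) / n
        m3 = sum((v - m) ** 3 for v in x) / n
        return m3 / m2 ** 1.5
    if stat == "kurtosis":
        if max(x) == min(x):
            return 0.0
        m2 = sum((v - m) ** 2 for v in x) / n
        m4 = sum((v - m) ** 4 for v in x) / n
        return m4 / m2 ** 2 - 3.0
    if stat == "energy":
        return sum(v * v for v in x)
    if stat == "mav":
        return sum(abs(v) for v in x) / n
    if stat == "zero_crossings":
        return float(sum(1 for i in range(n - 1) if x[i] * x[i + 1] < 0))
    if stat == "mean_crossings":
        c = [v - m for v in x]
        return float(sum(1 for i in range(n - 1) if c[i] * c[i + 1] < 0))
    if stat == "first_last_diff":
        return x[-1] - x[0]
    if stat == "autocorr_lag1":
        return _pearson(x[:-1], x[1:])

    p = _dft_power(x)
    total = sum(p)
    freqs = [k * fs / n for k in range(1, len(p) + 1)]
    if stat == "dom_freq":
        return 0.0 if total == 0 else freqs[p.index(max(p))]
    if stat == "dom_freq_power":
        return 0.0 if total == 0 else max(p) / total
    if stat == "spectral_entropy":
        if total == 0:
            return 0.0
        return -sum((v / total) * math.log(v / total) for v in p if v > 0)
    if stat == "spectral_centroid":
        if total == 0:
            return 0.0
        return sum(f * v for f, v in zip(freqs, p)) / total
    if stat.startswith("bandpower_"):
        lo, hi = (float(v) for v in stat.split("_")[1:3])
        if total == 0:
            return 0.0
        return sum(v for f, v in zip(freqs, p) if lo <= f < hi) / total
    raise KeyError(stat)


def naive_feature_vector(step, registry):
    """Recompute a whole step's feature vector from the registry entries."""

    def series(name):
        if name == "acc_norm":
            return [math.sqrt(sum(c * c for c in row[:3])) for row in step.channels]
        if name == "gyr_norm":
            return [math.sqrt(sum(c * c for c in row[3:])) for row in step.channels]
        from gaitpd.preprocess import CHANNEL_NAMES
        return list(step.channels[:, CHANNEL_NAMES.index(name)])

    out = []
    for e in registry.entries:
        if e.kind == "corr":
            out.append(_pearson(series(e.channels[0]), series(e.channels[1])))
        else:
            out.append(naive_stat(series(e.channels[0]), e.stat, step.fs))
    return out
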