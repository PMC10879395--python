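"""Independent reference implementations used as oracles in tests.

These deliberately share no code with the package: the event scan is an
explicit per-sample Python loop, the modulation index is a direct
histogram-plus-entropy computation, and the single-taper spectrogram is a
plain Hann periodogram.
"""

from __future__ import annotations

import math

import numpy as np


def scan_events(
    env: np.ndarray,
    fs: float,
    usable: np.ndarray,
    threshold_sd: float,
    min_duration_ms: float,
) -> list[tuple[int, int]]:
    """Naive per-sample scan of the envelope implementing the detection rule.

    Baseline mean/SD over ``usable`` samples; cores are runs above
    mean + threshold_sd*SD lasting >= min_duration_ms, extended sample by
    sample to the nearest baseline (mean) crossing, merged when spans touch,
    and dropped if they leave ``usable`` or hit the trace ends.
    Returns half-open (start, stop) sample spans.
    """
    vals = [e for e, u in zip(env, usable) if u]
    mu = sum(vals) / len(vals)
    sd = math.sqrt(sum((v - mu) ** 2 for v in vals) / len(vals))
    thr = mu + threshold_sd * sd
    min_n = math.ceil(min_duration_ms / 1000.0 * fs)
    n = len(env)

    spans = []
    i = 0
    while i < n:
        if env[i] > thr:
            j = i
            while j < n and env[j] > thr:
                j += 1
            if j - i >= min_n:
                lo = i
                while lo > 0 and env[lo - 1] > mu:
                    lo -= 1
                hi = j
                while hi < n and env[hi] > mu:
                    hi += 1
                if spans and lo <= spans[-1][1]:
                    spans[-1] = (spans[-1][0], max(spans[-1][1], hi))
                else:
                    spans.append((lo, hi))
            i = j
        else:
            i += 1

    kept = []
    for lo, hi in spans:
        if lo == 0 or hi == n:
            continue
        if not all(usable[lo:hi]):
            continue
        kept.append((lo, hi))
    return kept


def direct_mi(phase: np.ndarray, amp: np.ndarray, n_bins: int) -> float:
    """Modulation index by direct binning and Shannon entropy."""
    edges = [-math.pi + 2 * math.pi * b / n_bins for b in range(n_bins + 1)]
    sums = [0.0] * n_bins
    counts = [0] * n_bins
    for ph, a in zip(phase, amp):
        b = int((ph + math.pi) / (2 * math.pi) * n_bins)
        if b == n_bins:  # ph == +pi boundary
            b = n_bins - 1
        sums[b] += a
        counts[b] += 1
    means = [s / c if c else 0.0 for s, c in zip(sums, counts)]
    total = sum(means)
    p = [m / total for m in means]
    h = -sum(q * math.log(q) for q in p if q > 0)
    return (math.log(n_bins) - h) / math.log(n_bins)


def hann_spectrogram(
    x: np.ndarray, fs: float, window_s: float, step_s: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-taper (Hann) spectrogram: times, freqs, power [freq x time]."""
    n_win = int(round(window_s * fs))
    n_step = int(round(step_s * fs))
    win = np.hanning(n_win)
    win = win / np.sqrt((win**2).sum())
    starts = np.arange(0, x.size - n_win + 1, n_step)
    power = []
    for s in starts:
        seg = x[s : s + n_win] * win
        spec = np.fft.rfft(seg)
        p = np.abs(spec) ** 2 / fs
        p[1:] *= 2
        if n_win % 2 == 0:
            p[-1] /= 2
        power.append(p)
    freqs = np.fft.rfftfreq(n_win, 1 / fs)
    times = (starts + (n_win - 1) / 2) / fs
    return times, freqs, np.array(power).T


def anova_by_hand(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """One-way ANOVA F from explicit sums of squares; returns (F, df1, df2)."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(all_vals) - len(groups)
    return (ssb / df1) / (ssw / df2), df1, df2
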