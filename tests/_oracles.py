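"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: f0 comes from an
autocorrelation peak (not a cumulative-mean-normalised difference dip),
entropies are summed with plain ``math``, and rank-sum p-values are
enumerated exhaustively.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def autocorr_f0_frames(
    samples: np.ndarray,
    sample_rate: float,
    window_s: float = 0.033,
    hop_s: float = 0.0007,
    f0_min: float = 80.0,
    f0_max: float = 1200.0,
) -> np.ndarray:
    """Per-frame f0 from the highest autocorrelation peak in the lag range,
    parabolic-refined; frames match the analysis framing (2 windows/frame)."""
    sr = sample_rate
    W = int(round(window_s * sr))
    hop = max(1, int(round(hop_s * sr)))
    span = 2 * W
    frames = sliding_window_view(np.asarray(samples, float), span)[::hop]
    lag_lo = max(2, int(sr / f0_max))
    lag_hi = min(span - 2, int(math.ceil(sr / f0_min)))
    nfft = 1 << (2 * span - 1).bit_length()
    # Hann-taper the segment and normalise by the window's own
    # autocorrelation: this suppresses the edge ripple of finite-segment
    # autocorrelation, which otherwise biases long-lag peak positions
    win = np.hanning(span)
    spec = np.fft.rfft(frames * win, nfft, axis=1)
    ac = np.fft.irfft(spec * spec.conj(), nfft, axis=1)[:, : lag_hi + 2]
    wspec = np.fft.rfft(win, nfft)
    ac_w = np.fft.irfft(wspec * wspec.conj(), nfft)[: lag_hi + 2]
    ac /= ac_w
    out = np.empty(len(frames))
    for i, row in enumerate(ac):
        window = row[lag_lo : lag_hi + 1]
        peak = float(np.max(window))
        # a periodic signal peaks equally at every multiple of its period;
        # take the smallest lag whose peak is essentially the global one
        near = np.nonzero(window >= 0.98 * peak)[0]
        lag = lag_lo + int(near[0])
        while lag + 1 <= lag_hi + 1 and row[lag + 1] > row[lag]:
            lag += 1
        a, b, c = row[lag - 1], row[lag], row[lag + 1]
        denom = a - 2 * b + c
        shift = 0.5 * (a - c) / denom if denom < 0 else 0.0
        out[i] = sr / (lag + float(np.clip(shift, -0.5, 0.5)))
    return out


def entropy_oracle(labels) -> float:
    counts: dict = {}
    for y in labels:
        counts[y] = counts.get(y, 0) + 1
    n = sum(counts.values())
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def information_gain_oracle(feature, labels, cuts) -> float:
    """IG over explicitly stated bin cut points, by direct enumeration."""
    bins: dict[int, list] = {}
    for x, y in zip(feature, labels):
        b = sum(x > c for c in cuts)
        bins.setdefault(b, []).append(y)
    n = len(labels)
    cond = sum(len(ys) / n * entropy_oracle(ys) for ys in bins.values())
    return entropy_oracle(labels) - cond


def ranksum_exact_p(a, b) -> float:
    """Two-sided rank-sum p-value by exhaustive enumeration of group
    assignments (tie-free samples, small n only)."""
    pooled = sorted(list(a) + list(b))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    na = len(a)
    observed = sum(ranks[v] for v in a)
    mean = na * (len(pooled) + 1) / 2
    sums = [sum(c) for c in combinations(range(1, len(pooled) + 1), na)]
    extreme = sum(abs(s - mean) >= abs(observed - mean) - 1e-9 for s in sums)
    return extreme / len(sums)


def mannwhitney_u_oracle(a, b) -> float:
    """U statistic by direct pair counting (ties count half)."""
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u
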