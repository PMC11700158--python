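"""Independent brute-force re-implementations used as test oracles.

These deliberately avoid the package's vectorized code paths: plain Python
loops, one rule at a time.
"""

import numpy as np


def brute_force_weight_shift(left, right, weight, fs=100.0,
                             window_s=2.0, stride_s=0.1):
    """Straight-line re-implementation of the gait quantification:
    rescale -> merge/mirror -> per-window sum of absolute differences."""
    n = len(left)
    merged = []
    for i in range(n):
        lo = left[i] / weight
        ro = right[i] / weight
        if lo >= ro:
            merged.append(lo)
        else:
            merged.append(1.0 - ro)
    n_win = int(round(window_s * fs))
    n_stride = int(round(stride_s * fs))
    times, values = [], []
    end = n_win
    while end <= n:
        tv = 0.0
        for i in range(end - n_win, end - 1):
            tv += abs(merged[i + 1] - merged[i])
        times.append(end / fs)
        values.append(tv)
        end += n_stride
    return np.array(times), np.array(values)


def brute_force_kendall_tau_b(x, y):
    """O(n^2) pair counting with tie correction."""
    n = len(x)
    concordant = discordant = tied_in_x = tied_in_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0:
                tied_in_x += 1
            if dy == 0:
                tied_in_y += 1
            if dx != 0 and dy != 0:
                if dx * dy > 0:
                    concordant += 1
                else:
                    discordant += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tied_in_x) * (n0 - tied_in_y))
    if denom == 0:
        return np.nan
    return (concordant - discordant) / denom
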