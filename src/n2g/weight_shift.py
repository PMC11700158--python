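"""Gait quantification from dual force plates.

Forces are rescaled to body-weight fractions, the two plates are merged by
taking the greater sample and mirroring the other plate about half weight,
and the amount of shifting over each 2-s window (0.1-s stride) is scored
as the total variation of the merged trace. Per-participant normalization
maps the maximum 2-s shift across all provided visits to 1; a motionless
trace scores exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_preproc import Recording

WINDOW_S = 2.0
STRIDE_S = 0.1


@dataclass
class MergedTrace:
    values: np.ndarray        # body-weight fraction, nominal [0, 1]
    fs: float
    origin_flags: np.ndarray  # True where the left plate supplied the sample
    t0: float = 0.0


@dataclass
class WeightShiftSeries:
    times: np.ndarray             # window END times, 0.1-s grid
    raw_values: np.ndarray        # nonnegative total-variation shifts
    normalized_values: np.ndarray | None = None
    normalizer: float | None = None

    def __len__(self):
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"time_s": self.times, "raw": self.raw_values})
        if self.normalized_values is not None:
            frame["normalized"] = self.normalized_values
        return frame


def rescale_by_weight(force: Recording, weight: float) -> Recording:
    if weight <= 0:
        raise ValueError("participant weight must be positive")
    return Recording(data=force.data / weight, fs=force.fs,
                     channel_labels=force.channel_labels, t0=force.t0)


def merge_and_mirror(left: np.ndarray, right: np.ndarray,
                     fs: float = 100.0, t0: float = 0.0) -> MergedTrace:
    """Per sample: take the higher plate; mirror right-plate picks about 0.5.

    All weight on the left maps to 1, all on the right to 0, balance to 0.5.
    Ties go to the left plate (both branches agree at the 0.5/0.5 balance
    point; elsewhere ties are measure-zero).
    """
    left = np.asarray(left, dtype=np.float64)
    right = np.asarray(right, dtype=np.float64)
    if left.shape != right.shape:
        raise ValueError("plate series length mismatch")
    from_left = left >= right
    values = np.where(from_left, left, 1.0 - right)
    return MergedTrace(values=values, fs=fs, origin_flags=from_left, t0=t0)


def windowed_shift(merged: MergedTrace, window_s: float = WINDOW_S,
                   stride_s: float = STRIDE_S) -> WeightShiftSeries:
    """Total variation of the merged trace over each trailing window.

    Windows end on the stride grid: end time t covers the half-open
    interval (t - window_s, t]; the value is the sum of absolute first
    differences of the samples inside the window.
    """
    n_win = int(round(window_s * merged.fs))
    n_stride = int(round(stride_s * merged.fs))
    n = len(merged.values)
    if n < n_win:
        warnings.warn("recording shorter than one window; empty shift series",
                      stacklevel=2)
        return WeightShiftSeries(times=np.empty(0), raw_values=np.empty(0))
    absdiff = np.abs(np.diff(merged.values))
    ends = np.arange(n_win, n + 1, n_stride)  # sample count up to window end
    raw = np.array([absdiff[e - n_win:e - 1].sum() for e in ends])
    times = merged.t0 + ends / merged.fs
    return WeightShiftSeries(times=np.round(times, 9), raw_values=raw)


def normalize_across_visits(
        series_by_visit: dict[str, WeightShiftSeries],
        normalizer_visits: list[str] | None = None,
) -> dict[str, WeightShiftSeries]:
    """Divide every visit by the participant-level max raw shift.

    By default the normalizer is the maximum over all provided visits;
    `normalizer_visits` can restrict it (e.g. to the training visit only).
    """
    if not series_by_visit:
        raise ValueError("need at least one visit")
    pool = normalizer_visits or list(series_by_visit)
    normalizer = max(float(series_by_visit[v].raw_values.max(initial=0.0))
                     for v in pool)
    if normalizer <= 0:
        raise ValueError("no movement detected; normalizer undefined")
    out = {}
    for name, series in series_by_visit.items():
        out[name] = WeightShiftSeries(
            times=series.times,
            raw_values=series.raw_values,
            normalized_values=series.raw_values / normalizer,
            normalizer=normalizer,
        )
    return out


def compute_visit_shift(force_bw: Recording) -> WeightShiftSeries:
    """Merged-and-mirrored windowed shift for one visit.

    `force_bw` must already be low-pass filtered and rescaled to
    body-weight fractions (left plate first channel, right second).
    """
    merged = merge_and_mirror(force_bw.data[0], force_bw.data[1],
                              fs=force_bw.fs, t0=force_bw.t0)
    return windowed_shift(merged)
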