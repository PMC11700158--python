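"""Windowed (LFP, label) examples.

Each example pairs the trailing 5 s of two-channel LFP at 211 Hz with the
weight shift over that window's last 2 s, on a 0.1-s end-time grid. The
0.1-s stride is 21.1 LFP samples, so window ends are defined on the force
grid and snapped to the nearest LFP sample (max misalignment ~2.4 ms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_preproc import (Recording, SessionManifest, estimate_body_weight,
                         preprocess_force, preprocess_lfp, read_recording)
from .weight_shift import (WeightShiftSeries, compute_visit_shift,
                           normalize_across_visits, rescale_by_weight)

WIN_S = 5.0
LABEL_WIN_S = 2.0
STRIDE_S = 0.1
LFP_WIN_SAMPLES = 1055  # round(5 * 211)


@dataclass
class WindowedDataset:
    lfp_windows: np.ndarray   # [n, 2, 1055]
    labels: np.ndarray        # [n], in [0, 1]
    end_times: np.ndarray     # [n], seconds
    role: str = ""
    participant_id: str = ""

    def __len__(self):
        return len(self.labels)

    def __post_init__(self):
        if len(self.lfp_windows) != len(self.labels) != len(self.end_times):
            raise ValueError("inconsistent example counts")


def build_windowed_dataset(lfp: Recording, labels: WeightShiftSeries,
                           win_s: float = WIN_S, stride_s: float = STRIDE_S,
                           role: str = "", participant_id: str = "",
                           task_interval: tuple[float, float] | None = None,
                           ) -> WindowedDataset:
    """One example per label end time >= win_s that fits in the LFP stream."""
    if labels.times.size:
        # both streams share an origin; label grid must land on the stride grid
        phase = (labels.times[0] - lfp.t0) / stride_s
        if abs(phase - round(phase)) * stride_s > 0.005:  # half a 100 Hz sample
            raise ValueError("LFP and label streams misaligned beyond half "
                             "a force sample")
    n_win = LFP_WIN_SAMPLES if win_s == WIN_S else int(round(win_s * lfp.fs))
    values = (labels.normalized_values if labels.normalized_values is not None
              else labels.raw_values)
    windows, out_labels, out_times = [], [], []
    for t_end, label in zip(labels.times, values):
        if t_end < win_s - 1e-9:
            continue
        if task_interval is not None and not (
                task_interval[0] - 1e-9 <= t_end <= task_interval[1] + 1e-9):
            continue
        start = int(round((t_end - win_s - lfp.t0) * lfp.fs))
        stop = start + n_win
        if start < 0 or stop > lfp.n_samples:
            continue
        windows.append(lfp.data[:, start:stop])
        out_labels.append(label)
        out_times.append(t_end)
    if not windows:
        warnings.warn("task shorter than one input window; empty dataset",
                      stacklevel=2)
        return WindowedDataset(np.empty((0, 2, n_win)), np.empty(0),
                               np.empty(0), role, participant_id)
    return WindowedDataset(np.stack(windows), np.asarray(out_labels),
                           np.asarray(out_times), role, participant_id)


def load_visit(manifest: SessionManifest, role: str):
    """Load and preprocess one visit: (lfp@211 filtered, force@100 filtered,
    body-weight-fraction force)."""
    visit = manifest.visit(role)
    lfp_raw = read_recording(visit.lfp_path, expected_fs=visit.lfp_fs,
                             expected_channels=2)
    force_raw = read_recording(visit.force_path, expected_fs=visit.force_fs,
                               expected_channels=2)
    lfp = preprocess_lfp(lfp_raw)
    force = preprocess_force(force_raw)
    weight = estimate_body_weight(force, visit.baseline_interval)
    force_bw = rescale_by_weight(force, weight)
    return lfp, force_bw, weight


def assemble_splits(manifest: SessionManifest,
                    normalizer_visits: list[str] | None = None,
                    ) -> dict[str, WindowedDataset]:
    """Per-participant train/validation/test datasets in chronological order."""
    manifest.validate()
    roles = SessionManifest.ROLES
    for role in roles:
        manifest.visit(role)  # raises if missing

    lfps, shifts, task_intervals = {}, {}, {}
    for role in roles:
        lfp, force_bw, _ = load_visit(manifest, role)
        lfps[role] = lfp
        shifts[role] = compute_visit_shift(force_bw)
        task_intervals[role] = manifest.visit(role).task_interval
    normalized = normalize_across_visits(shifts, normalizer_visits)
    return {
        role: build_windowed_dataset(
            lfps[role], normalized[role], role=role,
            participant_id=manifest.participant_id,
            task_interval=task_intervals[role])
        for role in roles
    }


def subsample(ds: WindowedDataset, stride: int) -> WindowedDataset:
    """Every `stride`-th example (used to scale training runs down)."""
    return WindowedDataset(ds.lfp_windows[::stride], ds.labels[::stride],
                           ds.end_times[::stride], ds.role, ds.participant_id)
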