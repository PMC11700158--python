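"""Session I/O and fixed preprocessing.

Recordings are delimited text with a `time` column (seconds) plus one
column per channel. LFP streams are decimated 422 -> 211 Hz and band-pass
filtered 8-100 Hz with a causal 4th-order Butterworth; force streams are
decimated to 100 Hz and low-pass filtered at 2 Hz. Causal (single-pass)
filtering is used throughout because the decoder targets streaming use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal

LFP_RAW_FS = 422.0
LFP_FS = 211.0
FORCE_FS = 100.0
LFP_BAND = (8.0, 100.0)
FORCE_LOWPASS_HZ = 2.0
IIR_ORDER = 4


class LoadError(ValueError):
    """Raised when a session file violates the storage contract."""


@dataclass
class Recording:
    """Uniformly sampled multichannel time series."""

    data: np.ndarray  # [channels, samples]
    fs: float
    channel_labels: tuple[str, ...]
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("channel label count does not match data rows")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def validate(self):
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains NaN/Inf")
        return self


@dataclass
class VisitSpec:
    visit_label: str
    months_since_ip: int
    lfp_path: str
    force_path: str
    baseline_interval: tuple[float, float]
    role: str  # train | validation | test
    lfp_fs: float = LFP_RAW_FS
    force_fs: float = FORCE_FS
    stream_offset_s: float = 0.0
    task_interval: tuple[float, float] | None = None


@dataclass
class SessionManifest:
    participant_id: str
    visits: list[VisitSpec] = field(default_factory=list)

    ROLES = ("train", "validation", "test")

    def validate(self) -> "SessionManifest":
        roles = [v.role for v in self.visits]
        for role in roles:
            if role not in self.ROLES:
                raise ValueError(f"unknown role {role!r}")
        if len(set(roles)) != len(roles):
            raise ValueError("two visits share a role")
        months = {v.role: v.months_since_ip for v in self.visits}
        order = [months[r] for r in self.ROLES if r in months]
        if order != sorted(order) or len(set(order)) != len(order):
            raise ValueError(
                "roles must follow chronological order: train earliest, test latest")
        for v in self.visits:
            lo, hi = v.baseline_interval
            if not (0 <= lo < hi):
                raise ValueError(f"bad baseline interval for visit {v.visit_label}")
        return self

    def visit(self, role: str) -> VisitSpec:
        for v in self.visits:
            if v.role == role:
                return v
        raise KeyError(f"manifest has no visit with role {role!r}")


def read_manifest(path: str | Path) -> SessionManifest:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    visits = []
    for v in raw["visits"]:
        visits.append(VisitSpec(
            visit_label=str(v["visit_label"]),
            months_since_ip=int(v["months_since_ip"]),
            lfp_path=str((path.parent / v["lfp_path"])),
            force_path=str((path.parent / v["force_path"])),
            baseline_interval=tuple(float(x) for x in v["baseline_interval"]),
            role=str(v["role"]),
            lfp_fs=float(v.get("lfp_fs", LFP_RAW_FS)),
            force_fs=float(v.get("force_fs", FORCE_FS)),
            stream_offset_s=float(v.get("stream_offset_s", 0.0)),
            task_interval=(tuple(float(x) for x in v["task_interval"])
                           if v.get("task_interval") else None),
        ))
    return SessionManifest(participant_id=str(raw["participant_id"]),
                           visits=visits).validate()


def write_manifest(manifest: SessionManifest, path: str | Path):
    path = Path(path)
    doc = {
        "participant_id": manifest.participant_id,
        "visits": [
            {
                "visit_label": v.visit_label,
                "months_since_ip": v.months_since_ip,
                "lfp_path": str(Path(v.lfp_path).name),
                "force_path": str(Path(v.force_path).name),
                "baseline_interval": list(v.baseline_interval),
                "role": v.role,
                "lfp_fs": v.lfp_fs,
                "force_fs": v.force_fs,
            }
            for v in manifest.visits
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_recording(path: str | Path, expected_fs: float | None = None,
                   expected_channels: int | None = None) -> Recording:
    """Parse a `time,<ch1>,<ch2>,...` CSV into a Recording.

    The sampling rate is inferred from the time column and checked against
    `expected_fs` within 0.1%.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise LoadError(f"{path}: unreadable CSV ({exc})") from exc
    if "time" not in frame.columns:
        raise LoadError(f"{path}: missing 'time' column")
    channels = [c for c in frame.columns if c != "time"]
    if not channels:
        raise LoadError(f"{path}: no channel columns")
    if expected_channels is not None and len(channels) != expected_channels:
        raise LoadError(
            f"{path}: expected {expected_channels} channels, found {len(channels)}")
    if frame.isna().any().any():
        row = int(frame.isna().any(axis=1).idxmax())
        raise LoadError(f"{path}: NaN cell at row {row}")
    t = frame["time"].to_numpy(dtype=np.float64)
    if len(t) < 2:
        raise LoadError(f"{path}: need at least two samples")
    dt = np.diff(t)
    dt0 = np.median(dt)
    if dt0 <= 0:
        raise LoadError(f"{path}: non-increasing time column")
    bad = np.abs(dt - dt0) > 0.01 * dt0
    if bad.any():
        row = int(np.argmax(bad)) + 1
        raise LoadError(f"{path}: non-uniform sampling at row {row}")
    fs = 1.0 / dt0
    if expected_fs is not None:
        if abs(fs - expected_fs) > 1e-3 * expected_fs:
            raise LoadError(
                f"{path}: inferred fs {fs:.4f} Hz deviates from expected "
                f"{expected_fs}")
        fs = float(expected_fs)  # snap to the declared rate
    data = frame[channels].to_numpy(dtype=np.float64).T
    return Recording(data=data, fs=float(round(fs, 6)),
                     channel_labels=tuple(channels), t0=float(t[0])).validate()


def write_recording(rec: Recording, path: str | Path):
    path = Path(path)
    frame = pd.DataFrame({"time": rec.times})
    for label, row in zip(rec.channel_labels, rec.data):
        frame[label] = row
    frame.to_csv(path, index=False, float_format="%.10g")


def _sos_lowpass(cutoff: float, fs: float, order: int):
    return signal.butter(order, cutoff, btype="low", fs=fs, output="sos")


def design_iir(lo: float | None, hi: float | None, fs: float,
               order: int = IIR_ORDER):
    """Causal Butterworth SOS: band-pass, low-pass (lo None) or high-pass."""
    nyq = fs / 2.0
    if lo is None and hi is None:
        raise ValueError("at least one band edge required")
    for edge in (lo, hi):
        if edge is not None and not (0 < edge < nyq):
            raise ValueError(f"band edge {edge} outside (0, {nyq})")
    if lo is None:
        return signal.butter(order, hi, btype="low", fs=fs, output="sos")
    if hi is None:
        return signal.butter(order, lo, btype="high", fs=fs, output="sos")
    if lo >= hi:
        raise ValueError("lo must be < hi")
    return signal.butter(order, [lo, hi], btype="band", fs=fs, output="sos")


def iir_gain(sos, freq_hz: float, fs: float) -> float:
    """Magnitude of the designed transfer function at one frequency."""
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]))


def bandpass_iir(rec: Recording, lo: float | None, hi: float | None,
                 order: int = IIR_ORDER) -> Recording:
    sos = design_iir(lo, hi, rec.fs, order)
    poles = np.concatenate([np.roots(section[3:]) for section in np.atleast_2d(sos)])
    if not np.all(np.abs(poles) < 1.0 + 1e-9):
        raise ValueError("designed filter is unstable")
    data = signal.sosfilt(sos, rec.data, axis=1)
    return Recording(data=data, fs=rec.fs, channel_labels=rec.channel_labels,
                     t0=rec.t0).validate()


def lowpass_force(rec: Recording, cutoff: float = FORCE_LOWPASS_HZ,
                  order: int = IIR_ORDER) -> Recording:
    return bandpass_iir(rec, None, cutoff, order)


def resample(rec: Recording, target_fs: float) -> Recording:
    """Integer-factor decimation with a causal 8th-order anti-alias low-pass."""
    factor = rec.fs / target_fs
    if abs(factor - round(factor)) > 1e-6:
        raise ValueError(
            f"resampling {rec.fs} -> {target_fs} Hz is not an integer factor")
    factor = int(round(factor))
    if factor == 1:
        return rec
    cutoff = 0.8 * (target_fs / 2.0)
    sos = _sos_lowpass(cutoff, rec.fs, order=8)
    filtered = signal.sosfilt(sos, rec.data, axis=1)
    data = filtered[:, ::factor]
    return Recording(data=data, fs=target_fs,
                     channel_labels=rec.channel_labels, t0=rec.t0).validate()


def estimate_body_weight(force: Recording,
                         baseline_interval: tuple[float, float]) -> float:
    """Mean of (left + right) force over a declared motionless interval."""
    lo, hi = baseline_interval
    if hi - lo < 1.0:
        raise ValueError("baseline interval shorter than 1 s is unreliable")
    i0 = int(round((lo - force.t0) * force.fs))
    i1 = int(round((hi - force.t0) * force.fs))
    if i0 < 0 or i1 > force.n_samples:
        raise ValueError("baseline interval outside recording")
    segment = force.data[:, i0:i1]
    return float(segment.sum(axis=0).mean())


def preprocess_lfp(raw: Recording, band: tuple[float, float] = LFP_BAND,
                   target_fs: float = LFP_FS) -> Recording:
    """Decimate to the analysis rate then apply the 8-100 Hz band-pass."""
    rec = resample(raw, target_fs) if raw.fs != target_fs else raw
    return bandpass_iir(rec, band[0], band[1])


def preprocess_force(raw: Recording, target_fs: float = FORCE_FS) -> Recording:
    rec = resample(raw, target_fs) if raw.fs != target_fs else raw
    return lowpass_force(rec)


def preprocessing_log(fs_lfp: float = LFP_FS, fs_force: float = FORCE_FS) -> dict:
    """Filter designs actually applied, for the run log."""
    lfp_sos = design_iir(*LFP_BAND, fs=fs_lfp)
    force_sos = design_iir(None, FORCE_LOWPASS_HZ, fs=fs_force)
    return {
        "lfp_bandpass": {"band_hz": list(LFP_BAND), "order": IIR_ORDER,
                         "family": "butterworth-causal",
                         "sos": np.asarray(lfp_sos).tolist()},
        "force_lowpass": {"cutoff_hz": FORCE_LOWPASS_HZ, "order": IIR_ORDER,
                          "family": "butterworth-causal",
                          "sos": np.asarray(force_sos).tolist()},
        "decimation": {"antialias": "butterworth order 8 at 0.8x target nyquist",
                       "lfp": [LFP_RAW_FS, LFP_FS], "force": [1000.0, FORCE_FS]},
    }


def write_json(obj, path: str | Path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
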