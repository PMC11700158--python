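"""Synthetic participants: paired force-plate and LFP sessions with a
known neural-to-gait coupling.

A session is an initial motionless stance (for body-weight estimation)
followed by alternating stepping whose vigor a(t) varies slowly in [0, 1].
The two-channel LFP is a 1/f-type aperiodic background plus band-limited
oscillations; the chosen coupling band's envelope is modulated by
(1 + sign * strength * a(t)), so band power tracks stepping vigor by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .io_preproc import (Recording, SessionManifest, VisitSpec,
                         write_manifest, write_recording)
from .variation_ratio import CANONICAL_BANDS, FrequencyBand

_BAND_BY_NAME = {b.name: b for b in CANONICAL_BANDS}

# baseline oscillation bands present in every synthetic LFP
_BASE_BANDS: dict[str, tuple[float, float, float]] = {
    # name -> (lo, hi, baseline amplitude relative to aperiodic RMS)
    "alpha": (8.0, 13.0, 0.5),
    "low_beta": (13.0, 20.0, 0.5),
    "high_beta": (20.0, 36.0, 0.5),
    "low_gamma": (36.0, 70.0, 0.3),
}


@dataclass
class SyntheticSpec:
    seed: int = 0
    duration_s: float = 100.0
    baseline_s: float = 8.0          # motionless lead-in, >= 5 s
    weight_n: float = 800.0
    cadence_hz: float = 0.8
    coupling_band: str = "high_beta"
    coupling_sign: int = 1
    coupling_strength: float = 1.0
    aperiodic_exponent: float = 1.0
    noise_sd: float = 0.2
    force_noise_n: float = 2.0
    lfp_fs: float = 422.0
    force_fs: float = 100.0

    def __post_init__(self):
        if min(self.duration_s, self.cadence_hz, self.lfp_fs,
               self.force_fs) <= 0:
            raise ValueError("rates and durations must be positive")
        if self.coupling_strength < 0:
            raise ValueError("coupling strength must be >= 0")
        if self.baseline_s < 5.0:
            raise ValueError("motionless lead-in must be >= 5 s")
        if self.coupling_band not in _BAND_BY_NAME:
            raise ValueError(f"unknown coupling band {self.coupling_band!r}")
        lo, hi = _BAND_BY_NAME[self.coupling_band].edges_for_fs(self.lfp_fs)
        if not (0 < lo < hi < self.lfp_fs / 2):
            raise ValueError("coupling band outside (0, Nyquist)")


def _smooth_vigor(spec: SyntheticSpec, rng: np.random.Generator,
                  amplitude_scale: float = 1.0) -> np.ndarray:
    """Slowly varying stepping vigor a(t) in [0, 1] on the force grid,
    zero during the motionless lead-in."""
    n = int(round(spec.duration_s * spec.force_fs))
    t = np.arange(n) / spec.force_fs
    knot_spacing = 4.0
    knots_t = np.arange(0.0, spec.duration_s + knot_spacing, knot_spacing)
    knots = rng.uniform(0.15, 1.0, size=len(knots_t))
    a = np.interp(t, knots_t, knots)
    # half-second moving average keeps the profile smooth
    k = int(round(0.5 * spec.force_fs))
    a = np.convolve(a, np.ones(k) / k, mode="same")
    ramp = np.clip((t - spec.baseline_s) / 2.0, 0.0, 1.0)
    return np.clip(a * ramp * amplitude_scale, 0.0, 1.0)


def generate_forces(spec: SyntheticSpec,
                    rng: np.random.Generator | None = None,
                    vigor: np.ndarray | None = None,
                    ) -> tuple[Recording, np.ndarray]:
    """Two alternating force plates at 100 Hz plus the ground-truth vigor."""
    rng = rng or np.random.default_rng(spec.seed)
    if vigor is None:
        vigor = _smooth_vigor(spec, rng)
    n = len(vigor)
    t = np.arange(n) / spec.force_fs
    # square-ish stepping waveform smoothed at 2 Hz (causal, like the analysis)
    s = signal.square(2 * np.pi * spec.cadence_hz * t)
    sos = signal.butter(4, 2.0, btype="low", fs=spec.force_fs, output="sos")
    s = signal.sosfilt(sos, s)
    s = np.clip(s, -1.0, 1.0)
    half = spec.weight_n / 2.0
    left = half * (1.0 + vigor * s)
    right = spec.weight_n - left
    left = left + rng.normal(0, spec.force_noise_n, size=n)
    right = right + rng.normal(0, spec.force_noise_n, size=n)
    left = np.clip(left, 0.0, None)   # swing-phase floor
    right = np.clip(right, 0.0, None)
    rec = Recording(data=np.vstack([left, right]), fs=spec.force_fs,
                    channel_labels=("FP_L", "FP_R"))
    return rec, vigor


def _aperiodic_background(n: int, fs: float, exponent: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise via spectral synthesis."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=len(freqs))
    spec_c = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec_c, n=n)
    return x / x.std()


def _band_noise(n: int, fs: float, lo: float, hi: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited noise."""
    sos = signal.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def generate_lfp(spec: SyntheticSpec, vigor: np.ndarray,
                 rng: np.random.Generator | None = None) -> Recording:
    """Two-channel LFP at the native rate; shared vigor, independent noise."""
    rng = rng or np.random.default_rng(spec.seed + 1)
    n = int(round(spec.duration_s * spec.lfp_fs))
    t_force = np.arange(len(vigor)) / spec.force_fs
    t_lfp = np.arange(n) / spec.lfp_fs
    a = np.interp(t_lfp, t_force, vigor)
    channels = []
    for _ in range(2):
        x = _aperiodic_background(n, spec.lfp_fs, spec.aperiodic_exponent, rng)
        for name, (lo, hi, amp) in _BASE_BANDS.items():
            osc = amp * _band_noise(n, spec.lfp_fs, lo, hi, rng)
            if name == spec.coupling_band:
                osc = osc * (1.0 + spec.coupling_sign
                             * spec.coupling_strength * a)
            x = x + osc
        x = x + rng.normal(0, spec.noise_sd, size=n)
        channels.append(x)
    return Recording(data=np.vstack(channels), fs=spec.lfp_fs,
                     channel_labels=("STN_L", "STN_R"))


def generate_session(spec: SyntheticSpec) -> tuple[Recording, Recording,
                                                   np.ndarray]:
    """(lfp, force, vigor) for one visit, all driven by spec.seed."""
    rng = np.random.default_rng(spec.seed)
    force, vigor = generate_forces(spec, rng)
    lfp = generate_lfp(spec, vigor, rng)
    return lfp, force, vigor


@dataclass
class ParticipantSpec:
    template: SyntheticSpec = field(default_factory=SyntheticSpec)
    visit_months: tuple[int, int, int] = (6, 9, 12)
    aperiodic_drift_per_visit: float = 0.15
    participant_id: str = "synthetic-01"


def generate_participant(pspec: ParticipantSpec, out_dir: str | Path,
                         ) -> SessionManifest:
    """Write three paired sessions (CSV) plus manifest and ground truth."""
    m1, m2, m3 = pspec.visit_months
    if not (m1 < m2 < m3):
        raise ValueError("visit months must be strictly increasing")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    roles = ("train", "validation", "test")
    visits, truth = [], {}
    for i, (months, role) in enumerate(zip(pspec.visit_months, roles)):
        vspec = replace(
            pspec.template,
            seed=pspec.template.seed + 1000 * i,
            aperiodic_exponent=(pspec.template.aperiodic_exponent
                                + pspec.aperiodic_drift_per_visit * i))
        lfp, force, vigor = generate_session(vspec)
        lfp_path = out_dir / f"visit{i + 1}_lfp.csv"
        force_path = out_dir / f"visit{i + 1}_force.csv"
        write_recording(lfp, lfp_path)
        write_recording(force, force_path)
        visits.append(VisitSpec(
            visit_label=f"visit{i + 1}",
            months_since_ip=months,
            lfp_path=str(lfp_path),
            force_path=str(force_path),
            baseline_interval=(1.0, vspec.baseline_s - 1.0),
            role=role,
            lfp_fs=vspec.lfp_fs,
            force_fs=vspec.force_fs,
        ))
        truth[role] = {"vigor": vigor.tolist(), "spec": asdict(vspec)}
    manifest = SessionManifest(participant_id=pspec.participant_id,
                               visits=visits).validate()
    write_manifest(manifest, out_dir / "manifest.yaml")
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh)
    return manifest


def coupling_band_edges(spec: SyntheticSpec) -> FrequencyBand:
    return _BAND_BY_NAME[spec.coupling_band]
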