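"""Frequency attribution by output-variance ratios.

The training-visit LFP is band-filtered into six canonical bands, each
filtered stream is windowed exactly like the training dataset and run
through the trained network, and the variance of the pre-ReLU scalar per
band is normalized so the six ratios sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import WindowedDataset, build_windowed_dataset
from .io_preproc import Recording, bandpass_iir
from .model import ModelHandle
from .weight_shift import WeightShiftSeries


@dataclass(frozen=True)
class FrequencyBand:
    name: str
    lo: float | None  # None: low-pass-type band
    hi: float | None  # None: high-pass-type band

    def edges_for_fs(self, fs: float) -> tuple[float, float]:
        """Concrete stable band edges: 1 Hz floor, just-below-Nyquist ceiling."""
        lo = self.lo if self.lo is not None else 1.0
        hi = self.hi if self.hi is not None else 0.986 * (fs / 2.0)
        return lo, hi


# canonical six bands partitioned at 8, 13, 20, 36, 70 Hz
CANONICAL_BANDS = (
    FrequencyBand("delta_theta", None, 8.0),
    FrequencyBand("alpha", 8.0, 13.0),
    FrequencyBand("low_beta", 13.0, 20.0),
    FrequencyBand("high_beta", 20.0, 36.0),
    FrequencyBand("low_gamma", 36.0, 70.0),
    FrequencyBand("high_gamma", 70.0, None),
)


@dataclass
class VariationRatioReport:
    ratios: dict[str, float]
    variances: dict[str, float]
    n_windows_per_band: int

    def validate(self) -> "VariationRatioReport":
        vals = np.array(list(self.ratios.values()))
        assert len(vals) == len(self.variances)
        assert np.all(vals >= 0)
        assert abs(vals.sum() - 1.0) < 1e-9
        return self

    @property
    def argmax_band(self) -> str:
        return max(self.ratios, key=self.ratios.get)


def band_preactivations(predict_fn, lfp: Recording, label_times: np.ndarray,
                        band: FrequencyBand) -> np.ndarray:
    """Filter the stream to one band, window it on the training grid, and
    collect the pre-ReLU output per window."""
    lo, hi = band.edges_for_fs(lfp.fs)
    filtered = bandpass_iir(lfp, lo, hi)
    labels = WeightShiftSeries(times=np.asarray(label_times),
                               raw_values=np.zeros(len(label_times)))
    ds = build_windowed_dataset(filtered, labels)
    return np.asarray(predict_fn(ds.lfp_windows))


def variation_ratio(handle_or_fn, train_lfp: Recording,
                    label_times: np.ndarray,
                    bands: tuple[FrequencyBand, ...] = CANONICAL_BANDS,
                    ) -> VariationRatioReport:
    """Per-band unbiased variance of pre-ReLU outputs, normalized to sum 1.

    `handle_or_fn` is a trained ModelHandle, or any callable mapping an
    array of windows [n, 2, L] to one scalar per window (pre-ReLU).
    """
    if isinstance(handle_or_fn, ModelHandle):
        def predict_fn(windows):
            pre, _ = handle_or_fn.network.predict(windows, return_pre=True)
            return pre
    else:
        predict_fn = handle_or_fn

    variances: dict[str, float] = {}
    n_windows = None
    for band in bands:
        pre = band_preactivations(predict_fn, train_lfp, label_times, band)
        if len(pre) < 2:
            raise ValueError(f"need >= 2 windows per band, got {len(pre)}")
        variances[band.name] = float(np.var(pre, ddof=1))
        n_windows = len(pre)
    total = sum(variances.values())
    if total <= 0:
        raise ValueError("degenerate model output: zero total variance")
    ratios = {name: v / total for name, v in variances.items()}
    return VariationRatioReport(ratios=ratios, variances=variances,
                                n_windows_per_band=n_windows).validate()


def bootstrap_ci(replicate_ratios: np.ndarray, level: float = 0.95,
                 n_resamples: int = 10_000, seed: int = 0,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap CI over replicate ratio vectors [n_rep, n_bands]."""
    replicate_ratios = np.atleast_2d(np.asarray(replicate_ratios, dtype=float))
    n_rep = replicate_ratios.shape[0]
    if n_rep < 2:
        raise ValueError("need >= 2 replicates for a bootstrap CI")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_rep, size=(n_resamples, n_rep))
    means = replicate_ratios[idx].mean(axis=1)  # [n_resamples, n_bands]
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(means, alpha, axis=0)
    hi = np.quantile(means, 1.0 - alpha, axis=0)
    return lo, hi
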