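"""Evaluation: MAE/MSE, Kendall tau-b association, and the per-lead 2-s
beta-power baseline the model is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .io_preproc import Recording, bandpass_iir
from .weight_shift import WeightShiftSeries

BETA_BAND = (13.0, 36.0)
LABEL_WIN_S = 2.0


class DegenerateInputError(ValueError):
    """Kendall tau is undefined for a constant argument."""


@dataclass
class MetricsReport:
    mae: float
    mse: float
    tau_model: float
    tau_beta_left: float
    tau_beta_right: float
    tau_beta_lower: float
    tau_beta_higher: float
    n_examples: int
    split: str = ""
    tau_model_defined: bool = True  # False when predictions are constant

    def validate(self) -> "MetricsReport":
        assert self.mae >= 0 and self.mse >= 0
        for tau in (self.tau_model, self.tau_beta_left, self.tau_beta_right):
            assert -1.0 - 1e-12 <= tau <= 1.0 + 1e-12
        assert self.tau_beta_lower <= self.tau_beta_higher
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def _check_pair(pred, label):
    pred = np.asarray(pred, dtype=np.float64)
    label = np.asarray(label, dtype=np.float64)
    if pred.shape != label.shape:
        raise ValueError("series length mismatch")
    if pred.size == 0:
        raise ValueError("empty series")
    return pred, label


def mae(pred, label) -> float:
    pred, label = _check_pair(pred, label)
    return float(np.mean(np.abs(pred - label)))


def mse(pred, label) -> float:
    pred, label = _check_pair(pred, label)
    return float(np.mean((pred - label) ** 2))


def kendall_tau(x, y) -> float:
    """Tie-corrected (tau-b) Kendall coefficient."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length series of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("kendall tau undefined for constant input")
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def beta_power_labels(lfp: Recording, label_times: np.ndarray,
                      band: tuple[float, float] = BETA_BAND,
                      win_s: float = LABEL_WIN_S) -> np.ndarray:
    """Per-lead mean squared beta-filtered LFP over each trailing 2-s window.

    Returns [n_leads, n_times]. The band filter is the same causal 4th-order
    IIR family used in preprocessing, applied to the analysis stream.
    """
    filt = bandpass_iir(lfp, band[0], band[1])
    power = filt.data ** 2
    out = np.empty((lfp.data.shape[0], len(label_times)))
    for j, t in enumerate(np.asarray(label_times, dtype=np.float64)):
        i1 = int(round((t - lfp.t0) * lfp.fs))
        i0 = i1 - int(round(win_s * lfp.fs))
        if i0 < 0 or i1 > lfp.n_samples:
            raise ValueError(f"label window ending at {t} s out of bounds")
        out[:, j] = power[:, i0:i1].mean(axis=1)
    return out


def correlation_comparison(pred: np.ndarray, lfp: Recording,
                           labels: WeightShiftSeries,
                           label_times: np.ndarray | None = None,
                           split: str = "") -> MetricsReport:
    """Model-vs-beta-power Kendall comparison against the weight shifts."""
    if label_times is None:
        label_times = labels.times
    values = (labels.normalized_values if labels.normalized_values is not None
              else labels.raw_values)
    mask = np.isin(np.round(labels.times, 6), np.round(label_times, 6))
    y = np.asarray(values)[mask]
    pred, y = _check_pair(pred, y)
    beta = beta_power_labels(lfp, label_times)
    tau_left = kendall_tau(beta[0], y)
    tau_right = kendall_tau(beta[1], y)
    try:
        tau_model = kendall_tau(pred, y)
        tau_defined = True
    except DegenerateInputError:
        tau_model, tau_defined = 0.0, False
    return MetricsReport(
        mae=mae(pred, y),
        mse=mse(pred, y),
        tau_model=tau_model,
        tau_beta_left=tau_left,
        tau_beta_right=tau_right,
        tau_beta_lower=min(tau_left, tau_right),
        tau_beta_higher=max(tau_left, tau_right),
        n_examples=int(y.size),
        split=split,
        tau_model_defined=tau_defined,
    ).validate()


def group_comparison(values_a: np.ndarray, values_b: np.ndarray,
                     paired: bool = False) -> dict:
    """Thin nonparametric reporting utility over per-participant metrics.

    Mann-Whitney U for independent groups (threshold 0.05), Wilcoxon
    signed-rank for paired comparisons (Bonferroni threshold 0.025).
    """
    if paired:
        res = stats.wilcoxon(values_a, values_b)
        return {"test": "wilcoxon", "statistic": float(res.statistic),
                "p_value": float(res.pvalue), "alpha": 0.025,
                "significant": bool(res.pvalue < 0.025)}
    res = stats.mannwhitneyu(values_a, values_b, alternative="two-sided")
    return {"test": "mann-whitney", "statistic": float(res.statistic),
            "p_value": float(res.pvalue), "alpha": 0.05,
            "significant": bool(res.pvalue < 0.05)}
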