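"""Regression network: band-power-like feature extraction with optional
element-wise division (relative features), temporal squeeze-and-excitation,
a 3-layer bidirectional LSTM, and a groupwise-convolution regression head.

No layer carries bias parameters except the squeeze-and-excitation block.
The head exposes both the pre-ReLU scalar (needed by the frequency
attribution procedure) and the rectified prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .autograd import Tensor, concat

VARIANTS: dict[str, tuple[bool, bool, bool]] = {
    # name -> (use_div, use_se, use_bi)
    "N2GNet": (True, True, True),
    "FExt-Div+SE+Bi": (False, True, True),
    "FExt-Div+SE": (False, True, False),
    "FExt-Div+Bi": (False, False, True),
    "FExt-Div": (False, False, False),
    "FExt+SE+Bi": (True, True, True),  # alias of the full model
    "FExt+SE": (True, True, False),
    "FExt+Bi": (True, False, True),
    "FExt": (True, False, False),
}
CANONICAL_VARIANTS = ("FExt-Div", "FExt-Div+SE", "FExt-Div+Bi",
                      "FExt-Div+SE+Bi", "FExt", "FExt+SE", "FExt+Bi", "N2GNet")


@dataclass
class ModelConfig:
    use_div: bool = True
    use_se: bool = True
    use_bi: bool = True
    n_filters_per_channel: int = 32
    conv_kernel_len: int = 63
    pool_len: int = 53
    pool_stride: int = 11
    se_reduction: int = 4
    lstm_hidden: int = 64
    lstm_layers: int = 3
    head_kernel_len: int = 5
    head_channels_per_group: int = 16
    division_epsilon: float = 1e-6
    window_samples: int = 1055
    n_leads: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.use_div and self.n_filters_per_channel % 2:
            raise ValueError("filters per lead must be even with division")
        for name in ("n_filters_per_channel", "conv_kernel_len", "pool_len",
                     "pool_stride", "se_reduction", "lstm_hidden",
                     "lstm_layers", "head_kernel_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.conv_kernel_len > self.window_samples:
            raise ValueError("conv kernel longer than window")
        if self.pool_len > self.window_samples:
            raise ValueError("pool window longer than conv output")
        n_features = self.n_leads * self.n_filters_per_channel
        if n_features % self.se_reduction:
            raise ValueError("feature dimension not divisible by se_reduction")
        if self.division_epsilon <= 0:
            raise ValueError("division epsilon must be positive")

    @property
    def n_features(self) -> int:
        return self.n_leads * self.n_filters_per_channel

    @property
    def n_time_steps(self) -> int:
        # "same"-padded conv preserves the window length
        return (self.window_samples - self.pool_len) // self.pool_stride + 1

    @classmethod
    def for_variant(cls, name: str, **overrides) -> "ModelConfig":
        if name not in VARIANTS:
            raise ValueError(
                f"unknown variant {name!r}; valid names: "
                + ", ".join(CANONICAL_VARIANTS))
        div, se, bi = VARIANTS[name]
        overrides = {**overrides, "use_div": div, "use_se": se, "use_bi": bi}
        return cls(**overrides)


class RelativeDivision(nn.Module):
    """Within each lead's feature group, divide the first half by the second
    and concatenate numerators with the ratios (denominators are consumed)."""

    def __init__(self, n_leads: int, per_lead: int, eps: float):
        super().__init__()
        if per_lead % 2:
            raise ValueError("per-lead feature count must be even")
        self.n_leads = n_leads
        self.per_lead = per_lead
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:  # [N, leads*per_lead, T]
        half = self.per_lead // 2
        parts = []
        for lead in range(self.n_leads):
            base = lead * self.per_lead
            numer = x[:, base:base + half]
            denom = x[:, base + half:base + self.per_lead]
            parts.append(numer)
            parts.append(numer / (denom + self.eps))
        return concat(parts, axis=1)


class FeatureExtraction(nn.Module):
    """Depthwise conv -> batch norm -> square -> average pool (per lead)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv1d(cfg.n_leads, cfg.n_features, cfg.conv_kernel_len,
                              groups=cfg.n_leads, rng=rng, padding="same")
        self.bn = nn.BatchNorm1d(cfg.n_features)
        self.pool_len = cfg.pool_len
        self.pool_stride = cfg.pool_stride
        self.div = (RelativeDivision(cfg.n_leads, cfg.n_filters_per_channel,
                                     cfg.division_epsilon)
                    if cfg.use_div else None)
        self.bypass_bn = False  # test hook: skip normalization

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv(x)
        if not self.bypass_bn:
            h = self.bn(h)
        h = h.square()
        h = h.avg_pool1d(self.pool_len, self.pool_stride)
        if self.div is not None:
            h = self.div(h)
        return h


class SqueezeExcite(nn.Module):
    """Per-time-step feature gating; the only block allowed bias parameters."""

    def __init__(self, n_features: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        if n_features % reduction:
            raise ValueError("feature dimension not divisible by reduction")
        hidden = n_features // reduction
        self.encode = nn.Linear(n_features, hidden, bias=True, rng=rng)
        self.decode = nn.Linear(hidden, n_features, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:  # [N, F, T]
        h = x.transpose(0, 2, 1)             # [N, T, F]
        gate = self.decode(self.encode(h).relu()).sigmoid()
        return x * gate.transpose(0, 2, 1)


class RegressionHead(nn.Module):
    """Groupwise temporal conv -> pointwise merge -> global average -> dense."""

    def __init__(self, in_channels: int, groups: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        mid = cfg.head_channels_per_group * groups
        self.group_conv = nn.Conv1d(in_channels, mid, cfg.head_kernel_len,
                                    groups=groups, rng=rng)
        self.merge_conv = nn.Conv1d(mid, cfg.head_channels_per_group, 1,
                                    groups=1, rng=rng)
        self.dense = nn.Linear(cfg.head_channels_per_group, 1, bias=False,
                               rng=rng)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = self.group_conv(x)
        h = self.merge_conv(h)
        h = h.mean(axis=2)                   # global temporal average -> [N, C]
        pre = self.dense(h).reshape(-1)      # [N]
        return pre, pre.relu()


class GaitRegressor(nn.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.fext = FeatureExtraction(cfg, rng)
        self.se = (SqueezeExcite(cfg.n_features, cfg.se_reduction, rng)
                   if cfg.use_se else None)
        self.bilstm = (nn.BiLSTM(cfg.n_features, cfg.lstm_hidden,
                                 cfg.lstm_layers, bias=False, rng=rng)
                       if cfg.use_bi else None)
        head_in = 2 * cfg.lstm_hidden if cfg.use_bi else cfg.n_features
        head_groups = 2 if cfg.use_bi else 1
        self.head = RegressionHead(head_in, head_groups, cfg, rng)

    def forward(self, x, return_pre: bool = False):
        """x: [N, 2, window_samples] array or Tensor -> prediction [N]."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        if x.shape[1] != self.cfg.n_leads or x.shape[2] != self.cfg.window_samples:
            raise ValueError(
                f"expected input [N, {self.cfg.n_leads}, "
                f"{self.cfg.window_samples}], got {x.shape}")
        h = self.fext(x)
        if self.se is not None:
            h = self.se(h)
        if self.bilstm is not None:
            h = self.bilstm(h)
        pre, pred = self.head(h)
        return (pre, pred) if return_pre else pred

    def predict(self, windows: np.ndarray, batch_size: int = 64,
                return_pre: bool = False) -> np.ndarray:
        """Evaluation-mode forward over an array of windows."""
        was_training = self.training
        self.eval()
        pre_out, pred_out = [], []
        for i in range(0, len(windows), batch_size):
            pre, pred = self.forward(windows[i:i + batch_size], return_pre=True)
            pre_out.append(pre.data)
            pred_out.append(pred.data)
        self.train(was_training)
        pre_all = np.concatenate(pre_out) if pre_out else np.empty(0)
        pred_all = np.concatenate(pred_out) if pred_out else np.empty(0)
        return (pre_all, pred_all) if return_pre else pred_all


@dataclass
class ModelHandle:
    config: ModelConfig
    network: GaitRegressor
    structural_report: dict = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.network.parameters())


def bias_audit(net: GaitRegressor) -> dict:
    """Enumerate bias-like parameters; they must all live in the SE block."""
    biases = [name for name, p in net.named_parameters() if p.is_bias]
    offenders = [b for b in biases if not b.startswith("se.")]
    return {"bias_parameters": biases, "outside_se": offenders,
            "ok": not offenders}


def build_model(variant_or_config: str | ModelConfig, **overrides) -> ModelHandle:
    if isinstance(variant_or_config, str):
        cfg = ModelConfig.for_variant(variant_or_config, **overrides)
        name = variant_or_config
    else:
        cfg = variant_or_config
        name = "custom"
    net = GaitRegressor(cfg)
    audit = bias_audit(net)
    if not audit["ok"]:
        raise AssertionError(f"bias parameters outside SE block: "
                             f"{audit['outside_se']}")
    report = {
        "variant": name,
        "blocks": {"fext": True, "div": cfg.use_div, "se": cfg.use_se,
                   "bi": cfg.use_bi, "regression": True},
        "bias_audit": audit,
        "n_parameters": sum(p.data.size for p in net.parameters()),
        "n_time_steps": cfg.n_time_steps,
    }
    return ModelHandle(config=cfg, network=net, structural_report=report)


def save_checkpoint(handle: ModelHandle, path):
    """Binary weights + JSON sidecar (runtime artifact, not a deliverable)."""
    import json
    from pathlib import Path
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **handle.network.state_dict())
    sidecar = {"config": asdict(handle.config),
               "structural_report": handle.structural_report}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> ModelHandle:
    import json
    from pathlib import Path
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig(**sidecar["config"])
    handle = build_model(cfg)
    with np.load(path.with_suffix(".npz")) as data:
        handle.network.load_state_dict({k: data[k] for k in data.files})
    handle.structural_report = sidecar["structural_report"]
    return handle
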