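"""Subject-dependent training: ADAM at 1e-5, l1 loss, batches of 16,
up to 2000 epochs with early stopping after 100 epochs without a strictly
better validation l1; the best-validation-epoch weights are kept.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .autograd import Tensor
from .dataset import WindowedDataset
from .model import ModelHandle, save_checkpoint


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-5
    batch_size: int = 16
    max_epochs: int = 2000
    patience: int = 100
    shuffle_seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.patience) <= 0:
            raise ValueError("training hyperparameters must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be below max_epochs")

    @classmethod
    def fast(cls, **overrides) -> "TrainingConfig":
        """Reduced profile for CI/acceptance runs."""
        return cls(**{"max_epochs": 100, "patience": 20, **overrides})


@dataclass
class TrainResult:
    best_epoch: int
    best_val_l1: float
    train_curve: list[float] = field(default_factory=list)
    val_curve: list[float] = field(default_factory=list)
    checkpoint_path: str | None = None
    stopped_early: bool = False

    def to_json(self, path: str | Path):
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _epoch_l1(handle: ModelHandle, ds: WindowedDataset,
              batch_size: int = 64) -> float:
    """Mean-per-example l1 in evaluation mode."""
    preds = handle.network.predict(ds.lfp_windows, batch_size=batch_size)
    return float(np.mean(np.abs(preds - ds.labels)))


def train(handle: ModelHandle, train_ds: WindowedDataset,
          val_ds: WindowedDataset, cfg: TrainingConfig,
          checkpoint_path: str | Path | None = None,
          log_every: int | None = None) -> TrainResult:
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("training and validation datasets must be nonempty")
    net = handle.network
    # Output-sign calibration: the terminal ReLU passes no gradient when the
    # preactivation is negative for every window, and random init leaves the
    # (tightly clustered) preactivations all-negative for ~half the seeds.
    # The sign of the last linear layer is arbitrary at init, so flip it if
    # the probe-batch mean preactivation is negative.
    probe_pre, _ = net.predict(train_ds.lfp_windows[:64], return_pre=True)
    if float(np.mean(probe_pre)) < 0:
        net.head.dense.weight.data *= -1.0
    opt = nn.Adam(net.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.shuffle_seed)
    n = len(train_ds)

    best_val = np.inf
    best_epoch = 0
    best_state: dict | None = None
    train_curve: list[float] = []
    val_curve: list[float] = []
    stopped_early = False
    last_epoch = 0

    for epoch in range(1, cfg.max_epochs + 1):
        last_epoch = epoch
        order = rng.permutation(n)
        net.train()
        losses, counts = [], []
        for i in range(0, n, cfg.batch_size):  # last incomplete batch kept
            idx = order[i:i + cfg.batch_size]
            x = Tensor(train_ds.lfp_windows[idx])
            y = Tensor(train_ds.labels[idx])
            pred = net(x)
            loss = (pred - y).abs().mean()
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"NaN loss at epoch {epoch}, batch {i // cfg.batch_size}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(idx))
            counts.append(len(idx))
        train_curve.append(sum(losses) / sum(counts))
        val_l1 = _epoch_l1(handle, val_ds)
        val_curve.append(val_l1)
        if log_every and epoch % log_every == 0:
            print(f"epoch {epoch}: train l1 {train_curve[-1]:.4f} "
                  f"val l1 {val_l1:.4f}")
        if val_l1 < best_val:  # strict improvement
            best_val = val_l1
            best_epoch = epoch
            best_state = copy.deepcopy(net.state_dict())
        elif epoch - best_epoch >= cfg.patience:
            stopped_early = True
            break

    if best_state is not None:
        net.load_state_dict(best_state)
    result = TrainResult(best_epoch=best_epoch, best_val_l1=float(best_val),
                         train_curve=train_curve, val_curve=val_curve,
                         stopped_early=stopped_early)
    assert not stopped_early or last_epoch - best_epoch == cfg.patience
    if checkpoint_path is not None:
        save_checkpoint(handle, checkpoint_path)
        result.checkpoint_path = str(checkpoint_path)
    return result


def predict_series(handle: ModelHandle, ds: WindowedDataset,
                   batch_size: int = 64) -> np.ndarray:
    """Evaluation-mode predictions aligned to ds.end_times."""
    if len(ds) and ds.lfp_windows.shape[1:] != (
            handle.config.n_leads, handle.config.window_samples):
        raise ValueError("dataset window shape incompatible with checkpoint")
    return handle.network.predict(ds.lfp_windows, batch_size=batch_size)
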