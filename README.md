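# n2g — neural-to-gait decoding

A self-contained pipeline that translates bilateral subthalamic-nucleus
local field potentials (LFPs) into a real-time gait-performance measure
(weight shift), together with everything needed to exercise it end-to-end
on synthetic sessions with known ground truth:

- **io_preproc** — CSV session I/O, integer-factor decimation (422→211 Hz
  LFP, 1000→100 Hz force), causal 4th-order Butterworth filtering
  (8–100 Hz LFP band-pass, 2 Hz force low-pass), body-weight estimation.
- **weight_shift** — force rescaling to body-weight fractions, plate
  merge-and-mirror about half weight, total-variation shift over 2-s
  windows at 0.1-s stride, per-participant normalization across visits.
- **dataset** — paired (5-s two-channel LFP window, scalar weight-shift
  label) examples; chronological train/validation/test splits per visit.
- **model** — the regression network: depthwise conv + batch norm + square
  + average pooling (band-power-like features), element-wise division
  (relative features), temporal squeeze-and-excitation, 3-layer BiLSTM,
  groupwise-convolution regression head with an exposed pre-ReLU scalar.
  Eight ablation variants (`FExt-Div`, `FExt-Div+SE`, `FExt-Div+Bi`,
  `FExt-Div+SE+Bi`, `FExt`, `FExt+SE`, `FExt+Bi`, `N2GNet`). No layer
  carries bias parameters except the squeeze-and-excitation block.
- **training** — subject-dependent ADAM (lr 1e-5), l1 loss, batches of 16,
  up to 2000 epochs, early stopping after 100 epochs without validation
  improvement, best-validation-epoch checkpointing. `--fast` CI profile.
- **evaluation** — MAE/MSE, tie-corrected Kendall tau, and the per-lead
  2-s beta-power (13–36 Hz) baseline comparison.
- **variation_ratio** — frequency attribution: band-filter the training
  LFP into six bands (≤8, 8–13, 13–20, 20–36, 36–70, ≥70 Hz), collect the
  model's pre-ReLU outputs per band, normalize per-band output variances
  to ratios summing to 1; percentile-bootstrap CIs.
- **synthetic_data** — full synthetic participants (three visits of paired
  LFP + force sessions): alternating stepping with slowly varying vigor,
  1/f aperiodic background with across-visit drift, and a configurable
  oscillatory band whose envelope is coupled to stepping vigor.

The network runs on a small NumPy reverse-mode autodiff engine bundled in
the package (`n2g.autograd`, `n2g.nn`) — no deep-learning framework is
required; everything is CPU-only and deterministic under a fixed seed.

## CLI

```bash
# 1. generate a synthetic participant with known high-beta coupling
n2g simulate --seed 0 --out runs/sim --coupling-band high_beta --strength 1.0

# 2. inspect preprocessing (filtered sessions, weight-shift series, filter log)
n2g preprocess --manifest runs/sim/manifest.yaml --out runs/prep

# 3. train a variant (full-scale profile by default; --fast for CI scale)
n2g train --manifest runs/sim/manifest.yaml --variant N2GNet --seed 0 \
    --fast --train-subsample 5 --filters 8 --lstm-hidden 16 --out runs/fit

# 4. evaluate on the held-out latest visit
n2g evaluate --checkpoint runs/fit/N2GNet_checkpoint \
    --manifest runs/sim/manifest.yaml --split test --out runs/fit

# 5. all eight ablation variants, shared seed/data
n2g ablate --manifest runs/sim/manifest.yaml --seed 0 --fast --out runs/abl

# 6. frequency attribution of the trained model
n2g varratio --checkpoint runs/fit/N2GNet_checkpoint \
    --manifest runs/sim/manifest.yaml --out runs/fit
```

Every command writes line-delimited JSON logs; exit code 2 marks
configuration errors, 1 runtime failures.

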