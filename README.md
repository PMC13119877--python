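# motionfuse

Multimodal temporal motion-state perception from video-derived skeleton
keypoints (30 Hz), wearable inertial sensors (IMU, 100 Hz) and surface
electromyography (EMG, 1000 Hz).  The package is aimed at researchers in
human-movement analysis — rehabilitation assessment, sports-training
monitoring, wearable interaction — who need one temporal representation
of three streams that disagree in rate, clock and reliability.

Three problems are addressed jointly:

* **action recognition** — a 12-class label per trial;
* **motion-phase segmentation** — a frame-level phase label;
* **posture-stability scoring** — a scalar in [0, 1].

## The model

After keypoint normalization (per frame: centroid removed, divided by
torso length σ_t, i.e. x̃ = (x − μ_t)/σ_t), Butterworth band-pass +
Z-score standardization of the sensor channels, and cubic-spline
resampling of all streams to one temporal grid, the pipeline is:

1. **Modality encoders** — Transformer (skeleton), bidirectional LSTM
   (IMU), dilated temporal convolutions (EMG) — emit token sequences
   F_S, F_I, F_E ∈ R^{T×d} at a common token rate.
2. **Cross-modal temporal alignment attention** — vision-anchored local
   attention with a learnable per-modality offset δ_M entering through a
   continuous-lag relative-position bias R(t−k−δ_M).  The attention
   row's expected lag E[k−t] estimates the inter-stream lag the module
   has absorbed; on synthetic pairs with a known lag it converges to the
   truth (see the acceptance checks).
3. **Interleaved multimodal Transformer** — S, I, E tokens of each time
   step are adjacent in one 3T-token sequence; pre-norm self-attention
   layers carry relative-time and modality-pair logit biases.
4. **Uncertainty-aware fusion** — per-timestep uncertainties
   σ_t^(m) = softplus(u_t^(m)), weights ω_t^(m) = softmax_m(−σ_t^(m)),
   fused representation z_t = Σ_m ω_t^(m) h_t^(m), plus a temporal
   smoothness penalty Σ_t ‖z_t − z_{t−1}‖².
5. **Multi-task heads** for class / phase / stability.

A bundled synthetic-data generator defines reproducible study conditions
(class-discriminative kinematics, kinematically consistent IMU, envelope-
modulated EMG with a neuromuscular lead, known clock offsets, quantified
corruptions), since the modeling questions — can the offsets be
recovered, does fusion down-weight corrupted streams, does alignment
matter under injected lags — are all answerable with known ground truth.
No deep-learning framework is required: the package includes a small
gradient-checked reverse-mode autodiff engine over numpy.

## Worked example

```python
import numpy as np
from motionfuse import (GeneratorConfig, generate_dataset,
                        PreprocessConfig, SessionPreprocessor,
                        MotionStateClassifier)

cfg = GeneratorConfig(n_subjects=20, trials_per_subject=60, seed=0)
sessions, manifest = generate_dataset(cfg)          # 1200 trials, 12 classes

pre = SessionPreprocessor(PreprocessConfig(grid_rate=16.0,
                                           window_stride_seconds=4.0))
train = [s for s, k in zip(sessions, manifest.split == "train") if k]
test = [s for s, k in zip(sessions, manifest.split == "test") if k]
pre.fit(train)                                      # freeze Z-score stats
w_train, w_test = pre.transform(train), pre.transform(test)

est = MotionStateClassifier(epochs=30, seed=0,
                            skeleton_layers=1, align_layers=1,
                            token_rate=4.0)
est.fit(w_train)
acc = (est.predict(w_test) == [w.action_class for w in w_test]).mean()
print(f"test accuracy: {acc:.3f}")
print(est.diagnostics(w_test))
```

Output from this exact run:

```
test accuracy: 1.000
{'omega_skeleton': 0.4814, 'omega_imu': 0.2669, 'omega_emg': 0.2517,
 'lag_imu': 0.0338, 'lag_emg': -0.0008,
 'delta_imu': 0.0184, 'delta_emg': 0.0000}
```

`test accuracy` is measured on *held-out subjects* (subject-independent
70/10/20 split); 1.000 means every test window of the 240 held-out trials
was classified correctly.  The `omega_*` values are mean fusion weights —
the skeleton stream carries most of the class signal here, so fusion
leans on it — and `lag_*`/`delta_*` are the mean expected attention lags
and the learned offsets in tokens (near zero: this dataset has only small
clock offsets).

The command-line interface wraps the same pipeline:

```sh
motionfuse generate --out data/ --seed 0
motionfuse train --data data/ --out runs/ --folds 5
motionfuse robustness --data data/ --out runs/
motionfuse ablate --data data/ --out runs/
```

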