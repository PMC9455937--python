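# motionmend

Enhancement of skeletal motion data captured by low-cost depth sensors
("D-Mocap": joint trajectories estimated from RGB-D cameras), for clinical
biomechanics and gait analysis.  Depth-sensor skeletons are noisy,
occlusion-prone and unstable compared with marker-based optical motion
capture; `motionmend` cleans them by combining two complementary models:

* a **Tobit Kalman filter (TKF)** — each joint is tracked with a
  constant-velocity model (state `[p, v]` per Cartesian axis,
  `p_k = p_{k-1} + v Δt`), and measurements are treated as *censored*: per
  axis, an observation outside `[T_L, T_H]` is recorded as the threshold
  value, and the update weights the innovation by the Gaussian probability
  mass `p_uc` of the uncensored region.  The thresholds adapt per frame,
  `T_{H/L} = p̂_{k-1} ± |v_max| Δt`, with `|v_max|` the largest measured
  joint speed in a window around the previous frame — occlusion artifacts
  arrive with implausible velocity and are automatically down-weighted.
  With wide thresholds the update reduces exactly to the linear Kalman
  filter.

* a **convolutional-autoencoder motion manifold** — a single temporal
  convolution layer (256 filters × 25 frames at full size) with factor-2
  max-pooling and ReLU encodes an `M × 3N` clip of joint positions into a
  latent code `H = ReLU(S(X*W + b))`; the decoder applies the exact adjoint
  convolution, `X̂ = (S⁻¹(H) − b) * W̃`.  Trained on clean, homogeneous
  walking corpora it learns what valid human motion looks like, so
  out-of-manifold noise is expunged on reconstruction.

The two are merged by **latent-space optimization**: the TKF output becomes
the target of a Cartesian L² cost `Σ_{j,k} ‖Ψ(H)_{k,j} − r_{k,j}‖²`
minimized over the latent code only (decoder frozen), so the result keeps
the filter's per-joint kinematics while remaining on the motion manifold
(*TKF-assisted* paradigm, for noisy data).  For missing data the models are
cascaded instead: manifold reconstruction fills the gaps, then the TKF
restores per-joint kinematics (*TKF-refined* paradigm).

The package also provides the surrounding pipeline: a synthetic gait
generator (forward kinematics over fixed bone lengths) and corruption
protocols (white noise, drop-out, occlusion bursts and outlier spikes);
Hampel outlier filtering, SVD rigid registration and per-joint bias
removal; and evaluation metrics (joint RMSE, bone-length error, six gait
angles, body-quadrant summaries).

Everything is numpy/scipy; the autoencoder's gradients are closed-form
adjoints (validated against numerical differentiation in the tests), so no
deep-learning framework is required.

## Worked example

Train a desk-scale manifold model on synthetic walking data, corrupt
held-out clips with 10 cm white noise, and compare the enhancement modes:

```python
from motionmend.experiment import BenchmarkConfig, run_benchmark, train_model

cfg = BenchmarkConfig(preset="awgn10", n_train_clips=50, n_test_clips=3,
                      epochs=80, n_filters=64, seed=7)
params, losses = train_model(cfg)          # ~1 min on one CPU
report = run_benchmark(cfg, params)
for name, row in report["rows"].items():
    print(f"{name:<14} {row['rmse']:>7.2f} cm  {row['bone_error']:>6.2f} cm"
          f"  {row['angle_error']:>6.2f} deg")
```

which prints

```
corrupted         9.99 cm    6.64 cm   12.45 deg
ae_only           6.53 cm    4.15 cm    7.04 deg
tkf_only          5.41 cm    3.29 cm    6.52 deg
kf_assisted       3.98 cm    2.36 cm    4.39 deg
tkf_assisted      3.99 cm    2.37 cm    4.41 deg
```

Read the rows as: the corrupted input sits at the injected noise level
(~10 cm mean joint RMSE, with bone lengths and gait angles similarly
degraded); the autoencoder alone and the TKF alone each remove part of the
error; and the TKF-assisted combination (filter target + latent-space
optimization) cuts the position error by ~60% relative to the corrupted
input while restoring near-rigid bone structure — better than either
component used alone.  The same pipeline is exposed on the command line:

```bash
motionmend synth --frames 240 --seed 3 clean.csv
motionmend corrupt --mode awgn --sigma 10 clean.csv noisy.csv
motionmend enhance --mode tkf --sigma-r 5.8 noisy.csv filtered.csv
motionmend evaluate --ref clean.csv --est filtered.csv --report report.json
motionmend experiment --preset awgn10 --seed 1   # the full benchmark
```

Motion files are plain CSV (`frame,<joint>_x,<joint>_y,<joint>_z,...`, cm,
y-up, empty cell = missing sample); skeletons are JSON descriptors, with
21-joint, 16-joint and 6-joint (lower-body gait) reference models built in.

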