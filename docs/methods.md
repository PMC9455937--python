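# Methods

This note documents the models implemented in `motionmend`, the parameter
choices that matter, what the synthetic data generator does and does not
emulate, and the numerical decisions made where the design was open.

## Data model and coordinates

Motion is a `frames × joints × 3` array of positions in centimetres, in a
right-handed, y-up world frame with the floor at `y = 0`; frame index is
0-based and the sampling interval is `1/fps` (60 fps throughout the
synthetic pipeline — 240-frame training clips correspond to four seconds of
motion).  A boolean per-joint-frame mask records drop-out; unobserved
coordinates carry the fill value 0, which after normalization is an
out-of-manifold signal the autoencoder learns to repair.  Skeletons are
rooted trees with fixed bone lengths; three reference models are built in
(21-joint full body, 16-joint, and a 6-joint lower-body gait model: hips,
knees, ankles).

**Trajectory localization.**  Manifold training and enhancement run in
trajectory-local coordinates: the horizontal (x, z) pelvis track, smoothed
with a mask-aware 61-frame moving average, is subtracted from every joint
and stored, and the *phantom joint* — the floor projection of the pelvis
center — is appended so the network keeps a floor/height reference while
learning local body motion rather than world translation (the phantom then
sits near the origin).  The subtraction is inverted exactly after
enhancement, so localization is error-neutral with respect to world-frame
evaluation.  A temporal-convolutional manifold trained on world-frame
walking data would have to spend capacity representing unbounded forward
drift; localized clips make the corpus stationary.

## The autoencoder

Encoder: flatten to `M × 3N`; normalize; convolve `F` filters of width 25
along time (stride 1, zero same-padding); add a per-filter bias; max-pool
frames by 2 (odd tails keep the lone frame); ReLU.  Decoder: replicate each
pooled value into its two frames, subtract the bias, and convolve with the
weight tensor reflected along the frame axis and transposed in the
filter/channel axes — algebraically the exact adjoint of the encoder
convolution (weights are tied).  Max-pooling and ReLU commute, so the order
of the two is immaterial.

**Normalization.**  Per-dimension mean, one *shared* standard-deviation
scale across all 3N input dimensions.  A per-dimension z-score would
amplify isotropic sensor noise by `1/σ_d` on low-range channels (the
phantom joint's coordinates, the lateral hip axis), destroying exactly the
denoising behavior the manifold exists for; a single scale keeps the noise
isotropic in normalized space and the transform scale-stable.  The scale
and means are stored in the model archive.

**Training.**  Loss is the squared reconstruction error (sum over the clip,
averaged per clip in the batch, computed in normalized units) plus an L1
penalty `α‖θ‖₁` on weights and biases, minimized with Adam (moments
0.9/0.999, learning rate 0.001).  Input-level dropout at rate 0.2
regularizes training (this is neural-network dropout, unrelated to data
drop-out).  Defaults: `α = 0.01`, batch size 16, 200 epochs at desk scale,
seeded initialization (`std = sqrt(2/(3N·w + F))`) — all exposed.
Gradients are hand-derived adjoints of the (piecewise-)linear forward pass;
the test suite checks them against central differences and the decoder
against a direct-summation oracle.  Training is bit-deterministic given the
seed.  Clips in a corpus must share one skeleton and one frame count; after
training the model accepts clips of any length ≥ the filter width.

## The Tobit Kalman filter

Each joint is filtered independently (data association by joint index) with
the 6-state constant-velocity model; the observation extracts the position
block.  Process noise is discrete white-noise acceleration with intensity
`σ_a`; measurement noise is `R = σ_r² I`.

**Defaults and why.**  `σ_a = 1500 cm/s²`: peak limb acceleration in gait
is `A(2πf)² ≈ 40 cm × (2π·1 Hz)² ≈ 1600 cm/s²` at the feet and hands; a
much smaller intensity makes the CV filter lag fast joints so badly that
filtering can be worse than no filtering.  `σ_r = 3 cm` by default; when
the sensor noise level is known (as in the simulated-corruption benchmark)
set `σ_r` to the per-coordinate noise std — a filter run with `R` far above
the true noise lags the data, and under the adaptive thresholds that lag
compounds, so calibrating `R` is not optional.  Initial state: first
observed position, first finite-difference velocity;
`P0 = diag(σ_r²·1₃, 2σ_r²/Δt²·1₃)`.

**Censoring.**  Per axis, `T_{H/L} = p̂_{k-1} ± |v_max| Δt` with `|v_max|`
the maximum absolute finite-difference velocity of the *measured*
trajectory over a `window_frames` window (default 60, the 50–80 range
covering a complete action at 60 fps) centered at the previous frame and
truncated at the edges; a `causal` flag restricts the window to past
frames.  The measurement is clamped to the interval; the update uses the
censored-measurement moments: with predicted measurement mean `μ = Hx̂` and
per-axis std `s = sqrt(diag(HPHᵀ + R))`, the region masses are
`p_l = Φ((T_L−μ)/s)`, `p_h = 1 − Φ((T_H−μ)/s)`, `p_uc = 1 − p_l − p_h`; the
expected measurement is `E(Y) = p_uc ⊙ (μ + s λ) + p_l ⊙ T_L + p_h ⊙ T_H`
with `λ` the truncated-normal mean correction; the gain is
`K = R_XY R_YY⁻¹` with `R_XY = P Hᵀ P_uc` and
`R_YY = P_uc (H P Hᵀ) P_uc + R`; state and covariance update as
`x = x̂ + K(ρ − E(Y))`, `P = (I − K P_uc H) P̂`.  At `p_uc = 1` this *is*
the linear Kalman filter (asserted to 1e-8 against an independent
implementation); as `p_uc → 0` the gain vanishes and the covariance is
kept, i.e. a fully censored measurement is ignored.  Masked (dropped-out)
measurements are treated as fully censored: prediction only.

**Known degeneracies.**
* A trajectory moving *exactly* at the window's maximum velocity rides the
  threshold boundary (`q_k = T_H` every frame) and is perpetually
  half-censored; real data never sit on this measure-zero edge, but exact
  synthetic CV trajectories do, which is why the CV-tracking oracle test
  runs with wide fixed thresholds.
* With the *centered* velocity window, the window's look-ahead contains the
  entry spike of an occlusion burst, which widens the thresholds by exactly
  the burst bias and neutralizes censoring against that burst.  The causal
  window does not see the spike when it matters and resists sustained
  occlusion bias — it is the recommended mode for occlusion-type artifacts
  and the mode under which the TKF demonstrably beats the plain KF on the
  occlusion benchmark.  Under pure white noise the two windows behave
  alike and the TKF essentially matches the KF, as expected: censoring
  earns its keep on structured artifacts, not i.i.d. noise.

## Latent-space optimization and the two paradigms

`latent_optimize` initializes `H = encode(input)` and minimizes
`Σ_{j,k} ‖Ψ(H)_{k,j} − r_{k,j}‖²` over `H` with Adam (default learning
rate 0.01, 100 iterations), decoder frozen; `H` is projected to the
non-negative orthant after each step (the ReLU range), and the
lowest-cost iterate is returned, so the final cost never exceeds the
initial one.  The output is `decode(H*)` by construction — always on the
manifold.  An optional bone term `Σ_k Σ_b (‖b_{m,k} − b_{n,k}‖ − l_b)²`
on the *decoded Cartesian* positions (weight `λ_b`, default 0 for
enhancement, > 0 in `bone_constrained_fit` for structure-matching a
mismatched skeleton to the training skeleton) pulls decoded bone lengths
toward the skeleton's known values.  Per-joint latent inversion is not
well-defined for a many-to-one decoder, so the whole-clip latent is the
optimization variable and all per-joint terms are evaluated in Cartesian
space.

*TKF-assisted* (noisy data): filter the raw sequence, use the result as the
target `r`.  *KF-assisted*: identical with censoring disabled
(`threshold_mode="none"`), the comparison baseline.  *TKF-refined* (missing
data): reconstruct through the manifold first (masked entries enter as
zero), then filter the reconstruction; the manifold bridges voids the
filter cannot.

## Preprocessing

Hampel filter: per scalar channel, sliding window of 7 samples, window
median `m` and `σ = 1.4826·MAD`; a sample deviating more than 3σ from `m`
is replaced by `m`.  Edge windows are truncated; when the MAD is zero any
deviation from the median is replaced (preserves the filter's intent on
locally constant signals).  Rigid registration pools all joint-frames of
both sequences into two point clouds and solves the closed-form Kabsch
problem via SVD, with the reflection corrected to `det(R) = +1` so
skeletons are never mirrored; one global transform per sequence (per-frame
alignment is out of scope).  Bias removal subtracts the per-joint mean
offset between aligned sequences (skeleton-definition differences, not
noise).

## Synthetic data: what it emulates, what it does not

The generator drives the skeleton's hip, knee, shoulder and elbow joints
with sinusoidal angle trajectories (hip flexion `A sin(2πft)`, knee flexion
`A(1−cos)/2 ≥ 0`, contralateral phase for arms) through rigid forward
kinematics, plus pelvis bob and forward travel.  Defaults and corpus ranges
are ordinary adult walking values: stride frequency 0.7–1.4 Hz, hip
amplitude 15–35°, knee 25–60°, speed 50–140 cm/s, hip height 94 cm.  Bone
lengths are exactly constant by construction, and the commanded angle
traces are returned so angle metrics can be checked against ground truth
(knee flexion recovery is exact by construction of both the generator and
the metric).

Corruptions: AWGN with `σ` interpreted as RMS 3-D displacement per joint
(per-coordinate std `σ/√3`), so the corrupted-vs-clean RMSE equals `σ` —
the convention under which the published noise levels are self-consistent;
a per-coordinate flag selects the alternative.  Drop-out removes whole
joint-frames independently with the given rate (fill 0, mask recorded).
The depth-sensor-like protocol adds jitter, occlusion bursts (the joint
freezes at a biased offset *carried along with the pelvis* — a world-frozen
joint while the subject walks away is not how trackers fail — producing the
velocity spike at re-emergence), and meter-scale single-axis outlier
spikes, with all injections logged.  AWGN and drop-out are keyed per joint
name, so corruption commutes with joint reordering.

What passing tests on this data do **not** show: the generator is
kinematic, not dynamic — no ground-contact constraint (feet can slide), no
soft-tissue artifact, no pose-dependent sensor bias, no correlated noise,
and far less motion diversity than a real capture corpus.  Results
demonstrate that the pipeline's machinery works and reproduces the
published *structure* (orderings, improvement magnitudes) at desk scale,
not that the absolute error levels transfer to real depth-sensor data.

## Problem sizes

Desk-scale defaults used by the test suite and the reproduction script: 64
filters (the architecture is unchanged; filter count and corpus size are
config), 50–200 training clips of 240 frames, 80–100 epochs, 3–10 held-out
test clips.  The full-size configuration (256 filters) is exercised for
shape/contract tests; training it is a matter of budget, not code.

## Limitations

* The TKF is offline in its adaptive-threshold form (centered window looks
  ahead); use `causal=True` for streaming-compatible behavior.
* Joints are filtered independently; skeletal coupling enters only through
  the manifold and the optional bone constraint.
* The manifold must be retrained per skeleton model (21/16/6-joint), as the
  input dimensionality is baked into the weight tensor.
* Latent optimization is non-convex (ReLU boundaries); the cost is
  guaranteed non-increasing, not globally minimal.
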