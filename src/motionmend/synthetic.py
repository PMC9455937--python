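"""Synthetic gait corpora and measurement-corruption operators.

The generator drives a fixed-bone-length skeleton with sinusoidal joint-angle
trajectories through forward kinematics, emulating the homogeneous-skeleton
walking clips a motion manifold is trained on.  Corruption operators emulate
depth-sensor artifacts: additive white Gaussian noise (AWGN), random
joint-frame drop-out, and occlusion bursts / outlier spikes.

AWGN convention: ``sigma_cm`` is the RMS 3-D displacement per joint, i.e.
each coordinate receives independent noise with std ``sigma_cm / sqrt(3)``.
Under this convention the corrupted-vs-clean RMS Euclidean joint error
equals ``sigma_cm``.  A per-coordinate interpretation is selectable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .sequence import MotionSequence
from .skeleton import Skeleton, cmu21_skeleton


# ----------------------------------------------------------------------
# Gait parameters and forward kinematics
# ----------------------------------------------------------------------

@dataclass
class GaitParams:
    """Sinusoidal gait-cycle parameters.

    Angles are amplitudes in degrees; one stride = one full cycle of each
    leg at ``stride_frequency`` Hz.
    """

    stride_frequency: float = 1.0
    hip_amplitude: float = 25.0
    knee_amplitude: float = 45.0
    hip_abduction_amplitude: float = 3.0
    shoulder_amplitude: float = 20.0
    elbow_amplitude: float = 25.0
    forward_speed: float = 100.0  # cm/s
    bob_amplitude: float = 2.0    # vertical pelvis oscillation, cm
    phase: float = 0.0            # initial stride phase, radians
    noise_free: bool = True
    angle_noise_deg: float = 1.0  # smooth angle jitter when not noise_free
    seed: int = 0

    def __post_init__(self):
        if self.stride_frequency <= 0:
            raise ValueError("stride_frequency must be positive")
        for a in (self.hip_amplitude, self.knee_amplitude,
                  self.hip_abduction_amplitude, self.shoulder_amplitude,
                  self.elbow_amplitude):
            if not 0.0 <= a <= 150.0:
                raise ValueError("angle amplitudes must lie in [0, 150] degrees")


def _rot_x(theta: np.ndarray) -> np.ndarray:
    """(M,3,3) rotation about +x by theta (radians)."""
    c, s = np.cos(theta), np.sin(theta)
    R = np.zeros(theta.shape + (3, 3))
    R[..., 0, 0] = 1
    R[..., 1, 1] = c
    R[..., 1, 2] = -s
    R[..., 2, 1] = s
    R[..., 2, 2] = c
    return R


def _rot_z(theta: np.ndarray) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    R = np.zeros(theta.shape + (3, 3))
    R[..., 2, 2] = 1
    R[..., 0, 0] = c
    R[..., 0, 1] = -s
    R[..., 1, 0] = s
    R[..., 1, 1] = c
    return R


def generate_motion(
    skeleton: Optional[Skeleton] = None,
    n_frames: int = 240,
    fps: float = 60.0,
    params: Optional[GaitParams] = None,
) -> Tuple[MotionSequence, Dict[str, np.ndarray]]:
    """Generate a walking clip by forward kinematics.

    Returns the sequence together with the commanded joint-angle traces
    (degrees, per frame) so parameter-recovery tests can compare measured
    against commanded angles.  Bone lengths are exactly constant because
    positions are produced by rigid forward kinematics.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    skeleton = skeleton if skeleton is not None else cmu21_skeleton()
    params = params if params is not None else GaitParams()
    if skeleton.rest_pose is None:
        raise ValueError("generator requires a skeleton rest pose")

    t = np.arange(n_frames) / fps
    phi = 2 * np.pi * params.stride_frequency * t + params.phase
    rng = np.random.default_rng(params.seed)

    def jitter():
        if params.noise_free or params.angle_noise_deg == 0:
            return np.zeros(n_frames)
        # smooth, band-limited angle noise
        raw = rng.normal(0.0, 1.0, n_frames)
        k = max(int(fps / 6), 1)
        kernel = np.hanning(2 * k + 1)
        kernel /= kernel.sum()
        smooth = np.convolve(raw, kernel, mode="same")
        return params.angle_noise_deg * smooth / max(np.std(smooth), 1e-12)

    d2r = np.pi / 180.0
    angles: Dict[str, np.ndarray] = {}
    angles["l_hip_flexion"] = params.hip_amplitude * np.sin(phi) + jitter()
    angles["r_hip_flexion"] = params.hip_amplitude * np.sin(phi + np.pi) + jitter()
    # knee flexion is non-negative; peaks during the swing phase
    angles["l_knee_flexion"] = params.knee_amplitude * (0.5 - 0.5 * np.cos(phi)) + jitter()
    angles["r_knee_flexion"] = params.knee_amplitude * (0.5 - 0.5 * np.cos(phi + np.pi)) + jitter()
    angles["l_hip_abduction"] = params.hip_abduction_amplitude * np.sin(phi)
    angles["r_hip_abduction"] = params.hip_abduction_amplitude * np.sin(phi + np.pi)
    angles["l_shoulder_flexion"] = params.shoulder_amplitude * np.sin(phi + np.pi)
    angles["r_shoulder_flexion"] = params.shoulder_amplitude * np.sin(phi)
    angles["l_elbow_flexion"] = params.elbow_amplitude * (0.5 - 0.5 * np.cos(phi + np.pi))
    angles["r_elbow_flexion"] = params.elbow_amplitude * (0.5 - 0.5 * np.cos(phi))
    for k in ("l_knee_flexion", "r_knee_flexion", "l_elbow_flexion", "r_elbow_flexion"):
        angles[k] = np.clip(angles[k], 0.0, 150.0)

    # local rotation of each joint (applies to its children's offsets)
    eye = np.broadcast_to(np.eye(3), (n_frames, 3, 3))
    local = {name: eye for name in skeleton.joint_names}

    def set_local(name, R):
        if name in skeleton.joint_names:
            local[name] = R

    # sign conventions: positive flexion swings the limb forward (+z, the
    # direction of travel); positive abduction moves it away from the midline
    set_local("l_hip", _rot_x(-d2r * angles["l_hip_flexion"])
              @ _rot_z(-d2r * angles["l_hip_abduction"]))
    set_local("r_hip", _rot_x(-d2r * angles["r_hip_flexion"])
              @ _rot_z(d2r * angles["r_hip_abduction"]))
    # knee flexion bends the shank backward relative to the thigh
    set_local("l_knee", _rot_x(d2r * angles["l_knee_flexion"]))
    set_local("r_knee", _rot_x(d2r * angles["r_knee_flexion"]))
    set_local("l_shoulder", _rot_x(-d2r * angles["l_shoulder_flexion"]))
    set_local("r_shoulder", _rot_x(-d2r * angles["r_shoulder_flexion"]))
    set_local("l_elbow", _rot_x(-d2r * angles["l_elbow_flexion"]))
    set_local("r_elbow", _rot_x(-d2r * angles["r_elbow_flexion"]))

    rest = skeleton.rest_pose
    root = skeleton.root
    n = skeleton.n_joints
    pos = np.zeros((n_frames, n, 3))
    glob = {}

    root_name = skeleton.joint_names[root]
    root_pos = np.tile(rest[root], (n_frames, 1)).astype(float)
    root_pos[:, 1] += params.bob_amplitude * np.sin(2 * phi)
    root_pos[:, 2] += params.forward_speed * t
    pos[:, root, :] = root_pos
    glob[root] = local[root_name]

    # children in topological order (parents precede children by walking depth)
    order = []
    pending = [root]
    children = {j: [] for j in range(n)}
    for j, p in enumerate(skeleton.parent_index):
        if p >= 0:
            children[int(p)].append(j)
    while pending:
        j = pending.pop(0)
        order.append(j)
        pending.extend(children[j])
    for j in order:
        if j == root:
            continue
        p = int(skeleton.parent_index[j])
        off = rest[j] - rest[p]
        pos[:, j, :] = pos[:, p, :] + np.einsum("mij,j->mi", glob[p], off)
        glob[j] = glob[p] @ local[skeleton.joint_names[j]]

    seq = MotionSequence(skeleton, fps, pos)
    return seq, angles


def sample_gait_params(rng: np.random.Generator, seed: int) -> GaitParams:
    """Draw gait parameters from realistic walking ranges."""
    return GaitParams(
        stride_frequency=rng.uniform(0.7, 1.4),
        hip_amplitude=rng.uniform(15.0, 35.0),
        knee_amplitude=rng.uniform(25.0, 60.0),
        hip_abduction_amplitude=rng.uniform(1.0, 5.0),
        shoulder_amplitude=rng.uniform(10.0, 30.0),
        elbow_amplitude=rng.uniform(10.0, 40.0),
        forward_speed=rng.uniform(50.0, 140.0),
        bob_amplitude=rng.uniform(1.0, 3.0),
        phase=rng.uniform(0.0, 2 * np.pi),
        seed=seed,
    )


def generate_corpus(
    skeleton: Optional[Skeleton] = None,
    n_clips: int = 20,
    frames_per_clip: int = 240,
    fps: float = 60.0,
    seed: int = 0,
) -> List[MotionSequence]:
    """Generate a corpus of walking clips with varied gait parameters."""
    if n_clips < 1:
        raise ValueError("n_clips must be >= 1")
    rng = np.random.default_rng(seed)
    clips = []
    for i in range(n_clips):
        params = sample_gait_params(rng, seed=int(rng.integers(0, 2**31 - 1)))
        clip, _ = generate_motion(skeleton, frames_per_clip, fps, params)
        clips.append(clip)
    return clips


# ----------------------------------------------------------------------
# Corruption operators
# ----------------------------------------------------------------------

@dataclass
class CorruptionSpec:
    """Parameters of a corruption protocol (one mode active per application)."""

    mode: str = "dmocap_like"  # awgn | dropout | dmocap_like
    sigma_cm: float = 0.0
    per_coordinate_sigma: bool = False
    dropout_rate: float = 0.0
    burst_rate: float = 0.0        # expected bursts per joint over the clip
    burst_length: int = 60         # frames (~1 s of self-occlusion at 60 fps)
    burst_bias_cm: float = 15.0
    outlier_rate: float = 0.0      # per joint-frame probability
    outlier_magnitude_cm: float = 100.0  # meter-scale depth failures
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("awgn", "dropout", "dmocap_like"):
            raise ValueError(f"unknown corruption mode {self.mode!r}")
        if self.sigma_cm < 0:
            raise ValueError("sigma_cm must be >= 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")


def _joint_rng(seed: int, joint_name: str) -> np.random.Generator:
    """Per-joint RNG keyed on the joint name, so corruption commutes with
    joint reordering."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(joint_name.encode())])


def corrupt_awgn(
    seq: MotionSequence,
    sigma_cm: float,
    seed: int = 0,
    per_coordinate: bool = False,
) -> MotionSequence:
    """Add zero-mean white Gaussian noise to every observed coordinate.

    ``sigma_cm`` is the RMS 3-D displacement per joint (per-coordinate std
    ``sigma_cm/sqrt(3)``) unless ``per_coordinate`` is set.
    """
    if sigma_cm < 0:
        raise ValueError("sigma_cm must be >= 0")
    out = seq.copy()
    if sigma_cm == 0:
        return out
    std = sigma_cm if per_coordinate else sigma_cm / np.sqrt(3.0)
    for j, name in enumerate(seq.skeleton.joint_names):
        rng = _joint_rng(seed, name)
        noise = rng.normal(0.0, std, (seq.n_frames, 3))
        obs = seq.mask[:, j]
        out.positions[obs, j, :] += noise[obs]
    return out


def corrupt_dropout(seq: MotionSequence, rate: float, seed: int = 0) -> MotionSequence:
    """Randomly remove joint-frames (all 3 coordinates together).

    Removed entries are masked out and carry the fill value 0.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("dropout rate must lie in [0, 1]")
    out = seq.copy()
    if rate == 0:
        return out
    for j, name in enumerate(seq.skeleton.joint_names):
        rng = _joint_rng(seed, name)
        drop = rng.random(seq.n_frames) < rate
        out.mask[drop, j] = False
        out.positions[drop, j, :] = 0.0
    return out


def corrupt_dmocap_like(
    seq: MotionSequence, spec: CorruptionSpec
) -> Tuple[MotionSequence, Dict]:
    """Emulate depth-sensor artifacts: jitter, occlusion bursts, outliers.

    Occlusion bursts freeze a joint at a biased position for a contiguous
    run of frames, producing a velocity spike when the joint re-emerges.
    Returns the corrupted sequence and a log of injected bursts/outliers.
    """
    if spec.mode != "dmocap_like":
        raise ValueError("spec.mode must be 'dmocap_like'")
    rng = np.random.default_rng(spec.seed)
    out = seq.copy()
    log = {"bursts": [], "outliers": []}

    if spec.sigma_cm > 0:
        out = corrupt_awgn(out, spec.sigma_cm, seed=spec.seed,
                           per_coordinate=spec.per_coordinate_sigma)

    m, n = seq.n_frames, seq.n_joints
    if spec.burst_rate > 0:
        # occluded joints stick to a biased offset carried along with the
        # body (the estimator latches onto a nearby body part), producing a
        # velocity spike when the joint re-emerges
        hip = seq.skeleton.hip_center_positions(seq.positions)  # (M, 3)
        for j in range(n):
            k = rng.poisson(spec.burst_rate)
            for _ in range(k):
                start = int(rng.integers(0, max(m - spec.burst_length, 1)))
                length = int(min(spec.burst_length, m - start))
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                bias = spec.burst_bias_cm * direction
                carried = hip[start:start + length] - hip[start]
                out.positions[start:start + length, j, :] = (
                    seq.positions[start, j, :] + bias + carried)
                log["bursts"].append({"joint": j, "start": start, "length": length,
                                      "bias": bias.tolist()})

    if spec.outlier_rate > 0:
        # spikes hit one axis at full magnitude (depth-axis style failures),
        # guaranteeing per-channel detectability by a median/MAD filter
        hits = np.argwhere(rng.random((m, n)) < spec.outlier_rate)
        for f, j in hits:
            axis = int(rng.integers(0, 3))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            out.positions[f, j, axis] = (seq.positions[f, j, axis]
                                         + sign * spec.outlier_magnitude_cm)
            log["outliers"].append({"frame": int(f), "joint": int(j),
                                    "axis": axis})

    return out, log
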