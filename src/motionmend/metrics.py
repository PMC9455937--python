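"""Evaluation metrics for enhanced motion: joint-position RMSE, bone-length
error, gait joint angles, and body-quadrant summaries.

Conventions
-----------
* "RMSE" is the root-mean-square over frames of the per-frame 3-D Euclidean
  joint distance, averaged over joints; a plain mean-distance variant is
  available via ``mean_distance=True``.
* Bone-length error is the mean over frames of the absolute difference
  between estimated and reference bone lengths, per bone.
* Six gait angles are reported: left/right knee flexion (LKF/RKF), hip
  flexion-extension (LHF/RHF) and hip abduction-adduction (LHA/RHA).  The
  sagittal/frontal planes are derived per frame from the pelvis (hip-left to
  hip-right) axis projected onto the floor plane; a vertically hanging leg
  has all angles equal to zero, and a shank perpendicular to the thigh has
  90 degrees of knee flexion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .sequence import MotionSequence, compute_velocities
from .skeleton import Skeleton

ANGLE_NAMES = ("LKF", "RKF", "LHF", "RHF", "LHA", "RHA")

_LEG = {
    "LKF": ("l_hip", "l_knee", "l_ankle"),
    "RKF": ("r_hip", "r_knee", "r_ankle"),
}


# ----------------------------------------------------------------------
# Joint position error
# ----------------------------------------------------------------------

def joint_rmse(
    est: MotionSequence, ref: MotionSequence, mean_distance: bool = False
) -> Tuple[np.ndarray, float]:
    """Per-joint (and mean-over-joints) Euclidean position error in cm.

    Frames where the reference joint is unobserved are excluded.
    """
    if est.positions.shape != ref.positions.shape:
        raise ValueError("sequences must share frame and joint counts")
    d = np.linalg.norm(est.positions - ref.positions, axis=2)  # (M, N)
    n = d.shape[1]
    per_joint = np.empty(n)
    for j in range(n):
        dj = d[ref.mask[:, j], j]
        if dj.size == 0:
            per_joint[j] = np.nan
            continue
        per_joint[j] = dj.mean() if mean_distance else np.sqrt(np.mean(dj ** 2))
    return per_joint, float(np.nanmean(per_joint))


# ----------------------------------------------------------------------
# Bone length error
# ----------------------------------------------------------------------

def bone_length_error(
    est: MotionSequence, ref: MotionSequence, skeleton: Optional[Skeleton] = None
) -> Tuple[np.ndarray, float]:
    """Mean absolute deviation of estimated bone lengths from reference
    bone lengths, per bone and averaged (cm)."""
    skeleton = skeleton or ref.skeleton
    if est.positions.shape != ref.positions.shape:
        raise ValueError("sequences must share frame and joint counts")
    bones = skeleton.bones()
    child = np.array([c for c, _ in bones])
    par = np.array([p for _, p in bones])
    le = np.linalg.norm(est.positions[:, child] - est.positions[:, par], axis=2)
    lr = np.linalg.norm(ref.positions[:, child] - ref.positions[:, par], axis=2)
    per_bone = np.abs(le - lr).mean(axis=0)
    return per_bone, float(per_bone.mean())


def bone_length_deviation(seq: MotionSequence, skeleton: Optional[Skeleton] = None
                          ) -> Tuple[np.ndarray, float]:
    """Deviation from the skeleton's fixed (known) bone lengths, per bone."""
    skeleton = skeleton or seq.skeleton
    bones = skeleton.bones()
    child = np.array([c for c, _ in bones])
    par = np.array([p for _, p in bones])
    ls = np.linalg.norm(seq.positions[:, child] - seq.positions[:, par], axis=2)
    ref = skeleton.bone_lengths[child]
    per_bone = np.abs(ls - ref).mean(axis=0)
    return per_bone, float(per_bone.mean())


# ----------------------------------------------------------------------
# Gait joint angles
# ----------------------------------------------------------------------

def _unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 1e-12, v / n, np.nan)


def joint_angles(seq: MotionSequence, skeleton: Optional[Skeleton] = None
                 ) -> Dict[str, np.ndarray]:
    """Per-frame gait angle traces in degrees (see module docstring).

    Frames with a degenerate (zero-length) segment yield NaN for the
    affected angle.
    """
    skeleton = skeleton or seq.skeleton
    try:
        ji = {n: skeleton.index(n) for n in
              ("l_hip", "l_knee", "l_ankle", "r_hip", "r_knee", "r_ankle")}
    except KeyError as e:
        raise ValueError(f"skeleton lacks the leg chains needed for gait angles: {e}")
    pos = seq.positions
    y_up = np.array([0.0, 1.0, 0.0])

    lateral = pos[:, skeleton.hip_right] - pos[:, skeleton.hip_left]
    lateral[:, 1] = 0.0  # project pelvis axis onto the floor plane
    lateral = _unit(lateral)
    forward = _unit(np.cross(lateral, np.broadcast_to(y_up, lateral.shape)))

    out: Dict[str, np.ndarray] = {}

    for name, (hip, knee, ankle) in _LEG.items():
        thigh = pos[:, ji[knee]] - pos[:, ji[hip]]
        to_hip = _unit(-thigh)
        to_ankle = _unit(pos[:, ji[ankle]] - pos[:, ji[knee]])
        cosang = np.clip(np.sum(to_hip * to_ankle, axis=1), -1.0, 1.0)
        out[name] = 180.0 - np.degrees(np.arccos(cosang))

    for side, hip, knee in (("L", "l_hip", "l_knee"), ("R", "r_hip", "r_knee")):
        thigh = pos[:, ji[knee]] - pos[:, ji[hip]]
        # sagittal plane: remove the lateral component; flexion is forward
        lat_c = np.sum(thigh * lateral, axis=1)
        t_sag = thigh - lat_c[:, None] * lateral
        fwd = np.sum(t_sag * forward, axis=1)
        down = -t_sag[:, 1]
        flex = np.degrees(np.arctan2(fwd, down))
        flex = np.where(np.linalg.norm(t_sag, axis=1) > 1e-9, flex, np.nan)
        out[side + "HF"] = flex
        # frontal plane: remove the forward component; abduction is lateral
        fwd_c = np.sum(thigh * forward, axis=1)
        t_front = thigh - fwd_c[:, None] * forward
        away = 1.0 if side == "R" else -1.0
        lat = away * np.sum(t_front * lateral, axis=1)
        abd = np.degrees(np.arctan2(lat, -t_front[:, 1]))
        abd = np.where(np.linalg.norm(t_front, axis=1) > 1e-9, abd, np.nan)
        out[side + "HA"] = abd

    return out


def angle_error(
    est: MotionSequence, ref: MotionSequence,
    skeleton: Optional[Skeleton] = None, rms: bool = False
) -> Tuple[Dict[str, float], float]:
    """Mean absolute (or RMS) difference of the six gait-angle traces, deg."""
    ea = joint_angles(est, skeleton)
    ra = joint_angles(ref, skeleton)
    per_angle = {}
    for name in ANGLE_NAMES:
        diff = ea[name] - ra[name]
        diff = diff[np.isfinite(diff)]
        if rms:
            per_angle[name] = float(np.sqrt(np.mean(diff ** 2)))
        else:
            per_angle[name] = float(np.mean(np.abs(diff)))
    return per_angle, float(np.mean(list(per_angle.values())))


# ----------------------------------------------------------------------
# Quadrant analysis
# ----------------------------------------------------------------------

_GROUPS = {
    "upper": ("upper-left", "upper-right"),
    "lower": ("lower-left", "lower-right"),
    "left": ("upper-left", "lower-left"),
    "right": ("upper-right", "lower-right"),
    "upper-left": ("upper-left",),
    "upper-right": ("upper-right",),
    "lower-left": ("lower-left",),
    "lower-right": ("lower-right",),
}


def quadrant_report(
    estimates: Dict[str, MotionSequence],
    corrupted: MotionSequence,
    ref: MotionSequence,
    skeleton: Optional[Skeleton] = None,
) -> pd.DataFrame:
    """Regional summary table over body quadrants.

    Rows: upper/lower/left/right and the four quadrants.  Columns: mean
    joint speed of the reference and of the corrupted input (cm/s), the
    percent velocity difference (corrupted - reference) / corrupted * 100,
    the corrupted-input RMSE, and RMSE + improvement (corrupted RMSE minus
    estimate RMSE) for every named estimate.
    """
    skeleton = skeleton or ref.skeleton
    quad = np.array(skeleton.quadrant)
    speeds_ref = np.linalg.norm(compute_velocities(ref), axis=2).mean(axis=0)
    speeds_cor = np.linalg.norm(compute_velocities(corrupted), axis=2).mean(axis=0)
    rmse_cor, _ = joint_rmse(corrupted, ref)
    rmse_est = {name: joint_rmse(est, ref)[0] for name, est in estimates.items()}

    rows = []
    for group, labels in _GROUPS.items():
        sel = np.isin(quad, labels)
        if not sel.any():
            raise ValueError(f"no joints labelled for group {group!r}")
        vr = float(speeds_ref[sel].mean())
        vc = float(speeds_cor[sel].mean())
        row = {
            "group": group,
            "ref_velocity": vr,
            "corrupted_velocity": vc,
            "pct_velocity_diff": 100.0 * (vc - vr) / vc if vc > 0 else 0.0,
            "corrupted_rmse": float(np.nanmean(rmse_cor[sel])),
        }
        for name, rj in rmse_est.items():
            r = float(np.nanmean(rj[sel]))
            row[f"rmse_{name}"] = r
            row[f"improvement_{name}"] = row["corrupted_rmse"] - r
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


# ----------------------------------------------------------------------
# Aggregate report
# ----------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Aggregate evaluation of one estimate against a reference."""

    per_joint_rmse: np.ndarray
    mean_rmse: float
    per_bone_error: np.ndarray
    mean_bone_error: float
    per_angle_error: Optional[Dict[str, float]] = None
    mean_angle_error: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "per_joint_rmse": self.per_joint_rmse.tolist(),
            "mean_rmse": self.mean_rmse,
            "per_bone_error": self.per_bone_error.tolist(),
            "mean_bone_error": self.mean_bone_error,
        }
        if self.per_angle_error is not None:
            d["per_angle_error"] = self.per_angle_error
            d["mean_angle_error"] = self.mean_angle_error
        return d


def evaluate(est: MotionSequence, ref: MotionSequence,
             skeleton: Optional[Skeleton] = None) -> MetricsReport:
    """Position, bone-length and (when leg chains exist) angle errors."""
    skeleton = skeleton or ref.skeleton
    pj, mj = joint_rmse(est, ref)
    pb, mb = bone_length_error(est, ref, skeleton)
    pa = ma = None
    try:
        pa, ma = angle_error(est, ref, skeleton)
    except ValueError:
        pass
    return MetricsReport(pj, mj, pb, mb, pa, ma)
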