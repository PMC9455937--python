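"""Motion sequences: the frames x joints x 3 container and its text I/O.

Positions are centimetres in a right-handed, y-up world frame (the floor is
the y = 0 plane); frame index is 0-based and the sampling interval is
1 / fps.  A boolean mask records which joint-frames were actually observed;
unobserved (dropped-out) coordinates carry the fill value 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .skeleton import Skeleton, subset_skeleton

PHANTOM_NAME = "phantom"


class MotionFormatError(ValueError):
    """Raised when a motion file does not match the expected dialect/skeleton."""


@dataclass
class MotionSequence:
    """Joint-position time series over a skeleton.

    Attributes
    ----------
    skeleton : Skeleton
    fps : float
        Sampling rate, Hz.
    positions : (M, N, 3) float array, cm.
    mask : (M, N) bool array; True where the joint was observed.
    """

    skeleton: Skeleton
    fps: float
    positions: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must be (frames, joints, 3)")
        m, n, _ = self.positions.shape
        if m < 1:
            raise ValueError("a motion sequence needs at least one frame")
        if n != self.skeleton.n_joints:
            raise ValueError(
                f"positions have {n} joints but skeleton has {self.skeleton.n_joints}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.mask is None:
            self.mask = np.ones((m, n), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (m, n):
                raise ValueError("mask must be (frames, joints)")
        if not np.isfinite(self.positions[self.mask]).all():
            raise ValueError("observed positions must be finite")

    # ------------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_joints(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        return 1.0 / self.fps

    def copy(self) -> "MotionSequence":
        return MotionSequence(self.skeleton, self.fps,
                              self.positions.copy(), self.mask.copy())

    def flat(self) -> np.ndarray:
        """(M, 3N) view-order flattening (joint-major triplets)."""
        return self.positions.reshape(self.n_frames, 3 * self.n_joints)

    def bone_vectors(self) -> np.ndarray:
        """(M, B, 3) child-minus-parent vectors for every bone."""
        bones = self.skeleton.bones()
        child = np.array([c for c, _ in bones])
        par = np.array([p for _, p in bones])
        return self.positions[:, child, :] - self.positions[:, par, :]


# ----------------------------------------------------------------------
# Text I/O: header "frame,<joint>_x,<joint>_y,<joint>_z,...", one row per
# frame, empty cell = unobserved coordinate.
# ----------------------------------------------------------------------

def _columns(skel: Skeleton):
    cols = ["frame"]
    for name in skel.joint_names:
        cols += [f"{name}_x", f"{name}_y", f"{name}_z"]
    return cols


def write_motion(seq: MotionSequence, path, float_format: str = "%.9g") -> None:
    """Write a sequence as delimited text (see module docstring for dialect)."""
    m, n = seq.n_frames, seq.n_joints
    data = seq.positions.reshape(m, 3 * n).astype(object)
    holes = np.repeat(~seq.mask, 3, axis=1)
    data[holes] = np.nan
    df = pd.DataFrame(data, columns=_columns(seq.skeleton)[1:])
    df.insert(0, "frame", np.arange(m))
    df.to_csv(path, index=False, float_format=float_format)


def read_motion(path, skeleton: Skeleton, fps: float = 60.0) -> MotionSequence:
    """Read a motion file, validating the header against the skeleton.

    Raises
    ------
    MotionFormatError
        If the header names joints absent from (or missing in) the skeleton.
    ValueError
        For non-numeric cells, with the row/column location.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as e:
        raise MotionFormatError(f"cannot parse motion file {path}: {e}") from e
    expected = _columns(skeleton)
    if list(df.columns) != expected:
        raise MotionFormatError(
            f"motion file columns {list(df.columns)[:4]}... do not match "
            f"skeleton columns {expected[:4]}...")
    body = df[expected[1:]]
    # locate non-numeric cells precisely before coercion
    coerced = body.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & body.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {r}, column {body.columns[c]!r}")
    vals = coerced.to_numpy(dtype=float)
    m = vals.shape[0]
    n = skeleton.n_joints
    pos = vals.reshape(m, n, 3)
    mask = np.isfinite(pos).all(axis=2)
    pos = np.where(np.isfinite(pos), pos, 0.0)
    return MotionSequence(skeleton, fps, pos, mask)


# ----------------------------------------------------------------------
# Geometric utilities
# ----------------------------------------------------------------------

def add_phantom_joint(seq: MotionSequence) -> MotionSequence:
    """Append the floor projection of the pelvis center as an extra joint.

    The phantom joint sits at (x_hip, 0, z_hip) every frame; it anchors the
    skeleton to the floor so a manifold model learns local body motion
    rather than world translation.
    """
    skel = seq.skeleton
    if skel.phantom_index is not None:
        raise ValueError("sequence already has a phantom joint")
    hip = skel.hip_center_positions(seq.positions)  # (M, 3)
    phantom = hip.copy()
    phantom[:, 1] = 0.0
    pos = np.concatenate([seq.positions, phantom[:, None, :]], axis=1)
    mask = np.concatenate([seq.mask, np.ones((seq.n_frames, 1), bool)], axis=1)

    parent = skel.hip_center if skel.hip_center is not None else skel.root
    rest = skel.rest_pose
    if rest is not None:
        hip_rest = (rest[skel.hip_center] if skel.hip_center is not None
                    else 0.5 * (rest[skel.hip_left] + rest[skel.hip_right]))
        ph_rest = np.array([hip_rest[0], 0.0, hip_rest[2]])
        length = max(np.linalg.norm(hip_rest - ph_rest), 1e-6)
        rest = np.vstack([rest, ph_rest])
    else:
        length = max(float(np.mean(hip[:, 1])), 1e-6)
    new_skel = Skeleton(
        joint_names=skel.joint_names + (PHANTOM_NAME,),
        parent_index=np.append(skel.parent_index, parent),
        bone_lengths=np.append(skel.bone_lengths, length),
        quadrant=skel.quadrant + ("axial",),
        hip_left=skel.hip_left,
        hip_right=skel.hip_right,
        hip_center=skel.hip_center,
        phantom_index=skel.n_joints,
        rest_pose=rest,
    )
    return MotionSequence(new_skel, seq.fps, pos, mask)


def drop_phantom_joint(seq: MotionSequence) -> MotionSequence:
    """Inverse of :func:`add_phantom_joint` (removes the phantom joint)."""
    skel = seq.skeleton
    if skel.phantom_index is None:
        raise ValueError("sequence has no phantom joint")
    keep = [n for i, n in enumerate(skel.joint_names) if i != skel.phantom_index]
    return subset_joints(seq, keep)


def scale_by_hip_height(
    seq: MotionSequence,
    reference_height_cm: float,
    subject_height_cm: Optional[float] = None,
) -> Tuple[MotionSequence, float]:
    """Scale a subject to a reference skeleton via hip-to-floor height ratio.

    ``subject_height_cm`` defaults to the mean pelvis-center height of the
    sequence itself (a T-pose clip in practice).  Returns the scaled
    sequence and the factor so the transform can be inverted exactly.
    """
    if subject_height_cm is None:
        subject_height_cm = float(
            np.mean(seq.skeleton.hip_center_positions(seq.positions)[:, 1]))
    if subject_height_cm <= 0 or reference_height_cm <= 0:
        raise ValueError("hip heights must be positive")
    scale = reference_height_cm / subject_height_cm
    skel = seq.skeleton
    new_skel = replace_bone_scale(skel, scale)
    return MotionSequence(new_skel, seq.fps, seq.positions * scale, seq.mask.copy()), scale


def replace_bone_scale(skel: Skeleton, scale: float) -> Skeleton:
    """Skeleton with bone lengths (and rest pose) scaled uniformly."""
    from dataclasses import replace as _rp
    return _rp(
        skel,
        bone_lengths=skel.bone_lengths * scale,
        rest_pose=None if skel.rest_pose is None else skel.rest_pose * scale,
    )


def subset_joints(seq: MotionSequence, names: Sequence[str]) -> MotionSequence:
    """Reorder/reduce a sequence to the named joints (tree re-rooted)."""
    new_skel = subset_skeleton(seq.skeleton, names)
    idx = [seq.skeleton.index(n) for n in names]
    return MotionSequence(new_skel, seq.fps,
                          seq.positions[:, idx, :], seq.mask[:, idx])


def localize_to_trajectory(
    seq: MotionSequence, window: int = 61
) -> Tuple[MotionSequence, np.ndarray]:
    """Express a sequence relative to its smoothed horizontal hip trajectory.

    The pelvis-center x/z track is smoothed with a centered, mask-aware
    moving average (``window`` frames, truncated at the edges) and
    subtracted from every observed joint (y is untouched, so the floor
    stays at y = 0).  Returns the localized sequence and the (M, 3)
    trajectory (y component 0) so :func:`delocalize` can restore world
    coordinates exactly.  Manifold models train and operate on localized
    clips: the body hovers near the origin and the learned filters capture
    local body motion rather than world translation.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    hip = seq.skeleton.hip_center_positions(seq.positions)  # (M, 3)
    if seq.skeleton.hip_center is not None:
        obs = seq.mask[:, seq.skeleton.hip_center]
    else:
        obs = seq.mask[:, seq.skeleton.hip_left] & seq.mask[:, seq.skeleton.hip_right]
    if not obs.any():
        raise ValueError("pelvis is never observed; cannot localize")
    window = min(window, seq.n_frames - (seq.n_frames + 1) % 2)  # keep odd
    kernel = np.ones(window)
    w = obs.astype(float)
    denom = np.convolve(w, kernel, mode="same")
    traj = np.zeros((seq.n_frames, 3))
    for c in (0, 2):
        num = np.convolve(hip[:, c] * w, kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = num / denom
        if np.isnan(sm).any():  # windows with no observed hip: interpolate
            good = np.flatnonzero(~np.isnan(sm))
            sm = np.interp(np.arange(seq.n_frames), good, sm[good])
        traj[:, c] = sm
    out = seq.copy()
    out.positions[seq.mask] = (seq.positions - traj[:, None, :])[seq.mask]
    return out, traj


def delocalize(seq: MotionSequence, trajectory: np.ndarray) -> MotionSequence:
    """Restore world coordinates removed by :func:`localize_to_trajectory`."""
    traj = np.asarray(trajectory, dtype=float)
    if traj.shape != (seq.n_frames, 3):
        raise ValueError("trajectory must be (n_frames, 3)")
    out = seq.copy()
    out.positions[seq.mask] = (seq.positions + traj[:, None, :])[seq.mask]
    return out


def compute_velocities(seq: MotionSequence) -> np.ndarray:
    """Per-joint velocities (cm/s), (M, N, 3).

    Frame-to-frame differences scaled by fps; the first frame duplicates
    the second so the output has one velocity per frame.
    """
    if seq.n_frames < 2:
        raise ValueError("need at least 2 frames to compute velocities")
    v = np.empty_like(seq.positions)
    v[1:] = np.diff(seq.positions, axis=0) * seq.fps
    v[0] = v[1]
    return v
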