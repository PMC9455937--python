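"""Skeleton descriptors for joint-position motion data.

A :class:`Skeleton` is a rooted tree of named joints with fixed bone lengths
(cm), a body-quadrant label per joint, and designated hip joints.  Quadrant
labels partition the non-axial joints into upper/lower x left/right groups
used for regional error analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

QUADRANTS = ("upper-left", "upper-right", "lower-left", "lower-right", "axial")

#: Lower-body gait subset (hips, knees, ankles) of the 21-joint model.
LOWER_BODY_6 = (
    "l_hip", "l_knee", "l_ankle", "r_hip", "r_knee", "r_ankle",
)


@dataclass
class Skeleton:
    """Rooted joint tree with bone lengths and body-quadrant labels.

    Parameters
    ----------
    joint_names : sequence of str
        Ordered joint labels.
    parent_index : array of int
        Parent of each joint; the single root carries ``-1``.
    bone_lengths : array of float
        Length (cm) of the bone from each joint to its parent; ``nan`` at
        the root.
    quadrant : sequence of str
        One of ``upper-left``, ``upper-right``, ``lower-left``,
        ``lower-right`` or ``axial`` per joint.
    hip_left, hip_right : int
        Indices of the two hip joints.
    hip_center : int or None
        Pelvis-center joint; when ``None`` it is derived as the midpoint of
        the two hips.
    phantom_index : int or None
        Index of the floor-projection phantom joint, if present.
    rest_pose : (N, 3) array or None
        Reference (T-pose-like) joint positions, cm, y-up; used to
        recompute bone lengths when joints are subset.
    """

    joint_names: tuple
    parent_index: np.ndarray
    bone_lengths: np.ndarray
    quadrant: tuple
    hip_left: int
    hip_right: int
    hip_center: Optional[int] = None
    phantom_index: Optional[int] = None
    rest_pose: Optional[np.ndarray] = None

    def __post_init__(self):
        self.joint_names = tuple(self.joint_names)
        self.quadrant = tuple(self.quadrant)
        self.parent_index = np.asarray(self.parent_index, dtype=int)
        self.bone_lengths = np.asarray(self.bone_lengths, dtype=float)
        if self.rest_pose is not None:
            self.rest_pose = np.asarray(self.rest_pose, dtype=float)
        self._validate()

    # ------------------------------------------------------------------
    def _validate(self):
        n = self.n_joints
        if len(set(self.joint_names)) != n:
            raise ValueError("joint names must be unique")
        if self.parent_index.shape != (n,) or self.bone_lengths.shape != (n,):
            raise ValueError("parent_index/bone_lengths must have one entry per joint")
        if len(self.quadrant) != n:
            raise ValueError("quadrant must have one label per joint")
        for q in self.quadrant:
            if q not in QUADRANTS:
                raise ValueError(f"unknown quadrant label {q!r}")
        roots = np.flatnonzero(self.parent_index < 0)
        if roots.size != 1:
            raise ValueError("parent_index must define exactly one root")
        # walk to the root from every joint; a cycle never reaches it
        for j in range(n):
            seen = set()
            k = j
            while self.parent_index[k] >= 0:
                if k in seen:
                    raise ValueError("parent_index contains a cycle")
                seen.add(k)
                k = int(self.parent_index[k])
                if not 0 <= k < n:
                    raise ValueError("parent_index out of range")
        non_root = self.parent_index >= 0
        bl = self.bone_lengths[non_root]
        if not (np.isfinite(bl).all() and (bl > 0).all()):
            raise ValueError("bone lengths must be strictly positive and finite")
        for idx in (self.hip_left, self.hip_right):
            if not 0 <= idx < n:
                raise ValueError("hip index out of range")
        if self.hip_left == self.hip_right:
            raise ValueError("hip_left and hip_right must be distinct")
        if self.hip_center is not None and not 0 <= self.hip_center < n:
            raise ValueError("hip_center index out of range")
        if self.rest_pose is not None and self.rest_pose.shape != (n, 3):
            raise ValueError("rest_pose must be (n_joints, 3)")

    # ------------------------------------------------------------------
    @property
    def n_joints(self) -> int:
        return len(self.joint_names)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent_index < 0)[0])

    def index(self, name: str) -> int:
        try:
            return self.joint_names.index(name)
        except ValueError:
            raise KeyError(f"unknown joint {name!r}") from None

    def bones(self):
        """(child, parent) index pairs for every non-root joint."""
        return [(j, int(p)) for j, p in enumerate(self.parent_index) if p >= 0]

    def hip_center_positions(self, positions: np.ndarray) -> np.ndarray:
        """Pelvis-center trajectory, (M, 3), from explicit joint or hip midpoint."""
        if self.hip_center is not None:
            return positions[:, self.hip_center, :]
        return 0.5 * (positions[:, self.hip_left, :] + positions[:, self.hip_right, :])

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "joint_names": list(self.joint_names),
            "parent_index": self.parent_index.tolist(),
            "bone_lengths": [None if not np.isfinite(b) else float(b)
                             for b in self.bone_lengths],
            "quadrant": list(self.quadrant),
            "hip_left": self.hip_left,
            "hip_right": self.hip_right,
            "hip_center": self.hip_center,
            "phantom_index": self.phantom_index,
        }
        if self.rest_pose is not None:
            d["rest_pose"] = self.rest_pose.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Skeleton":
        bl = np.array([np.nan if b is None else b for b in d["bone_lengths"]])
        return cls(
            joint_names=tuple(d["joint_names"]),
            parent_index=np.asarray(d["parent_index"]),
            bone_lengths=bl,
            quadrant=tuple(d["quadrant"]),
            hip_left=d["hip_left"],
            hip_right=d["hip_right"],
            hip_center=d.get("hip_center"),
            phantom_index=d.get("phantom_index"),
            rest_pose=None if d.get("rest_pose") is None else np.asarray(d["rest_pose"]),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "Skeleton":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ----------------------------------------------------------------------
# Reference skeleton models
# ----------------------------------------------------------------------

def cmu21_skeleton() -> Skeleton:
    """Simplified 21-joint full-body model (homogeneous training skeleton).

    Rest pose: upright, y-up, hips at ~94 cm, arms hanging, toes forward
    (+z).  Bone lengths are fixed anthropometric values in cm.
    """
    J = {}  # name -> (parent, offset from parent in rest pose)
    J["hip_center"] = (None, (0.0, 94.0, 0.0))
    J["l_hip"] = ("hip_center", (-11.0, 0.0, 0.0))
    J["l_knee"] = ("l_hip", (0.0, -42.0, 0.0))
    J["l_ankle"] = ("l_knee", (0.0, -42.0, 0.0))
    J["l_toe"] = ("l_ankle", (0.0, -10.0, 11.18033988749895))
    J["r_hip"] = ("hip_center", (11.0, 0.0, 0.0))
    J["r_knee"] = ("r_hip", (0.0, -42.0, 0.0))
    J["r_ankle"] = ("r_knee", (0.0, -42.0, 0.0))
    J["r_toe"] = ("r_ankle", (0.0, -10.0, 11.18033988749895))
    J["spine"] = ("hip_center", (0.0, 12.0, 0.0))
    J["chest"] = ("spine", (0.0, 14.0, 0.0))
    J["neck"] = ("chest", (0.0, 16.0, 0.0))
    J["head"] = ("neck", (0.0, 12.0, 0.0))
    J["l_shoulder"] = ("chest", (-18.0, 8.0, 0.0))
    J["l_elbow"] = ("l_shoulder", (0.0, -30.0, 0.0))
    J["l_wrist"] = ("l_elbow", (0.0, -26.0, 0.0))
    J["l_hand"] = ("l_wrist", (0.0, -9.0, 0.0))
    J["r_shoulder"] = ("chest", (18.0, 8.0, 0.0))
    J["r_elbow"] = ("r_shoulder", (0.0, -30.0, 0.0))
    J["r_wrist"] = ("r_elbow", (0.0, -26.0, 0.0))
    J["r_hand"] = ("r_wrist", (0.0, -9.0, 0.0))

    names = tuple(J)
    parent = np.array([-1 if J[n][0] is None else names.index(J[n][0]) for n in names])
    rest = np.zeros((len(names), 3))
    for i, n in enumerate(names):
        p, off = J[n]
        rest[i] = (rest[names.index(p)] if p is not None else 0.0) + np.asarray(off)
    lengths = np.full(len(names), np.nan)
    for i, p in enumerate(parent):
        if p >= 0:
            lengths[i] = np.linalg.norm(rest[i] - rest[p])

    quad = {
        "hip_center": "axial", "spine": "axial", "chest": "axial",
        "neck": "axial", "head": "axial",
        "l_hip": "lower-left", "l_knee": "lower-left", "l_ankle": "lower-left",
        "l_toe": "lower-left",
        "r_hip": "lower-right", "r_knee": "lower-right", "r_ankle": "lower-right",
        "r_toe": "lower-right",
        "l_shoulder": "upper-left", "l_elbow": "upper-left",
        "l_wrist": "upper-left", "l_hand": "upper-left",
        "r_shoulder": "upper-right", "r_elbow": "upper-right",
        "r_wrist": "upper-right", "r_hand": "upper-right",
    }
    return Skeleton(
        joint_names=names,
        parent_index=parent,
        bone_lengths=lengths,
        quadrant=tuple(quad[n] for n in names),
        hip_left=names.index("l_hip"),
        hip_right=names.index("r_hip"),
        hip_center=names.index("hip_center"),
        rest_pose=rest,
    )


def subset_skeleton(skel: Skeleton, names: Sequence[str]) -> Skeleton:
    """Reduce/reorder a skeleton to the requested joints.

    Each retained joint is re-parented to its nearest retained ancestor;
    bone lengths are recomputed from the rest pose.  If several retained
    joints lose all ancestors, the first becomes the root and the others
    are attached to it so the result stays a single tree.
    """
    if len(names) == 0:
        raise ValueError("joint subset must not be empty")
    idx = [skel.index(n) for n in names]
    if skel.rest_pose is None:
        raise ValueError("subset requires a skeleton rest pose to recompute bone lengths")
    old2new = {o: k for k, o in enumerate(idx)}
    parent = np.full(len(idx), -1, dtype=int)
    orphans = []
    for k, o in enumerate(idx):
        p = int(skel.parent_index[o])
        while p >= 0 and p not in old2new:
            p = int(skel.parent_index[p])
        if p >= 0:
            parent[k] = old2new[p]
        else:
            orphans.append(k)
    # keep a single root: later orphans hang off the first one
    for k in orphans[1:]:
        parent[k] = orphans[0]
    rest = skel.rest_pose[idx]
    lengths = np.full(len(idx), np.nan)
    for k, p in enumerate(parent):
        if p >= 0:
            lengths[k] = np.linalg.norm(rest[k] - rest[p])

    def keep(j):
        return j in old2new

    hl = old2new[skel.hip_left] if keep(skel.hip_left) else 0
    hr = old2new[skel.hip_right] if keep(skel.hip_right) else min(1, len(idx) - 1)
    hc = old2new.get(skel.hip_center) if skel.hip_center is not None else None
    ph = old2new.get(skel.phantom_index) if skel.phantom_index is not None else None
    return Skeleton(
        joint_names=tuple(names),
        parent_index=parent,
        bone_lengths=lengths,
        quadrant=tuple(skel.quadrant[o] for o in idx),
        hip_left=hl,
        hip_right=hr,
        hip_center=hc,
        phantom_index=ph,
        rest_pose=rest,
    )


def mhad16_skeleton() -> Skeleton:
    """16-joint model (head/neck/chest/pelvis, arms to wrists, legs to ankles)."""
    names = (
        "head", "neck", "chest", "hip_center",
        "l_shoulder", "l_elbow", "l_wrist",
        "r_shoulder", "r_elbow", "r_wrist",
        "l_hip", "l_knee", "l_ankle",
        "r_hip", "r_knee", "r_ankle",
    )
    return subset_skeleton(cmu21_skeleton(), names)


def osu6_skeleton() -> Skeleton:
    """6-joint lower-body gait model: hips, knees and ankles."""
    return subset_skeleton(cmu21_skeleton(), LOWER_BODY_6)


NAMED_SKELETONS = {
    "cmu21": cmu21_skeleton,
    "mhad16": mhad16_skeleton,
    "osu6": osu6_skeleton,
}
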