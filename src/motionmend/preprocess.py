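"""Cleaning pipeline for depth-sensor motion data.

Three stages, each usable on its own or as an sklearn-style transformer:

* Hampel outlier removal — sliding-window median/MAD filter per scalar
  coordinate channel.
* Rigid registration — a single global rotation/translation aligning the
  mobile point cloud (all joints, all frames pooled) onto a reference,
  solved in closed form by SVD (Kabsch) with reflection correction.
* Bias removal — subtracts the per-joint mean offset between two aligned
  sequences, removing systematic skeleton-definition differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

from .sequence import MotionSequence

MAD_TO_SIGMA = 1.4826


# ----------------------------------------------------------------------
# Hampel filter
# ----------------------------------------------------------------------

def hampel_filter(series: np.ndarray, window: int = 7, n_sigmas: float = 3.0) -> np.ndarray:
    """Replace spikes by the sliding-window median.

    For each sample, the median ``m`` and the MAD-based std estimate
    ``sigma = 1.4826 * MAD`` are computed over a ``window``-sample centered
    window (truncated at the series edges); the sample is replaced by ``m``
    when ``|x - m| > n_sigmas * sigma``.  When the MAD is zero, any
    deviation from the window median is replaced.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("hampel_filter operates on 1-D channels")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    n = series.size
    half = window // 2
    out = series.copy()

    if n >= window:
        win = sliding_window_view(series, window)          # (n - window + 1, window)
        med = np.median(win, axis=1)
        mad = np.median(np.abs(win - med[:, None]), axis=1)
        center = series[half:n - half]
        dev = np.abs(center - med)
        sigma = MAD_TO_SIGMA * mad
        replace = np.where(sigma > 0, dev > n_sigmas * sigma, dev > 0)
        out[half:n - half] = np.where(replace, med, center)

    # truncated windows at the edges
    edge = list(range(min(half, n))) + list(range(max(n - half, 0), n))
    for i in edge:
        lo, hi = max(0, i - half), min(n, i + half + 1)
        w = series[lo:hi]
        med = np.median(w)
        sigma = MAD_TO_SIGMA * np.median(np.abs(w - med))
        dev = abs(series[i] - med)
        if (dev > n_sigmas * sigma) if sigma > 0 else (dev > 0):
            out[i] = med
    return out


def hampel_sequence(seq: MotionSequence, window: int = 7,
                    n_sigmas: float = 3.0) -> MotionSequence:
    """Hampel-filter every joint coordinate channel of a sequence."""
    out = seq.copy()
    for j in range(seq.n_joints):
        for c in range(3):
            out.positions[:, j, c] = hampel_filter(
                seq.positions[:, j, c], window, n_sigmas)
    return out


class HampelFilter(BaseEstimator, TransformerMixin):
    """Sliding-window median/MAD outlier filter (stateless transformer)."""

    def __init__(self, window: int = 7, n_sigmas: float = 3.0):
        self.window = window
        self.n_sigmas = n_sigmas

    def fit(self, X, y=None):
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be odd and >= 3")
        return self

    def transform(self, X):
        self.fit(X)
        if isinstance(X, MotionSequence):
            return hampel_sequence(X, self.window, self.n_sigmas)
        return hampel_filter(np.asarray(X), self.window, self.n_sigmas)


# ----------------------------------------------------------------------
# Rigid registration by SVD
# ----------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Proper rigid transform x -> R x + t (rotation 3x3, translation cm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def register_svd(
    mobile: MotionSequence, reference: MotionSequence
) -> Tuple[RigidTransform, MotionSequence]:
    """Align a mobile sequence onto a reference with one global rigid transform.

    All joint positions of all frames are pooled into two point clouds; the
    closed-form Kabsch solution gives the rotation (reflections corrected to
    det(R) = +1) and the translation maps the mobile centroid onto the
    reference centroid.  Relative joint geometry is untouched.
    """
    if mobile.positions.shape != reference.positions.shape:
        raise ValueError("mobile and reference must share frame and joint counts")
    P = mobile.positions.reshape(-1, 3)
    Q = reference.positions.reshape(-1, 3)
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points for registration")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    A = (P - cp).T @ (Q - cq)  # 3x3 cross-covariance
    if np.linalg.matrix_rank(A, tol=1e-9 * max(np.abs(A).max(), 1e-30)) < 2:
        raise ValueError("degenerate (rank < 2) point configuration")
    U, _, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    xf = RigidTransform(R, t)
    aligned = MotionSequence(
        mobile.skeleton, mobile.fps,
        xf.apply(mobile.positions.reshape(-1, 3)).reshape(mobile.positions.shape),
        mobile.mask.copy(),
    )
    return xf, aligned


class RigidRegistration(BaseEstimator, TransformerMixin):
    """Global SVD registration onto a reference sequence.

    ``fit(reference)`` stores the reference; ``transform(mobile)`` returns
    the aligned mobile sequence, with the recovered transform available as
    ``transform_``.
    """

    def fit(self, X: MotionSequence, y=None):
        self.reference_ = X
        return self

    def transform(self, X: MotionSequence) -> MotionSequence:
        xf, aligned = register_svd(X, self.reference_)
        self.transform_ = xf
        return aligned


# ----------------------------------------------------------------------
# Bias removal
# ----------------------------------------------------------------------

def remove_bias(
    dmocap: MotionSequence, mocap: MotionSequence
) -> Tuple[np.ndarray, MotionSequence]:
    """Subtract the per-joint mean offset between two aligned sequences.

    Returns the (N, 3) bias (mean over frames of dmocap - mocap per joint)
    and the corrected sequence; the corrected per-joint mean residual is
    zero by construction.
    """
    if dmocap.positions.shape != mocap.positions.shape:
        raise ValueError("sequences must share frame and joint counts")
    bias = (dmocap.positions - mocap.positions).mean(axis=0)  # (N, 3)
    out = dmocap.copy()
    out.positions = out.positions - bias[None, :, :]
    return bias, out


class BiasRemover(BaseEstimator, TransformerMixin):
    """Removes per-joint systematic offsets relative to a reference.

    ``fit(X, y=reference)`` estimates the bias of X against the reference;
    ``transform`` subtracts it.
    """

    def fit(self, X: MotionSequence, y: Optional[MotionSequence] = None):
        if y is None:
            raise ValueError("BiasRemover.fit requires a reference sequence as y")
        self.bias_, _ = remove_bias(X, y)
        return self

    def transform(self, X: MotionSequence) -> MotionSequence:
        out = X.copy()
        out.positions = out.positions - self.bias_[None, :, :]
        return out
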