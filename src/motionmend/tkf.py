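"""Per-joint Tobit Kalman filtering with velocity-adaptive censoring limits.

Each joint is tracked independently with a 6-state constant-velocity model
(position + velocity per Cartesian axis).  Measurements are treated as
censored: per axis, an observation outside the interval [T_L, T_H] is
recorded as the threshold value, and the update step weights the
innovation by the probability mass of the uncensored region under the
predicted measurement distribution.  The thresholds adapt per frame from
the previous filtered position +- |v_max| * dt, where |v_max| is the
largest measured joint speed (per axis) in a window centered at the
previous frame — occluded joints re-emerge with a velocity spike, which
tightens censoring exactly when measurements are least trustworthy.

With infinitely wide thresholds the update reduces exactly to the linear
Kalman filter; with ``threshold_mode='none'`` the plain KF update is used
directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.special import ndtr
from sklearn.base import BaseEstimator, TransformerMixin

from .sequence import MotionSequence

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _phi(x):
    return np.exp(-0.5 * np.clip(x * x, 0.0, 1400.0)) / _SQRT2PI


def _Phi(x):
    return ndtr(x)


def cv_transition(dt: float) -> np.ndarray:
    """Constant-velocity 6x6 transition: positions advance by velocity * dt."""
    F = np.eye(6)
    F[0, 3] = F[1, 4] = F[2, 5] = dt
    return F


def cv_process_noise(dt: float, sigma_a: float) -> np.ndarray:
    """Discrete white-noise-acceleration process covariance (per-axis blocks)."""
    q11 = dt ** 4 / 4.0
    q12 = dt ** 3 / 2.0
    q22 = dt ** 2
    Q = np.zeros((6, 6))
    for i in range(3):
        Q[i, i] = q11
        Q[i, i + 3] = Q[i + 3, i] = q12
        Q[i + 3, i + 3] = q22
    return sigma_a ** 2 * Q


OBSERVATION = np.zeros((3, 6))
OBSERVATION[0, 0] = OBSERVATION[1, 1] = OBSERVATION[2, 2] = 1.0


@dataclass
class TKFConfig:
    """Filter configuration.

    ``sigma_a`` (cm/s^2) sets the white-noise-acceleration process
    covariance; ``sigma_r`` (cm) the per-coordinate measurement noise std.
    ``window_frames`` is the measured-velocity window for the adaptive
    thresholds (50-80 frames spans a complete action at 60 fps).
    """

    dt: float = 1.0 / 60.0
    sigma_a: float = 1500.0
    sigma_r: float = 3.0
    window_frames: int = 60
    threshold_mode: str = "adaptive"  # adaptive | fixed | none
    fixed_t_low: Optional[np.ndarray] = None
    fixed_t_high: Optional[np.ndarray] = None
    causal: bool = False
    Q: Optional[np.ndarray] = None
    R: Optional[np.ndarray] = None
    P0: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.window_frames < 1:
            raise ValueError("window_frames must be >= 1")
        if self.threshold_mode not in ("adaptive", "fixed", "none"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "fixed":
            if self.fixed_t_low is None or self.fixed_t_high is None:
                raise ValueError("fixed mode requires fixed_t_low/fixed_t_high")

    @property
    def F(self) -> np.ndarray:
        return cv_transition(self.dt)

    @property
    def Hm(self) -> np.ndarray:
        return OBSERVATION

    def process_noise(self) -> np.ndarray:
        return self.Q if self.Q is not None else cv_process_noise(self.dt, self.sigma_a)

    def measurement_noise(self) -> np.ndarray:
        return self.R if self.R is not None else self.sigma_r ** 2 * np.eye(3)

    def initial_covariance(self) -> np.ndarray:
        if self.P0 is not None:
            return self.P0
        pvar = self.sigma_r ** 2
        vvar = 2.0 * self.sigma_r ** 2 / self.dt ** 2
        return np.diag([pvar] * 3 + [vvar] * 3)


@dataclass
class TKFState:
    """6-vector state [px py pz vx vy vz] with 6x6 covariance."""

    x: np.ndarray
    P: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float).reshape(6)
        self.P = np.asarray(self.P, dtype=float).reshape(6, 6)


@dataclass
class Thresholds:
    """Per-axis censoring interval [t_low, t_high] (cm)."""

    t_low: np.ndarray
    t_high: np.ndarray

    def __post_init__(self):
        self.t_low = np.asarray(self.t_low, dtype=float).reshape(3)
        self.t_high = np.asarray(self.t_high, dtype=float).reshape(3)
        if (self.t_low > self.t_high).any():
            raise ValueError("t_low must be <= t_high elementwise")


@dataclass
class CensorProbs:
    """Probability masses of the uncensored / low / high measurement regions."""

    p_uc: np.ndarray
    p_l: np.ndarray
    p_h: np.ndarray

    def __post_init__(self):
        for a in (self.p_uc, self.p_l, self.p_h):
            if ((a < -1e-12) | (a > 1 + 1e-12)).any():
                raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(self.p_uc + self.p_l + self.p_h, 1.0, atol=1e-9):
            raise ValueError("censoring probabilities must sum to 1 per axis")


# ----------------------------------------------------------------------
# Elementary steps
# ----------------------------------------------------------------------

def windowed_vmax(measured: np.ndarray, fps: float, frame_k: int,
                  window_frames: int, causal: bool = False) -> np.ndarray:
    """Per-axis max |velocity| of the measured trajectory over a window
    centered at frame k-1 (truncated at the sequence edges)."""
    m = measured.shape[0]
    v = np.abs(np.diff(measured, axis=0)) * fps  # velocity at frames 1..m-1
    center = frame_k - 1
    if causal:
        lo, hi = center - window_frames + 1, center
    else:
        half = window_frames // 2
        lo, hi = center - half, center + half
    lo = max(lo, 1)
    hi = min(hi, m - 1)
    if hi < lo:
        return np.zeros(3)
    return v[lo - 1:hi].max(axis=0)


def compute_thresholds(prev_pos: np.ndarray, measured_positions: np.ndarray,
                       frame_k: int, config: TKFConfig,
                       fps: Optional[float] = None) -> Thresholds:
    """Adaptive censoring limits: previous estimate +- |v_max| * dt."""
    if frame_k < 1:
        raise ValueError("thresholds are defined from frame 1 onward")
    fps = fps if fps is not None else 1.0 / config.dt
    vmax = windowed_vmax(np.asarray(measured_positions, float), fps, frame_k,
                         config.window_frames, config.causal)
    prev = np.asarray(prev_pos, dtype=float).reshape(3)
    delta = np.abs(vmax) * config.dt
    return Thresholds(prev - delta, prev + delta)


def censor(q: np.ndarray, thresholds: Thresholds) -> np.ndarray:
    """Censored measurement: clamp each axis to [t_low, t_high]."""
    return np.clip(np.asarray(q, dtype=float).reshape(3),
                   thresholds.t_low, thresholds.t_high)


def predict(state: TKFState, config: TKFConfig) -> TKFState:
    """Time update under the constant-velocity model."""
    F = config.F
    x = F @ state.x
    P = F @ state.P @ F.T + config.process_noise()
    return TKFState(x, 0.5 * (P + P.T))


def tobit_update(state_pred: TKFState, rho: np.ndarray, thresholds: Thresholds,
                 config: TKFConfig) -> Tuple[TKFState, CensorProbs]:
    """Measurement update with censored-measurement moments.

    Per axis, the predicted measurement is Gaussian with mean Hx and
    variance diag(HPH' + R); the expectation of the censored measurement
    combines the truncated-normal mean of the uncensored region with the
    threshold values weighted by their tail masses.  The gain
    K = R_XY R_YY^{-1} uses the censored cross- and auto-covariances; in
    the uncensored limit (p_uc -> 1) the update reduces to the linear KF.
    """
    H = config.Hm
    R = config.measurement_noise()
    x, P = state_pred.x, state_pred.P
    mu = H @ x
    S = H @ P @ H.T + R
    s = np.sqrt(np.clip(np.diag(S), 1e-30, None))

    a = (thresholds.t_low - mu) / s
    b = (thresholds.t_high - mu) / s
    Fa, Fb = _Phi(a), _Phi(b)
    p_l = Fa
    p_h = 1.0 - Fb
    p_uc = np.clip(Fb - Fa, 0.0, 1.0)
    probs = CensorProbs(p_uc=p_uc, p_l=p_l, p_h=np.clip(p_h, 0.0, 1.0))

    # truncated-normal mean of the uncensored region
    safe = p_uc > 1e-12
    lam = np.zeros(3)
    lam[safe] = (_phi(a[safe]) - _phi(b[safe])) / p_uc[safe]
    e_trunc = mu + s * lam
    # 0 * (+-inf) guards: a zero-mass tail contributes nothing
    lo_term = np.where(p_l > 0, p_l * thresholds.t_low, 0.0)
    hi_term = np.where(p_h > 0, p_h * thresholds.t_high, 0.0)
    e_y = p_uc * e_trunc + lo_term + hi_term

    # censored-measurement covariances: the prior measurement spread is
    # weighted by the uncensored mass per axis, the sensor noise is not —
    # the gain reduces to the linear KF at p_uc = 1 and vanishes smoothly
    # as the interval closes (p_uc -> 0)
    Puc = np.diag(p_uc)
    R_XY = P @ H.T @ Puc
    R_YY = Puc @ (H @ P @ H.T) @ Puc + R
    diag = np.diag(R_YY)
    bad = diag < 1e-12 * max(np.max(diag), 1.0)
    if bad.any():  # only reachable with a degenerate (zero) R
        warnings.warn("R_YY numerically singular; using regularized inverse",
                      RuntimeWarning, stacklevel=2)
        R_YY = R_YY + np.diag(np.where(bad, 1e-9, 0.0))
    K = np.linalg.solve(R_YY.T, R_XY.T).T

    rho = np.asarray(rho, dtype=float).reshape(3)
    x_post = x + K @ (rho - e_y)
    P_post = (np.eye(6) - K @ Puc @ H) @ P
    return TKFState(x_post, 0.5 * (P_post + P_post.T)), probs


def _kf_update(state_pred: TKFState, q: np.ndarray, config: TKFConfig) -> TKFState:
    """Standard linear KF measurement update (threshold_mode 'none')."""
    H = config.Hm
    R = config.measurement_noise()
    x, P = state_pred.x, state_pred.P
    S = H @ P @ H.T + R
    K = np.linalg.solve(S.T, (P @ H.T).T).T
    x_post = x + K @ (np.asarray(q, float).reshape(3) - H @ x)
    P_post = (np.eye(6) - K @ H) @ P
    return TKFState(x_post, 0.5 * (P_post + P_post.T))


# ----------------------------------------------------------------------
# Sequence-level filtering
# ----------------------------------------------------------------------

def filter_sequence(
    seq: MotionSequence, config: Optional[TKFConfig] = None
) -> Tuple[MotionSequence, Dict]:
    """Filter every joint independently; masked measurements are treated
    as fully censored (prediction only).

    Returns the filtered sequence and diagnostics with per-frame
    thresholds and censoring probabilities.
    """
    if seq.n_frames < 2:
        raise ValueError("need at least 2 frames to filter")
    config = config or TKFConfig(dt=seq.dt)
    m, n = seq.n_frames, seq.n_joints
    out = np.empty_like(seq.positions)
    thr_lo = np.full((m, n, 3), -np.inf)
    thr_hi = np.full((m, n, 3), np.inf)
    p_uc = np.zeros((m, n, 3))

    for j in range(n):
        q = seq.positions[:, j, :]
        obs = seq.mask[:, j]
        obs_idx = np.flatnonzero(obs)
        if obs_idx.size == 0:
            warnings.warn(f"joint {j} has no observed frames; prediction-only",
                          RuntimeWarning)
            out[:, j, :] = q
            continue
        i0 = int(obs_idx[0])
        x0 = np.zeros(6)
        x0[:3] = q[i0]
        if obs_idx.size > 1:
            i1 = int(obs_idx[1])
            x0[3:] = (q[i1] - q[i0]) / ((i1 - i0) * config.dt)
        state = TKFState(x0, config.initial_covariance())
        out[:i0 + 1, j, :] = q[i0]
        p_uc[i0, j, :] = 1.0  # the initializing measurement is accepted

        for k in range(i0 + 1, m):
            prev_pos = state.x[:3].copy()
            state = predict(state, config)
            if not obs[k]:
                out[k, j, :] = state.x[:3]
                p_uc[k, j, :] = 0.0
                continue
            if config.threshold_mode == "none":
                state = _kf_update(state, q[k], config)
                p_uc[k, j, :] = 1.0
            else:
                if config.threshold_mode == "adaptive":
                    thr = compute_thresholds(prev_pos, q, k, config, fps=seq.fps)
                else:
                    thr = Thresholds(config.fixed_t_low, config.fixed_t_high)
                rho = censor(q[k], thr)
                state, probs = tobit_update(state, rho, thr, config)
                thr_lo[k, j, :] = thr.t_low
                thr_hi[k, j, :] = thr.t_high
                p_uc[k, j, :] = probs.p_uc
            out[k, j, :] = state.x[:3]

    filtered = MotionSequence(seq.skeleton, seq.fps, out)
    diagnostics = {"t_low": thr_lo, "t_high": thr_hi, "p_uc": p_uc}
    return filtered, diagnostics


class TobitKalmanFilter(BaseEstimator, TransformerMixin):
    """sklearn-style transformer applying the per-joint TKF to a sequence."""

    def __init__(self, dt: float = 1.0 / 60.0, sigma_a: float = 1500.0,
                 sigma_r: float = 3.0, window_frames: int = 60,
                 threshold_mode: str = "adaptive", causal: bool = False):
        self.dt = dt
        self.sigma_a = sigma_a
        self.sigma_r = sigma_r
        self.window_frames = window_frames
        self.threshold_mode = threshold_mode
        self.causal = causal

    def _config(self, seq: Optional[MotionSequence] = None) -> TKFConfig:
        dt = seq.dt if seq is not None else self.dt
        return TKFConfig(dt=dt, sigma_a=self.sigma_a, sigma_r=self.sigma_r,
                         window_frames=self.window_frames,
                         threshold_mode=self.threshold_mode, causal=self.causal)

    def fit(self, X=None, y=None):
        self._config()  # validate
        return self

    def transform(self, X: MotionSequence) -> MotionSequence:
        filtered, self.diagnostics_ = filter_sequence(X, self._config(X))
        return filtered
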