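"""Latent-space optimization and the two enhancement paradigms.

TKF-assisted (parallel, for noisy data): the Tobit Kalman filter output of
the raw sequence becomes the optimization target; the sequence's latent
code is adjusted (decoder frozen) to minimize the Cartesian distance of the
decoded motion to that target, so the result keeps the filter's kinematics
while staying on the learned motion manifold.

TKF-refined (serial, for missing data): the autoencoder first fills the
drop-outs by manifold reconstruction, then the TKF smooths the result.

A bone-length constraint — squared deviation of decoded inter-joint
distances from the skeleton's known bone lengths — can be added to the
latent cost, and drives structure matching of heterogeneous skeletons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._nnops import Adam
from .autoencoder import (AEParams, LatentCode, decode, decode_array,
                          decode_grad_latent, encode, reconstruct)
from .sequence import MotionSequence
from .skeleton import Skeleton
from .tkf import TKFConfig, filter_sequence

MODES = ("tkf_assisted", "tkf_refined", "ae_only", "tkf_only", "kf_assisted")


@dataclass
class EnhanceConfig:
    """Latent-optimization settings shared by all enhancement modes."""

    mode: str = "tkf_assisted"
    opt_learning_rate: float = 0.01
    opt_iterations: int = 100
    bone_weight: float = 0.0
    target_weight: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.opt_iterations < 1:
            raise ValueError("opt_iterations must be >= 1")
        if self.bone_weight < 0 or self.target_weight < 0:
            raise ValueError("weights must be >= 0")


def _bone_cost_grad(pos: np.ndarray, skeleton: Skeleton
                    ) -> Tuple[float, np.ndarray]:
    """Cost sum_k sum_b (||bone vector|| - l_b)^2 and its position gradient."""
    bones = skeleton.bones()
    child = np.array([c for c, _ in bones])
    par = np.array([p for _, p in bones])
    lb = skeleton.bone_lengths[child]
    d = pos[:, child] - pos[:, par]              # (M, B, 3)
    norms = np.linalg.norm(d, axis=2)
    dev = norms - lb
    cost = float(np.sum(dev ** 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(norms[..., None] > 1e-12, d / norms[..., None], 0.0)
    g = 2.0 * dev[..., None] * unit
    grad = np.zeros_like(pos)
    np.add.at(grad, (slice(None), child), g)
    np.add.at(grad, (slice(None), par), -g)
    return cost, grad


def latent_optimize(
    seq_in: MotionSequence,
    target: Union[MotionSequence, np.ndarray],
    params: AEParams,
    config: Optional[EnhanceConfig] = None,
    skeleton: Optional[Skeleton] = None,
) -> MotionSequence:
    """Adjust the latent code of ``seq_in`` toward a Cartesian target.

    The latent is initialized from ``encode(seq_in)`` and optimized with
    Adam while the decoder stays frozen; the returned sequence decodes the
    best (lowest-cost) latent visited, so the final cost never exceeds the
    initial one.  ``config.bone_weight > 0`` adds the bone-length
    constraint against the skeleton's known lengths.
    """
    config = config or EnhanceConfig()
    r = target.positions if isinstance(target, MotionSequence) else np.asarray(target)
    if not np.isfinite(r).all():
        raise ValueError("target contains non-finite values")
    m = seq_in.n_frames
    if r.shape != (m, seq_in.n_joints, 3):
        raise ValueError("target must be frame/joint aligned with the input")
    r_flat = r.reshape(m, -1)
    skeleton = skeleton or seq_in.skeleton

    latent = encode(seq_in, params)
    h = latent.values.T.copy()                   # (U, F)

    def cost_grad(hmat):
        x = decode_array(LatentCode(np.maximum(hmat.T, 0.0), m), params)
        resid = x - r_flat
        c = config.target_weight * float(np.sum(resid ** 2))
        dx = 2.0 * config.target_weight * resid
        if config.bone_weight > 0:
            bc, bg = _bone_cost_grad(x.reshape(m, -1, 3), skeleton)
            c += config.bone_weight * bc
            dx = dx + config.bone_weight * bg.reshape(m, -1)
        return c, decode_grad_latent(dx, params)

    best_h = h.copy()
    best_c, g = cost_grad(h)
    opt = Adam([h.shape], learning_rate=config.opt_learning_rate)
    for _ in range(config.opt_iterations):
        opt.step([h], [g])
        np.maximum(h, 0.0, out=h)                # latent stays in ReLU range
        c, g = cost_grad(h)
        if c < best_c:
            best_c = c
            best_h = h.copy()

    x = decode(LatentCode(best_h.T, m), params)
    return MotionSequence(seq_in.skeleton, seq_in.fps, x)


def bone_constrained_fit(
    seq: MotionSequence,
    params: AEParams,
    skeleton: Optional[Skeleton] = None,
    config: Optional[EnhanceConfig] = None,
) -> MotionSequence:
    """Project a sequence onto the manifold while enforcing known bone lengths.

    The latent cost combines fidelity to the input with the squared
    deviation of decoded bone lengths from the skeleton's fixed lengths
    (structure matching of a mismatched skeleton to the training skeleton).
    """
    skeleton = skeleton or seq.skeleton
    if config is None:
        config = EnhanceConfig(bone_weight=1.0, target_weight=0.05,
                               opt_iterations=200)
    if config.bone_weight <= 0:
        raise ValueError("bone_constrained_fit requires bone_weight > 0")
    return latent_optimize(seq, seq.positions, params, config, skeleton)


# ----------------------------------------------------------------------
# Enhancement paradigms
# ----------------------------------------------------------------------

def enhance_tkf_assisted(
    seq: MotionSequence,
    params: AEParams,
    tkf_config: Optional[TKFConfig] = None,
    config: Optional[EnhanceConfig] = None,
) -> Tuple[MotionSequence, Dict]:
    """Parallel paradigm for noisy data: TKF target, latent optimization.

    Pipeline: (1) TKF-filter the raw data into a target matrix; (2-3)
    encode the raw data into the latent space; (4-5) decode to a manifold
    estimate; (6) form the Cartesian cost against the target; (7) optimize
    the latent code.  Returns the enhanced sequence and a run log.
    """
    tkf_config = tkf_config or TKFConfig(dt=seq.dt)
    config = config or EnhanceConfig(mode="tkf_assisted")
    target, tkf_diag = filter_sequence(seq, tkf_config)
    out = latent_optimize(seq, target, params, config)
    log = {"stages": ["tkf_target", "encode", "latent_optimize", "decode"],
           "mode": config.mode,
           "threshold_mode": tkf_config.threshold_mode}
    return out, log


def enhance_kf_assisted(
    seq: MotionSequence,
    params: AEParams,
    tkf_config: Optional[TKFConfig] = None,
    config: Optional[EnhanceConfig] = None,
) -> Tuple[MotionSequence, Dict]:
    """TKF-assisted pipeline with a plain (uncensored) Kalman filter target."""
    base = tkf_config or TKFConfig(dt=seq.dt)
    kf_config = TKFConfig(dt=base.dt, sigma_a=base.sigma_a, sigma_r=base.sigma_r,
                          window_frames=base.window_frames, threshold_mode="none",
                          Q=base.Q, R=base.R, P0=base.P0)
    config = config or EnhanceConfig(mode="kf_assisted")
    return enhance_tkf_assisted(seq, params, kf_config, config)


def enhance_tkf_refined(
    seq: MotionSequence,
    params: AEParams,
    tkf_config: Optional[TKFConfig] = None,
    config: Optional[EnhanceConfig] = None,
) -> Tuple[MotionSequence, Dict]:
    """Serial paradigm for missing data: autoencoder first, TKF second.

    Masked joint-frames enter the encoder as the fill value (zero after
    normalization); the manifold reconstruction bridges the gaps and the
    TKF then restores per-joint kinematics.
    """
    tkf_config = tkf_config or TKFConfig(dt=seq.dt)
    recon = reconstruct(seq, params)
    out, _ = filter_sequence(recon, tkf_config)
    log = {"stages": ["autoencoder", "tkf"], "mode": "tkf_refined",
           "threshold_mode": tkf_config.threshold_mode}
    return out, log


def enhance(
    seq: MotionSequence,
    params: AEParams,
    tkf_config: Optional[TKFConfig] = None,
    config: Optional[EnhanceConfig] = None,
) -> Tuple[MotionSequence, Dict]:
    """Dispatch on ``config.mode`` over all five enhancement variants."""
    config = config or EnhanceConfig()
    tkf_config = tkf_config or TKFConfig(dt=seq.dt)
    if config.mode == "tkf_assisted":
        return enhance_tkf_assisted(seq, params, tkf_config, config)
    if config.mode == "kf_assisted":
        return enhance_kf_assisted(seq, params, tkf_config, config)
    if config.mode == "tkf_refined":
        return enhance_tkf_refined(seq, params, tkf_config, config)
    if config.mode == "ae_only":
        return reconstruct(seq, params), {"stages": ["autoencoder"],
                                          "mode": "ae_only"}
    if config.mode == "tkf_only":
        out, _ = filter_sequence(seq, tkf_config)
        return out, {"stages": ["tkf"], "mode": "tkf_only",
                     "threshold_mode": tkf_config.threshold_mode}
    raise ValueError(f"unknown mode {config.mode!r}")


# ----------------------------------------------------------------------
# Estimators
# ----------------------------------------------------------------------

class MotionEnhancer(BaseEstimator, TransformerMixin):
    """sklearn-style enhancer combining a trained manifold model and a TKF.

    Parameters mirror :class:`EnhanceConfig` plus the TKF settings; the
    trained :class:`~motionmend.autoencoder.AEParams` (or a fitted
    ``MotionAutoencoder``) is passed at construction.  ``transform`` runs
    the selected paradigm on one sequence; the run log of the last call is
    kept in ``log_``.
    """

    def __init__(self, autoencoder=None, mode: str = "tkf_assisted",
                 opt_learning_rate: float = 0.01, opt_iterations: int = 100,
                 bone_weight: float = 0.0, sigma_a: float = 1500.0,
                 sigma_r: float = 3.0, window_frames: int = 60):
        self.autoencoder = autoencoder
        self.mode = mode
        self.opt_learning_rate = opt_learning_rate
        self.opt_iterations = opt_iterations
        self.bone_weight = bone_weight
        self.sigma_a = sigma_a
        self.sigma_r = sigma_r
        self.window_frames = window_frames

    def _params(self) -> AEParams:
        ae = self.autoencoder
        if ae is None:
            raise ValueError("MotionEnhancer requires a trained autoencoder")
        return ae.params_ if hasattr(ae, "params_") else ae

    def fit(self, X=None, y=None):
        self._params()
        return self

    def transform(self, X: MotionSequence) -> MotionSequence:
        cfg = EnhanceConfig(mode=self.mode,
                            opt_learning_rate=self.opt_learning_rate,
                            opt_iterations=self.opt_iterations,
                            bone_weight=self.bone_weight)
        tkf_cfg = TKFConfig(dt=X.dt, sigma_a=self.sigma_a, sigma_r=self.sigma_r,
                            window_frames=self.window_frames)
        out, self.log_ = enhance(X, self._params(), tkf_cfg, cfg)
        return out
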