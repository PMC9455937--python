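"""Single-layer temporal convolutional autoencoder over joint positions.

The encoder flattens a clip to an (M, 3N) matrix, z-scores each input
dimension, convolves 25-frame-wide temporal filters across it (stride 1,
zero same-padding), adds a bias, max-pools frames by 2 and applies ReLU.
The decoder inverts each stage: pooled values are replicated into adjacent
frame pairs, the bias is subtracted, and the weight tensor — reflected
along the frame axis and transposed in the other two — is convolved back
(the exact adjoint of the encoder convolution), then the output is
de-normalized.

Training minimizes the squared reconstruction error plus an L1 sparsity
penalty on the weights with Adam; input-level dropout regularizes the
encoder.  Everything is plain numpy with closed-form gradients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._nnops import (Adam, conv_adjoint, conv_grad_w, conv_same, maxpool2,
                     maxpool2_grad, unpool2, unpool2_adjoint)
from .sequence import MotionSequence

POOL_FACTOR = 2


@dataclass
class AEParams:
    """Trained autoencoder parameters.

    W : (filters, 3N, width) convolution weights; b : (filters,) bias;
    norm_mean/norm_std : per-input-dimension z-score statistics;
    joint_names : skeleton fingerprint the model was trained for.
    """

    W: np.ndarray
    b: np.ndarray
    norm_mean: np.ndarray
    norm_std: np.ndarray
    pool_factor: int = POOL_FACTOR
    joint_names: Optional[tuple] = None

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.norm_mean = np.asarray(self.norm_mean, dtype=float)
        self.norm_std = np.asarray(self.norm_std, dtype=float)
        if self.W.ndim != 3:
            raise ValueError("W must be (filters, input_dims, width)")
        if self.W.shape[2] % 2 == 0:
            raise ValueError("filter width must be odd")
        if self.b.shape != (self.W.shape[0],):
            raise ValueError("b must have one entry per filter")
        if not (self.norm_std > 0).all():
            raise ValueError("norm_std must be strictly positive")
        if not (np.isfinite(self.W).all() and np.isfinite(self.b).all()):
            raise ValueError("parameters must be finite")

    @property
    def n_filters(self) -> int:
        return self.W.shape[0]

    @property
    def input_dims(self) -> int:
        return self.W.shape[1]

    @property
    def width(self) -> int:
        return self.W.shape[2]

    def save(self, path) -> None:
        np.savez(path, W=self.W, b=self.b, norm_mean=self.norm_mean,
                 norm_std=self.norm_std, pool_factor=self.pool_factor,
                 joint_names=np.array(self.joint_names if self.joint_names
                                      else [], dtype=object))

    @classmethod
    def load(cls, path) -> "AEParams":
        d = np.load(path, allow_pickle=True)
        names = tuple(d["joint_names"].tolist()) or None
        return cls(W=d["W"], b=d["b"], norm_mean=d["norm_mean"],
                   norm_std=d["norm_std"], pool_factor=int(d["pool_factor"]),
                   joint_names=names)


@dataclass
class LatentCode:
    """Non-negative latent matrix (filters x pooled frames) for one clip."""

    values: np.ndarray  # (F, ceil(M/2))
    n_frames: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("latent values must be 2-D (filters x pooled frames)")
        if (self.values < 0).any():
            raise ValueError("latent values must be non-negative (ReLU range)")
        if self.values.shape[1] != (self.n_frames + 1) // POOL_FACTOR:
            raise ValueError("pooled length inconsistent with n_frames")


@dataclass
class TrainHyper:
    """Training hyperparameters (Adam moments/learning rate as published)."""

    alpha: float = 0.01
    learning_rate: float = 0.001
    adam_moments: Tuple[float, float] = (0.9, 0.999)
    dropout_rate: float = 0.2
    epochs: int = 200
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must lie in (0, 1]")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


# ----------------------------------------------------------------------
# Functional core
# ----------------------------------------------------------------------

def _normalized_input(seq: Union[MotionSequence, np.ndarray],
                      params: AEParams) -> np.ndarray:
    """(M, D) z-scored input; unobserved joint-frames enter as 0."""
    if isinstance(seq, MotionSequence):
        x = seq.flat()
        holes = np.repeat(~seq.mask, 3, axis=1)
    else:
        x = np.asarray(seq, dtype=float)
        holes = None
    if x.shape[1] != params.input_dims:
        raise ValueError(
            f"input has {x.shape[1]} dims, model expects {params.input_dims}")
    xn = (x - params.norm_mean) / params.norm_std
    if holes is not None:
        xn[holes] = 0.0
    return xn


def encode(seq: Union[MotionSequence, np.ndarray], params: AEParams) -> LatentCode:
    """Project a clip onto the motion manifold's latent space."""
    xn = _normalized_input(seq, params)
    m = xn.shape[0]
    if m < params.width:
        raise ValueError("clip shorter than the filter width")
    z = conv_same(xn, params.W) + params.b
    p, _ = maxpool2(z)
    h = np.maximum(p, 0.0)
    return LatentCode(values=h.T, n_frames=m)


def decode_array(latent: LatentCode, params: AEParams) -> np.ndarray:
    """Decode a latent code to an (M, 3N) position matrix."""
    h = latent.values.T  # (U, F)
    if h.shape[1] != params.n_filters:
        raise ValueError("latent filter count does not match the model")
    g = unpool2(h, latent.n_frames)
    yn = conv_adjoint(g - params.b, params.W)
    return yn * params.norm_std + params.norm_mean


def decode(latent: LatentCode, params: AEParams) -> np.ndarray:
    """Decode to a frames x joints x 3 array."""
    x = decode_array(latent, params)
    return x.reshape(latent.n_frames, -1, 3)


def decode_grad_latent(d_out: np.ndarray, params: AEParams) -> np.ndarray:
    """Backpropagate a gradient w.r.t. the decoded (M, 3N) output to the
    (U, F) latent matrix (decoder weights frozen)."""
    dyn = d_out * params.norm_std
    dg = conv_same(dyn, params.W)
    return unpool2_adjoint(dg)


def reconstruct(seq: MotionSequence, params: AEParams) -> MotionSequence:
    """Autoencoder round trip: the manifold's estimate of clean motion."""
    x = decode(encode(seq, params), params)
    return MotionSequence(seq.skeleton, seq.fps, x)


# ----------------------------------------------------------------------
# Training
# ----------------------------------------------------------------------

def _corpus_matrix(corpus: Sequence[MotionSequence]) -> np.ndarray:
    if len(corpus) == 0:
        raise ValueError("empty training corpus")
    names = corpus[0].skeleton.joint_names
    m = corpus[0].n_frames
    for c in corpus:
        if c.skeleton.joint_names != names:
            raise ValueError("corpus clips must share one skeleton")
        if c.n_frames != m:
            raise ValueError("corpus clips must share one frame count")
    return np.stack([c.flat() for c in corpus])  # (B, M, D)


def train(
    corpus: Sequence[MotionSequence],
    hyper: Optional[TrainHyper] = None,
    n_filters: int = 256,
    width: int = 25,
) -> Tuple[AEParams, List[float]]:
    """Train the autoencoder on a homogeneous corpus.

    Returns the fitted parameters and the per-epoch training-loss log
    (squared reconstruction error in normalized units, averaged per clip,
    plus the L1 penalty).
    """
    hyper = hyper or TrainHyper()
    X = _corpus_matrix(corpus)  # (B, M, D)
    nb, m, d = X.shape
    if m < width:
        raise ValueError("clips must be at least as long as the filter width")

    # per-dimension centering, one shared scale: an isotropic normalization
    # keeps measurement noise isotropic (a per-dimension z-score would blow
    # up sensor noise on low-range channels such as the phantom joint)
    mean = X.reshape(-1, d).mean(axis=0)
    scale = float((X - mean).std())
    std = np.full(d, scale if scale > 1e-8 else 1.0)
    Xn = (X - mean) / std

    rng = np.random.default_rng(hyper.seed)
    scale = np.sqrt(2.0 / (d * width + n_filters))
    W = rng.normal(0.0, scale, (n_filters, d, width))
    b = np.zeros(n_filters)

    opt = Adam([W.shape, b.shape], hyper.learning_rate,
               hyper.adam_moments[0], hyper.adam_moments[1])
    keep = 1.0 - hyper.dropout_rate
    losses: List[float] = []

    for epoch in range(hyper.epochs):
        order = rng.permutation(nb)
        epoch_loss = 0.0
        for start in range(0, nb, hyper.batch_size):
            idx = order[start:start + hyper.batch_size]
            xb = Xn[idx]  # (B, M, D)
            if hyper.dropout_rate > 0:
                drop = rng.random(xb.shape) < hyper.dropout_rate
                xin = np.where(drop, 0.0, xb) / keep
            else:
                xin = xb
            # forward
            z = conv_same(xin, W) + b
            p, arg = maxpool2(z)
            h = np.maximum(p, 0.0)
            g = unpool2(h, m)
            gb = g - b
            yn = conv_adjoint(gb, W)
            resid = yn - xb
            bsz = len(idx)
            rec = float(np.sum(resid ** 2)) / bsz
            l1 = hyper.alpha * (np.abs(W).sum() + np.abs(b).sum())
            epoch_loss += (rec + l1) * bsz
            # backward
            dyn = (2.0 / bsz) * resid
            dW = conv_grad_w(dyn, gb, width)          # decoder weights
            dgb = conv_same(dyn, W)
            db = -dgb.sum(axis=(0, 1))                # decoder bias
            dh = unpool2_adjoint(dgb)
            dp = dh * (p > 0)
            dz = maxpool2_grad(dp, arg, m)
            dW += conv_grad_w(xin, dz, width)         # encoder weights
            db += dz.sum(axis=(0, 1))                 # encoder bias
            if hyper.alpha > 0:
                dW += hyper.alpha * np.sign(W)
                db += hyper.alpha * np.sign(b)
            opt.step([W, b], [dW, db])
        losses.append(epoch_loss / nb)

    params = AEParams(W=W, b=b, norm_mean=mean, norm_std=std,
                      joint_names=corpus[0].skeleton.joint_names)
    return params, losses


# ----------------------------------------------------------------------
# Estimator
# ----------------------------------------------------------------------

class MotionAutoencoder(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper: ``fit`` trains on a corpus of clips,
    ``transform`` reconstructs a clip through the learned manifold.

    Fitted attributes: ``W_``, ``b_``, ``norm_mean_``, ``norm_std_``,
    ``loss_history_``, ``params_``.
    """

    def __init__(self, n_filters: int = 256, width: int = 25,
                 alpha: float = 0.01, learning_rate: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999,
                 dropout_rate: float = 0.2, epochs: int = 200,
                 batch_size: int = 16, seed: int = 0):
        self.n_filters = n_filters
        self.width = width
        self.alpha = alpha
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.dropout_rate = dropout_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    def fit(self, X: Sequence[MotionSequence], y=None):
        hyper = TrainHyper(alpha=self.alpha, learning_rate=self.learning_rate,
                           adam_moments=(self.beta1, self.beta2),
                           dropout_rate=self.dropout_rate, epochs=self.epochs,
                           batch_size=self.batch_size, seed=self.seed)
        self.params_, self.loss_history_ = train(
            X, hyper, n_filters=self.n_filters, width=self.width)
        self.W_ = self.params_.W
        self.b_ = self.params_.b
        self.norm_mean_ = self.params_.norm_mean
        self.norm_std_ = self.params_.norm_std
        return self

    def transform(self, X: MotionSequence) -> MotionSequence:
        return reconstruct(X, self.params_)

    def encode(self, X: MotionSequence) -> LatentCode:
        return encode(X, self.params_)

    def decode(self, latent: LatentCode) -> np.ndarray:
        return decode(latent, self.params_)
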