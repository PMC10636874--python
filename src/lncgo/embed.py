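"""Stacked denoising autoencoder for low-dimensional node features.

The PPMI matrix is high-dimensional (one column per network node), so node
feature rows are compressed with a stack of denoising autoencoders trained
greedily: stage k learns to reconstruct the clean layer-(k-1) representation
from a corrupted copy by minimizing the squared reconstruction loss

    min_{theta1, theta2}  sum_i  || x_i - g_theta2(f_theta1(x~_i)) ||^2

with f_theta1(x) = sigma(W1 x + b1) (logistic sigmoid) and a linear
reconstruction g_theta2(y) = W2 y + b2, where x~ is the input with entries
independently masked to zero.  The narrowest (bottleneck) layer supplies the
embedding.  An optional end-to-end fine-tuning pass through the whole
encoder/decoder stack is available but off by default.

Optimization uses minibatch Adam; every source of randomness (init,
shuffling, corruption masks) derives from the configured seed, so a given
(seed, config, data) triple reproduces the embedding bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SDAEConfig:
    """Layer widths include the input width first and must not increase
    toward the bottleneck (the published full-scale configuration is
    [36863, 10000, 3000, 1000, 512]; tests and small networks use reduced
    widths with the same shape constraint)."""

    widths: list[int]
    corruption: float = 0.2
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0
    fine_tune: bool = False
    minmax_scale: bool = False

    def __post_init__(self):
        if len(self.widths) < 2:
            raise ValueError("need at least an input width and one hidden width")
        if any(w <= 0 for w in self.widths):
            raise ValueError("layer widths must be strictly positive")
        if any(b > a for a, b in zip(self.widths, self.widths[1:])):
            raise ValueError("layer widths must be non-increasing toward the bottleneck")
        if not 0.0 <= self.corruption < 1.0:
            raise ValueError(f"corruption fraction {self.corruption} outside [0, 1)")


@dataclass
class EncoderState:
    """Trained per-layer encoder/decoder parameters and loss traces."""

    widths: list[int]
    encoders: list[tuple[np.ndarray, np.ndarray]]  # (W1, b1) per stage
    decoders: list[tuple[np.ndarray, np.ndarray]]  # (W2, b2) per stage
    loss_traces: list[list[float]]
    scale: tuple[np.ndarray, np.ndarray] | None = None  # (min, range) if scaled

    @property
    def bottleneck_width(self) -> int:
        return self.widths[-1]


@dataclass
class EmbeddingMatrix:
    node_ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        if self.matrix.shape[0] != len(self.node_ids):
            raise ValueError("embedding row count must equal node count")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding contains non-finite values")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def corrupt(x: np.ndarray, fraction: float, rng: np.random.Generator | int) -> np.ndarray:
    """Masking noise: each entry independently set to 0 with the given
    probability.  The same seed always yields the same mask."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"corruption fraction {fraction} outside [0, 1)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if fraction == 0.0:
        return np.array(x, dtype=float, copy=True)
    mask = rng.random(x.shape) >= fraction
    return np.asarray(x, dtype=float) * mask


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _train_stage(H: np.ndarray, width_out: int, cfg: SDAEConfig,
                 rng: np.random.Generator, stage: int) -> tuple:
    n, d = H.shape
    W1 = _glorot(rng, d, width_out)
    b1 = np.zeros(width_out)
    W2 = _glorot(rng, width_out, d)
    b2 = np.zeros(d)
    opt = _Adam([W1, b1, W2, b2], cfg.learning_rate)
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        sq_sum = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = H[idx]
            xt = corrupt(xb, cfg.corruption, rng)
            y = _sigmoid(xt @ W1 + b1)
            z = y @ W2 + b2
            err = z - xb
            sq_sum += float((err ** 2).sum())
            dZ = 2.0 * err / err.size
            gW2 = y.T @ dZ
            gb2 = dZ.sum(axis=0)
            dY = dZ @ W2.T
            dS = dY * y * (1.0 - y)
            gW1 = xt.T @ dS
            gb1 = dS.sum(axis=0)
            opt.step([gW1, gb1, gW2, gb2])
        loss = sq_sum / H.size
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss in SDAE stage {stage} epoch {epoch}")
        trace.append(loss)
    return (W1, b1), (W2, b2), trace


def train_sdae(X, cfg: SDAEConfig) -> EncoderState:
    """Greedy layer-wise training of the autoencoder stack on feature rows.

    ``X`` is the PPMI matrix (or any finite 2-D array whose column count
    equals ``cfg.widths[0]``).  Each stage's loss trace (mean squared
    reconstruction error per epoch) is recorded; non-finite losses raise,
    citing the stage and epoch.
    """
    H = np.asarray(getattr(X, "matrix", X), dtype=float)
    if not np.all(np.isfinite(H)):
        raise ValueError("input features must be finite")
    if H.shape[1] != cfg.widths[0]:
        raise ValueError(
            f"input width {H.shape[1]} does not match configured width {cfg.widths[0]}")
    scale = None
    if cfg.minmax_scale:
        lo = H.min(axis=0)
        rng_ = H.max(axis=0) - lo
        rng_[rng_ == 0] = 1.0
        scale = (lo, rng_)
        H = (H - lo) / rng_
    rng = np.random.default_rng(cfg.seed)
    encoders, decoders, traces = [], [], []
    for stage, width_out in enumerate(cfg.widths[1:], start=1):
        (W1, b1), (W2, b2), trace = _train_stage(H, width_out, cfg, rng, stage)
        encoders.append((W1, b1))
        decoders.append((W2, b2))
        traces.append(trace)
        H = _sigmoid(H @ W1 + b1)
    state = EncoderState(widths=list(cfg.widths), encoders=encoders,
                         decoders=decoders, loss_traces=traces, scale=scale)
    if cfg.fine_tune:
        _fine_tune(state, np.asarray(getattr(X, "matrix", X), dtype=float), cfg, rng)
    return state


def _fine_tune(state: EncoderState, X: np.ndarray, cfg: SDAEConfig,
               rng: np.random.Generator) -> None:
    """End-to-end pass through the full encoder/decoder stack (in place)."""
    H = X
    if state.scale is not None:
        lo, rng_ = state.scale
        H = (H - lo) / rng_
    params: list[np.ndarray] = []
    for W, b in state.encoders + state.decoders:
        params.extend((W, b))
    opt = _Adam(params, cfg.learning_rate)
    trace: list[float] = []
    n = H.shape[0]
    K = len(state.encoders)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        sq_sum = 0.0
        for start in range(0, n, cfg.batch_size):
            xb = H[order[start:start + cfg.batch_size]]
            xt = corrupt(xb, cfg.corruption, rng)
            # forward: encoders (sigmoid), then decoders deepest-first (linear)
            acts = [xt]
            for W, b in state.encoders:
                acts.append(_sigmoid(acts[-1] @ W + b))
            h = acts[-1]
            dec_in = [h]
            for W, b in reversed(state.decoders):
                dec_in.append(dec_in[-1] @ W + b)
            z = dec_in[-1]
            err = z - xb
            sq_sum += float((err ** 2).sum())
            grads = [np.zeros_like(p) for p in params]
            d = 2.0 * err / err.size
            for k in range(K):  # decoders: state.decoders[0] is applied last
                W, _ = state.decoders[k]
                gi = 2 * K + 2 * k
                grads[gi] = dec_in[K - 1 - k].T @ d
                grads[gi + 1] = d.sum(axis=0)
                d = d @ W.T
            for k in reversed(range(K)):
                y = acts[k + 1]
                d = d * y * (1.0 - y)
                W, _ = state.encoders[k]
                grads[2 * k] = acts[k].T @ d
                grads[2 * k + 1] = d.sum(axis=0)
                d = d @ W.T
            opt.step(grads)
        loss = sq_sum / H.size
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss in fine-tune epoch {epoch}")
        trace.append(loss)
    state.loss_traces.append(trace)


def encode(state: EncoderState, X, node_ids=None) -> EmbeddingMatrix:
    """Apply the encoder stack only, returning bottleneck features per row."""
    H = np.asarray(getattr(X, "matrix", X), dtype=float)
    if H.shape[1] != state.widths[0]:
        raise ValueError(
            f"input width {H.shape[1]} does not match encoder input width "
            f"{state.widths[0]}")
    if state.scale is not None:
        lo, rng_ = state.scale
        H = (H - lo) / rng_
    for W, b in state.encoders:
        H = _sigmoid(H @ W + b)
    if node_ids is None:
        node_ids = tuple(str(i) for i in range(H.shape[0]))
    return EmbeddingMatrix(node_ids=tuple(node_ids), matrix=H)
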