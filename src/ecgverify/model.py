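"""Shared-weight 1D-CNN Siamese encoder with an ensemble similarity head.

Architecture
------------
Eight 1D convolutional layers (kernel 3, same padding, ReLU), with filter
counts 32, 32, 64, 64, 128, 128, 256, 256; a ceil-mode max-pool of size 2
and stride 2 after every convolution, so an input of length 200 or 256
collapses to length 1 over eight halvings; a final linear dense layer
producing a 512-dimensional embedding.  One parameter set serves every
branch of the Siamese comparison — "which branch" an input passes through
is immaterial by construction.

Similarity between two embeddings is a logistic head on their elementwise
absolute difference::

    similarity(a, b) = sigmoid(w . |a - b| + b0)

which is symmetric in (a, b) and strictly inside (0, 1).  A bundle's score
is the arithmetic mean of the probe's similarity to each of the n_ref
reference embeddings (permutation-invariant in the references).

Training minimizes binary cross-entropy of the bundle score against the
match/mismatch label plus an L2 penalty on the weight matrices, using
Adam.  Everything — forward, backward, optimizer — is plain NumPy, which
keeps inference bit-deterministic and the dependency surface minimal.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .bundles import Bundle
from .errors import InvalidArgumentError, ShapeError
from .preprocess import FeatureMatrix

_EPS = 1e-7  # probability clip for the cross-entropy


@dataclass(frozen=True)
class EncoderConfig:
    """Hyperparameters of the encoder and its training loop."""

    conv_filters: tuple[int, ...] = (32, 32, 64, 64, 128, 128, 256, 256)
    kernel_size: int = 3
    embed_dim: int = 512
    l2_coeff: float = 1e-4
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 8:
            raise InvalidArgumentError("conv_filters must list 8 layers")
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise InvalidArgumentError("kernel_size must be odd")
        if self.embed_dim < 1:
            raise InvalidArgumentError("embed_dim must be >= 1")
        if self.learning_rate <= 0:
            raise InvalidArgumentError("learning_rate must be > 0")
        if self.l2_coeff < 0:
            raise InvalidArgumentError("l2_coeff must be >= 0")
        if self.epochs < 0 or self.batch_size < 1:
            raise InvalidArgumentError("bad epochs/batch_size")


def _ceil_pool_length(L: int, n_layers: int) -> int:
    for _ in range(n_layers):
        L = (L + 1) // 2
    return L


def _conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded conv: x (B,C,L), W (F,C,K) -> (B,F,L); returns cache."""
    K = W.shape[2]
    pad = K // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # (B,C,L,K)
    out = np.tensordot(win, W, axes=([1, 3], [1, 2]))  # (B,L,F)
    out = np.ascontiguousarray(out.transpose(0, 2, 1)) + b[None, :, None]
    return out, (win, W, x.shape)


def _conv1d_backward(dout: np.ndarray, cache):
    win, W, x_shape = cache
    B, C, L = x_shape
    K = W.shape[2]
    pad = K // 2
    db = dout.sum(axis=(0, 2))
    dW = np.tensordot(dout, win, axes=([0, 2], [0, 2]))  # (F,C,K)
    dwin = np.tensordot(dout, W, axes=([1], [0]))  # (B,L,C,K)
    dxp = np.zeros((B, C, L + 2 * pad))
    for kk in range(K):
        dxp[:, :, kk : kk + L] += dwin[:, :, :, kk].transpose(0, 2, 1)
    dx = dxp[:, :, pad : pad + L]
    return dx, dW, db


def _maxpool_forward(x: np.ndarray):
    """Ceil-mode pool, size 2 stride 2: odd lengths are padded with -inf."""
    B, C, L = x.shape
    L2 = (L + 1) // 2
    if L % 2:
        x = np.pad(x, ((0, 0), (0, 0), (0, 1)), constant_values=-np.inf)
    xr = x.reshape(B, C, L2, 2)
    arg = xr.argmax(axis=3)
    out = np.take_along_axis(xr, arg[..., None], axis=3)[..., 0]
    return out, (arg, L)


def _maxpool_backward(dout: np.ndarray, cache):
    arg, L = cache
    B, C, L2 = dout.shape
    dxr = np.zeros((B, C, L2, 2))
    np.put_along_axis(dxr, arg[..., None], dout[..., None], axis=3)
    dx = dxr.reshape(B, C, 2 * L2)[:, :, :L]
    return dx


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy of similarity scores against 0/1 labels."""
    p = np.clip(np.asarray(scores, dtype=np.float64), _EPS, 1 - _EPS)
    y = np.asarray(labels, dtype=np.float64)
    return float(np.mean(-y * np.log(p) - (1 - y) * np.log(1 - p)))


class SiameseModel:
    """Parameter store + forward/backward passes of the ensemble network."""

    def __init__(self, config: EncoderConfig, L: int, params: dict):
        self.config = config
        self.L = int(L)
        self.params = params
        self.n_conv = len(config.conv_filters)
        self.flattened_dim = (
            config.conv_filters[-1] * _ceil_pool_length(L, self.n_conv)
        )

    # ------------------------------------------------------------- setup
    @classmethod
    def initialize(cls, config: EncoderConfig, L: int) -> "SiameseModel":
        """He-initialized parameters, deterministic under ``config.seed``."""
        if L < 2 ** len(config.conv_filters) // 2:
            raise InvalidArgumentError(f"input length {L} too short")
        rng = np.random.default_rng(config.seed)
        params: dict[str, np.ndarray] = {}
        c_in = 2
        K = config.kernel_size
        for i, c_out in enumerate(config.conv_filters):
            std = np.sqrt(2.0 / (c_in * K))
            params[f"conv{i}_W"] = rng.normal(0, std, size=(c_out, c_in, K))
            params[f"conv{i}_b"] = np.zeros(c_out)
            c_in = c_out
        flat = config.conv_filters[-1] * _ceil_pool_length(
            L, len(config.conv_filters)
        )
        params["dense_W"] = rng.normal(
            0, np.sqrt(2.0 / flat), size=(flat, config.embed_dim)
        )
        params["dense_b"] = np.zeros(config.embed_dim)
        params["head_w"] = rng.normal(0, 0.05, size=config.embed_dim)
        params["head_b"] = np.zeros(1)
        return cls(config, L, params)

    def fingerprint(self) -> str:
        """Stable content hash of all parameters."""
        h = hashlib.sha256()
        for name in sorted(self.params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.params[name]).tobytes())
        return h.hexdigest()

    # ----------------------------------------------------------- encoder
    def _encode_batch(self, X: np.ndarray, want_cache: bool = False):
        """X: (B, 2, L) channels-first batch -> (B, embed_dim)."""
        caches = []
        h = X
        for i in range(self.n_conv):
            h, conv_cache = _conv1d_forward(
                h, self.params[f"conv{i}_W"], self.params[f"conv{i}_b"]
            )
            relu_mask = h > 0
            h = h * relu_mask
            h, pool_cache = _maxpool_forward(h)
            caches.append((conv_cache, relu_mask, pool_cache))
        B = h.shape[0]
        flat = h.reshape(B, -1)
        emb = flat @ self.params["dense_W"] + self.params["dense_b"]
        if want_cache:
            return emb, (caches, flat, h.shape)
        return emb

    def _encoder_backward(self, demb: np.ndarray, cache, grads: dict):
        caches, flat, h_shape = cache
        grads["dense_W"] += flat.T @ demb
        grads["dense_b"] += demb.sum(axis=0)
        dh = (demb @ self.params["dense_W"].T).reshape(h_shape)
        for i in reversed(range(self.n_conv)):
            conv_cache, relu_mask, pool_cache = caches[i]
            dh = _maxpool_backward(dh, pool_cache)
            dh = dh * relu_mask
            dh, dW, db = _conv1d_backward(dh, conv_cache)
            grads[f"conv{i}_W"] += dW
            grads[f"conv{i}_b"] += db
        return dh

    def _check_shape(self, fm: FeatureMatrix) -> None:
        if fm.data.shape != (self.L, 2):
            raise ShapeError(
                f"expected feature matrix of shape ({self.L}, 2), "
                f"got {fm.data.shape}"
            )

    def encode(self, fm: FeatureMatrix) -> np.ndarray:
        """Embed one feature matrix; deterministic in inference."""
        self._check_shape(fm)
        X = fm.data.T[None, :, :]  # (1, 2, L)
        return self._encode_batch(X)[0]

    # -------------------------------------------------------- similarity
    def similarity(self, a: np.ndarray, b: np.ndarray) -> float:
        """sigmoid(w . |a - b| + b0); symmetric, strictly in (0, 1)."""
        a = np.asarray(a, dtype=np.float64)
        b = np.asarray(b, dtype=np.float64)
        if a.shape != b.shape or a.ndim != 1:
            raise ShapeError(f"embedding shapes differ: {a.shape} vs {b.shape}")
        if a.size != self.config.embed_dim:
            raise ShapeError(
                f"expected embeddings of dimension {self.config.embed_dim}"
            )
        z = self.params["head_w"] @ np.abs(a - b) + self.params["head_b"][0]
        return float(sigmoid(np.array([z]))[0])

    def bundle_score(self, bundle: Bundle) -> float:
        """Mean similarity of the probe to each reference embedding."""
        probe = self.encode(bundle.probe)
        sims = [self.similarity(probe, self.encode(r)) for r in bundle.refs]
        return float(np.mean(sims))

    def score_bundles(self, bundles: list[Bundle]) -> np.ndarray:
        """Vectorized bundle scoring (used by evaluation loops)."""
        if not bundles:
            return np.array([])
        n_ref = len(bundles[0].refs)
        if any(len(b.refs) != n_ref for b in bundles):
            return np.array([self.bundle_score(b) for b in bundles])
        for b in bundles:
            self._check_shape(b.probe)
            for r in b.refs:
                self._check_shape(r)
        X = np.stack(
            [fm.data.T for b in bundles for fm in (*b.refs, b.probe)]
        )
        emb = self._encode_batch(X).reshape(len(bundles), n_ref + 1, -1)
        refs, probes = emb[:, :n_ref], emb[:, n_ref]
        d = np.abs(probes[:, None, :] - refs)  # (B, n_ref, D)
        z = d @ self.params["head_w"] + self.params["head_b"][0]
        return sigmoid(z).mean(axis=1)

    # ------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        """Portable checkpoint: npz parameters + embedded config JSON."""
        meta = json.dumps({"config": asdict(self.config), "L": self.L})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "SiameseModel":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            params = {k: npz[k] for k in npz.files if k != "__meta__"}
        cfg = meta["config"]
        cfg["conv_filters"] = tuple(cfg["conv_filters"])
        return cls(EncoderConfig(**cfg), meta["L"], params)


@dataclass
class TrainResult:
    model: SiameseModel
    loss_trace: list[float] = field(default_factory=list)

    def trace_json(self) -> str:
        return json.dumps({"epoch_loss": self.loss_trace})


def train(bundles: list[Bundle], config: EncoderConfig) -> TrainResult:
    """Fit the ensemble Siamese network on labeled bundles.

    Minimizes ``BCE(bundle_score, label) + l2_coeff * sum ||W||^2`` with
    Adam; the per-epoch mean training loss is recorded.  All reference
    and probe signals of a mini-batch pass through one shared encoder in
    a single batched call.
    """
    if not bundles:
        raise InvalidArgumentError("training set is empty")
    labels = np.array([b.label for b in bundles], dtype=np.float64)
    if labels.min() == labels.max():
        raise InvalidArgumentError("training set must contain both labels")
    n_ref = len(bundles[0].refs)
    if any(len(b.refs) != n_ref for b in bundles):
        raise InvalidArgumentError("all bundles must share one n_ref")
    L = bundles[0].probe.L

    model = SiameseModel.initialize(config, L)
    result = TrainResult(model=model)
    if config.epochs == 0:
        return result

    rng = np.random.default_rng(config.seed + 1)
    # Adam state
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    weight_keys = [
        k for k in model.params if k.endswith("_W") or k == "head_w"
    ]

    for _epoch in range(config.epochs):
        order = rng.permutation(len(bundles))
        epoch_loss, n_seen = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = [bundles[i] for i in idx]
            y = labels[idx]
            B = len(batch)

            X = np.stack(
                [fm.data.T for b in batch for fm in (*b.refs, b.probe)]
            )
            emb, cache = model._encode_batch(X, want_cache=True)
            D = emb.shape[1]
            e = emb.reshape(B, n_ref + 1, D)
            refs, probes = e[:, :n_ref], e[:, n_ref]
            diff = probes[:, None, :] - refs  # (B, n_ref, D)
            d = np.abs(diff)
            w, b0 = model.params["head_w"], model.params["head_b"][0]
            z = d @ w + b0  # (B, n_ref)
            s = sigmoid(z)
            p = s.mean(axis=1)
            pc = np.clip(p, _EPS, 1 - _EPS)
            loss = float(np.mean(-y * np.log(pc) - (1 - y) * np.log(1 - pc)))
            epoch_loss += loss * B
            n_seen += B

            grads = {k: np.zeros_like(par) for k, par in model.params.items()}
            g_p = (pc - y) / (pc * (1 - pc)) / B
            g_z = g_p[:, None] * s * (1 - s) / n_ref  # (B, n_ref)
            grads["head_w"] += np.einsum("bn,bnd->d", g_z, d)
            grads["head_b"] += g_z.sum()
            g_d = g_z[:, :, None] * w[None, None, :]
            g_diff = g_d * np.sign(diff)
            demb = np.empty_like(e)
            demb[:, :n_ref] = -g_diff
            demb[:, n_ref] = g_diff.sum(axis=1)
            model._encoder_backward(demb.reshape(B * (n_ref + 1), D),
                                    cache, grads)
            for k in weight_keys:
                grads[k] += 2.0 * config.l2_coeff * model.params[k]

            step += 1
            for k, par in model.params.items():
                g = grads[k]
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**step)
                vhat = v[k] / (1 - beta2**step)
                par -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)

        result.loss_trace.append(epoch_loss / n_seen)
    return result
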