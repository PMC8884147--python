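"""A small 1-D convolutional network for segment quality, in pure numpy.

Architecture (fixed): two blocks of two stride-2 convolutions with kernel
size 32 and edge-replication ("same end values") padding — 10 filters per
layer in the first block, 5 in the second — each followed by ReLU; then
global average pooling over time and a dense softmax layer with two outputs.
Global average pooling makes the network applicable to inputs of any length:
a 960-sample segment produces a 5-channel x 60-step feature map before
pooling, a 480-sample one 5 x 30, and both pool to the same 5-value feature
vector, analogous to the five hand-crafted features of the SVM.  The whole
network has 5,962 trainable parameters.

Training is mini-batch Adam on the softmax cross-entropy.  Transfer to a new
population copies the trained network, retrains only the dense
classification layer on the new data (the convolutional weights stay
bit-identical), and optionally fine-tunes all weights for a few epochs at a
reduced learning rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..core import Segment, ValidationError
from ..preprocessing import normalize_segment
from .config import AdaptationConfig, CnnHyper

KERNEL_SIZE = 32
STRIDE = 2
#: (in_channels, out_channels) of the four convolutional layers.
CONV_SHAPES = ((1, 10), (10, 10), (10, 5), (5, 5))
N_CLASSES = 2


def _pad_replicate(x: np.ndarray, L_out: int) -> tuple[np.ndarray, int]:
    """Edge-replication padding so that stride-2 windows produce ceil(L/2)."""
    L = x.shape[-1]
    pad_total = max((L_out - 1) * STRIDE + KERNEL_SIZE - L, 0)
    pad_left = pad_total // 2
    pad_right = pad_total - pad_left
    return np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad_left, pad_right)], mode="edge"), pad_left


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x: (B, C_in, L) -> (B, C_out, ceil(L/2)); returns output and cache."""
    L = x.shape[-1]
    L_out = math.ceil(L / STRIDE)
    xp, pad_left = _pad_replicate(x, L_out)
    win = sliding_window_view(xp, KERNEL_SIZE, axis=2)[:, :, ::STRIDE, :][:, :, :L_out, :]
    out = np.einsum("bilk,oik->bol", win, W, optimize=True) + b[None, :, None]
    return out, (x.shape, xp.shape, pad_left, win)


def _conv_backward(dout: np.ndarray, W: np.ndarray, cache):
    x_shape, xp_shape, pad_left, win = cache
    dW = np.einsum("bol,bilk->oik", dout, win, optimize=True)
    db = dout.sum(axis=(0, 2))
    dxp = np.zeros(xp_shape)
    L_out = dout.shape[-1]
    contrib = np.einsum("bol,oik->bilk", dout, W, optimize=True)
    for t in range(KERNEL_SIZE):
        dxp[:, :, t : t + (L_out - 1) * STRIDE + 1 : STRIDE] += contrib[:, :, :, t]
    # fold padded-edge gradients back onto the replicated edge samples
    L = x_shape[-1]
    dx = dxp[:, :, pad_left : pad_left + L].copy()
    dx[:, :, 0] += dxp[:, :, :pad_left].sum(axis=2)
    dx[:, :, -1] += dxp[:, :, pad_left + L :].sum(axis=2)
    return dx, dW, db


@dataclass
class CnnModel:
    """Weight bundle of the fixed architecture."""

    conv_weights: list[np.ndarray]   # each (C_out, C_in, 32)
    conv_biases: list[np.ndarray]
    dense_weight: np.ndarray         # (2, 5)
    dense_bias: np.ndarray           # (2,)
    fs: float
    seed: int

    @classmethod
    def initialize(cls, seed: int, fs: float = 16.0) -> "CnnModel":
        rng = np.random.default_rng(seed)
        Ws, bs = [], []
        for c_in, c_out in CONV_SHAPES:
            fan_in = c_in * KERNEL_SIZE
            Ws.append(rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(c_out, c_in, KERNEL_SIZE)))
            bs.append(np.zeros(c_out))
        dense_W = rng.normal(0.0, math.sqrt(2.0 / CONV_SHAPES[-1][1]), size=(N_CLASSES, CONV_SHAPES[-1][1]))
        return cls(Ws, bs, dense_W, np.zeros(N_CLASSES), fs=fs, seed=seed)

    @property
    def parameter_count(self) -> int:
        n = sum(W.size + b.size for W, b in zip(self.conv_weights, self.conv_biases))
        return n + self.dense_weight.size + self.dense_bias.size

    def parameters(self) -> list[np.ndarray]:
        return [*self.conv_weights, *self.conv_biases, self.dense_weight, self.dense_bias]

    def copy(self) -> "CnnModel":
        return CnnModel(
            [W.copy() for W in self.conv_weights],
            [b.copy() for b in self.conv_biases],
            self.dense_weight.copy(),
            self.dense_bias.copy(),
            fs=self.fs,
            seed=self.seed,
        )

    # ---- forward passes -------------------------------------------------

    def feature_map(self, x: np.ndarray) -> np.ndarray:
        """Pre-pooling feature map, shape (B, 5, ceil(L/16))."""
        h = self._as_batch(x)[:, None, :]
        for W, b in zip(self.conv_weights, self.conv_biases):
            h, _ = _conv_forward(h, W, b)
            h = np.maximum(h, 0.0)
        return h

    def features(self, x: np.ndarray) -> np.ndarray:
        """Globally averaged 5-value feature vectors, shape (B, 5)."""
        return self.feature_map(x).mean(axis=2)

    def predict_proba_full(self, x: np.ndarray) -> np.ndarray:
        """(B, 2) softmax probabilities (noisy, clean)."""
        logits = self.features(x) @ self.dense_weight.T + self.dense_bias
        return _softmax(logits)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Probability of the clean class per input."""
        return self.predict_proba_full(x)[:, 1]

    def _as_batch(self, x) -> np.ndarray:
        if isinstance(x, Segment):
            x = normalize_segment(x).samples[None, :]
        elif isinstance(x, (list, tuple)) and x and isinstance(x[0], Segment):
            x = np.stack([normalize_segment(s).samples for s in x])
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[-1] < 2:
            raise ValidationError("CNN input too short")
        return x

    def _forward_train(self, x: np.ndarray):
        caches = []
        h = x[:, None, :]
        for W, b in zip(self.conv_weights, self.conv_biases):
            h, cache = _conv_forward(h, W, b)
            mask = h > 0
            h = h * mask
            caches.append((cache, mask))
        fmap = h
        feats = fmap.mean(axis=2)
        logits = feats @ self.dense_weight.T + self.dense_bias
        return logits, (caches, fmap, feats)

    def _backward(self, dlogits: np.ndarray, ctx):
        caches, fmap, feats = ctx
        grads: dict[str, list | np.ndarray] = {
            "dense_W": dlogits.T @ feats,
            "dense_b": dlogits.sum(axis=0),
            "conv_W": [None] * len(self.conv_weights),
            "conv_b": [None] * len(self.conv_weights),
        }
        dfeats = dlogits @ self.dense_weight
        dmap = np.repeat(dfeats[:, :, None], fmap.shape[2], axis=2) / fmap.shape[2]
        dh = dmap
        for li in range(len(self.conv_weights) - 1, -1, -1):
            cache, mask = caches[li]
            dh = dh * mask
            dh, dW, db = _conv_backward(dh, self.conv_weights[li], cache)
            grads["conv_W"][li] = dW
            grads["conv_b"][li] = db
        return grads


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _prepare_inputs(segments, y) -> tuple[np.ndarray, np.ndarray, float]:
    if isinstance(segments, np.ndarray):
        return np.asarray(segments, dtype=float), np.asarray(y).astype(int), 16.0
    fs = segments[0].fs
    for s in segments:
        if s.fs != fs:
            raise ValidationError("all training segments must share one sampling rate")
    lengths = {s.n_samples for s in segments}
    if len(lengths) > 1:
        raise ValidationError(
            "training batches require equal-length segments (inference accepts "
            "any length via global average pooling)"
        )
    X = np.stack([normalize_segment(s).samples for s in segments])
    return X, np.asarray(y).astype(int), fs


def _run_epochs(
    model: CnnModel,
    X: np.ndarray,
    y: np.ndarray,
    lr: float,
    epochs: int,
    batch_size: int,
    rng: np.random.Generator,
    trainable: str = "all",
) -> None:
    params = (
        model.parameters()
        if trainable == "all"
        else [model.dense_weight, model.dense_bias]
    )
    opt = _Adam(params, lr=lr)
    n = X.shape[0]
    onehot = np.eye(N_CLASSES)[y]
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, tb = X[idx], onehot[idx]
            logits, ctx = model._forward_train(xb)
            probs = _softmax(logits)
            dlogits = (probs - tb) / xb.shape[0]
            grads = model._backward(dlogits, ctx)
            if trainable == "all":
                glist = [*grads["conv_W"], *grads["conv_b"], grads["dense_W"], grads["dense_b"]]
            else:
                glist = [grads["dense_W"], grads["dense_b"]]
            opt.step(params, glist)


def train_cnn(
    segments,
    y,
    hyper: CnnHyper = CnnHyper(),
    seed: int = 0,
) -> CnnModel:
    """Train the CNN from a fresh initialization.

    Mini-batch Adam on cross-entropy with early stopping: a stratified
    ``val_frac`` split is held out, and training stops once the validation
    loss has not improved for ``patience`` epochs (the best-epoch weights
    are restored).
    """
    X, y, fs = _prepare_inputs(segments, y)
    if len(np.unique(y)) < 2:
        raise ValidationError("CNN training needs both classes present")
    rng = np.random.default_rng(seed)
    model = CnnModel.initialize(seed=seed, fs=fs)

    # stratified validation split
    n = X.shape[0]
    val_idx: list[int] = []
    for cls in np.unique(y):
        cls_idx = np.flatnonzero(y == cls)
        k = max(1, int(round(hyper.val_frac * cls_idx.size)))
        val_idx.extend(rng.permutation(cls_idx)[:k])
    val_mask = np.zeros(n, dtype=bool)
    val_mask[val_idx] = True
    Xtr, ytr = X[~val_mask], y[~val_mask]
    Xva, yva = X[val_mask], y[val_mask]

    best_loss, best_state, stale = np.inf, None, 0
    onehot_va = np.eye(N_CLASSES)[yva]
    for _ in range(hyper.max_epochs):
        _run_epochs(model, Xtr, ytr, hyper.learning_rate, 1, hyper.batch_size, rng)
        pva = model.predict_proba_full(Xva)
        loss = float(-(onehot_va * np.log(np.clip(pva, 1e-12, None))).sum() / yva.size)
        if loss < best_loss - 1e-6:
            best_loss, best_state, stale = loss, [p.copy() for p in model.parameters()], 0
        else:
            stale += 1
            if stale >= hyper.patience:
                break
    if best_state is not None:
        for p, b in zip(model.parameters(), best_state):
            p[...] = b
    return model


def transfer_cnn(
    src: CnnModel,
    segments_new,
    y_new,
    cfg: AdaptationConfig,
    batch_size: int = 32,
) -> CnnModel:
    """Two-stage transfer of a trained CNN to a new population.

    Stage 1 freezes every convolutional layer and retrains the dense
    classification layer on the new data; the convolutional weights of the
    result are bit-identical to the source's.  If ``cfg.finetune_epochs`` is
    positive, a fine-tuning stage then un-freezes all weights for a few
    epochs at the (lower) fine-tuning rate.
    """
    X, y, fs = _prepare_inputs(segments_new, y_new)
    if fs != src.fs:
        raise ValidationError(
            f"new data sampled at {fs} Hz but the source model expects {src.fs} Hz"
        )
    rng = np.random.default_rng(cfg.seed)
    model = src.copy()
    _run_epochs(model, X, y, cfg.stage1_lr, cfg.stage1_epochs, batch_size, rng,
                trainable="dense")
    if cfg.finetune_epochs > 0:
        _run_epochs(model, X, y, cfg.finetune_lr, cfg.finetune_epochs, batch_size, rng)
    return model
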