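"""The restraint-predicting network: a gated residual 1-D convolutional
regressor with masked multi-head MSE loss, cross-validated training and
ensembled prediction.

Architecture (per sample; frame length 50):

    h -> embedding(12) -> rows scaled by mask m
      -> concat with S (50 x 15) and C (50 x 50)            -> (50, 77)
      -> conv1d(128, 7) -> BN -> ReLU -> spatial dropout
      -> 2 x residual gated conv block
      -> flatten -> dense(1024) -> BN -> ReLU -> dropout
      -> heads: dense 2500 (ReLU) -> (50, 50) * M   CA-CA distances
                dense 2500 (ReLU) -> (50, 50) * M   CB-CB distances
                dense  200 (tanh) -> (50, 4)  * m   (cos, sin) of phi and psi

Each residual gated conv block applies three gated conv1d(128, 7) layers
(output = conv_a(x) * sigmoid(conv_b(x))): the first two are followed by
batch norm + ReLU, the third by spatial dropout; the block input is then
added back, batch normalized, ReLU-activated and spatially dropped out.

The loss sums the three heads' masked MSEs, each averaged over its masked
entries only.  Training uses Nadam at learning rate 0.001; the parameters of
the epoch with the lowest validation loss are retained (no early stopping).

The network is implemented directly on numpy arrays (float32) with
hand-written backpropagation; inference is deterministic (dropout disabled,
batch norm on running statistics).
"""

from __future__ import annotations

import json
import math
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .dataset import TrainingTargets, make_targets
from .featurize import (
    FRAME,
    EncodedSample,
    PredictionStats,
    augment,
    encode_peptide,
    n_predict_frames,
    unshift_average,
)
from .structures import PeptideRecord, StructureEnsemble

__all__ = [
    "NetworkHyperparams",
    "ModelBundle",
    "build_network",
    "masked_mse",
    "train_cv",
    "predict_ensemble",
    "save_bundle",
    "load_bundle",
]

VOCAB = 23  # codes 0..22 (21 used: empty, 20 natural, unknown=22)
F32 = np.float32


@dataclass
class NetworkHyperparams:
    embed_dim: int = 12
    conv_filters: int = 128
    conv_window: int = 7
    n_res_blocks: int = 2
    dense_units: int = 1024
    out_sizes: tuple[int, int, int] = (2500, 2500, 200)
    dropout_rate: float = 0.2
    learning_rate: float = 0.001
    epochs: int = 400
    optimizer: str = "nadam"
    batch_size: int = 32

    def __post_init__(self):
        if self.out_sizes[0] != FRAME * FRAME or self.out_sizes[2] != FRAME * 4:
            raise ValueError("out_sizes must reshape to (50,50), (50,50), (50,4)")


# ---------------------------------------------------------------------------
# Layers (forward caches what backward needs)
# ---------------------------------------------------------------------------

class _Layer:
    def params(self) -> dict:
        return {}

    def grads(self) -> dict:
        return {}


class _Embedding(_Layer):
    def __init__(self, rng, vocab, dim):
        self.W = (rng.normal(0, 0.05, size=(vocab, dim))).astype(F32)
        self.dW = np.zeros_like(self.W)

    def forward(self, h):
        self.h = h
        return self.W[h]

    def backward(self, grad):
        self.dW[:] = 0
        np.add.at(self.dW, self.h, grad)
        return None

    def params(self):
        return {"W": self.W}

    def grads(self):
        return {"W": self.dW}


class _Conv1D(_Layer):
    """Same-padded 1-D convolution on (B, L, C_in) tensors."""

    def __init__(self, rng, c_in, c_out, k):
        fan_in = c_in * k
        self.W = rng.normal(0, math.sqrt(2.0 / fan_in), size=(k * c_in, c_out)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k = k
        self.c_in = c_in

    def _windows(self, x):
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        B, Lp, C = xp.shape
        L = x.shape[1]
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)  # (B, L, C, k)
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, L, self.k * C)

    def forward(self, x):
        self.x_shape = x.shape
        self.win = self._windows(x)
        return self.win @ self.W + self.b

    def backward(self, grad):
        B, L, _ = grad.shape
        flat_win = self.win.reshape(-1, self.W.shape[0])
        flat_g = grad.reshape(-1, self.W.shape[1])
        self.dW[:] = flat_win.T @ flat_g
        self.db[:] = flat_g.sum(axis=0)
        dwin = (flat_g @ self.W.T).reshape(B, L, self.k, self.c_in)
        pad = self.k // 2
        dxp = np.zeros((B, L + 2 * pad, self.c_in), dtype=grad.dtype)
        for t in range(self.k):
            dxp[:, t : t + L] += dwin[:, :, t]
        return dxp[:, pad : pad + L]

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class _BatchNorm(_Layer):
    """Batch norm per channel; reduces over all leading axes."""

    def __init__(self, c, momentum=0.99, eps=1e-3):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(c, dtype=F32)
        self.run_var = np.ones(c, dtype=F32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (self.momentum * self.run_mean + (1 - self.momentum) * mean).astype(F32)
            self.run_var = (self.momentum * self.run_var + (1 - self.momentum) * var).astype(F32)
        else:
            mean, var = self.run_mean, self.run_var
        self.inv_std = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        self.xhat = (x - mean) * self.inv_std
        self.axes = axes
        self.m = x.size // x.shape[-1]
        self.training = training
        return self.gamma * self.xhat + self.beta

    def backward(self, grad):
        self.dgamma[:] = np.sum(grad * self.xhat, axis=self.axes)
        self.dbeta[:] = np.sum(grad, axis=self.axes)
        if not self.training:
            return grad * self.gamma * self.inv_std
        m = self.m
        gxh = grad * self.gamma
        return (
            self.inv_std
            / m
            * (m * gxh - np.sum(gxh, axis=self.axes) - self.xhat * np.sum(gxh * self.xhat, axis=self.axes))
        ).astype(F32)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {"run_mean": self.run_mean, "run_var": self.run_var}


class _ReLU(_Layer):
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad):
        return grad * self.mask


class _Tanh(_Layer):
    def forward(self, x):
        self.y = np.tanh(x)
        return self.y

    def backward(self, grad):
        return grad * (1.0 - self.y**2)


class _Dropout(_Layer):
    """Inverted dropout; ``spatial`` drops whole channels of (B, L, C)."""

    def __init__(self, rate, spatial=False):
        self.rate = rate
        self.spatial = spatial

    def forward(self, x, training, rng):
        if not training or self.rate <= 0:
            self.mask = None
            return x
        shape = (x.shape[0], 1, x.shape[2]) if self.spatial else x.shape
        self.mask = (rng.random(shape) >= self.rate).astype(F32) / (1.0 - self.rate)
        return x * self.mask

    def backward(self, grad):
        return grad if self.mask is None else grad * self.mask


class _Dense(_Layer):
    def __init__(self, rng, n_in, n_out):
        self.W = rng.normal(0, math.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self.x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[:] = self.x.T @ grad
        self.db[:] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class _GatedConv(_Layer):
    """Gated convolution: conv_a(x) * sigmoid(conv_b(x))."""

    def __init__(self, rng, c_in, c_out, k):
        self.conv_a = _Conv1D(rng, c_in, c_out, k)
        self.conv_b = _Conv1D(rng, c_in, c_out, k)

    def forward(self, x):
        self.a = self.conv_a.forward(x)
        self.sig = 1.0 / (1.0 + np.exp(-self.conv_b.forward(x)))
        return self.a * self.sig

    def backward(self, grad):
        da = grad * self.sig
        db = grad * self.a * self.sig * (1.0 - self.sig)
        return self.conv_a.backward(da) + self.conv_b.backward(db)

    def params(self):
        return {f"a_{k}": v for k, v in self.conv_a.params().items()} | {
            f"b_{k}": v for k, v in self.conv_b.params().items()
        }

    def grads(self):
        return {f"a_{k}": v for k, v in self.conv_a.grads().items()} | {
            f"b_{k}": v for k, v in self.conv_b.grads().items()
        }


class _ResidualGatedBlock(_Layer):
    def __init__(self, rng, c, k, rate):
        self.g1 = _GatedConv(rng, c, c, k)
        self.bn1 = _BatchNorm(c)
        self.r1 = _ReLU()
        self.g2 = _GatedConv(rng, c, c, k)
        self.bn2 = _BatchNorm(c)
        self.r2 = _ReLU()
        self.g3 = _GatedConv(rng, c, c, k)
        self.sd3 = _Dropout(rate, spatial=True)
        self.bn_out = _BatchNorm(c)
        self.r_out = _ReLU()
        self.sd_out = _Dropout(rate, spatial=True)

    def forward(self, x, training, rng):
        y = self.r1.forward(self.bn1.forward(self.g1.forward(x), training))
        y = self.r2.forward(self.bn2.forward(self.g2.forward(y), training))
        y = self.sd3.forward(self.g3.forward(y), training, rng)
        y = y + x  # residual add
        y = self.r_out.forward(self.bn_out.forward(y, training))
        return self.sd_out.forward(y, training, rng)

    def backward(self, grad):
        grad = self.sd_out.backward(grad)
        grad = self.bn_out.backward(self.r_out.backward(grad))
        skip = grad
        grad = self.g3.backward(self.sd3.backward(grad))
        grad = self.g2.backward(self.bn2.backward(self.r2.backward(grad)))
        grad = self.g1.backward(self.bn1.backward(self.r1.backward(grad)))
        return grad + skip

    def sublayers(self):
        return {
            "g1": self.g1,
            "bn1": self.bn1,
            "g2": self.g2,
            "bn2": self.bn2,
            "g3": self.g3,
            "bn_out": self.bn_out,
        }


class GatedResidualConvNet:
    """The full network; see the module docstring for the topology."""

    def __init__(self, hp: NetworkHyperparams, seed: int = 0):
        self.hp = hp
        rng = np.random.default_rng(seed)
        c, k = hp.conv_filters, hp.conv_window
        self.emb = _Embedding(rng, VOCAB, hp.embed_dim)
        in_width = hp.embed_dim + 15 + FRAME  # 77 with the default embedding
        self.stem = _Conv1D(rng, in_width, c, k)
        self.stem_bn = _BatchNorm(c)
        self.stem_relu = _ReLU()
        self.stem_sd = _Dropout(hp.dropout_rate, spatial=True)
        self.blocks = [_ResidualGatedBlock(rng, c, k, hp.dropout_rate) for _ in range(hp.n_res_blocks)]
        self.dense = _Dense(rng, FRAME * c, hp.dense_units)
        self.dense_bn = _BatchNorm(hp.dense_units)
        self.dense_relu = _ReLU()
        self.dense_do = _Dropout(hp.dropout_rate, spatial=False)
        self.head_ca = _Dense(rng, hp.dense_units, hp.out_sizes[0])
        self.head_cb = _Dense(rng, hp.dense_units, hp.out_sizes[1])
        self.head_trig = _Dense(rng, hp.dense_units, hp.out_sizes[2])
        self.relu_ca = _ReLU()
        self.relu_cb = _ReLU()
        self.tanh_trig = _Tanh()

    # -- bookkeeping ------------------------------------------------------

    def _layer_map(self) -> dict[str, _Layer]:
        layers = {"emb": self.emb, "stem": self.stem, "stem_bn": self.stem_bn,
                  "dense": self.dense, "dense_bn": self.dense_bn,
                  "head_ca": self.head_ca, "head_cb": self.head_cb,
                  "head_trig": self.head_trig}
        for bi, block in enumerate(self.blocks):
            for name, sub in block.sublayers().items():
                layers[f"block{bi}_{name}"] = sub
        return layers

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for lname, layer in self._layer_map().items():
            for pname, arr in layer.params().items():
                out[f"{lname}.{pname}"] = arr
            if isinstance(layer, _BatchNorm):
                for pname, arr in layer.state().items():
                    out[f"{lname}.{pname}"] = arr
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for lname, layer in self._layer_map().items():
            for pname, arr in layer.grads().items():
                out[f"{lname}.{pname}"] = arr
        return out

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def set_state(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        if set(params) != set(state):
            raise ValueError("state does not match network topology")
        for k, arr in params.items():
            arr[:] = state[k]

    # -- forward / backward ----------------------------------------------

    def forward(self, batch: dict, training: bool = False, rng=None):
        """``batch`` holds float32 arrays h (B,50) int, S, C, m, M."""
        h, S, C, m, M = batch["h"], batch["S"], batch["C"], batch["m"], batch["M"]
        self._m = m
        self._M = M
        x = self.emb.forward(h) * m[:, :, None]
        x = np.concatenate([x, S, C], axis=2, dtype=F32)
        self._in_width = x.shape[2]
        x = self.stem_sd.forward(
            self.stem_relu.forward(self.stem_bn.forward(self.stem.forward(x), training)),
            training, rng)
        for block in self.blocks:
            x = block.forward(x, training, rng)
        B = x.shape[0]
        flat = x.reshape(B, -1)
        z = self.dense_do.forward(
            self.dense_relu.forward(self.dense_bn.forward(self.dense.forward(flat), training)),
            training, rng)
        dca = self.relu_ca.forward(self.head_ca.forward(z)).reshape(B, FRAME, FRAME) * M
        dcb = self.relu_cb.forward(self.head_cb.forward(z)).reshape(B, FRAME, FRAME) * M
        trig = self.tanh_trig.forward(self.head_trig.forward(z)).reshape(B, FRAME, 4) * m[:, :, None]
        return {"dca": dca, "dcb": dcb, "trig": trig}

    def backward(self, grads: dict):
        B = grads["dca"].shape[0]
        g_ca = self.head_ca.backward(self.relu_ca.backward((grads["dca"] * self._M).reshape(B, -1)))
        g_cb = self.head_cb.backward(self.relu_cb.backward((grads["dcb"] * self._M).reshape(B, -1)))
        g_tr = self.head_trig.backward(
            self.tanh_trig.backward((grads["trig"] * self._m[:, :, None]).reshape(B, -1)))
        g = g_ca + g_cb + g_tr
        g = self.dense.backward(self.dense_bn.backward(self.dense_relu.backward(self.dense_do.backward(g))))
        g = g.reshape(B, FRAME, self.hp.conv_filters)
        for block in reversed(self.blocks):
            g = block.backward(g)
        g = self.stem.backward(self.stem_bn.backward(self.stem_relu.backward(self.stem_sd.backward(g))))
        g = g[:, :, : self.hp.embed_dim] * self._m[:, :, None]
        self.emb.backward(g)


# ---------------------------------------------------------------------------
# Loss and optimizer
# ---------------------------------------------------------------------------

def masked_mse(y_true: np.ndarray, y_pred: np.ndarray, mask: np.ndarray) -> float:
    """Mean squared error over masked entries only; 0 for an all-zero mask."""
    n = mask.sum()
    if n == 0:
        return 0.0
    return float(np.sum(((y_true - y_pred) ** 2) * mask) / n)


def _loss_and_grads(pred: dict, batch: dict):
    """Summed three-head masked MSE and the gradients wrt head outputs."""
    loss = 0.0
    grads = {}
    for head, target_key, mask_key in (
        ("dca", "y_dca", "mask_ca"),
        ("dcb", "y_dcb", "mask_cb"),
        ("trig", "y_trig", "mask_trig"),
    ):
        y, yhat, mask = batch[target_key], pred[head], batch[mask_key]
        n = mask.sum()
        if n == 0:
            grads[head] = np.zeros_like(yhat)
            continue
        diff = (yhat - y) * mask
        loss += float(np.sum(diff * diff) / n)
        grads[head] = (2.0 / n * diff).astype(F32)
    return loss, grads


class _Nadam:
    def __init__(self, grads: dict, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in grads.items()}
        self.v = {k: np.zeros_like(v) for k, v in grads.items()}
        self.t = 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for k, g in grads.items():
            m = self.m[k] = b1 * self.m[k] + (1 - b1) * g
            v = self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = m / (1 - b1 ** (self.t + 1))
            vhat = v / (1 - b2**self.t)
            update = (b1 * mhat + (1 - b1) / (1 - b1**self.t) * g) / (np.sqrt(vhat) + self.eps)
            params[k] -= (self.lr * update).astype(params[k].dtype)


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

CorpusItem = tuple[PeptideRecord, StructureEnsemble]


@dataclass
class ModelBundle:
    """Trained fold models plus the fold assignment and best validation losses."""

    networks: list[GatedResidualConvNet]
    fold_assignment: dict[str, int]  # record id -> validation fold
    best_val_losses: list[float]
    best_epochs: list[int]
    hyperparams: NetworkHyperparams
    seed: int
    A: np.ndarray  # property matrix the bundle was trained with

    @property
    def n_folds(self) -> int:
        return len(self.networks)


def build_network(hp: NetworkHyperparams, seed: int = 0) -> GatedResidualConvNet:
    return GatedResidualConvNet(hp, seed=seed)


def _sample_batch(items: list[tuple[EncodedSample, TrainingTargets]]):
    """Stack encoded samples + targets into float32 batch arrays."""
    return {
        "h": np.stack([s.h for s, _ in items]),
        "S": np.stack([s.S for s, _ in items]).astype(F32),
        "C": np.stack([s.C for s, _ in items]).astype(F32),
        "m": np.stack([s.m for s, _ in items]).astype(F32),
        "M": np.stack([s.M for s, _ in items]).astype(F32),
        "y_dca": np.stack([t.dca for _, t in items]).astype(F32),
        "y_dcb": np.stack([t.dcb for _, t in items]).astype(F32),
        "y_trig": np.stack([t.trig for _, t in items]).astype(F32),
        "mask_ca": np.stack([t.mask_ca for _, t in items]).astype(F32),
        "mask_cb": np.stack([t.mask_cb for _, t in items]).astype(F32),
        "mask_trig": np.stack([t.mask_trig for _, t in items]).astype(F32),
    }


def _take(data: dict, idx) -> dict:
    return {k: v[idx] for k, v in data.items()}


def _augmented_samples(corpus: Sequence[CorpusItem], A: np.ndarray, rng) -> list:
    """20 frame-shifted (input, target) pairs per peptide, matching offsets."""
    out = []
    from .featurize import TRAIN_SAMPLES_PER_PEPTIDE

    for record, ensemble in corpus:
        n = len(record)
        offsets = rng.integers(0, FRAME - n + 1, size=TRAIN_SAMPLES_PER_PEPTIDE)
        for off in offsets:
            out.append(
                (encode_peptide(record, A, int(off)), make_targets(ensemble, int(off)))
            )
    return out


def _epoch_loss(net: GatedResidualConvNet, data: dict, batch_size: int) -> float:
    """Mean per-batch loss in inference mode (running BN stats, no dropout)."""
    losses = []
    n = data["h"].shape[0]
    for lo in range(0, n, batch_size):
        batch = _take(data, slice(lo, lo + batch_size))
        pred = net.forward(batch, training=False)
        losses.append(_loss_and_grads(pred, batch)[0])
    return float(np.mean(losses))


def train_cv(
    corpus: Sequence[CorpusItem],
    A: np.ndarray,
    hp: Optional[NetworkHyperparams] = None,
    folds: int = 10,
    seed: int = 0,
    epochs: Optional[int] = None,
    verbose: bool = False,
) -> tuple[ModelBundle, list[list[float]]]:
    """K-fold cross-validated training.

    Per fold: train on the other folds' peptides, validate on the held-out
    fold, and retain the parameters of the epoch with the lowest validation
    loss.  Returns the bundle and the per-fold validation-loss history.
    ``epochs`` overrides ``hp.epochs`` (useful for smoke-scale runs).
    """
    hp = hp or NetworkHyperparams()
    n_epochs = epochs if epochs is not None else hp.epochs
    corpus = list(corpus)
    if len(corpus) < folds:
        raise ValueError(f"need at least {folds} records for {folds}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    fold_of = {corpus[idx][0].id: int(k % folds) for k, idx in enumerate(order)}

    networks, best_losses, best_epochs_out, histories = [], [], [], []
    for fold in range(folds):
        train_items = [c for c in corpus if fold_of[c[0].id] != fold]
        val_items = [c for c in corpus if fold_of[c[0].id] == fold]
        aug_rng = np.random.default_rng([seed, fold, 1])
        train_data = _sample_batch(_augmented_samples(train_items, A, aug_rng))
        val_data = _sample_batch(
            _augmented_samples(val_items, A, np.random.default_rng([seed, fold, 2]))
        )
        n_train = train_data["h"].shape[0]

        net = GatedResidualConvNet(hp, seed=seed + 1000 * fold)
        grads = net.gradients()
        opt = _Nadam(grads, lr=hp.learning_rate)
        drop_rng = np.random.default_rng([seed, fold, 3])
        shuffle_rng = np.random.default_rng([seed, fold, 4])

        best_loss, best_state, best_epoch, history = math.inf, None, -1, []
        params = {k: v for k, v in net.parameters().items() if k in grads}
        for epoch in range(n_epochs):
            perm = shuffle_rng.permutation(n_train)
            for lo in range(0, n_train, hp.batch_size):
                batch = _take(train_data, perm[lo : lo + hp.batch_size])
                pred = net.forward(batch, training=True, rng=drop_rng)
                _, head_grads = _loss_and_grads(pred, batch)
                net.backward(head_grads)
                opt.step(params, net.gradients())
            val_loss = _epoch_loss(net, val_data, hp.batch_size)
            history.append(val_loss)
            if val_loss < best_loss:
                best_loss, best_state, best_epoch = val_loss, net.get_state(), epoch
            if verbose:
                print(f"fold {fold} epoch {epoch}: val loss {val_loss:.4f}")
        net.set_state(best_state)
        networks.append(net)
        best_losses.append(best_loss)
        best_epochs_out.append(best_epoch)
        histories.append(history)

    bundle = ModelBundle(
        networks=networks,
        fold_assignment=fold_of,
        best_val_losses=best_losses,
        best_epochs=best_epochs_out,
        hyperparams=hp,
        seed=seed,
        A=np.asarray(A, dtype=float),
    )
    return bundle, histories


def predict_ensemble(record: PeptideRecord, bundle: ModelBundle) -> PredictionStats:
    """Ensemble prediction: all frames x all fold models, unshift-averaged.

    Returned matrices are cropped to the peptide (n x n / n x 4); undefined
    entries (glycine CB pairs, terminal phi/psi) are NaN.
    """
    n = len(record)
    if not 5 <= n <= 40:
        raise ValueError("sequence length must be in [5, 40]")
    samples = augment(record, bundle.A, mode="predict")
    batch = {
        "h": np.stack([s.h for s in samples]),
        "S": np.stack([s.S for s in samples]).astype(F32),
        "C": np.stack([s.C for s in samples]).astype(F32),
        "m": np.stack([s.m for s in samples]).astype(F32),
        "M": np.stack([s.M for s in samples]).astype(F32),
    }
    outputs = []
    for net in bundle.networks:
        pred = net.forward(batch, training=False)
        for k, s in enumerate(samples):
            outputs.append(
                (s.offset, {"dca": pred["dca"][k], "dcb": pred["dcb"][k], "trig": pred["trig"][k]})
            )
    stats = unshift_average(outputs, n)
    # mask undefined entries
    gly = np.array([aa == "G" for aa in record.sequence])
    for mat in (stats.dcb_mean, stats.dcb_sd):
        mat[gly, :] = np.nan
        mat[:, gly] = np.nan
    for mat in (stats.trig_mean, stats.trig_sd):
        mat[0, 0:2] = np.nan  # phi undefined at the first residue
        mat[n - 1, 2:4] = np.nan  # psi undefined at the last
    return stats


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_bundle(bundle: ModelBundle, directory) -> None:
    """One .npz archive per fold plus a manifest JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, net in enumerate(bundle.networks):
        np.savez_compressed(directory / f"fold{k:02d}.npz", **net.get_state())
    np.save(directory / "property_matrix.npy", bundle.A)
    manifest = {
        "hyperparams": asdict(bundle.hyperparams),
        "seed": bundle.seed,
        "n_folds": bundle.n_folds,
        "fold_assignment": bundle.fold_assignment,
        "best_epochs": bundle.best_epochs,
        "best_val_losses": bundle.best_val_losses,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_bundle(directory) -> ModelBundle:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    hp_dict = manifest["hyperparams"]
    hp_dict["out_sizes"] = tuple(hp_dict["out_sizes"])
    hp = NetworkHyperparams(**hp_dict)
    networks = []
    for k in range(manifest["n_folds"]):
        net = GatedResidualConvNet(hp, seed=0)
        with np.load(directory / f"fold{k:02d}.npz") as data:
            net.set_state({key: data[key] for key in data.files})
        networks.append(net)
    return ModelBundle(
        networks=networks,
        fold_assignment=manifest["fold_assignment"],
        best_val_losses=manifest["best_val_losses"],
        best_epochs=manifest["best_epochs"],
        hyperparams=hp,
        seed=manifest["seed"],
        A=np.load(directory / "property_matrix.npy"),
    )
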