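"""Self-contained 1-D convolutional network engine (NumPy).

Implements the small building blocks needed for the per-read and per-site
classifiers: same-padding 1-D convolutions, batch normalisation, ReLU,
residual blocks, global average pooling and a sigmoid head, together with
manual backpropagation and the AMSGrad optimizer.  The architecture
follows the compact Jasper-style pattern of stacked convolutional blocks
with batch-norm and residual connections, scaled to desk size.

Everything is deterministic given the construction seed and the data
order; parameters and optimizer state are plain NumPy arrays.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Tuple

import numpy as np

_EPS_BN = 1e-5


class _Layer:
    def params(self) -> Dict[str, np.ndarray]:
        return {}

    def grads(self) -> Dict[str, np.ndarray]:
        return {}


class Conv1d(_Layer):
    """Same-padding 1-D convolution, stride 1, odd kernel size."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32):
        assert kernel % 2 == 1
        scale = math.sqrt(2.0 / (c_in * kernel))
        self.w = (rng.standard_normal((c_out, c_in, kernel)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.k = kernel
        self._cache = None
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, length = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        patches = np.empty((n, c, self.k, length), dtype=x.dtype)
        for j in range(self.k):
            patches[:, :, j, :] = xp[:, :, j : j + length]
        y = np.einsum("nckl,ock->nol", patches, self.w, optimize=True)
        y += self.b[None, :, None]
        if train:
            self._cache = patches
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        patches = self._cache
        n, c, k, length = patches.shape
        self.gw = np.einsum("nol,nckl->ock", dy, patches, optimize=True)
        self.gb = dy.sum(axis=(0, 2))
        dpatches = np.einsum("nol,ock->nckl", dy, self.w, optimize=True)
        pad = self.k // 2
        dxp = np.zeros((n, c, length + 2 * pad), dtype=dy.dtype)
        for j in range(self.k):
            dxp[:, :, j : j + length] += dpatches[:, :, j, :]
        self._cache = None
        return dxp[:, :, pad : pad + length]

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.gw, "b": self.gb}


class BatchNorm1d(_Layer):
    def __init__(self, channels: int, momentum: float = 0.1, dtype=np.float32):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self._cache = None
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(x.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + _EPS_BN)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n, _, length = dy.shape
        m = n * length
        self.ggamma = (dy * xhat).sum(axis=(0, 2))
        self.gbeta = dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma[None, :, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        dx = (inv_std[None, :, None] / m) * (m * dxhat - s1 - xhat * s2)
        self._cache = None
        return dx

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.ggamma, "beta": self.gbeta}


class ReLU(_Layer):
    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        return dy * self._mask


class ResidualBlock(_Layer):
    """conv-BN-ReLU-conv-BN plus identity (or 1×1 projected) skip, then ReLU."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.conv1 = Conv1d(c_in, c_out, kernel, rng, dtype)
        self.bn1 = BatchNorm1d(c_out, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(c_out, c_out, kernel, rng, dtype)
        self.bn2 = BatchNorm1d(c_out, dtype=dtype)
        self.proj: Optional[Conv1d] = (
            Conv1d(c_in, c_out, 1, rng, dtype) if c_in != c_out else None
        )

    def forward(self, x, train):
        y = self.bn1.forward(self.conv1.forward(x, train), train)
        y = self.relu1.forward(y, train)
        y = self.bn2.forward(self.conv2.forward(y, train), train)
        skip = self.proj.forward(x, train) if self.proj is not None else x
        out = y + skip
        if train:
            self._mask = out > 0
        return np.maximum(out, 0)

    def backward(self, dy):
        dy = dy * self._mask
        dmain = self.conv1.backward(
            self.bn1.backward(
                self.relu1.backward(self.conv2.backward(self.bn2.backward(dy)))
            )
        )
        dskip = self.proj.backward(dy) if self.proj is not None else dy
        return dmain + dskip

    def _sub(self) -> List[Tuple[str, _Layer]]:
        subs = [("conv1", self.conv1), ("bn1", self.bn1),
                ("conv2", self.conv2), ("bn2", self.bn2)]
        if self.proj is not None:
            subs.append(("proj", self.proj))
        return subs

    def params(self):
        return {f"{n}.{k}": v for n, l in self._sub() for k, v in l.params().items()}

    def grads(self):
        return {f"{n}.{k}": v for n, l in self._sub() for k, v in l.grads().items()}


class Dense(_Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = math.sqrt(1.0 / d_in)
        self.w = (rng.standard_normal((d_out, d_in)) * scale).astype(dtype)
        self.b = np.zeros(d_out, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy):
        self.gw = dy.T @ self._x
        self.gb = dy.sum(axis=0)
        return dy @ self.w

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.gw, "b": self.gb}


class ConvNet:
    """Stem conv + residual blocks + global average pool + sigmoid head.

    Outputs a single logit per example; :meth:`predict_proba` applies the
    sigmoid.
    """

    def __init__(self, c_in: int, channels: Tuple[int, ...] = (16, 16),
                 kernel: int = 5, seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.dtype = dtype
        self.stem = Conv1d(c_in, channels[0], 7, rng, dtype)
        self.stem_bn = BatchNorm1d(channels[0], dtype=dtype)
        self.stem_relu = ReLU()
        self.blocks = []
        prev = channels[0]
        for c in channels:
            self.blocks.append(ResidualBlock(prev, c, kernel, rng, dtype))
            prev = c
        self.head = Dense(prev, 1, rng, dtype)
        self._length = None

    # -- forward / backward -------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.dtype)
        h = self.stem_relu.forward(
            self.stem_bn.forward(self.stem.forward(x, train), train), train
        )
        for blk in self.blocks:
            h = blk.forward(h, train)
        self._length = h.shape[2]
        pooled = h.mean(axis=2)
        return self.head.forward(pooled, train)[:, 0]

    def backward(self, dlogit: np.ndarray) -> None:
        dpooled = self.head.backward(dlogit[:, None].astype(self.dtype))
        dh = np.repeat(dpooled[:, :, None], self._length, axis=2) / self._length
        for blk in reversed(self.blocks):
            dh = blk.backward(dh)
        self.stem.backward(self.stem_bn.backward(self.stem_relu.backward(dh)))

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            z = self.forward_logits(x[i : i + batch_size], train=False)
            out.append(1.0 / (1.0 + np.exp(-z.astype(np.float64))))
        return np.concatenate(out) if out else np.empty(0)

    # -- parameter plumbing --------------------------------------------------
    def _layers(self) -> List[Tuple[str, _Layer]]:
        layers = [("stem", self.stem), ("stem_bn", self.stem_bn)]
        layers += [(f"block{i}", b) for i, b in enumerate(self.blocks)]
        layers.append(("head", self.head))
        return layers

    def params(self) -> Dict[str, np.ndarray]:
        return {f"{n}.{k}": v for n, l in self._layers()
                for k, v in l.params().items()}

    def grads(self) -> Dict[str, np.ndarray]:
        return {f"{n}.{k}": v for n, l in self._layers()
                for k, v in l.grads().items()}

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.params().items()}
        for name, layer in self._layers():
            if isinstance(layer, BatchNorm1d):
                state[f"{name}.running_mean"] = layer.running_mean.copy()
                state[f"{name}.running_var"] = layer.running_var.copy()
            if isinstance(layer, ResidualBlock):
                for sub, sl in layer._sub():
                    if isinstance(sl, BatchNorm1d):
                        state[f"{name}.{sub}.running_mean"] = sl.running_mean.copy()
                        state[f"{name}.{sub}.running_var"] = sl.running_var.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = self.params()
        for k, v in params.items():
            v[...] = state[k]
        for name, layer in self._layers():
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = state[f"{name}.running_mean"].copy()
                layer.running_var = state[f"{name}.running_var"].copy()
            if isinstance(layer, ResidualBlock):
                for sub, sl in layer._sub():
                    if isinstance(sl, BatchNorm1d):
                        sl.running_mean = state[f"{name}.{sub}.running_mean"].copy()
                        sl.running_var = state[f"{name}.{sub}.running_var"].copy()


class AMSGrad:
    """Adam variant keeping the running maximum of the second moment."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.vhat = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray],
             grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k, p in params.items():
            g = grads[k].astype(np.float64)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            np.maximum(self.vhat[k], self.v[k], out=self.vhat[k])
            update = (self.lr * (self.m[k] / bc1)
                      / (np.sqrt(self.vhat[k] / bc2) + self.eps))
            p -= update.astype(p.dtype)
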