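"""A small convolutional network in plain numpy.

The tile classifier needs more than predictions: the saliency stage requires
raw access to every convolutional activation, its gradient, and a guided
variant of backpropagation.  Implementing the network directly on numpy
keeps all of that first-class — every layer caches its forward pass and can
replay gradients in standard or guided mode (guided: ReLU passes a gradient
only where both the activation and the incoming gradient are positive).

Layout convention is NCHW float32.  Convolutions are im2col + matmul; the
default backbone downsamples the 256 px tile 4x on entry (average pooling)
so four 3x3 conv blocks with 2x max-pooling operate on a 64 px field.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SmallConvNet", "sigmoid", "bce_with_logits", "bce_grad"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> float:
    """Numerically stable mean binary cross-entropy."""
    z = np.asarray(z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    return float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))


def bce_grad(z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d(mean BCE)/dz = (sigmoid(z) - y) / n."""
    return (sigmoid(z) - np.asarray(y, dtype=z.dtype)) / z.shape[0]


class _AvgPoolDown:
    """Fixed k x k average-pool downsampling (the tile-entry reducer)."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        self._in_shape = x.shape
        return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(self, g: np.ndarray, guided: bool = False) -> np.ndarray:
        n, c, h, w = self._in_shape
        k = self.k
        return np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)


class _Conv2d:
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, stride: int = 1):
        # He initialization
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = (rng.standard_normal((cout, cin * k * k)) * std).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k = k
        self.stride = stride
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s = self.k, self.stride
        p = k // 2
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = v.shape[2], v.shape[3]
        cols = v.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
        self._cols = cols
        self._x_shape = x.shape
        self._out_hw = (ho, wo)
        out = np.einsum("oc,ncl->nol", self.w, cols, optimize=True) + self.b[None, :, None]
        return out.reshape(n, -1, ho, wo).astype(np.float32)

    def backward(self, g: np.ndarray, guided: bool = False, need_dx: bool = True) -> np.ndarray | None:
        n, cout, ho, wo = g.shape
        k, s = self.k, self.stride
        p = k // 2
        gf = g.reshape(n, cout, ho * wo)
        self.gw += np.einsum("nol,ncl->oc", gf, self._cols, optimize=True).astype(np.float32)
        self.gb += gf.sum(axis=(0, 2)).astype(np.float32)
        if not need_dx:
            return None
        dcols = np.einsum("oc,nol->ncl", self.w, gf, optimize=True)  # (n, cin*k*k, l)
        cin = self._x_shape[1]
        h, w = self._x_shape[2], self._x_shape[3]
        dcols = dcols.reshape(n, cin, k, k, ho, wo)
        dxp = np.zeros((n, cin, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
        return dxp[:, :, p : p + h, p : p + w]


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray, guided: bool = False) -> np.ndarray:
        out = g * self._mask
        if guided:
            out = out * (g > 0)
        return out


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray, guided: bool = False) -> np.ndarray:
        n, c, h, w = self._in_shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(out, self._idx[..., None], g[..., None], axis=-1)
        return out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class _GlobalAvgPool:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g: np.ndarray, guided: bool = False) -> np.ndarray:
        n, c, h, w = self._in_shape
        return np.broadcast_to(g[:, :, None, None], (n, c, h, w)).copy() / (h * w)


class _Linear:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / cin)
        self.w = (rng.standard_normal((cout, cin)) * std).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, g: np.ndarray, guided: bool = False) -> np.ndarray:
        self.gw += (g.T @ self._x).astype(np.float32)
        self.gb += g.sum(axis=0).astype(np.float32)
        return g @ self.w


class SmallConvNet:
    """Four 3x3 conv blocks (conv-ReLU-maxpool), global average pooling and a
    single-logit head, preceded by a fixed 4x average-pool tile reducer.

    ``forward`` caches everything needed for ``backward``; ``backward``
    returns the input gradient and records per-conv-block activation
    gradients, which Grad-CAM consumes via :meth:`conv_activations` /
    :meth:`conv_gradients`.
    """

    def __init__(
        self,
        channels: tuple[int, ...] = (8, 16, 32, 32),
        in_channels: int = 3,
        downsample: int = 4,
        pool: str = "stride",
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.downsample = downsample
        self.channels = tuple(channels)
        self.pool = pool
        self.layers: list = [_AvgPoolDown(downsample)] if downsample > 1 else []
        cin = in_channels
        self._conv_out_indices: list[int] = []
        for cout in channels:
            self.layers.append(_Conv2d(cin, cout, 3, rng, stride=2 if pool == "stride" else 1))
            self.layers.append(_ReLU())
            self._conv_out_indices.append(len(self.layers) - 1)  # post-ReLU activation
            if pool == "max":
                self.layers.append(_MaxPool2())
            cin = cout
        self.layers.append(_GlobalAvgPool())
        self.head = _Linear(cin, 1, rng)
        self._acts: list[np.ndarray] = []
        self._act_grads: dict[int, np.ndarray] = {}

    # ------------------------------------------------------------------
    def reduce_input(self, x: np.ndarray) -> np.ndarray:
        """Apply the fixed (parameter-free) entry downsample.  The trainer
        precomputes this once per dataset instead of once per epoch."""
        if not self.layers or not isinstance(self.layers[0], _AvgPoolDown):
            return x.astype(np.float32)
        return self.layers[0].forward(x.astype(np.float32))

    def forward(self, x: np.ndarray, pre_reduced: bool = False) -> np.ndarray:
        """x: (N, 3, H, W) float32 normalized. Returns logits (N,).

        With ``pre_reduced`` the input is assumed to have passed through
        :meth:`reduce_input` already and the entry downsample is skipped.
        """
        self._acts = []
        h = x.astype(np.float32)
        start = 0
        if pre_reduced and self.layers and isinstance(self.layers[0], _AvgPoolDown):
            start = 1
            self._acts.append(h)
        for layer in self.layers[start:]:
            h = layer.forward(h)
            self._acts.append(h)
        return self.head.forward(h)[:, 0]

    def backward(self, dlogits: np.ndarray, guided: bool = False, need_input_grad: bool = True) -> np.ndarray | None:
        """Backpropagate d(loss)/d(logit); returns d(loss)/d(input) (or None
        when ``need_input_grad`` is False — training only needs parameter
        gradients, and skipping the full-resolution input gradient is much
        cheaper).

        Per-conv-block activation gradients are stashed for Grad-CAM.
        """
        self._act_grads = {}
        first_conv = min(i for i, l in enumerate(self.layers) if isinstance(l, _Conv2d))
        g = self.head.backward(dlogits[:, None], guided=guided)
        for i in range(len(self.layers) - 1, -1, -1):
            if i in self._conv_out_indices:
                self._act_grads[i] = g.copy()
            layer = self.layers[i]
            if isinstance(layer, _Conv2d):
                need_dx = need_input_grad or i > first_conv
                g = layer.backward(g, guided=guided, need_dx=need_dx)
                if g is None:
                    return None
            elif isinstance(layer, _AvgPoolDown) and not need_input_grad:
                return None
            else:
                g = layer.backward(g, guided=guided)
        return g

    # ------------------------------------------------------------------
    @property
    def n_conv_blocks(self) -> int:
        return len(self._conv_out_indices)

    def conv_activations(self) -> list[np.ndarray]:
        """Post-ReLU activations of each conv block from the last forward."""
        return [self._acts[i] for i in self._conv_out_indices]

    def conv_gradients(self) -> list[np.ndarray]:
        """Matching activation gradients from the last backward."""
        return [self._act_grads[i] for i in self._conv_out_indices]

    # ------------------------------------------------------------------
    def parameters(self) -> list:
        mods = [l for l in self.layers if isinstance(l, _Conv2d)] + [self.head]
        out = []
        for m in mods:
            out.append((m, "w"))
            out.append((m, "b"))
        return out

    def zero_grad(self) -> None:
        for m, name in self.parameters():
            getattr(m, "g" + name).fill(0.0)

    def get_state(self) -> list[np.ndarray]:
        return [getattr(m, n).copy() for m, n in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for (m, n), v in zip(self.parameters(), state):
            setattr(m, n, v.copy())


class SGD:
    def __init__(self, net: SmallConvNet, lr: float):
        self.net = net
        self.lr = lr

    def step(self) -> None:
        for m, n in self.net.parameters():
            p = getattr(m, n)
            p -= (self.lr * getattr(m, "g" + n)).astype(p.dtype)


class Adam:
    def __init__(self, net: SmallConvNet, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(m, n)) for m, n in net.parameters()]
        self.v = [np.zeros_like(getattr(m, n)) for m, n in net.parameters()]

    def step(self) -> None:
        self.t += 1
        for i, (mod, n) in enumerate(self.net.parameters()):
            g = getattr(mod, "g" + n)
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p = getattr(mod, n)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
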