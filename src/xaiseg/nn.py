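"""Minimal differentiable convolutional network in NumPy.

This module provides the small, fully transparent backbone that the
attribution methods interrogate.  Everything runs in float64 with explicit
forward caching and hand-written backward passes, which gives three
properties the attribution layer depends on:

* exact (machine-precision) input gradients, so finite-difference oracles
  agree to ~1e-9 rather than the float32 ~1e-3 typical of GPU stacks;
* named access to every convolutional stage's activations and to the
  gradient of any class score with respect to those activations;
* a togglable "guided" rectifier backward rule (gradient passes only where
  the forward pre-activation was strictly positive AND the incoming
  gradient is strictly positive).

The head is a global-average-pool + linear classifier, so one network
accepts any input resolution whose spatial dims survive the pooling chain.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "AvgPool2d", "MaxPool2d", "GlobalAvgPool",
           "Linear", "TinyConvNet"]


class Layer:
    """Base layer: forward caches what backward needs; params/grads exposed."""

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad, guided=False):  # pragma: no cover - abstract
        raise NotImplementedError


def _im2col(xp, ksize, stride, out_h, out_w):
    n, c, _, _ = xp.shape
    cols = np.empty((n, c, ksize, ksize, out_h, out_w), dtype=xp.dtype)
    for i in range(ksize):
        for j in range(ksize):
            cols[:, :, i, j] = xp[:, :, i:i + stride * out_h:stride,
                                  j:j + stride * out_w:stride]
    return cols.reshape(n, c * ksize * ksize, out_h * out_w)


class Conv2d(Layer):
    """2D convolution (cross-correlation), square kernel, zero padding."""

    def __init__(self, in_channels, out_channels, ksize=3, stride=1, pad=1,
                 rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_channels * ksize * ksize
        # He initialisation suits the rectifier stages that follow.
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (out_channels, in_channels, ksize, ksize))
        self.b = np.zeros(out_channels)
        self.ksize, self.stride, self.pad = ksize, stride, pad
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        n, c, h, w = x.shape
        k, s, p = self.ksize, self.stride, self.pad
        out_h = (h + 2 * p - k) // s + 1
        out_w = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = _im2col(xp, k, s, out_h, out_w)
        self._cache = (x.shape, cols, out_h, out_w)
        wm = self.W.reshape(self.W.shape[0], -1)
        out = np.matmul(wm[None], cols) + self.b[None, :, None]
        return out.reshape(n, -1, out_h, out_w)

    def backward(self, grad, guided=False):
        x_shape, cols, out_h, out_w = self._cache
        n, c, h, w = x_shape
        k, s, p = self.ksize, self.stride, self.pad
        cout = self.W.shape[0]
        gm = grad.reshape(n, cout, out_h * out_w)
        wm = self.W.reshape(cout, -1)
        self.dW = np.einsum("nop,nfp->of", gm, cols).reshape(self.W.shape)
        self.db = gm.sum(axis=(0, 2))
        dcols = np.matmul(wm.T[None], gm)  # (n, c*k*k, P)
        dcols = dcols.reshape(n, c, k, k, out_h, out_w)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * out_h:s, j:j + s * out_w:s] += dcols[:, :, i, j]
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0  # strictly positive passes; exact zero blocks
        self.out = np.where(self._mask, x, 0.0)
        return self.out

    def backward(self, grad, guided=False):
        g = np.where(self._mask, grad, 0.0)
        if guided:
            g = np.where(g > 0, g, 0.0)
        return g


class AvgPool2d(Layer):
    """Non-overlapping average pooling; odd trailing rows/cols are dropped."""

    def __init__(self, size=2):
        self.size = size

    def forward(self, x):
        s = self.size
        n, c, h, w = x.shape
        ho, wo = h // s, w // s
        self._in_shape = x.shape
        xc = x[:, :, :ho * s, :wo * s]
        self.out = xc.reshape(n, c, ho, s, wo, s).mean(axis=(3, 5))
        return self.out

    def backward(self, grad, guided=False):
        s = self.size
        n, c, h, w = self._in_shape
        ho, wo = h // s, w // s
        dx = np.zeros((n, c, h, w))
        up = np.repeat(np.repeat(grad, s, axis=2), s, axis=3) / (s * s)
        dx[:, :, :ho * s, :wo * s] = up
        return dx


class MaxPool2d(Layer):
    """Non-overlapping max pooling; odd trailing rows/cols are dropped.

    Backward routes the gradient to the (first) argmax of each window —
    the routing that, combined with rectifier gating, gives guided
    backpropagation its characteristically sharp input maps.
    """

    def __init__(self, size=2):
        self.size = size

    def forward(self, x):
        s = self.size
        n, c, h, w = x.shape
        ho, wo = h // s, w // s
        self._in_shape = x.shape
        xc = x[:, :, :ho * s, :wo * s].reshape(n, c, ho, s, wo, s)
        xc = xc.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, s * s)
        self._argmax = xc.argmax(axis=-1)
        self.out = np.take_along_axis(xc, self._argmax[..., None],
                                      axis=-1)[..., 0]
        return self.out

    def backward(self, grad, guided=False):
        s = self.size
        n, c, h, w = self._in_shape
        ho, wo = h // s, w // s
        flat = np.zeros((n, c, ho, wo, s * s))
        np.put_along_axis(flat, self._argmax[..., None], grad[..., None],
                          axis=-1)
        flat = flat.reshape(n, c, ho, wo, s, s).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((n, c, h, w))
        dx[:, :, :ho * s, :wo * s] = flat.reshape(n, c, ho * s, wo * s)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad, guided=False):
        n, c, h, w = self._in_shape
        return np.broadcast_to(grad[:, :, None, None], (n, c, h, w)) / (h * w)


class Linear(Layer):
    def __init__(self, in_features, out_features, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(1.0 / in_features),
                            (out_features, in_features))
        self.b = np.zeros(out_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad, guided=False):
        self.dW = grad.T @ self._x
        self.db = grad.sum(axis=0)
        return grad @ self.W


class TinyConvNet:
    """Four-stage conv/ReLU backbone with a 2-way (by default) linear head.

    Stages are named ``conv1`` .. ``conv4``; a stage's "activation" is the
    output of its rectifier, which is what the layer-level attribution
    methods inspect.  Average pooling between the first three stages and a
    global average pool before the head make the network input-size
    agnostic (any H, W >= 8 works).
    """

    def __init__(self, in_channels=1, widths=(8, 16, 32, 32), n_classes=2,
                 seed=0):
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.widths = tuple(widths)
        self.n_classes = n_classes
        self.seed = seed
        self.layers = []
        self.stage_out_index = {}
        cin = in_channels
        for i, cout in enumerate(widths, start=1):
            self.layers.append(Conv2d(cin, cout, rng=rng))
            self.layers.append(ReLU())
            self.stage_out_index[f"conv{i}"] = len(self.layers) - 1
            if i < len(widths):
                self.layers.append(MaxPool2d(2))
            cin = cout
        self.layers.append(GlobalAvgPool())
        self.feature_dim = widths[-1]
        self.head = Linear(self.feature_dim, n_classes, rng=rng)
        self.layers.append(self.head)

    # -- plumbing -----------------------------------------------------------
    def stage_names(self):
        return list(self.stage_out_index)

    def parameters(self):
        ps = []
        for layer in self.layers:
            ps.extend(layer.params())
        return ps

    def gradients(self):
        gs = []
        for layer in self.layers:
            gs.extend(layer.grads())
        return gs

    # -- forward / backward -------------------------------------------------
    def forward(self, x):
        """x: (N, C, H, W) float -> (N, n_classes) scores."""
        x = np.asarray(x, dtype=np.float64)
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dscores, guided=False):
        """Backprop from the scores; returns gradient w.r.t. the input.

        Must follow a ``forward`` call on the same input (caches are reused).
        """
        g = dscores
        for layer in reversed(self.layers):
            g = layer.backward(g, guided=guided)
        return g

    def backward_to_stage(self, stage, dscores):
        """Gradient of ``dscores . scores`` w.r.t. a named stage's output."""
        idx = self.stage_out_index[stage]
        g = dscores
        for layer in reversed(self.layers[idx + 1:]):
            g = layer.backward(g)
        return g

    def backward_from_stage(self, stage, dact, guided=False):
        """Backprop a gradient seeded at a stage's output down to the input."""
        idx = self.stage_out_index[stage]
        g = dact
        for layer in reversed(self.layers[:idx + 1]):
            g = layer.backward(g, guided=guided)
        return g

    def stage_activation(self, stage):
        """Activation maps of a named stage from the last forward pass."""
        return self.layers[self.stage_out_index[stage]].out

    # -- (de)serialisation ---------------------------------------------------
    def arch_config(self):
        return {"in_channels": self.in_channels, "widths": list(self.widths),
                "n_classes": self.n_classes, "seed": self.seed}

    def state_arrays(self):
        return self.parameters()

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p[...] = a
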