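"""Minimal NumPy layers with explicit forward/backward passes.

Data layout is channels-first: (C, D, H, W), batch size 1 throughout (one
PET patch per step). Each layer caches what its backward pass needs during
forward(); backward(dout) returns the gradient w.r.t. the layer input and
accumulates parameter gradients in ``grads``.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def zero_grad(self):
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution ('same' padding), stride 1 or 2.

    The output is accumulated as a sum over kernel offsets: for each of the
    k^3 taps, a (cout, cin) weight slice multiplies a shifted view of the
    padded input. This keeps memory traffic cache-friendly and avoids im2col
    buffers.
    """

    def __init__(self, cin, cout, kernel=3, stride=1, rng=None):
        super().__init__()
        self.cin, self.cout, self.k, self.stride = cin, cout, kernel, stride
        self.pad = kernel // 2
        fan_in = cin * kernel**3
        scale = np.sqrt(2.0 / fan_in)
        rng = rng or np.random.default_rng(0)
        self.params["W"] = rng.normal(0.0, scale, size=(cout, cin, kernel, kernel, kernel))
        self.params["b"] = np.zeros(cout)
        self.zero_grad()

    def _out_shape(self, xshape):
        return tuple((n + 2 * self.pad - self.k) // self.stride + 1 for n in xshape[1:])

    def forward(self, x):
        k, s, p = self.k, self.stride, self.pad
        W = self.params["W"]
        if k == 1 and s == 1:
            self._cache = x
            out = np.tensordot(W[:, :, 0, 0, 0], x, axes=(1, 0))
            return out + self.params["b"][:, None, None, None]
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p))) if p else x
        do, ho, wo = self._out_shape(x.shape)
        out = np.zeros((self.cout, do * ho * wo))
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    sl = np.ascontiguousarray(
                        xp[:, a : a + s * do : s, b : b + s * ho : s, c : c + s * wo : s]
                    ).reshape(self.cin, -1)
                    out += W[:, :, a, b, c] @ sl
        out += self.params["b"][:, None]
        self._cache = (xp, x.shape, (do, ho, wo))
        return out.reshape(self.cout, do, ho, wo)

    def backward(self, dout):
        k, s, p = self.k, self.stride, self.pad
        W = self.params["W"]
        if k == 1 and s == 1:
            x = self._cache
            dmat = dout.reshape(self.cout, -1)
            xmat = x.reshape(self.cin, -1)
            self.grads["W"][:, :, 0, 0, 0] += dmat @ xmat.T
            self.grads["b"] += dmat.sum(axis=1)
            return np.tensordot(W[:, :, 0, 0, 0].T, dout, axes=(1, 0))
        xp, xshape, (do, ho, wo) = self._cache
        dmat = dout.reshape(self.cout, -1)
        self.grads["b"] += dmat.sum(axis=1)
        c_, d, h, w = xshape
        dxp = np.zeros_like(xp)
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    view = xp[:, a : a + s * do : s, b : b + s * ho : s, c : c + s * wo : s]
                    sl = np.ascontiguousarray(view).reshape(self.cin, -1)
                    self.grads["W"][:, :, a, b, c] += dmat @ sl.T
                    dxp[
                        :, a : a + s * do : s, b : b + s * ho : s, c : c + s * wo : s
                    ] += (W[:, :, a, b, c].T @ dmat).reshape(self.cin, do, ho, wo)
        return dxp[:, p : p + d, p : p + h, p : p + w] if p else dxp


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class SENorm(Layer):
    """Squeeze-and-excitation normalization.

    Instance-normalizes each channel, then modulates with a per-channel
    scale gamma = sigmoid(FC(z)) and shift beta = tanh(FC(z)), where z is the
    global average pool of the layer input and each FC stack is
    C -> C/r -> C with a ReLU in between (reduction ratio r = 2).
    """

    EPS = 1e-5

    def __init__(self, channels, reduction=2, rng=None):
        super().__init__()
        self.c = channels
        cr = max(channels // reduction, 1)
        self.cr = cr
        rng = rng or np.random.default_rng(0)

        def fc(ci, co):
            return rng.normal(0.0, np.sqrt(2.0 / ci), size=(co, ci))

        self.params["Wg1"], self.params["bg1"] = fc(channels, cr), np.zeros(cr)
        self.params["Wg2"], self.params["bg2"] = fc(cr, channels), np.zeros(channels)
        self.params["Wb1"], self.params["bb1"] = fc(channels, cr), np.zeros(cr)
        self.params["Wb2"], self.params["bb2"] = fc(cr, channels), np.zeros(channels)
        self.zero_grad()

    def forward(self, x):
        c = self.c
        sp = x.reshape(c, -1)
        n = sp.shape[1]
        mean = sp.mean(axis=1)
        var = sp.var(axis=1)
        std = np.sqrt(var + self.EPS)
        xn = (sp - mean[:, None]) / std[:, None]
        z = sp.mean(axis=1)  # global average pool of the input

        hg = self.params["Wg1"] @ z + self.params["bg1"]
        hg_r = np.maximum(hg, 0.0)
        gamma = _sigmoid(self.params["Wg2"] @ hg_r + self.params["bg2"])
        hb = self.params["Wb1"] @ z + self.params["bb1"]
        hb_r = np.maximum(hb, 0.0)
        beta = np.tanh(self.params["Wb2"] @ hb_r + self.params["bb2"])

        out = gamma[:, None] * xn + beta[:, None]
        self._cache = (xn, std, z, hg, hg_r, gamma, hb, hb_r, beta, n, x.shape)
        return out.reshape(x.shape)

    def backward(self, dout):
        xn, std, z, hg, hg_r, gamma, hb, hb_r, beta, n, xshape = self._cache
        dy = dout.reshape(self.c, -1)

        dgamma = (dy * xn).sum(axis=1)
        dbeta = dy.sum(axis=1)

        # instance-norm backward
        dxn = dy * gamma[:, None]
        dx = (dxn - dxn.mean(axis=1, keepdims=True) - xn * (dxn * xn).mean(axis=1, keepdims=True)) / std[:, None]

        # gamma branch
        dag = dgamma * gamma * (1.0 - gamma)
        self.grads["Wg2"] += np.outer(dag, hg_r)
        self.grads["bg2"] += dag
        dhg = (self.params["Wg2"].T @ dag) * (hg > 0)
        self.grads["Wg1"] += np.outer(dhg, z)
        self.grads["bg1"] += dhg
        dz = self.params["Wg1"].T @ dhg

        # beta branch
        dab = dbeta * (1.0 - beta * beta)
        self.grads["Wb2"] += np.outer(dab, hb_r)
        self.grads["bb2"] += dab
        dhb = (self.params["Wb2"].T @ dab) * (hb > 0)
        self.grads["Wb1"] += np.outer(dhb, z)
        self.grads["bb1"] += dhb
        dz += self.params["Wb1"].T @ dhb

        dx += dz[:, None] / n
        return dx.reshape(xshape)


def _upsample_axis(x, axis):
    x = np.moveaxis(x, axis, -1)
    prev = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)
    nxt = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)
    even = 0.75 * x + 0.25 * prev
    odd = 0.75 * x + 0.25 * nxt
    out = np.stack([even, odd], axis=-1).reshape(*x.shape[:-1], 2 * x.shape[-1])
    return np.moveaxis(out, -1, axis)


def _upsample_axis_adjoint(dout, axis):
    d = np.moveaxis(dout, axis, -1)
    n2 = d.shape[-1]
    d = d.reshape(*d.shape[:-1], n2 // 2, 2)
    de, do = d[..., 0], d[..., 1]
    dx = 0.75 * (de + do)
    # even outputs pull from x[k-1] (clamped at 0)
    dx[..., :-1] += 0.25 * de[..., 1:]
    dx[..., 0] += 0.25 * de[..., 0]
    # odd outputs pull from x[k+1] (clamped at n-1)
    dx[..., 1:] += 0.25 * do[..., :-1]
    dx[..., -1] += 0.25 * do[..., -1]
    return np.moveaxis(dx, -1, axis)


class Upsample2x(Layer):
    """Trilinear x2 upsampling (half-voxel aligned), with exact adjoint."""

    def forward(self, x):
        out = x
        for ax in (1, 2, 3):
            out = _upsample_axis(out, ax)
        return out

    def backward(self, dout):
        dx = dout
        for ax in (3, 2, 1):
            dx = _upsample_axis_adjoint(dx, ax)
        return dx


class Sigmoid(Layer):
    def forward(self, x):
        self._out = _sigmoid(x)
        return self._out

    def backward(self, dout):
        return dout * self._out * (1.0 - self._out)


class Softplus(Layer):
    """Smooth positive transform log(1 + e^x), numerically stable."""

    def forward(self, x):
        self._x = x
        return np.logaddexp(0.0, x)

    def backward(self, dout):
        return dout * _sigmoid(self._x)


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def iter_layers(self):
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.iter_layers()
            else:
                yield layer

    def parameter_count(self) -> int:
        return sum(l.parameter_count() for l in self.iter_layers())
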