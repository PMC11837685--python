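"""Minimal CPU convolutional-network engine.

Implements exactly the pieces the sway classifier needs — 2-D convolution,
max pooling, dense layers, softmax cross-entropy and Adam — as vectorised
numpy in float32, NHWC layout.  Convolutions run as im2col gathers followed
by one BLAS matmul per layer; because training is full-batch on a fixed
tensor, the first layer's im2col matrix is computed once per training run
and reused every epoch.  All randomness flows through a caller-supplied
``numpy.random.Generator``, so parameter initialisation and the whole
training trajectory are bit-reproducible on one machine.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ConvStage", "DenseStage", "CNNCore", "softmax", "cross_entropy"]


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


class ConvStage:
    """One convolution (+ bias, ReLU) followed by max pooling.

    Padding is fixed at ``kernel // 2`` on each border ("same" for stride 1).
    Pooling crops trailing rows/columns so the extent divides the pool size;
    for 3x3-kernel, stride-1 stages on 250-px inputs this loses at most the
    lowest-frequency rows / final time columns of the receptive field.
    """

    def __init__(self, in_ch, out_ch, kernel, stride, pool, in_hw):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.pool = _pair(pool)  # (rows, cols); may pool one axis only
        self.in_hw = _pair(in_hw)
        h, w = self.in_hw
        p = kernel // 2
        self.pad = p
        self.conv_hw = (
            (h + 2 * p - kernel) // stride + 1,
            (w + 2 * p - kernel) // stride + 1,
        )
        self.out_hw = (self.conv_hw[0] // self.pool[0],
                       self.conv_hw[1] // self.pool[1])
        if min(self.out_hw) < 1:
            raise ValueError(
                f"stage reduces {self.in_hw} to empty output "
                f"(conv {self.conv_hw}, pool {pool})"
            )

    def init_params(self, rng):
        k, c = self.kernel, self.in_ch
        fan_in = k * k * c
        bound = 1.0 / np.sqrt(fan_in)
        w = rng.uniform(-bound, bound, size=(fan_in, self.out_ch))
        b = rng.uniform(-bound, bound, size=self.out_ch)
        return w.astype(np.float32), b.astype(np.float32)

    def im2col(self, x):
        """(N, H, W, C) -> (N * Ho * Wo, k*k*C), one strided copy per
        kernel offset (faster than a fancy-index gather for small kernels)."""
        n = x.shape[0]
        p, k, s, c = self.pad, self.kernel, self.stride, self.in_ch
        ho, wo = self.conv_hw
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = np.empty((n, ho, wo, k, k, c), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                cols[:, :, :, di, dj, :] = xp[
                    :, di : di + ho * s : s, dj : dj + wo * s : s, :
                ]
        return cols.reshape(n * ho * wo, k * k * c)

    def _pool_backward(self, act, out, dout):
        """Route pooled gradients to window maxima (ties share the gradient;
        tied zeros are subsequently killed by the ReLU mask)."""
        ph, pw = self.pool
        hc, wc = self.out_hw[0] * ph, self.out_hw[1] * pw
        dact = np.zeros_like(act)
        for i in range(ph):
            for j in range(pw):
                sl = act[:, i:hc:ph, j:wc:pw, :]
                dact[:, i:hc:ph, j:wc:pw, :] = (sl == out) * dout
        return dact

    @staticmethod
    def _pool_max(act, pool, hc, wc):
        """Strided-slice max pooling, cropping to (hc, wc)."""
        ph, pw = pool
        out = act[:, 0:hc:ph, 0:wc:pw, :].copy()
        for i in range(ph):
            for j in range(pw):
                if i or j:
                    np.maximum(out, act[:, i:hc:ph, j:wc:pw, :], out=out)
        return out

    def forward(self, w, b, x=None, cols=None):
        """Returns (pooled output, cache).  Either ``x`` or a precomputed
        im2col matrix ``cols`` must be given."""
        if cols is None:
            cols = self.im2col(x)
        ho, wo = self.conv_hw
        n = cols.shape[0] // (ho * wo)
        act = cols @ w
        act += b
        np.maximum(act, 0.0, out=act)
        act = act.reshape(n, ho, wo, self.out_ch)
        hc = self.out_hw[0] * self.pool[0]
        wc = self.out_hw[1] * self.pool[1]
        out = self._pool_max(act, self.pool, hc, wc)
        return out, (cols, act, out)

    def backward(self, w, cache, dout, need_dx):
        cols, act, out = cache
        n = act.shape[0]
        ho, wo = self.conv_hw
        dact = self._pool_backward(act, out, dout)
        dact *= act > 0  # ReLU
        dmat = dact.reshape(n * ho * wo, self.out_ch)
        dw = cols.T @ dmat
        db = dmat.sum(axis=0)
        dx = self._dx_from(w, dmat, n) if need_dx else None
        return dw, db, dx

    def _dx_from(self, w, dmat, n):
        """Input gradient by the shift decomposition (one thin matmul and one
        strided slice-add per kernel offset — avoids a scatter)."""
        k, s, c = self.kernel, self.stride, self.in_ch
        h, w_in = self.in_hw
        hp, wp = h + 2 * self.pad, w_in + 2 * self.pad
        ho, wo = self.conv_hw
        wk = w.reshape(k, k, c, self.out_ch)
        dxp = np.zeros((n, hp, wp, c), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                t = (dmat @ wk[di, dj].T).reshape(n, ho, wo, c)
                dxp[:, di : di + ho * s : s, dj : dj + wo * s : s, :] += t
        pd = self.pad
        return dxp[:, pd : pd + h, pd : pd + w_in, :]


class DenseStage:
    def __init__(self, in_dim, out_dim, relu=True):
        self.in_dim, self.out_dim, self.relu = in_dim, out_dim, relu

    def init_params(self, rng):
        bound = 1.0 / np.sqrt(self.in_dim)
        w = rng.uniform(-bound, bound, size=(self.in_dim, self.out_dim))
        b = rng.uniform(-bound, bound, size=self.out_dim)
        return w.astype(np.float32), b.astype(np.float32)

    def forward(self, w, b, x):
        out = x @ w
        out += b
        if self.relu:
            np.maximum(out, 0.0, out=out)
        return out, (x, out)

    def backward(self, w, cache, dout):
        x, out = cache
        if self.relu:
            dout = dout * (out > 0)
        return x.T @ dout, dout.sum(axis=0), dout @ w.T


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits, y):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = len(y)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-30, None)).mean()
    g = p
    g[np.arange(n), y] -= 1.0
    return loss, (g / n).astype(np.float32)


class CNNCore:
    """Three conv/pool stages and three dense layers on single-channel images.

    Parameters are a flat dict ``{"conv0_w": ..., "dense2_b": ...}``; the
    class owns shapes and the forward/backward math, nothing else.
    """

    def __init__(self, input_hw, conv_channels, kernel_size, conv_strides,
                 pool_sizes, dense_widths, seed=0):
        if len(conv_channels) != 3 or len(dense_widths) != 3:
            raise ValueError("expected 3 conv stages and 3 dense stages")
        if dense_widths[-1] != 2:
            raise ValueError("final dense width must be 2 (binary head)")
        self.input_hw = _pair(input_hw)
        kernels = (kernel_size,) * 3 if np.isscalar(kernel_size) else tuple(kernel_size)
        self.stages = []
        in_ch, in_hw = 1, self.input_hw
        for ch, kn, st, pl in zip(conv_channels, kernels, conv_strides, pool_sizes):
            stage = ConvStage(in_ch, ch, kn, st, pl, in_hw)
            self.stages.append(stage)
            in_ch, in_hw = ch, stage.out_hw
        self.flat_dim = in_hw[0] * in_hw[1] * in_ch
        self.dense = []
        d_in = self.flat_dim
        for i, width in enumerate(dense_widths):
            self.dense.append(DenseStage(d_in, width, relu=i < 2))
            d_in = width
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.params = {}
        for i, stage in enumerate(self.stages):
            w, b = stage.init_params(rng)
            self.params[f"conv{i}_w"], self.params[f"conv{i}_b"] = w, b
        for i, layer in enumerate(self.dense):
            w, b = layer.init_params(rng)
            self.params[f"dense{i}_w"], self.params[f"dense{i}_b"] = w, b

    # -- plumbing ---------------------------------------------------------
    def n_params(self):
        return sum(int(p.size) for p in self.params.values())

    def conv0_cols(self, x):
        """Precompute the first stage's im2col matrix for a fixed batch."""
        return self.stages[0].im2col(self._as_images(x))

    def _as_images(self, x):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        return x

    # -- forward / backward ----------------------------------------------
    def forward(self, x=None, cols0=None, want_caches=False):
        caches = []
        out = None
        for i, stage in enumerate(self.stages):
            w, b = self.params[f"conv{i}_w"], self.params[f"conv{i}_b"]
            if i == 0:
                out, cache = stage.forward(
                    w, b,
                    x=None if cols0 is not None else self._as_images(x),
                    cols=cols0,
                )
            else:
                out, cache = stage.forward(w, b, x=out)
            caches.append(cache)
        n = out.shape[0]
        out = out.reshape(n, self.flat_dim)
        for i, layer in enumerate(self.dense):
            w, b = self.params[f"dense{i}_w"], self.params[f"dense{i}_b"]
            out, cache = layer.forward(w, b, out)
            caches.append(cache)
        return (out, caches) if want_caches else out

    def backward(self, caches, dlogits):
        grads = {}
        d = dlogits
        for i in range(2, -1, -1):
            layer = self.dense[i]
            dw, db, d = layer.backward(
                self.params[f"dense{i}_w"], caches[3 + i], d
            )
            grads[f"dense{i}_w"], grads[f"dense{i}_b"] = dw, db
        last = self.stages[-1]
        d = d.reshape(-1, *last.out_hw, last.out_ch)
        for i in range(2, -1, -1):
            stage = self.stages[i]
            dw, db, d = stage.backward(
                self.params[f"conv{i}_w"], caches[i], d, need_dx=i > 0
            )
            grads[f"conv{i}_w"], grads[f"conv{i}_b"] = dw, db
        return grads

    def predict_logits(self, x, chunk=512):
        """Chunked inference forward pass (memory guard, same arithmetic)."""
        x = self._as_images(x)
        outs = [self.forward(x=x[i : i + chunk]) for i in range(0, len(x), chunk)]
        return np.concatenate(outs, axis=0)

    # -- GradCAM support --------------------------------------------------
    def last_conv_activations_and_grads(self, x, target_class):
        """Post-ReLU activations of the last conv layer and the gradient of
        the target-class logit w.r.t. those activations, per sample."""
        logits, caches = self.forward(x=self._as_images(x), want_caches=True)
        n = logits.shape[0]
        d = np.zeros_like(logits)
        d[:, target_class] = 1.0
        for i in range(2, -1, -1):
            _, _, d = self.dense[i].backward(
                self.params[f"dense{i}_w"], caches[3 + i], d
            )
        last = self.stages[-1]
        d = d.reshape(n, *last.out_hw, last.out_ch)
        cols, act, out = caches[2]
        dact = last._pool_backward(act, out, d)
        return act, dact, logits


class Adam:
    """Adam with (coupled) L2 weight decay added to the raw gradient, the
    classical formulation used by the mainstream framework default."""

    def __init__(self, params, lr, weight_decay=0.0,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in params.items():
            g = grads[k].astype(np.float32)
            if self.wd:
                g = g + self.wd * p
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
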