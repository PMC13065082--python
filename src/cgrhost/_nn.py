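"""Minimal NumPy CNN: conv / max-pool / linear layers, softmax
cross-entropy, and Adam.

Kept deliberately small: same-padding stride-1 convolutions (via im2col and
one GEMM), 2x2 stride-2 max pooling, and dense layers — exactly the pieces
the host classifier needs.  All parameters and activations are float32; the
forward pass is deterministic given the weights.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "MaxPool2", "Linear", "ConvNet", "Adam", "softmax"]


def _im2col(x: np.ndarray, ksize: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*ksize*ksize) patch matrix, stride 1."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(
        xp, (ksize, ksize), axis=(2, 3)
    )  # (N, C, H, W, ksize, ksize)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * ksize * ksize)
    return np.ascontiguousarray(cols)


class Conv2d:
    """Same-padding, stride-1 2D convolution with He-initialized weights."""

    def __init__(
        self, in_ch: int, out_ch: int, ksize: int, rng: np.random.Generator
    ) -> None:
        self.in_ch, self.out_ch, self.ksize = in_ch, out_ch, ksize
        self.pad = ksize // 2
        fan_in = in_ch * ksize * ksize
        scale = np.sqrt(2.0 / fan_in)
        self.W = (rng.standard_normal((out_ch, fan_in)) * scale).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, _, h, w = x.shape
        cols = _im2col(x, self.ksize, self.pad)
        out = cols @ self.W.T + self.b
        if train:
            self._cols, self._shape = cols, x.shape
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        assert self._cols is not None and self._shape is not None
        n, _, h, w = self._shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)
        dW = dflat.T @ self._cols
        db = dflat.sum(axis=0)
        # dx: full correlation of dout with the flipped, channel-transposed
        # kernel — same-padding stride-1 makes it another conv of this shape.
        Wk = self.W.reshape(self.out_ch, self.in_ch, self.ksize, self.ksize)
        Wrot = Wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.in_ch, -1)
        cols_d = _im2col(dout, self.ksize, self.pad)
        dx = (cols_d @ Wrot.T).reshape(n, h, w, self.in_ch).transpose(0, 3, 1, 2)
        self._cols = None
        return np.ascontiguousarray(dx), [dW, db]


class MaxPool2:
    """2x2 max pooling with stride 2."""

    def __init__(self) -> None:
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    params: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        if train:
            self._idx = xr.argmax(axis=-1)
            self._shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        assert self._idx is not None and self._shape is not None
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dx = (
            dxr.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        self._idx = None
        return dx, []


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_out, n_in)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self._x: np.ndarray | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        assert self._x is not None
        dW = dout.T @ self._x
        db = dout.sum(axis=0)
        dx = dout @ self.W
        self._x = None
        return dx, [dW, db]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class ConvNet:
    """conv(5x5, same) + ReLU + pool, repeated, then flatten, FC + ReLU,
    and a softmax output layer."""

    def __init__(
        self,
        in_side: int,
        in_ch: int,
        conv_channels: tuple[int, ...],
        ksize: int,
        fc_units: int,
        n_classes: int,
        rng: np.random.Generator,
    ) -> None:
        if in_side % (2 ** len(conv_channels)) != 0:
            raise ValueError(
                f"input side {in_side} not divisible by 2^{len(conv_channels)} "
                "(one halving per conv block)"
            )
        self.in_side, self.in_ch = in_side, in_ch
        self.convs: list[Conv2d] = []
        self.pools: list[MaxPool2] = []
        ch = in_ch
        side = in_side
        for out_ch in conv_channels:
            self.convs.append(Conv2d(ch, out_ch, ksize, rng))
            self.pools.append(MaxPool2())
            ch = out_ch
            side //= 2
        self.flat_dim = ch * side * side
        self.fc = Linear(self.flat_dim, fc_units, rng)
        self.out = Linear(fc_units, n_classes, rng)
        self._relu_masks: list[np.ndarray] = []

    @property
    def params(self) -> list[np.ndarray]:
        ps: list[np.ndarray] = []
        for conv in self.convs:
            ps.extend(conv.params)
        ps.extend(self.fc.params)
        ps.extend(self.out.params)
        return ps

    def set_params(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self.params, values, strict=True):
            p[...] = v

    def layer_shapes(self, batch: int = 1) -> list[tuple[str, tuple[int, ...]]]:
        """(name, output shape) chain of the conv/pool stack, sans batch."""
        shapes: list[tuple[str, tuple[int, ...]]] = []
        ch, side = self.in_ch, self.in_side
        for i, conv in enumerate(self.convs, start=1):
            ch = conv.out_ch
            shapes.append((f"conv{i}", (ch, side, side)))
            side //= 2
            shapes.append((f"pool{i}", (ch, side, side)))
        shapes.append(("flatten", (self.flat_dim,)))
        shapes.append(("fc", (self.fc.W.shape[0],)))
        shapes.append(("output", (self.out.W.shape[0],)))
        return shapes

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a (N, C, side, side) float32 batch."""
        if train:
            self._relu_masks = []
        h = x
        for conv, pool in zip(self.convs, self.pools):
            h = conv.forward(h, train)
            mask = h > 0
            h = h * mask
            if train:
                self._relu_masks.append(mask)
            h = pool.forward(h, train)
        h = h.reshape(h.shape[0], -1)
        h = self.fc.forward(h, train)
        mask = h > 0
        h = h * mask
        if train:
            self._relu_masks.append(mask)
        return self.out.forward(h, train)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def loss_and_grads(
        self, x: np.ndarray, y: np.ndarray
    ) -> tuple[float, list[np.ndarray]]:
        """Mean categorical cross-entropy over the batch and its gradient
        with respect to every parameter (same order as ``params``)."""
        n = x.shape[0]
        logits = self.forward(x, train=True)
        p = softmax(logits)
        eps = np.finfo(np.float32).tiny
        loss = float(-np.log(p[np.arange(n), y] + eps).mean())

        dlogits = p.astype(np.float32)
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= np.float32(n)

        masks = self._relu_masks
        grads_rev: list[np.ndarray] = []
        dh, gs = self.out.backward(dlogits)
        grads_rev.extend(reversed(gs))
        dh = dh * masks[-1]
        dh, gs = self.fc.backward(dh)
        grads_rev.extend(reversed(gs))
        # reshape back to the last pooled activation
        ch = self.convs[-1].out_ch
        side = self.in_side // (2 ** len(self.convs))
        dh = dh.reshape(n, ch, side, side)
        for i in range(len(self.convs) - 1, -1, -1):
            dh, gs = self.pools[i].backward(dh)
            dh = dh * masks[i]
            dh, gs_c = self.convs[i].backward(dh)
            grads_rev.extend(reversed(gs_c))
        self._relu_masks = []
        return loss, list(reversed(grads_rev))


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            g = g.astype(p.dtype)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
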