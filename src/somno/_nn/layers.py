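"""Feed-forward layers with explicit forward/backward passes (float32).

Large activation and scratch arrays are kept as persistent per-layer
buffers and reused across steps: on a memory-bound CPU the page-fault
cost of reallocating ~100 MB arrays every step dominates the arithmetic
otherwise.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def _uniform(rng: np.random.Generator, bound: float, shape) -> np.ndarray:
    return rng.uniform(-bound, bound, size=shape).astype(F32)


class Module:
    """Base class: a layer owns `params` and matching `grads` dicts."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True
        self._buffers: dict[str, np.ndarray] = {}

    def _buf(self, name: str, shape, dtype=F32) -> np.ndarray:
        """Persistent scratch array, reallocated only on shape change."""
        buf = self._buffers.get(name)
        if buf is None or buf.shape != tuple(shape) or buf.dtype != dtype:
            buf = np.empty(shape, dtype)
            self._buffers[name] = buf
        return buf

    def train(self, mode: bool = True):
        self.training = mode
        for child in self.children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def children(self) -> list["Module"]:
        return [v for v in vars(self).values() if isinstance(v, Module)]

    def named_parameters(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for name, arr in self.params.items():
            out[f"{prefix}{name}"] = arr
        for attr, child in vars(self).items():
            if isinstance(child, Module):
                out.update(child.named_parameters(prefix=f"{prefix}{attr}."))
        return out

    def named_grads(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for name in self.params:
            out[f"{prefix}{name}"] = self.grads[name]
        for attr, child in vars(self).items():
            if isinstance(child, Module):
                out.update(child.named_grads(prefix=f"{prefix}{attr}."))
        return out

    def zero_grad(self):
        for name, p in self.params.items():
            g = self.grads.get(name)
            if g is None or g.shape != p.shape:
                self.grads[name] = np.zeros_like(p)
            else:
                g.fill(0)
        for child in self.children():
            child.zero_grad()

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.named_parameters().values()))

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


class Conv2d(Module):
    """'Same' odd-kernel convolution via shifted-slice im2col and GEMM."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 ksize: int = 3):
        super().__init__()
        if ksize % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.in_ch, self.out_ch, self.ksize = in_ch, out_ch, ksize
        fan_in = in_ch * ksize * ksize
        bound = 1.0 / np.sqrt(fan_in)
        self.params["weight"] = _uniform(rng, bound, (out_ch, in_ch, ksize, ksize))
        self.params["bias"] = _uniform(rng, bound, (out_ch,))
        self.zero_grad()
        self._shape = None

    def _wmat(self) -> np.ndarray:
        k = self.ksize
        # layout (out_ch, k*k*in_ch), kernel-offset-major, matching _im2col
        return np.ascontiguousarray(
            self.params["weight"].transpose(0, 2, 3, 1).reshape(
                self.out_ch, k * k * self.in_ch))

    def _im2col(self, xp: np.ndarray, h: int, w: int, col: np.ndarray) -> np.ndarray:
        k, c = self.ksize, self.in_ch
        col3 = col.reshape(k * k, c, h * w)
        for di in range(k):
            for dj in range(k):
                col3[di * k + dj] = xp[:, di:di + h, dj:dj + w].reshape(c, h * w)
        return col

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"Conv2d expected {self.in_ch} input channels, got {c}")
        k, p = self.ksize, self.ksize // 2
        wmat = self._wmat()
        out = self._buf("out", (b, self.out_ch, h, w))
        col = self._buf("col", (k * k * self.in_ch, h * w))
        xp = self._buf("xp", (b, c, h + 2 * p, w + 2 * p))
        xp[:, :, :p, :] = 0
        xp[:, :, -p:, :] = 0
        xp[:, :, :, :p] = 0
        xp[:, :, :, -p:] = 0
        xp[:, :, p:p + h, p:p + w] = x
        for i in range(b):
            self._im2col(xp[i], h, w, col)
            np.dot(wmat, col, out=out[i].reshape(self.out_ch, h * w))
            out[i] += self.params["bias"][:, None, None]
        self._shape = (b, h, w)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w = self._shape
        k, p = self.ksize, self.ksize // 2
        wmat = self._wmat()
        xp = self._buffers["xp"]
        col = self._buffers["col"]
        dxp = self._buf("dxp", xp.shape[1:])
        dx = self._buf("dx", (b, self.in_ch, h, w))
        dwmat = np.zeros_like(wmat)
        db = np.zeros_like(self.params["bias"])
        for i in range(b):
            dmat = dout[i].reshape(self.out_ch, h * w)
            self._im2col(xp[i], h, w, col)
            dwmat += dmat @ col.T
            db += dmat.sum(axis=1)
            np.dot(wmat.T, dmat, out=col)  # col no longer needed: reuse as dcol
            dxp.fill(0)
            dcol3 = col.reshape(k * k, self.in_ch, h, w)
            for di in range(k):
                for dj in range(k):
                    dxp[:, di:di + h, dj:dj + w] += dcol3[di * k + dj]
            dx[i] = dxp[:, p:p + h, p:p + w]
        self.grads["weight"] += dwmat.reshape(
            self.out_ch, k, k, self.in_ch).transpose(0, 3, 1, 2)
        self.grads["bias"] += db
        return dx


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.params["weight"] = np.ones(ch, dtype=F32)
        self.params["bias"] = np.zeros(ch, dtype=F32)
        self.running_mean = np.zeros(ch, dtype=F32)
        self.running_var = np.ones(ch, dtype=F32)
        self.zero_grad()
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            n = x.shape[0] * x.shape[2] * x.shape[3]
            s = x.sum(axis=(0, 2, 3), dtype=np.float64)
            ss = np.einsum("bchw,bchw->c", x, x)
            mean = (s / n).astype(F32)
            var = np.maximum(ss / n - mean.astype(np.float64) ** 2, 0.0).astype(F32)
            unbiased = var * n / max(n - 1, 1)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(F32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased).astype(F32)
            inv_std = (1.0 / np.sqrt(var + F32(self.eps))).astype(F32)
            x_hat = self._buf("x_hat", x.shape)
            np.subtract(x, mean[:, None, None], out=x_hat)
            x_hat *= inv_std[:, None, None]
            self._cache = inv_std
            # output written in place over x (the producer does not reuse it)
            np.multiply(x_hat, self.params["weight"][:, None, None], out=x)
            x += self.params["bias"][:, None, None]
            return x
        # eval: one fused affine pass in place, no cache
        inv_std = (1.0 / np.sqrt(self.running_var + F32(self.eps))).astype(F32)
        a = self.params["weight"] * inv_std
        b = self.params["bias"] - self.running_mean * a
        x *= a[:, None, None]
        x += b[:, None, None]
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_hat = self._buffers["x_hat"]
        inv_std = self._cache
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["weight"] += np.einsum("bchw,bchw->c", dout, x_hat)
        self.grads["bias"] += np.einsum("bchw->c", dout)
        # dx computed in place over dout (its producer does not reuse it)
        dout *= self.params["weight"][:, None, None]
        m1 = (np.einsum("bchw->c", dout) / n).astype(F32)
        m2 = (np.einsum("bchw,bchw->c", dout, x_hat) / n).astype(F32)
        for c in range(dout.shape[1]):  # channel loop keeps transients small
            dout[:, c] -= x_hat[:, c] * m2[c]
        dout -= m1[:, None, None]
        dout *= inv_std[:, None, None]
        self._cache = None
        return dout


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.maximum(x, 0, out=x)  # in place: upstream layers cache inputs
        self._mask = (out > 0) if self.training else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout *= self._mask
        self._mask = None
        return dout


class MaxPool2d(Module):
    """Non-overlapping max pooling.

    Backward routes gradient through every element equal to the window
    maximum (a valid subgradient; exact ties at positive values are
    measure-zero, and tied zeros are blocked by the preceding ReLU).
    """

    def __init__(self, pool: tuple[int, int]):
        super().__init__()
        self.ph, self.pw = pool
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        ph, pw = self.ph, self.pw
        if h % ph or w % pw:
            raise ValueError(f"pooling {ph}x{pw} does not divide input {h}x{w}")
        ho, wo = h // ph, w // pw
        out = self._buf("out", (b, c, ho, wo))
        # elementwise maxima over strided views beat tiny-axis reductions
        if pw > 1:
            m1 = self._buf("m1", (b, c, h, wo))
            xv = x.reshape(b, c, h, wo, pw)
            m1[:] = xv[..., 0]
            for j in range(1, pw):
                np.maximum(m1, xv[..., j], out=m1)
        else:
            m1 = x.reshape(b, c, h, wo)
        if ph > 1:
            mv = m1.reshape(b, c, ho, ph, wo)
            out[:] = mv[:, :, :, 0]
            for j in range(1, ph):
                np.maximum(out, mv[:, :, :, j], out=out)
        else:
            out[:] = m1.reshape(b, c, ho, wo)
        if self.training:
            self._cache = (x, (b, c, h, w))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, (b, c, h, w) = self._cache
        ph, pw = self.ph, self.pw
        ho, wo = h // ph, w // pw
        out = self._buffers["out"]
        dx = self._buf("dx", (b, c, h, w))
        mask = self._buf("mask", (b, c, ho, ph, wo, pw), dtype=bool)
        x6 = x.reshape(b, c, ho, ph, wo, pw)
        dx6 = dx.reshape(b, c, ho, ph, wo, pw)
        np.equal(x6, out[:, :, :, None, :, None], out=mask)
        np.multiply(mask, dout[:, :, :, None, :, None], out=dx6)
        self._cache = None
        return dx


class Linear(Module):
    """Affine map on the last axis of an (..., in_features) array."""

    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.in_f, self.out_f, self.use_bias = in_f, out_f, bias
        bound = 1.0 / np.sqrt(in_f)
        self.params["weight"] = _uniform(rng, bound, (out_f, in_f))
        if bias:
            self.params["bias"] = _uniform(rng, bound, (out_f,))
        self.zero_grad()
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x @ self.params["weight"].T
        if self.use_bias:
            out += self.params["bias"]
        self._cache = x if self.training else None
        return out.astype(F32, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        x2 = x.reshape(-1, self.in_f)
        d2 = dout.reshape(-1, self.out_f)
        self.grads["weight"] += d2.T @ x2
        if self.use_bias:
            self.grads["bias"] += d2.sum(axis=0)
        dx = (d2 @ self.params["weight"]).reshape(x.shape)
        self._cache = None
        return dx.astype(F32, copy=False)


class LayerNorm(Module):
    """Normalization over the last axis with learned affine terms."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.dim, self.eps = dim, eps
        self.params["weight"] = np.ones(dim, dtype=F32)
        self.params["bias"] = np.zeros(dim, dtype=F32)
        self.zero_grad()
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = ((x - mean) * inv_std).astype(F32)
        self._cache = (x_hat, inv_std.astype(F32)) if self.training else None
        return self.params["weight"] * x_hat + self.params["bias"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_hat, inv_std = self._cache
        d2 = dout.reshape(-1, self.dim)
        self.grads["weight"] += (dout * x_hat).reshape(-1, self.dim).sum(axis=0)
        self.grads["bias"] += d2.sum(axis=0)
        dxhat = dout * self.params["weight"]
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * x_hat).mean(axis=-1, keepdims=True)
        dx = (dxhat - m1 - x_hat * m2) * inv_std
        self._cache = None
        return dx.astype(F32, copy=False)


class SEBlock(Module):
    """Squeeze-and-excitation channel gate (global pool -> MLP -> sigmoid)."""

    def __init__(self, ch: int, reduction: int, rng: np.random.Generator,
                 bias: bool = False):
        super().__init__()
        hidden = ch // reduction
        if hidden < 1:
            raise ValueError("SE reduction too large for channel count")
        self.fc1 = Linear(ch, hidden, rng, bias=bias)
        self.fc2 = Linear(hidden, ch, rng, bias=bias)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        s = x.mean(axis=(2, 3)).astype(F32)  # squeeze: (B, C)
        z = np.maximum(self.fc1(s), 0)
        gate = (1.0 / (1.0 + np.exp(-self.fc2(z)))).astype(F32)
        out = self._buf("out", x.shape)
        np.multiply(x, gate[:, :, None, None], out=out)
        if self.training:
            self._cache = (x, z, gate, h * w)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, z, gate, hw = self._cache
        dgate = np.einsum("bchw,bchw->bc", dout, x).astype(F32)
        dx = self._buf("dx", x.shape)
        np.multiply(dout, gate[:, :, None, None], out=dx)
        da2 = dgate * gate * (1 - gate)
        dz = self.fc2.backward(da2.astype(F32))
        dz *= z > 0
        ds = self.fc1.backward(dz.astype(F32))
        dx += (ds / hw)[:, :, None, None]
        self._cache = None
        return dx


class Dropout(Module):
    """Inverted dropout; active only in training mode."""

    def __init__(self, p: float):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout p must lie in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(0)
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(F32) / F32(1 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx


class AdaptiveAvgPool1d(Module):
    """Mean-pool a (B, T_in) sequence onto T_out = T_in / k disjoint groups."""

    def __init__(self, t_out: int):
        super().__init__()
        self.t_out = t_out
        self._k = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, t_in = x.shape
        if t_in % self.t_out:
            raise ValueError(f"input length {t_in} not divisible by {self.t_out}")
        self._k = t_in // self.t_out
        return x.reshape(b, self.t_out, self._k).mean(axis=-1).astype(F32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self._k
        return (np.repeat(dout, k, axis=-1).reshape(dout.shape[0], -1) / k).astype(F32)
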