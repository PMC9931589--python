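"""Minimal 3D convolutional-network engine on numpy.

Forward and backward passes are written out by hand: 3x3x3 same-padded
convolutions via im2col + BLAS matmul, 2x2x2 max pooling, trilinear x2
upsampling (as a small per-axis interpolation matrix, so the adjoint is its
transpose), LeakyReLU, channel concatenation, and an Adam optimiser.  Arrays
are channel-first float32: (C, X, Y, T).

Inference uses a no-grad path that processes the im2col in t-chunks to bound
memory on large fields of view.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-8
_CHUNK_BYTES = 2 * 10**8  # im2col working-set cap in the no-grad path


class Conv3d:
    """k^3 same-padded convolution with bias (k in {1, 3})."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k**3
        # He initialisation for leaky-ReLU networks
        self.W = (rng.standard_normal((cout, fan_in)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    @staticmethod
    def _im2col(xp: np.ndarray, X: int, Y: int, T: int) -> np.ndarray:
        """(cin*27, X*Y*T) column matrix from a padded (cin, X+2, Y+2, T+2) input."""
        cin = xp.shape[0]
        cols = np.empty((cin, 3, 3, 3, X, Y, T), dtype=np.float32)
        for a in range(3):
            for b in range(3):
                for c in range(3):
                    cols[:, a, b, c] = xp[:, a : a + X, b : b + Y, c : c + T]
        return cols.reshape(cin * 27, X * Y * T)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cin, X, Y, T = x.shape
        assert cin == self.cin, (cin, self.cin)
        self._shape = x.shape
        if self.k == 1:
            y = (self.W @ x.reshape(cin, -1)) + self.b[:, None]
            if train:
                self._cols = x.reshape(cin, -1)  # (cin, N)
            return y.reshape(self.cout, X, Y, T)
        if train:
            xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
            cols = self._im2col(xp, X, Y, T)
            self._cols = cols
            y = self.W @ cols + self.b[:, None]
            return y.reshape(self.cout, X, Y, T)
        # no-grad path: chunk along t to bound the im2col working set
        y = np.empty((self.cout, X, Y, T), dtype=np.float32)
        bytes_per_t = X * Y * cin * 27 * 4
        chunk = max(1, min(T, _CHUNK_BYTES // max(bytes_per_t, 1)))
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        for t0 in range(0, T, chunk):
            t1 = min(T, t0 + chunk)
            cols = self._im2col(xp[:, :, :, t0 : t1 + 2], X, Y, t1 - t0)
            out = self.W @ cols + self.b[:, None]
            y[:, :, :, t0:t1] = out.reshape(self.cout, X, Y, t1 - t0)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cin, X, Y, T = self._shape
        N = X * Y * T
        dyf = dy.reshape(self.cout, N)
        if self.k == 1:
            self.dW += dyf @ self._cols.T
            self.db += dyf.sum(axis=1)
            dx = self.W.T @ dyf
            self._cols = None
            return dx.reshape(cin, X, Y, T)
        self.dW += dyf @ self._cols.T
        self.db += dyf.sum(axis=1)
        dcols = (self.W.T @ dyf).reshape(cin, 3, 3, 3, X, Y, T)
        self._cols = None
        dxp = np.zeros((cin, X + 2, Y + 2, T + 2), dtype=np.float32)
        for a in range(3):
            for b in range(3):
                for c in range(3):
                    dxp[:, a : a + X, b : b + Y, c : c + T] += dcols[:, a, b, c]
        return dxp[:, 1 : X + 1, 1 : Y + 1, 1 : T + 1]


class LeakyReLU:
    def __init__(self, slope: float = 0.1):
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, dy, self.slope * dy)
        self._mask = None
        return out


class MaxPool3d:
    """2x2x2 max pooling; extents must be even."""

    def __init__(self) -> None:
        self._argmax: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        C, X, Y, T = x.shape
        if X % 2 or Y % 2 or T % 2:
            raise ValueError(f"extents must be even for 2x2x2 pooling; got {x.shape}")
        v = x.reshape(C, X // 2, 2, Y // 2, 2, T // 2, 2)
        v = v.transpose(0, 1, 3, 5, 2, 4, 6).reshape(C, X // 2, Y // 2, T // 2, 8)
        if train:
            self._argmax = v.argmax(axis=-1)
            self._shape = x.shape
        return v.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        C, X, Y, T = self._shape
        flat = np.zeros((C, X // 2, Y // 2, T // 2, 8), dtype=np.float32)
        np.put_along_axis(flat, self._argmax[..., None], dy[..., None], axis=-1)
        self._argmax = None
        flat = flat.reshape(C, X // 2, Y // 2, T // 2, 2, 2, 2)
        flat = flat.transpose(0, 1, 4, 2, 5, 3, 6)
        return flat.reshape(C, X, Y, T)


def _linear_upsample_matrix(n: int) -> np.ndarray:
    """(2n, n) matrix of x2 linear interpolation with half-pixel alignment."""
    U = np.zeros((2 * n, n), dtype=np.float32)
    pos = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
    i0 = np.floor(pos).astype(int)
    w1 = (pos - i0).astype(np.float32)
    i1 = np.clip(i0 + 1, 0, n - 1)
    i0 = np.clip(i0, 0, n - 1)
    for r in range(2 * n):
        U[r, i0[r]] += 1.0 - w1[r]
        U[r, i1[r]] += w1[r]
    return U


class Upsample3d:
    """Trilinear x2 upsampling, applied as separable per-axis interpolation."""

    _cache: dict[int, np.ndarray] = {}

    def __init__(self) -> None:
        self._in_shape: tuple[int, ...] | None = None

    @classmethod
    def _matrix(cls, n: int) -> np.ndarray:
        if n not in cls._cache:
            cls._cache[n] = _linear_upsample_matrix(n)
        return cls._cache[n]

    @staticmethod
    def _apply_axis(x: np.ndarray, U: np.ndarray, axis: int) -> np.ndarray:
        y = np.tensordot(U, x, axes=(1, axis))       # new axis is first
        return np.moveaxis(y, 0, axis).astype(np.float32, copy=False)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._in_shape = x.shape
        y = x
        for axis in (1, 2, 3):
            y = self._apply_axis(y, self._matrix(x.shape[axis]), axis)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = dy
        for axis in (1, 2, 3):
            g = self._apply_axis(g, self._matrix(self._in_shape[axis]).T, axis)
        return g


class _Block:
    """Two convolutions, each followed by LeakyReLU."""

    def __init__(self, cin: int, mid: int, cout: int, rng: np.random.Generator):
        self.conv_a = Conv3d(cin, mid, 3, rng)
        self.act_a = LeakyReLU()
        self.conv_b = Conv3d(mid, cout, 3, rng)
        self.act_b = LeakyReLU()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.act_a.forward(self.conv_a.forward(x, train), train)
        return self.act_b.forward(self.conv_b.forward(h, train), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = self.conv_b.backward(self.act_b.backward(dy))
        return self.conv_a.backward(self.act_a.backward(g))

    @property
    def convs(self) -> list[Conv3d]:
        return [self.conv_a, self.conv_b]


class UNet3D:
    """All-3D encoder-decoder with skip concatenations.

    Four resolution levels (three 2x2x2 poolings), encoder blocks
    conv(in -> w/2) + conv(w/2 -> w), decoder blocks conv(concat -> w) +
    conv(w -> w) after trilinear upsampling, and a final 1x1x1 projection.
    Input extents must be divisible by 8 (use :meth:`predict` for reflective
    padding of arbitrary extents).
    """

    DIVISOR = 8  # 2^(levels - 1)

    def __init__(self, level_widths: tuple[int, ...], seed: int = 0):
        if list(level_widths) != sorted(set(level_widths)):
            raise ValueError(
                f"level widths must be strictly increasing; got {level_widths}"
            )
        self.level_widths = tuple(int(w) for w in level_widths)
        if len(self.level_widths) != 4:
            raise ValueError("this topology uses exactly 4 resolution levels")
        self.seed = seed
        rng = np.random.default_rng(seed)
        w = self.level_widths
        self.enc = []
        cin = 1
        for wi in w:
            mid = max(1, wi // 2)
            self.enc.append(_Block(cin, mid, wi, rng))
            cin = wi
        self.pools = [MaxPool3d() for _ in range(3)]
        self.ups = [Upsample3d() for _ in range(3)]
        self.dec = [
            _Block(w[3] + w[2], w[2], w[2], rng),
            _Block(w[2] + w[1], w[1], w[1], rng),
            _Block(w[1] + w[0], w[0], w[0], rng),
        ]
        self.final = Conv3d(w[0], 1, 1, rng)

    # ----- parameter plumbing -------------------------------------------------

    @property
    def conv_layers(self) -> list[Conv3d]:
        layers: list[Conv3d] = []
        for blk in self.enc + self.dec:
            layers.extend(blk.convs)
        layers.append(self.final)
        return layers

    @property
    def n_params(self) -> int:
        return sum(c.n_params for c in self.conv_layers)

    def zero_grad(self) -> None:
        for c in self.conv_layers:
            c.dW[:] = 0.0
            c.db[:] = 0.0

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, c in enumerate(self.conv_layers):
            out[f"W{i}"] = c.W
            out[f"b{i}"] = c.b
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, c in enumerate(self.conv_layers):
            c.W[:] = state[f"W{i}"]
            c.b[:] = state[f"b{i}"]

    # ----- forward / backward -------------------------------------------------

    def forward(self, vol: np.ndarray, train: bool = True) -> np.ndarray:
        """Map an (X, Y, T) volume to a denoised volume of the same shape."""
        if vol.ndim != 3:
            raise ValueError("expected a 3D (x, y, t) volume")
        for s in vol.shape:
            if s % self.DIVISOR:
                raise ValueError(
                    f"extents must be divisible by {self.DIVISOR}; got {vol.shape} "
                    f"(use predict() for automatic padding)"
                )
        x = vol[None].astype(np.float32, copy=False)
        e0 = self.enc[0].forward(x, train)
        e1 = self.enc[1].forward(self.pools[0].forward(e0, train), train)
        e2 = self.enc[2].forward(self.pools[1].forward(e1, train), train)
        e3 = self.enc[3].forward(self.pools[2].forward(e2, train), train)
        d2 = self.dec[0].forward(
            np.concatenate([self.ups[0].forward(e3, train), e2], axis=0), train
        )
        d1 = self.dec[1].forward(
            np.concatenate([self.ups[1].forward(d2, train), e1], axis=0), train
        )
        d0 = self.dec[2].forward(
            np.concatenate([self.ups[2].forward(d1, train), e0], axis=0), train
        )
        y = self.final.forward(d0, train)
        return y[0]

    def backward(self, dy: np.ndarray) -> None:
        w = self.level_widths
        g = self.final.backward(dy[None].astype(np.float32, copy=False))
        g = self.dec[2].backward(g)
        g_up, g_e0 = g[: w[1]], g[w[1] :]
        g = self.dec[1].backward(self.ups[2].backward(g_up))
        g_up, g_e1 = g[: w[2]], g[w[2] :]
        g = self.dec[0].backward(self.ups[1].backward(g_up))
        g_up, g_e2 = g[: w[3]], g[w[3] :]
        g = self.enc[3].backward(self.ups[0].backward(g_up))
        g = self.enc[2].backward(self.pools[2].backward(g) + g_e2)
        g = self.enc[1].backward(self.pools[1].backward(g) + g_e1)
        self.enc[0].backward(self.pools[0].backward(g) + g_e0)

    def predict(self, vol: np.ndarray) -> np.ndarray:
        """No-grad forward with reflective padding to the divisibility multiple."""
        vol = np.asarray(vol, dtype=np.float32)
        pads = []
        for s in vol.shape:
            target = -(-s // self.DIVISOR) * self.DIVISOR
            pads.append((0, target - s))
        if any(p[1] for p in pads):
            vol_p = np.pad(vol, pads, mode="reflect")
        else:
            vol_p = vol
        out = self.forward(vol_p, train=False)
        return out[: vol.shape[0], : vol.shape[1], : vol.shape[2]]


class Adam:
    """Adam optimiser over a UNet3D's convolution parameters."""

    def __init__(self, net: UNet3D, lr: float, betas: tuple[float, float] = (0.5, 0.9)):
        self.net = net
        self.lr = lr
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [
            (np.zeros_like(c.W), np.zeros_like(c.b)) for c in net.conv_layers
        ]
        self.v = [
            (np.zeros_like(c.W), np.zeros_like(c.b)) for c in net.conv_layers
        ]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for c, (mW, mb), (vW, vb) in zip(self.net.conv_layers, self.m, self.v):
            for p, g, m, v in ((c.W, c.dW, mW, vW), (c.b, c.db, mb, vb)):
                m *= self.b1
                m += (1.0 - self.b1) * g
                v *= self.b2
                v += (1.0 - self.b2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + _EPS)
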