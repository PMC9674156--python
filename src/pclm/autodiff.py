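"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model in this package is small (tens of thousands of parameters) and is
trained one protein at a time on a CPU, so instead of depending on a deep
learning framework we carry a compact tape-based autodiff engine.  Expensive
recurrent and convolutional blocks are implemented as *fused* ops with
hand-written, vectorised backward passes; everything else is composed from a
handful of primitive tensor ops.  All arithmetic is float64, which is what
makes the finite-difference gradient tests meaningful at 1e-4 relative error.

Only the operations the model needs are provided; this is not a general
framework.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit as _expit

__all__ = ["Tensor", "Adam", "glorot", "zeros_grad"]


class Tensor:
    """A node in the computation tape: float64 data, grad, and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, *,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None,
                 name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward
        self.name = name

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-sweep from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- primitive ops -----------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out_data = self.data + other.data

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, self.requires_grad or other.requires_grad,
                      parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g):
            self._accum(-g)
        return Tensor(-self.data, self.requires_grad, parents=(self,), backward=bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out_data = self.data * other.data

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, self.requires_grad or other.requires_grad,
                      parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __matmul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out_data = self.data @ other.data

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor(out_data, self.requires_grad or other.requires_grad,
                      parents=(self, other), backward=bw)

    @property
    def T(self) -> "Tensor":
        def bw(g):
            self._accum(g.T)
        return Tensor(self.data.T, self.requires_grad, parents=(self,), backward=bw)

    def sum(self) -> "Tensor":
        def bw(g):
            self._accum(np.full_like(self.data, float(g)))
        return Tensor(self.data.sum(), self.requires_grad, parents=(self,), backward=bw)

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor(self.data.reshape(*shape), self.requires_grad,
                      parents=(self,), backward=bw)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor(self.data * mask, self.requires_grad, parents=(self,), backward=bw)

    def sigmoid(self) -> "Tensor":
        s = _sigmoid(self.data)

        def bw(g):
            self._accum(g * s * (1.0 - s))

        return Tensor(s, self.requires_grad, parents=(self,), backward=bw)

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - t * t))

        return Tensor(t, self.requires_grad, parents=(self,), backward=bw)

    def log(self) -> "Tensor":
        def bw(g):
            self._accum(g / self.data)
        return Tensor(np.log(self.data), self.requires_grad, parents=(self,), backward=bw)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clip with straight-through gradient inside the interval, zero outside."""
        mask = (self.data > lo) & (self.data < hi)

        def bw(g):
            self._accum(g * mask)

        return Tensor(np.clip(self.data, lo, hi), self.requires_grad,
                      parents=(self,), backward=bw)

    def concat_cols(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        n = self.data.shape[1]
        out_data = np.concatenate([self.data, other.data], axis=1)

        def bw(g):
            self._accum(g[:, :n])
            other._accum(g[:, n:])

        return Tensor(out_data, self.requires_grad or other.requires_grad,
                      parents=(self, other), backward=bw)

    def row_softmax(self) -> "Tensor":
        z = self.data - self.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        a = e / e.sum(axis=1, keepdims=True)

        def bw(g):
            # dL/dz_ij = a_ij * (g_ij - sum_k g_ik a_ik)
            dot = (g * a).sum(axis=1, keepdims=True)
            self._accum(a * (g - dot))

        return Tensor(a, self.requires_grad, parents=(self,), backward=bw)

    def moving_mean_rows(self, w: int) -> "Tensor":
        """Mean over a length-w window of rows centred at each row (zero-padded
        at the ends but divided by the number of in-range rows, i.e. a true
        mean over valid neighbours).  w must be odd; w=1 is the identity."""
        if w % 2 != 1 or w < 1:
            raise ValueError("window width must be a positive odd integer")
        if w == 1:
            return self
        L = self.data.shape[0]
        half = w // 2
        counts = np.array([min(L - 1, i + half) - max(0, i - half) + 1
                           for i in range(L)], dtype=np.float64)[:, None]
        csum = np.cumsum(np.vstack([np.zeros((1,) + self.data.shape[1:]), self.data]),
                         axis=0)
        hi = np.minimum(L, np.arange(L) + half + 1)
        lo = np.maximum(0, np.arange(L) - half)
        out_data = (csum[hi] - csum[lo]) / counts

        def bw(g):
            gn = g / counts
            gcs = np.cumsum(np.vstack([np.zeros((1,) + g.shape[1:]), gn]), axis=0)
            # residue j receives gn_i for every window i covering j
            j_hi = np.minimum(L, np.arange(L) + half + 1)
            j_lo = np.maximum(0, np.arange(L) - half)
            self._accum(gcs[j_hi] - gcs[j_lo])

        return Tensor(out_data, self.requires_grad, parents=(self,), backward=bw)

    # -- fused ops ---------------------------------------------------------

    def conv2d_bank(self, kernels: "Tensor") -> "Tensor":
        """Correlate an LxL map with a bank of c kxk kernels, same zero padding.

        Returns an (L, L, c) tensor.  Gradients flow to the kernels only (the
        map is measured input, never a trainable quantity).
        """
        Y = self.data
        K = kernels.data  # (c, k, k)
        c, k, _ = K.shape
        pad = k // 2
        Yp = np.pad(Y, pad)
        win = sliding_window_view(Yp, (k, k))          # (L, L, k, k)
        L = Y.shape[0]
        cols = win.reshape(L * L, k * k)
        out_data = (cols @ K.reshape(c, k * k).T).reshape(L, L, c)

        def bw(g):
            if kernels.requires_grad:
                gk = (g.reshape(L * L, c).T @ cols).reshape(c, k, k)
                kernels._accum(gk)

        return Tensor(out_data, kernels.requires_grad, parents=(self, kernels),
                      backward=bw)

    def rowpool_mean_max(self) -> "Tensor":
        """(L, L, c) -> (L, 2c): per-residue mean and max over the partner axis."""
        x = self.data
        L = x.shape[0]
        mean = x.mean(axis=1)
        arg = x.argmax(axis=1)
        mx = np.take_along_axis(x, arg[:, None, :], axis=1)[:, 0, :]
        out_data = np.concatenate([mean, mx], axis=1)

        def bw(g):
            c = x.shape[2]
            gx = np.zeros_like(x)
            gx += g[:, None, :c] / L
            gmax = np.zeros_like(x)
            np.put_along_axis(gmax, arg[:, None, :], g[:, None, c:], axis=1)
            self._accum(gx + gmax)

        return Tensor(out_data, self.requires_grad, parents=(self,), backward=bw)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `g` down to `shape` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return _expit(x)


# ---------------------------------------------------------------------------
# fused Bi-LSTM


def lstm_direction(X: Tensor, Wx: Tensor, Wh: Tensor, b: Tensor,
                   reverse: bool = False) -> Tensor:
    """One LSTM direction over an (L, d_in) input; returns (L, h) hidden states.

    Gate layout along the 4h axis: input, forget, cell(g), output.  Zero
    initial hidden and cell state.  Backward pass is standard BPTT with the
    per-step caches kept from the forward sweep.
    """
    x = X.data[::-1] if reverse else X.data
    L = x.shape[0]
    h = Wh.data.shape[0]
    WhT = np.ascontiguousarray(Wh.data.T)
    xw = x @ Wx.data + b.data                     # (L, 4h) precomputed
    H = np.zeros((L, h))
    C = np.zeros((L, h))
    gates = np.zeros((L, 4 * h))                  # sigmoid on [:3h], tanh on [3h:]
    tanh_c = np.zeros((L, h))
    hp = np.zeros(h)
    cp = np.zeros(h)
    for t in range(L):
        z = xw[t] + hp @ Wh.data
        z[:3 * h] = _expit(z[:3 * h])
        g4 = np.tanh(z[3 * h:])
        i, f, o = z[:h], z[h:2 * h], z[2 * h:3 * h]
        cp = f * cp + i * g4
        tc = np.tanh(cp)
        hp = o * tc
        z[3 * h:] = g4
        gates[t] = z
        tanh_c[t] = tc
        C[t] = cp
        H[t] = hp

    out_data = H[::-1].copy() if reverse else H

    def bw(gout):
        gH = gout[::-1] if reverse else gout
        DZ = np.zeros((L, 4 * h))
        dh_next = np.zeros(h)
        dc_next = np.zeros(h)
        zeros_h = np.zeros(h)
        for t in range(L - 1, -1, -1):
            gt = gates[t]
            i, f, o, gg = gt[:h], gt[h:2 * h], gt[2 * h:3 * h], gt[3 * h:]
            c_prev = C[t - 1] if t > 0 else zeros_h
            dh = gH[t] + dh_next
            tc = tanh_c[t]
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            dz = DZ[t]
            dz[:h] = dc * gg * i * (1 - i)
            dz[h:2 * h] = dc * c_prev * f * (1 - f)
            dz[2 * h:3 * h] = do * o * (1 - o)
            dz[3 * h:] = dc * i * (1 - gg * gg)
            dh_next = dz @ WhT
            dc_next = dc * f
        Wx._accum(x.T @ DZ)
        Hprev = np.vstack([np.zeros((1, h)), H[:-1]])
        Wh._accum(Hprev.T @ DZ)
        b._accum(DZ.sum(axis=0))
        if X.requires_grad:
            dX = DZ @ Wx.data.T
            X._accum(dX[::-1] if reverse else dX)

    req = X.requires_grad or Wx.requires_grad or Wh.requires_grad or b.requires_grad
    return Tensor(out_data, req, parents=(X, Wx, Wh, b), backward=bw)


# ---------------------------------------------------------------------------
# fused motif convolution (1D over sequence positions, PWM kernels)


def motif_conv(Z: np.ndarray, kernels: list[Tensor], bias: Tensor) -> Tensor:
    """Scan each PWM kernel over a one-hot (L, 20) matrix, same padding.

    Each kernel is an (l_m, 20) tensor anchored at floor(l_m/2); positions
    outside [0, L) contribute zero.  Output (L, n_motifs), pre-activation.
    The one-hot input carries no gradient.
    """
    if not kernels:
        raise ValueError("empty motif kernel bank")
    L = Z.shape[0]
    n = len(kernels)
    out = np.empty((L, n))
    caches = []
    for m, K in enumerate(kernels):
        lm = K.data.shape[0]
        off = lm // 2
        Zp = np.pad(Z, ((off, lm - 1 - off), (0, 0)))
        win = sliding_window_view(Zp, (lm, 20))[:, 0]    # (L, lm, 20)
        out[:, m] = np.einsum("ijk,jk->i", win, K.data)
        caches.append(win)
    out += bias.data

    def bw(g):
        if bias.requires_grad:
            bias._accum(g.sum(axis=0))
        for m, K in enumerate(kernels):
            if K.requires_grad:
                K._accum(np.einsum("i,ijk->jk", g[:, m], caches[m]))

    req = bias.requires_grad or any(K.requires_grad for K in kernels)
    return Tensor(out, req, parents=tuple(kernels) + (bias,), backward=bw)


# ---------------------------------------------------------------------------
# parameters and optimiser


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


def zeros_grad(params: Iterable[Tensor]) -> None:
    for p in params:
        p.grad = None


class Adam:
    """Adam with the conventional bias-corrected moment estimates."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        zeros_grad(self.params.values())
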