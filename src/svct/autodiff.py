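"""Minimal reverse-mode automatic differentiation on numpy arrays.

The training graph of this package (U-Nets with attention-guided scaling,
a convolutional critic, and tomographic linear operators) is built from the
small set of primitives defined here.  The engine is a classic tape: each
:class:`Tensor` stores its value, a gradient buffer and a backward closure;
``Tensor.backward()`` walks the tape in reverse topological order.

Only first-order gradients are supported.  Where a second-order quantity is
needed (the WGAN gradient penalty), the inner gradient is constructed
explicitly as a vector-Jacobian chain of these primitives, so the outer
backward pass differentiates through it like any other expression.

Everything is plain numpy; dtype follows the inputs (float32 for training,
float64 for gradient checks).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "concatenate",
    "conv2d",
    "conv2d_transpose",
    "avg_pool2d",
    "upsample_bilinear2x",
    "pixel_shuffle",
    "pad2d",
    "softmax",
    "relu",
    "leaky_relu",
    "sigmoid",
    "linear_op",
    "Module",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- basic protocol -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    # -- autograd -------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        grad = np.asarray(grad)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g, other.data.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * self.data, other.data.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g / other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                              other.data.shape))
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p):
        assert np.isscalar(p)
        out = _make(self.data ** p, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = _make(np.matmul(self.data, other.data), (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                    self._accum(_unbroadcast(ga, self.data.shape))
                if other.requires_grad:
                    gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                    other._accum(_unbroadcast(gb, other.data.shape))
            out._backward = bw
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        if out.requires_grad:
            def bw(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
            out._backward = bw
        return out

    # -- elementwise ----------------------------------------------------
    def exp(self):
        e = np.exp(self.data)
        out = _make(e, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = _make(r, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / (2.0 * r))
        return out

    def abs(self):
        out = _make(np.abs(self.data), (self,))
        if out.requires_grad:
            s = np.sign(self.data)
            out._backward = lambda g: self._accum(g * s)
        return out

    # -- reductions / shaping --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = _make(self.data.transpose(axes), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data, parents) -> Tensor:
    req = any(isinstance(p, Tensor) and p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req,
                  _parents=tuple(p for p in parents if isinstance(p, Tensor)))


def constant(x) -> Tensor:
    return Tensor(np.asarray(x))


def parameter(x) -> Tensor:
    return Tensor(np.asarray(x), requires_grad=True)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = _make(np.where(mask, x.data, 0.0), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accum(g * mask)
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    mask = np.where(x.data > 0, 1.0, slope).astype(x.data.dtype)
    out = _make(x.data * mask, (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accum(g * mask)
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = _make(s, (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accum(g * s * (1.0 - s))
    return out


def softmax(x: Tensor, axis: int) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    s = e / e.sum(axis=axis, keepdims=True)
    out = _make(s, (x,))
    if out.requires_grad:
        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accum(s * (g - dot))
        out._backward = bw
    return out


def concatenate(tensors, axis: int) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        offs = np.cumsum([0] + sizes)

        def bw(g):
            for t, a, b in zip(tensors, offs[:-1], offs[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accum(g[tuple(sl)])
        out._backward = bw
    return out


# ---------------------------------------------------------------------------
# padding, pooling, resampling
# ---------------------------------------------------------------------------

def pad2d(x: Tensor, p: int, mode: str = "zero") -> Tensor:
    """Pad the last two axes by ``p`` pixels (``zero`` or ``edge``)."""
    if p == 0:
        return x
    npmode = "constant" if mode == "zero" else "edge"
    width = [(0, 0)] * (x.ndim - 2) + [(p, p), (p, p)]
    out = _make(np.pad(x.data, width, mode=npmode), (x,))
    if out.requires_grad:
        H, W = x.data.shape[-2:]

        def bw(g):
            gi = g[..., p:H + p, p:W + p].copy()
            if mode == "edge":
                gi[..., :1, :] += g[..., :p, p:W + p].sum(axis=-2, keepdims=True)
                gi[..., -1:, :] += g[..., H + p:, p:W + p].sum(axis=-2, keepdims=True)
                gi[..., :, :1] += g[..., p:H + p, :p].sum(axis=-1, keepdims=True)
                gi[..., :, -1:] += g[..., p:H + p, W + p:].sum(axis=-1, keepdims=True)
                gi[..., 0, 0] += g[..., :p, :p].sum(axis=(-2, -1))
                gi[..., 0, -1] += g[..., :p, W + p:].sum(axis=(-2, -1))
                gi[..., -1, 0] += g[..., H + p:, :p].sum(axis=(-2, -1))
                gi[..., -1, -1] += g[..., H + p:, W + p:].sum(axis=(-2, -1))
            x._accum(gi)
        out._backward = bw
    return out


def avg_pool2d(x: Tensor) -> Tensor:
    """2x2 average pooling (even H, W required)."""
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("avg_pool2d requires even spatial size")
    v = x.data.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))
    out = _make(v, (x,))
    if out.requires_grad:
        def bw(g):
            gg = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
            x._accum(gg)
        out._backward = bw
    return out


def _bilinear_matrix(n: int, dtype) -> np.ndarray:
    """(2n, n) interpolation matrix, align_corners=False convention."""
    U = np.zeros((2 * n, n), dtype=dtype)
    src = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
    i0 = np.floor(src).astype(int)
    f = src - i0
    lo = np.clip(i0, 0, n - 1)
    hi = np.clip(i0 + 1, 0, n - 1)
    U[np.arange(2 * n), lo] += 1.0 - f
    U[np.arange(2 * n), hi] += f
    return U


def upsample_bilinear2x(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    Uh = _bilinear_matrix(H, x.data.dtype)
    Uw = _bilinear_matrix(W, x.data.dtype)
    v = np.matmul(np.matmul(Uh, x.data), Uw.T)
    out = _make(v, (x,))
    if out.requires_grad:
        def bw(g):
            x._accum(np.matmul(np.matmul(Uh.T, g), Uw))
        out._backward = bw
    return out


def pixel_shuffle(x: Tensor, r: int = 2) -> Tensor:
    N, C, H, W = x.data.shape
    if C % (r * r):
        raise ValueError("channels not divisible by r^2")
    Co = C // (r * r)
    v = x.data.reshape(N, Co, r, r, H, W).transpose(0, 1, 4, 2, 5, 3)
    v = v.reshape(N, Co, H * r, W * r)
    out = _make(v, (x,))
    if out.requires_grad:
        def bw(g):
            gg = g.reshape(N, Co, H, r, W, r).transpose(0, 1, 3, 5, 2, 4)
            x._accum(gg.reshape(N, C, H, W))
        out._backward = bw
    return out


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    """xp: padded (N,C,Hp,Wp) -> cols (N, Ho*Wo, C*kh*kw)."""
    from numpy.lib.stride_tricks import sliding_window_view
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    N, C, Ho, Wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N, Ho * Wo, C * kh * kw)
    return cols, Ho, Wo


def _col2im(cols: np.ndarray, shape, kh: int, kw: int, stride: int, Ho: int, Wo: int):
    """cols (N, Ho*Wo, C*kh*kw) scattered back into (N,C,Hp,Wp)."""
    N, C, Hp, Wp = shape
    xp = np.zeros(shape, dtype=cols.dtype)
    c6 = cols.reshape(N, Ho, Wo, C, kh, kw)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride] += \
                c6[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return xp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0, pad_mode: str = "zero") -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout.

    ``w`` has shape (Cout, Cin, kh, kw).  ``pad_mode='edge'`` gives replicate
    boundary handling (used by the Sobel edge extractor).
    """
    xpad = pad2d(x, padding, mode=pad_mode) if padding else x
    xp = xpad.data
    O, Ci, kh, kw = w.data.shape
    cols, Ho, Wo = _im2col(xp, kh, kw, stride)
    Wmat = w.data.reshape(O, Ci * kh * kw)
    out_mat = cols @ Wmat.T                       # (N, HoWo, O)
    v = out_mat.transpose(0, 2, 1).reshape(xp.shape[0], O, Ho, Wo)
    if b is not None:
        v = v + b.data.reshape(1, O, 1, 1)
    parents = (xpad, w) + ((b,) if b is not None else ())
    out = _make(v, parents)
    if out.requires_grad:
        def bw(g):
            gmat = g.reshape(g.shape[0], O, Ho * Wo).transpose(0, 2, 1)  # (N,HoWo,O)
            if w.requires_grad:
                dW = gmat.reshape(-1, O).T @ cols.reshape(-1, cols.shape[2])
                w._accum(dW.reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if xpad.requires_grad:
                dcols = gmat @ Wmat
                xpad._accum(_col2im(dcols, xp.shape, kh, kw, stride, Ho, Wo))
        out._backward = bw
    return out


def conv2d_transpose(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 1, padding: int = 0,
                     output_size: tuple | None = None) -> Tensor:
    """Transposed convolution — exact adjoint of :func:`conv2d` (zero pad).

    ``w`` has the shape of the *forward* convolution's kernel
    (Cout_fwd, Cin_fwd, kh, kw); input x has Cout_fwd channels.
    ``output_size`` disambiguates odd sizes; defaults to
    (H-1)*stride + kh - 2*padding.
    """
    O, Ci, kh, kw = w.data.shape
    N, _, H, W = x.data.shape
    if output_size is None:
        Ho = (H - 1) * stride + kh - 2 * padding
        Wo = (W - 1) * stride + kw - 2 * padding
    else:
        Ho, Wo = output_size
    Hp, Wp = Ho + 2 * padding, Wo + 2 * padding
    Wmat = w.data.reshape(O, Ci * kh * kw)
    xmat = x.data.reshape(N, O, H * W).transpose(0, 2, 1)         # (N, HW, O)
    cols = xmat @ Wmat                                            # (N, HW, CiKK)
    vp = _col2im(cols, (N, Ci, Hp, Wp), kh, kw, stride, H, W)
    v = vp[:, :, padding:Hp - padding, padding:Wp - padding] if padding else vp
    if b is not None:
        v = v + b.data.reshape(1, Ci, 1, 1)
    parents = (x, w) + ((b,) if b is not None else ())
    out = _make(v, parents)
    if out.requires_grad:
        def bw(g):
            if padding:
                gp = np.zeros((N, Ci, Hp, Wp), dtype=g.dtype)
                gp[:, :, padding:Hp - padding, padding:Wp - padding] = g
            else:
                gp = g
            gcols, Ho2, Wo2 = _im2col(gp, kh, kw, stride)          # (N, HW, CiKK)
            if x.requires_grad:
                dx = gcols @ Wmat.T                                # (N, HW, O)
                x._accum(dx.transpose(0, 2, 1).reshape(N, O, H, W))
            if w.requires_grad:
                dW = xmat.reshape(-1, O).T @ gcols.reshape(-1, gcols.shape[2])
                w._accum(dW.reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
        out._backward = bw
    return out


# ---------------------------------------------------------------------------
# arbitrary linear operators (projection / FBP layers)
# ---------------------------------------------------------------------------

def linear_op(x: Tensor, forward, adjoint) -> Tensor:
    """Wrap a linear map given as a (forward, adjoint) pair of ndarray functions.

    The backward pass applies ``adjoint`` to the incoming gradient, which is
    exact for a truly adjoint pair.
    """
    out = _make(forward(x.data), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accum(adjoint(g).astype(x.data.dtype, copy=False))
    return out


# ---------------------------------------------------------------------------
# modules and optimizer
# ---------------------------------------------------------------------------

class Module:
    """Tiny parameter container with recursive traversal."""

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            out.extend(_collect(v))
        return out

    def named_parameters(self, prefix=""):
        out = []
        for k, v in self.__dict__.items():
            out.extend(_collect_named(v, f"{prefix}{k}"))
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"parameter name mismatch: {sorted(missing)[:5]}")
        for k, p in own.items():
            p.data = np.asarray(state[k]).astype(p.data.dtype, copy=True).reshape(p.data.shape)


def _collect(v):
    if isinstance(v, Tensor) and v.requires_grad:
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for u in v:
            out.extend(_collect(u))
        return out
    return []


def _collect_named(v, name):
    if isinstance(v, Tensor) and v.requires_grad:
        return [(name, v)]
    if isinstance(v, Module):
        return v.named_parameters(prefix=name + ".")
    if isinstance(v, (list, tuple)):
        out = []
        for i, u in enumerate(v):
            out.extend(_collect_named(u, f"{name}.{i}"))
        return out
    return []


class Adam:
    """Adam optimizer; ``lr`` may be reassigned between steps (lr schedules)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
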