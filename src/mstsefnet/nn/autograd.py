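"""A small reverse-mode automatic-differentiation engine on numpy arrays.

The network in this package is a compact DAG of 2-D convolutions, batch
normalisation, gated attention products and a linear classifier.  All of it
is expressed through the :class:`Tensor` below, which records a dynamic
computation graph and back-propagates with the standard chain rule.  Only
the operations the architecture needs are implemented; each backward rule
is covered by finite-difference tests.

Conventions
-----------
* Arrays are ``float32`` by default (``float64`` passes through untouched).
* Broadcasting follows numpy; gradients are summed over broadcast axes.
* ``Tensor.backward()`` seeds the output gradient with ones and walks the
  graph in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate"]


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype not in (np.float32, np.float64):
        a = a.astype(np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _im2col_grouped(x: np.ndarray, groups: int, kh: int, kw: int) -> np.ndarray:
    """Rearrange (B, Cin, H, W) into a (groups, B·Ho·Wo, Cin_g·kh·kw) matrix.

    Batch-major layout: the copy reads the time axis with stride 1, which
    keeps this close to memcpy speed.
    """
    B, Cin, H, W = x.shape
    Cin_g = Cin // groups
    Ho, Wo = H - kh + 1, W - kw + 1
    s = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, shape=(B, groups, Cin_g, kh, kw, Ho, Wo),
        strides=(s[0], s[1] * Cin_g, s[1], s[2], s[3], s[2], s[3]))
    cols = np.ascontiguousarray(patches.transpose(1, 0, 5, 6, 2, 3, 4))
    return cols.reshape(groups, B * Ho * Wo, Cin_g * kh * kw)


def _corr1d_fft(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Valid cross-correlation along the last axis via FFT (kh == 1 kernels).

    Chosen over im2col for wide temporal kernels, where the column matrix
    would be k times the input size.
    """
    from scipy import fft as sfft
    B, Cin, H, W = x.shape
    Cout, _, _, kw = w.shape
    Wo = W - kw + 1
    n = sfft.next_fast_len(W)
    Xf = sfft.rfft(x, n, axis=-1)                   # (B, Cin, H, nf)
    Kf = np.conj(sfft.rfft(w[:, :, 0, :], n, axis=-1))  # (Cout, Cin, nf)
    if Cin == 1:
        prod = Xf * Kf[None, :, 0, None, :]         # (B, Cout, H, nf)
    else:
        prod = np.einsum("bihn,oin->bohn", Xf, Kf, optimize=True)
    return np.ascontiguousarray(sfft.irfft(prod, n, axis=-1)[..., :Wo])


def _corr1d_fft_grad_w(x: np.ndarray, g: np.ndarray, kw: int) -> np.ndarray:
    """FFT weight gradient for kh == 1, groups == 1 kernels."""
    from scipy import fft as sfft
    B, Cin, H, W = x.shape
    Cout = g.shape[1]
    n = sfft.next_fast_len(W)
    Xf = sfft.rfft(x, n, axis=-1)
    Gf = np.conj(sfft.rfft(g, n, axis=-1))
    prod = np.einsum("bihn,bohn->oin", Xf, Gf, optimize=True)
    gw = sfft.irfft(prod, n, axis=-1)[..., :kw]
    return gw.reshape(Cout, Cin, 1, kw)


# FFT wins once the kernel is wide; the threshold only affects speed
_FFT_MIN_KW = 13


def _corr2d(x: np.ndarray, w: np.ndarray, groups: int) -> np.ndarray:
    """Valid-mode grouped cross-correlation via batched matrix product."""
    B, Cin, H, W = x.shape
    Cout, Cin_g, kh, kw = w.shape
    Cout_g = Cout // groups
    Ho, Wo = H - kh + 1, W - kw + 1
    if kh == 1 and kw >= _FFT_MIN_KW and groups == 1:
        return _corr1d_fft(x, w)
    cols = _im2col_grouped(x, groups, kh, kw)       # (g, B·Ho·Wo, K)
    wm = w.reshape(groups, Cout_g, Cin_g * kh * kw)
    out = np.matmul(cols, wm.transpose(0, 2, 1))    # (g, B·Ho·Wo, Cout_g)
    out = out.reshape(groups, B, Ho, Wo, Cout_g).transpose(1, 0, 4, 2, 3)
    return np.ascontiguousarray(out).reshape(B, Cout, Ho, Wo)


def _corr2d_grad_w(x: np.ndarray, g: np.ndarray, kshape: tuple[int, int],
                   groups: int) -> np.ndarray:
    """Weight gradient: correlate input patches with the output gradient."""
    B, Cin, H, W = x.shape
    kh, kw = kshape
    Cin_g = Cin // groups
    Cout = g.shape[1]
    Cout_g = Cout // groups
    Ho, Wo = H - kh + 1, W - kw + 1
    if kh == 1 and kw >= _FFT_MIN_KW and groups == 1:
        return _corr1d_fft_grad_w(x, g, kw)
    cols = _im2col_grouped(x, groups, kh, kw)       # (g, B·Ho·Wo, K)
    gm = np.ascontiguousarray(
        g.reshape(B, groups, Cout_g, Ho * Wo).transpose(1, 2, 0, 3)
    ).reshape(groups, Cout_g, B * Ho * Wo)
    gw = np.matmul(gm, cols)                        # (g, Cout_g, K)
    return gw.reshape(Cout, Cin_g, kh, kw)


def _pad_hw(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    """Zero-pad the last two axes (faster than np.pad for this case)."""
    if ph == 0 and pw == 0:
        return x
    shape = x.shape[:-2] + (x.shape[-2] + 2 * ph, x.shape[-1] + 2 * pw)
    out = np.zeros(shape, dtype=x.dtype)
    out[..., ph:ph + x.shape[-2], pw:pw + x.shape[-1]] = x
    return out


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev=(), name: str = ""):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = tuple(_prev)
        self.name = name

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            # fresh array in the common single-consumer case; broadcast-safe
            self.grad = np.array(np.broadcast_to(g, self.data.shape), dtype=self.data.dtype) \
                if g.shape != self.data.shape else g.astype(self.data.dtype, copy=False)
        else:
            self.grad = self.grad + g

    def _wrap(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        arr = np.asarray(other)
        if arr.ndim == 0:
            # keep python scalars from promoting a float32 graph to float64
            arr = arr.astype(self.data.dtype)
        return Tensor(arr)

    def _make(self, data, prev, backward) -> "Tensor":
        req = any(p.requires_grad for p in prev)
        out = Tensor(data, requires_grad=req, _prev=prev if req else ())
        if req:
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- shaping -----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._make(out_data, (self,), backward)

    def transpose(self, axes) -> "Tensor":
        inv = np.argsort(axes)
        out_data = np.transpose(self.data, axes)

        def backward(g):
            if self.requires_grad:
                self._accum(np.transpose(g, inv))

        return self._make(out_data, (self,), backward)

    def pad2d(self, ph: int, pw: int) -> "Tensor":
        """Zero-pad the last two axes symmetrically."""
        if ph == 0 and pw == 0:
            return self
        out_data = _pad_hw(self.data, ph, pw)
        H, W = self.data.shape[-2:]

        def backward(g):
            if self.requires_grad:
                sl = (Ellipsis, slice(ph, ph + H), slice(pw, pw + W))
                self._accum(g[sl])

        return self._make(out_data, (self,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int | tuple, keepdims: bool = False) -> "Tensor":
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_data)
        # ties share the gradient equally, keeping backward deterministic
        nmax = mask.sum(axis=axis, keepdims=True)
        res = out_data if keepdims else np.squeeze(out_data, axis=axis)

        def backward(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis) if isinstance(axis, int) else np.reshape(
                    g, nmax.shape)
            self._accum(mask * (g / nmax))

        return self._make(res, (self,), backward)

    # -- nonlinearities ----------------------------------------------------
    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        return self._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def log_softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        logsum = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - logsum
        softmax = np.exp(out_data)

        def backward(g):
            if self.requires_grad:
                self._accum(g - softmax * g.sum(axis=axis, keepdims=True))

        return self._make(out_data, (self,), backward)

    # -- convolution -------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               padding: tuple[int, int] = (0, 0), groups: int = 1) -> "Tensor":
        """Cross-correlation of an (B, Cin, H, W) map with (Cout, Cin/g, kh, kw).

        Stride is 1 (the architecture never strides); padding is symmetric
        zero-padding of the spatial axes.  The backward pass for the input
        reuses the forward primitive (full correlation with flipped,
        channel-transposed kernels).
        """
        x = self.pad2d(*padding) if padding != (0, 0) else self
        xd = x.data
        B, Cin, H, W = xd.shape
        Cout, Cin_g, kh, kw = weight.data.shape
        if Cin != Cin_g * groups or Cout % groups:
            raise ValueError(
                f"conv2d shape mismatch: input {Cin} channels, weight expects "
                f"{Cin_g}x{groups} (groups), out {Cout}")
        Ho, Wo = H - kh + 1, W - kw + 1
        if Ho <= 0 or Wo <= 0:
            raise ValueError(f"kernel ({kh},{kw}) larger than padded input ({H},{W})")

        full_height = (kh == H and kw == 1)
        if full_height:
            # electrode-collapsing convolutions (Ho == 1): plain contractions
            xg = xd.reshape(B, groups, Cin_g, H, W)
            wgr = weight.data.reshape(groups, Cout // groups, Cin_g, kh)
            out_data = np.einsum("bgihw,goih->bgow", xg, wgr,
                                 optimize=True).reshape(B, Cout, 1, W)
        else:
            out_data = _corr2d(xd, weight.data, groups)
        if bias is not None:
            out_data += bias.data.reshape(1, Cout, 1, 1)

        def backward(g):
            if full_height:
                xg = xd.reshape(B, groups, Cin_g, H, W)
                wgr = weight.data.reshape(groups, Cout // groups, Cin_g, kh)
                gg = g.reshape(B, groups, Cout // groups, W)
                if weight.requires_grad:
                    gw = np.einsum("bgihw,bgow->goih", xg, gg, optimize=True)
                    weight._accum(gw.reshape(Cout, Cin_g, kh, kw))
                if x.requires_grad:
                    gx = np.einsum("bgow,goih->bgihw", gg, wgr, optimize=True)
                    x._accum(np.ascontiguousarray(gx).reshape(B, Cin, H, W))
            else:
                if weight.requires_grad:
                    weight._accum(_corr2d_grad_w(xd, g, (kh, kw), groups))
                if x.requires_grad:
                    gpad = _pad_hw(g, kh - 1, kw - 1)
                    # regroup: (Cout, Cin_g, kh, kw) -> (Cin, Cout_g, kh, kw)
                    w2 = weight.data.reshape(groups, Cout // groups, Cin_g, kh, kw)
                    w2 = w2.transpose(0, 2, 1, 3, 4).reshape(Cin, Cout // groups, kh, kw)
                    x._accum(_corr2d(gpad, w2[:, :, ::-1, ::-1], groups))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))

        prev = [p for p in (x, weight, bias) if p is not None]
        out = self._make(out_data, tuple(prev), backward)
        return out

    def avg_pool2d(self, kernel: tuple[int, int]) -> "Tensor":
        """Non-overlapping average pooling; trailing remainder is dropped."""
        kh, kw = kernel
        B, C, H, W = self.data.shape
        Ho, Wo = H // kh, W // kw
        xt = self.data[:, :, :Ho * kh, :Wo * kw].reshape(B, C, Ho, kh, Wo, kw)
        out_data = xt.mean(axis=(3, 5))

        def backward(g):
            if not self.requires_grad:
                return
            gx = np.zeros_like(self.data)
            gexp = np.repeat(np.repeat(g, kh, axis=2), kw, axis=3) / (kh * kw)
            gx[:, :, :Ho * kh, :Wo * kw] = gexp
            self._accum(gx)

        return self._make(out_data, (self,), backward)

    # -- graph walk ----------------------------------------------------------
    def backward(self, grad=None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concatenate(tensors: list[Tensor], axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(out_data, requires_grad=req, _prev=tuple(tensors) if req else ())
    if req:
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])

        out._backward = backward
    return out
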