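"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is deliberately small: just the primitives needed by the regression
network (1-D grouped convolution, average pooling, dense products, the
usual pointwise nonlinearities and reductions). Shapes follow NumPy
broadcasting; gradients of broadcast operands are summed back to the
operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    """An ndarray plus a backward closure on a dynamically built tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += _unbroadcast(grad, self.data.shape)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data ** 2))

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def matmul(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accum(np.swapaxes(self.data, -1, -2) @ g)

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- pointwise ------------------------------------------------------------
    def square(self):
        def backward(g):
            if self.requires_grad:
                self._accum(2.0 * self.data * g)

        return self._make(self.data ** 2, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * sign)

        return self._make(np.abs(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return self._make(out_data, (self,), backward)

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(range(self.ndim))[::-1]
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(out_data, (self,), backward)

    def flip(self, axis: int):
        out_data = np.flip(self.data, axis=axis)

        def backward(g):
            if self.requires_grad:
                self._accum(np.flip(g, axis=axis))

        return self._make(out_data, (self,), backward)

    # -- convolution / pooling primitives -------------------------------------
    def conv1d(self, weight: "Tensor", groups: int = 1,
               pad: tuple[int, int] = (0, 0)) -> "Tensor":
        """Grouped 1-D cross-correlation, stride 1, zero padding, no bias.

        self: [N, C_in, L]; weight: [C_out, C_in // groups, K]
        returns [N, C_out, L + pad[0] + pad[1] - K + 1].
        """
        if pad != (0, 0):
            padded = self._zero_pad_time(pad)
            return padded.conv1d(weight, groups=groups)
        x, w = self.data, weight.data
        n, c_in, length = x.shape
        c_out, c_in_g, k = w.shape
        if c_in % groups or c_out % groups or c_in // groups != c_in_g:
            raise ValueError("incompatible conv1d group geometry")
        l_out = length - k + 1
        if l_out <= 0:
            raise ValueError("kernel longer than input")
        # im2col view: [N, C_in, L_out, K]
        cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
        out = np.empty((n, c_out, l_out))
        og = c_out // groups
        for gidx in range(groups):
            ci = slice(gidx * c_in_g, (gidx + 1) * c_in_g)
            co = slice(gidx * og, (gidx + 1) * og)
            # [N, Cg, L_out, K] x [Og, Cg, K] -> [N, Og, L_out]
            out[:, co] = np.einsum("nclk,ock->nol", cols[:, ci], w[co],
                                   optimize=True)

        def backward(g):
            if weight.requires_grad:
                gw = np.empty_like(w)
                for gi in range(groups):
                    ci = slice(gi * c_in_g, (gi + 1) * c_in_g)
                    co = slice(gi * og, (gi + 1) * og)
                    gw[co] = np.einsum("nclk,nol->ock", cols[:, ci], g[:, co],
                                       optimize=True)
                weight._accum(gw)
            if self.requires_grad:
                # full correlation of grad with flipped kernels
                gpad = np.pad(g, ((0, 0), (0, 0), (k - 1, k - 1)))
                gcols = np.lib.stride_tricks.sliding_window_view(gpad, k, axis=2)
                gx = np.empty_like(x)
                wf = w[:, :, ::-1]
                for gi in range(groups):
                    ci = slice(gi * c_in_g, (gi + 1) * c_in_g)
                    co = slice(gi * og, (gi + 1) * og)
                    gx[:, ci] = np.einsum("nolk,ock->ncl", gcols[:, co], wf[co],
                                          optimize=True)
                self._accum(gx)

        return self._make(out, (self, weight), backward)

    def _zero_pad_time(self, pad: tuple[int, int]) -> "Tensor":
        left, right = pad
        out_data = np.pad(self.data, ((0, 0), (0, 0), (left, right)))

        def backward(g):
            if self.requires_grad:
                stop = g.shape[2] - right if right else None
                self._accum(g[:, :, left:stop])

        return self._make(out_data, (self,), backward)

    def avg_pool1d(self, kernel: int, stride: int) -> "Tensor":
        """[N, C, L] -> [N, C, floor((L - kernel) / stride) + 1]."""
        x = self.data
        n, c, length = x.shape
        l_out = (length - kernel) // stride + 1
        if l_out <= 0:
            raise ValueError("pool window longer than input")
        windows = np.lib.stride_tricks.sliding_window_view(x, kernel, axis=2)
        out = windows[:, :, ::stride].mean(axis=-1)

        def backward(g):
            if not self.requires_grad:
                return
            gx = np.zeros_like(x)
            scale = 1.0 / kernel
            for j in range(l_out):
                s = j * stride
                gx[:, :, s:s + kernel] += g[:, :, j:j + 1] * scale
            self._accum(gx)

        return self._make(out, (self,), backward)

    # -- graph traversal ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires scalar output")
            grad = np.ones_like(self.data)
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None or node._backward is None:
                if g is not None and node.requires_grad and node._backward is None:
                    node._accum(g)
                continue
            # route through _accum on leaves; interior nodes just run closures.
            # parents may repeat (e.g. t * t), so dedupe by identity.
            parents = list({id(p): p for p in node._prev}.values())
            saved = {}
            for p in parents:
                saved[id(p)] = p.grad
                p.grad = None
            node._backward(g)
            for p in parents:
                contrib = p.grad
                p.grad = saved[id(p)]
                if contrib is None:
                    continue
                if p._backward is None:
                    # leaf: accumulate persistently
                    if p.grad is None:
                        p.grad = np.zeros_like(p.data)
                    p.grad += contrib
                else:
                    grads[id(p)] = grads.get(id(p), 0.0) + contrib


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)

        def backward(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * g.ndim
                    idx[axis] = slice(a, b)
                    t._accum(g[tuple(idx)])

        out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)

        def backward(g):
            parts = np.moveaxis(g, axis, 0)
            for t, part in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(part)

        out._backward = backward
    return out
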