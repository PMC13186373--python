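"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model only needs a handful of dense operations (matmul, bias add, ReLU,
row stacking/slicing, scalar combination) plus multiplication by *constant*
sparse adjacency matrices, so a tiny tape-based engine is both sufficient and
keeps the package free of a deep-learning framework dependency.  All values
are float64 so that finite-difference gradient checks are meaningful.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "constant",
    "matmul",
    "matmul_t",
    "spmm",
    "add",
    "add_bias",
    "relu",
    "vstack",
    "rows",
    "scale",
    "half_mse",
    "backward",
]


class Tensor:
    """A node in the computation graph.

    ``value`` is a numpy array (scalars are 0-d arrays); ``grad`` is filled in
    by :func:`backward`.  Leaf tensors (parameters, constants) have no
    parents.
    """

    __slots__ = ("value", "grad", "_parents", "_bwd")

    def __init__(
        self,
        value: np.ndarray,
        parents: Sequence["Tensor"] = (),
        bwd: Callable[[np.ndarray], None] | None = None,
    ):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._bwd = bwd

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, leaf={self._bwd is None})"


def constant(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=np.float64))


def _acc(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = np.zeros_like(t.value)
    t.grad += g


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_val = a.value @ b.value

    def bwd(g: np.ndarray) -> None:
        _acc(a, g @ b.value.T)
        _acc(b, a.value.T @ g)

    return Tensor(out_val, (a, b), bwd)


def matmul_t(a: Tensor, b: Tensor) -> Tensor:
    """``a @ b.T`` — used for inner-product interaction scores."""
    out_val = a.value @ b.value.T

    def bwd(g: np.ndarray) -> None:
        _acc(a, g @ b.value)
        _acc(b, g.T @ a.value)

    return Tensor(out_val, (a, b), bwd)


def spmm(S, x: Tensor) -> Tensor:
    """Multiply by a constant (non-trainable) sparse matrix: ``S @ x``."""
    S = sp.csr_matrix(S)
    out_val = S @ x.value
    St = S.T.tocsr()

    def bwd(g: np.ndarray) -> None:
        _acc(x, St @ g)

    return Tensor(out_val, (x,), bwd)


def add(*xs: Tensor) -> Tensor:
    out_val = xs[0].value.copy()
    for x in xs[1:]:
        out_val = out_val + x.value

    def bwd(g: np.ndarray) -> None:
        for x in xs:
            _acc(x, g)

    return Tensor(out_val, xs, bwd)


def add_bias(x: Tensor, b: Tensor) -> Tensor:
    """Add a row vector ``b`` to every row of ``x``."""
    out_val = x.value + b.value

    def bwd(g: np.ndarray) -> None:
        _acc(x, g)
        _acc(b, g.sum(axis=0))

    return Tensor(out_val, (x, b), bwd)


def relu(x: Tensor) -> Tensor:
    out_val = np.maximum(x.value, 0.0)
    mask = x.value > 0

    def bwd(g: np.ndarray) -> None:
        _acc(x, g * mask)

    return Tensor(out_val, (x,), bwd)


def vstack(xs: Sequence[Tensor]) -> Tensor:
    out_val = np.vstack([x.value for x in xs])
    offsets = np.cumsum([0] + [x.value.shape[0] for x in xs])

    def bwd(g: np.ndarray) -> None:
        for x, s, e in zip(xs, offsets[:-1], offsets[1:]):
            _acc(x, g[s:e])

    return Tensor(out_val, tuple(xs), bwd)


def rows(x: Tensor, start: int, stop: int) -> Tensor:
    out_val = x.value[start:stop]

    def bwd(g: np.ndarray) -> None:
        full = np.zeros_like(x.value)
        full[start:stop] = g
        _acc(x, full)

    return Tensor(out_val, (x,), bwd)


def scale(x: Tensor, c: float) -> Tensor:
    out_val = x.value * c

    def bwd(g: np.ndarray) -> None:
        _acc(x, g * c)

    return Tensor(out_val, (x,), bwd)


def half_mse(pred: Tensor, target: np.ndarray, keep: np.ndarray | None = None) -> Tensor:
    """``0.5 * mean((target - pred)**2)`` over entries where ``keep`` is True.

    ``keep=None`` keeps every entry.  Raises if the keep mask excludes the
    whole matrix, since the mean would be undefined.
    """
    target = np.asarray(target, dtype=np.float64)
    if keep is None:
        keep = np.ones(target.shape, dtype=bool)
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise ValueError("half_mse: keep mask excludes every entry")
    diff = np.where(keep, pred.value - target, 0.0)
    out_val = 0.5 * float((diff**2).sum()) / n_keep

    def bwd(g: np.ndarray) -> None:
        _acc(pred, (float(g) / n_keep) * diff)

    return Tensor(np.asarray(out_val), (pred,), bwd)


def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order


def backward(root: Tensor) -> None:
    """Accumulate gradients of ``root`` (any shape) into every ancestor."""
    order = _toposort(root)
    root.grad = np.ones_like(root.value)
    for node in reversed(order):
        if node._bwd is not None and node.grad is not None:
            node._bwd(node.grad)
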