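"""Vectorized forward-mode dual numbers.

Every IoU-family loss in this package is an elementwise composition of
arithmetic, min/max selections and a handful of transcendentals over the four
predicted-box parameters. Forward-mode differentiation with a fixed tangent
width of 4 (one direction per box parameter) therefore gives exact gradients
at roughly the cost of five value evaluations, fully vectorized over a batch
of box pairs.

A :class:`Dual` carries ``v`` with an arbitrary batch shape ``S`` and ``g``
with shape ``S + (4,)``. Plain numbers / ndarrays mix in as constants with
zero tangent. Selection primitives (``maximum``, ``minimum``, ``where``)
propagate the tangent of the chosen branch, which yields the almost-everywhere
derivative of the piecewise-smooth losses; exact ties resolve to the first
argument.
"""

from __future__ import annotations

import numpy as np

NTAN = 4  # tangent width: d/dx_c, d/dy_c, d/dw, d/dh of the predicted box


def _v(x):
    return x.v if isinstance(x, Dual) else np.asarray(x, dtype=float)


def _g(x, batch_shape):
    if isinstance(x, Dual):
        return x.g
    return np.zeros(batch_shape + (NTAN,))


class Dual:
    __slots__ = ("v", "g")

    # defer mixed ndarray <op> Dual expressions to the reflected Dual ops
    __array_ufunc__ = None

    def __init__(self, v, g):
        self.v = np.asarray(v, dtype=float)
        self.g = np.asarray(g, dtype=float)

    @classmethod
    def seed(cls, params):
        """Seed the 4 box parameters ``params`` (shape ``S + (4,)``) as duals.

        Returns four Duals (x_c, y_c, w, h), each with the identity tangent in
        its own direction.
        """
        params = np.asarray(params, dtype=float)
        batch = params.shape[:-1]
        out = []
        for i in range(NTAN):
            g = np.zeros(batch + (NTAN,))
            g[..., i] = 1.0
            out.append(cls(params[..., i], g))
        return out

    # -- arithmetic -------------------------------------------------------
    def __add__(self, o):
        return Dual(self.v + _v(o), self.g + _g(o, self.v.shape))

    __radd__ = __add__

    def __neg__(self):
        return Dual(-self.v, -self.g)

    def __sub__(self, o):
        return Dual(self.v - _v(o), self.g - _g(o, self.v.shape))

    def __rsub__(self, o):
        return Dual(_v(o) - self.v, -self.g)

    def __mul__(self, o):
        ov, og = _v(o), _g(o, self.v.shape)
        return Dual(self.v * ov, self.g * ov[..., None] + og * self.v[..., None])

    __rmul__ = __mul__

    def __truediv__(self, o):
        ov, og = _v(o), _g(o, self.v.shape)
        v = self.v / ov
        g = (self.g * ov[..., None] - og * self.v[..., None]) / (ov ** 2)[..., None]
        return Dual(v, g)

    def __rtruediv__(self, o):
        ov = _v(o)
        v = ov / self.v
        g = -self.g * (ov / self.v ** 2)[..., None]
        return Dual(v, g)

    def __pow__(self, n):
        if not isinstance(n, (int, float)):
            raise TypeError("dual ** dual is not supported")
        v = self.v ** n
        g = self.g * (n * self.v ** (n - 1))[..., None]
        return Dual(v, g)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Dual(v={self.v!r})"


# -- elementwise functions ------------------------------------------------

def value(x):
    """Primal value of a Dual or plain array."""
    return _v(x)


def sqrt(x):
    if not isinstance(x, Dual):
        return np.sqrt(x)
    v = np.sqrt(x.v)
    dv = np.where(v > 0, 0.5 / np.where(v > 0, v, 1.0), 0.0)
    return Dual(v, x.g * dv[..., None])


def exp(x):
    if not isinstance(x, Dual):
        return np.exp(x)
    v = np.exp(x.v)
    return Dual(v, x.g * v[..., None])


def absolute(x):
    if not isinstance(x, Dual):
        return np.abs(x)
    return Dual(np.abs(x.v), x.g * np.sign(x.v)[..., None])


def arctan(x):
    if not isinstance(x, Dual):
        return np.arctan(x)
    return Dual(np.arctan(x.v), x.g * (1.0 / (1.0 + x.v ** 2))[..., None])


def maximum(a, b):
    av, bv = _v(a), _v(b)
    if not isinstance(a, Dual) and not isinstance(b, Dual):
        return np.maximum(av, bv)
    take_a = av >= bv  # ties -> first argument
    batch = np.broadcast_shapes(av.shape, bv.shape)
    v = np.where(take_a, av, bv)
    g = np.where(take_a[..., None], _g(a, batch), _g(b, batch))
    return Dual(v, g)


def minimum(a, b):
    av, bv = _v(a), _v(b)
    if not isinstance(a, Dual) and not isinstance(b, Dual):
        return np.minimum(av, bv)
    take_a = av <= bv
    batch = np.broadcast_shapes(av.shape, bv.shape)
    v = np.where(take_a, av, bv)
    g = np.where(take_a[..., None], _g(a, batch), _g(b, batch))
    return Dual(v, g)


def where(cond, a, b):
    cond = np.asarray(cond, dtype=bool)
    av, bv = _v(a), _v(b)
    if not isinstance(a, Dual) and not isinstance(b, Dual):
        return np.where(cond, av, bv)
    batch = np.broadcast_shapes(cond.shape, av.shape, bv.shape)
    v = np.where(cond, av, bv)
    g = np.where(cond[..., None], _g(a, batch), _g(b, batch))
    return Dual(v, g)
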