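"""Affine moment parameterization of the information matrix.

The information matrix of an order-``n`` design, ``M = G'G = sum_i
a(g_i) a(g_i)'``, depends on the design points only through their
even-degree-``2n`` moments.  Entry ``(k, l)`` of ``a a'`` is a degree-``2n``
monomial times the product of two multinomial weights, so ``M`` is affine
in the vector ``q`` of distinct monomial sums: ``M(q) = sum_j q_j M_j``.
For order 4 there are 45 degree-8 monomials; for order 2 there are 15
degree-4 monomials.

Moment ordering (order 4) groups the monomials by symmetry class, each
class sorted by descending exponent triple:

* ``q1..q3``   pure       -- ``x^8``-type (q1 = sum x_i^8)
* ``q4..q9``   mixed62    -- ``x^6 y^2``-type
* ``q10..q12`` mixed44    -- ``x^4 y^4``-type (q10 = sum x_i^4 y_i^4)
* ``q13..q15`` mixed422   -- ``x^4 y^2 z^2``-type
* ``q16..q45`` odd        -- any monomial with an odd exponent

The weight vector ``u`` holds the multinomial coefficients of the
expansion of ``(x^2+y^2+z^2)^n``; on unit vectors ``u'q = N`` identically,
which is the convexified substitute for the per-point unit-norm
constraints.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .tensor_model import (
    DirectionSet,
    SUPPORTED_ORDERS,
    monomial_exponents,
    monomial_weights,
    n_coefficients,
)

__all__ = [
    "MomentBasis",
    "MomentVector",
    "CLASS_NAMES",
    "build_basis",
    "moments_from_points",
    "assemble",
]

#: symmetry-class names in storage order, per supported order
CLASS_NAMES = {
    4: ("pure", "mixed62", "mixed44", "mixed422", "odd"),
    2: ("pure", "mixed22", "odd"),
}


def _sorted_class(degree: int, pattern: tuple[int, ...]) -> list[tuple[int, int, int]]:
    """All degree-``degree`` exponent triples whose multiset of exponents is
    ``pattern``, in descending lexicographic order."""
    out = {
        p
        for p in itertools.permutations(pattern)
    }
    return sorted(out, reverse=True)


@lru_cache(maxsize=None)
def _moment_monomials(order: int):
    """Class-blocked list of degree-``2*order`` exponent triples and labels."""
    degree = 2 * order
    if order == 4:
        blocks = [
            ("pure", _sorted_class(degree, (8, 0, 0))),
            ("mixed62", _sorted_class(degree, (6, 2, 0))),
            ("mixed44", _sorted_class(degree, (4, 4, 0))),
            ("mixed422", _sorted_class(degree, (4, 2, 2))),
        ]
    elif order == 2:
        blocks = [
            ("pure", _sorted_class(degree, (4, 0, 0))),
            ("mixed22", _sorted_class(degree, (2, 2, 0))),
        ]
    else:
        raise ValueError(f"unsupported order {order}")
    even = {t for _, blk in blocks for t in blk}
    odd = sorted(
        (
            t
            for t in (
                (i, j, degree - i - j)
                for i in range(degree + 1)
                for j in range(degree - i + 1)
            )
            if t not in even
        ),
        reverse=True,
    )
    blocks.append(("odd", odd))
    monomials: list[tuple[int, int, int]] = []
    labels: list[str] = []
    for name, blk in blocks:
        monomials.extend(blk)
        labels.extend([name] * len(blk))
    return tuple(monomials), tuple(labels)


@dataclass(frozen=True)
class MomentBasis:
    """Basis matrices and bookkeeping of the affine map ``q -> M(q)``.

    Attributes
    ----------
    monomials : (J, 3) exponent triples of the distinct moments.
    labels : per-moment symmetry-class name.
    basis_mats : (J, m, m) integer-valued symmetric matrices ``M_j``.
    u : (J,) multinomial weights of ``(x^2+y^2+z^2)^order``; zero on the
        odd classes.
    """

    order: int
    monomials: np.ndarray
    labels: tuple[str, ...]
    basis_mats: np.ndarray
    u: np.ndarray

    @property
    def n_moments(self) -> int:
        return self.monomials.shape[0]

    def class_indices(self, name: str) -> np.ndarray:
        return np.array([i for i, lbl in enumerate(self.labels) if lbl == name])


@lru_cache(maxsize=None)
def build_basis(order: int = 4) -> MomentBasis:
    """Derive the moment basis by exact expansion of ``a(g) a(g)'``.

    Every entry of every ``M_j`` is a product of two multinomial weights,
    hence a nonnegative integer.  The construction guarantees
    ``M(moments_from_points(P)) == G'G`` for any point set ``P``.
    """
    if order not in SUPPORTED_ORDERS:
        raise ValueError(f"unsupported order {order}")
    monomials, labels = _moment_monomials(order)
    index = {t: j for j, t in enumerate(monomials)}
    m = n_coefficients(order)
    exps = monomial_exponents(order)
    wts = monomial_weights(order)
    mats = np.zeros((len(monomials), m, m))
    for k in range(m):
        for l in range(m):
            tot = tuple(exps[k] + exps[l])
            mats[index[tot], k, l] += wts[k] * wts[l]
    u = np.zeros(len(monomials))
    for j, (i, jj, k) in enumerate(monomials):
        if i % 2 or jj % 2 or k % 2:
            continue
        a, b, c = i // 2, jj // 2, k // 2
        u[j] = math.factorial(order) // (
            math.factorial(a) * math.factorial(b) * math.factorial(c)
        )
    mats.flags.writeable = False
    u.flags.writeable = False
    mono_arr = np.array(monomials, dtype=int)
    mono_arr.flags.writeable = False
    return MomentBasis(order, mono_arr, labels, mats, u)


@dataclass(frozen=True)
class MomentVector:
    """A moment vector ``q`` with its symmetry-class labels."""

    order: int
    q: np.ndarray

    def __post_init__(self) -> None:
        basis = build_basis(self.order)
        arr = np.asarray(self.q, dtype=float).ravel()
        if arr.size != basis.n_moments:
            raise ValueError(
                f"order-{self.order} moment vector has {basis.n_moments} "
                f"entries, got {arr.size}"
            )
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "q", arr)

    @property
    def labels(self) -> tuple[str, ...]:
        return build_basis(self.order).labels

    def class_values(self, name: str) -> np.ndarray:
        """Entries of ``q`` belonging to symmetry class ``name``."""
        idx = build_basis(self.order).class_indices(name)
        return self.q[idx]

    def total(self) -> float:
        """``u'q`` -- equals N for moments of N unit vectors."""
        return float(build_basis(self.order).u @ self.q)

    def __add__(self, other: "MomentVector") -> "MomentVector":
        if self.order != other.order:
            raise ValueError("cannot add moment vectors of different orders")
        return MomentVector(self.order, self.q + other.q)

    def __mul__(self, w: float) -> "MomentVector":
        return MomentVector(self.order, self.q * float(w))

    __rmul__ = __mul__


def moments_from_points(dirs: DirectionSet, order: int = 4) -> MomentVector:
    """Moment vector of a design: ``q_j = sum_i monomial_j(g_i)``."""
    basis = build_basis(order)
    pts = dirs.points
    q = np.prod(pts[:, None, :] ** basis.monomials[None, :, :], axis=2).sum(axis=0)
    return MomentVector(order, q)


def assemble(q, order: int | None = None) -> np.ndarray:
    """Assemble the information matrix ``M(q) = sum_j q_j M_j``."""
    if isinstance(q, MomentVector):
        order = q.order
        vec = q.q
    else:
        if order is None:
            raise ValueError("order is required when q is a plain array")
        vec = np.asarray(q, dtype=float).ravel()
    basis = build_basis(order)
    return np.tensordot(vec, basis.basis_mats, axes=1)
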