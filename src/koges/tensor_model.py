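"""Even-order symmetric tensor ADC model, design matrices and least squares.

Diffusion MRI measures the apparent diffusion coefficient (ADC) profile
``d(g)`` on the unit sphere through the Stejskal-Tanner attenuation
``S(g) = S0 * exp(-b * d(g))``.  For even tensor order ``n`` the profile is
modelled as ``d(g) = t . a(g)`` where ``t`` holds the
``(n+1)(n+2)/2`` distinct tensor entries and ``a(g)`` is the vector of
degree-``n`` monomials in the gradient direction ``g = (x, y, z)``, each
carrying its multinomial multiplicity.  Given log-attenuation measurements
along ``N`` directions the tensor is recovered by ordinary least squares;
the conditioning of that fit is what the K-optimal design machinery in
:mod:`koges.sdp_design` optimizes.

The order-4 monomial ordering used throughout the package is ``z^4`` first
and ``x^4`` last::

    [z^4, 4yz^3, 6y^2z^2, 4y^3z, y^4, 4xz^3, 12xyz^2, 12xy^2z, 4xy^3,
     6x^2z^2, 12x^2yz, 6x^2y^2, 4x^3z, 4x^3y, x^4]

and for order 2 it is ``[x^2, y^2, z^2, 2xy, 2xz, 2yz]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "SUPPORTED_ORDERS",
    "DirectionSet",
    "TensorCoeffs",
    "AcquisitionParams",
    "ConditionNumbers",
    "SingularDesignError",
    "n_coefficients",
    "monomial_exponents",
    "monomial_weights",
    "monomial_vector",
    "design_matrix",
    "fit_tensor",
    "adc",
    "embed_second_order",
    "condition_numbers",
]

SUPPORTED_ORDERS = (2, 4)

#: exponent triples (ex, ey, ez) of the monomial vector a(g), in the fixed
#: package ordering (order 4: z^4 first, x^4 last; order 2: x^2 first).
_EXPONENTS = {
    4: (
        (0, 0, 4), (0, 1, 3), (0, 2, 2), (0, 3, 1), (0, 4, 0),
        (1, 0, 3), (1, 1, 2), (1, 2, 1), (1, 3, 0),
        (2, 0, 2), (2, 1, 1), (2, 2, 0),
        (3, 0, 1), (3, 1, 0),
        (4, 0, 0),
    ),
    2: (
        (2, 0, 0), (0, 2, 0), (0, 0, 2),
        (1, 1, 0), (1, 0, 1), (0, 1, 1),
    ),
}


def n_coefficients(order: int) -> int:
    """Number of distinct entries of a symmetric order-``order`` tensor."""
    _check_order(order)
    return (order + 1) * (order + 2) // 2


def _check_order(order: int) -> None:
    if order not in SUPPORTED_ORDERS:
        raise ValueError(
            f"unsupported tensor order {order!r}: only even orders "
            f"{SUPPORTED_ORDERS} are implemented"
        )


def monomial_exponents(order: int) -> np.ndarray:
    """Exponent triples of ``a(g)`` as an ``(m, 3)`` integer array."""
    _check_order(order)
    return np.array(_EXPONENTS[order], dtype=int)


def monomial_weights(order: int) -> np.ndarray:
    """Multinomial multiplicities ``order!/(ex! ey! ez!)`` of ``a(g)``."""
    exps = monomial_exponents(order)
    fact = math.factorial(order)
    return np.array(
        [fact // (math.factorial(i) * math.factorial(j) * math.factorial(k))
         for i, j, k in exps],
        dtype=float,
    )


class SingularDesignError(ValueError):
    """Raised when a direction set cannot identify the tensor coefficients."""


@dataclass(frozen=True)
class DirectionSet:
    """A gradient encoding scheme: ``N`` unit 3-vectors.

    Parameters
    ----------
    points
        Array-like of shape ``(N, 3)``.
    unit_tol
        Maximum allowed deviation of each row norm from 1.  Direction
        tables printed to few decimals need a loose tolerance (e.g. 1e-3).
    normalize
        If true, rows are rescaled to exact unit norm before validation.
    """

    points: np.ndarray
    unit_tol: float = 1e-6
    normalize: bool = False

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"expected an (N, 3) array, got shape {pts.shape}")
        if pts.shape[0] < 1:
            raise ValueError("a DirectionSet needs at least one direction")
        norms = np.linalg.norm(pts, axis=1)
        if self.normalize:
            if np.any(norms == 0):
                raise ValueError("cannot normalize a zero direction")
            pts = pts / norms[:, None]
        elif np.any(np.abs(norms - 1.0) > self.unit_tol):
            worst = int(np.argmax(np.abs(norms - 1.0)))
            raise ValueError(
                f"direction {worst} has norm {norms[worst]:.6g}, outside "
                f"unit tolerance {self.unit_tol:g}"
            )
        pts.flags.writeable = False
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    def __iter__(self):
        return iter(self.points)

    @property
    def n(self) -> int:
        return len(self)

    def flipped(self, mask: Iterable[bool]) -> "DirectionSet":
        """Return a copy with the directions selected by ``mask`` negated."""
        mask = np.asarray(list(mask), dtype=bool)
        pts = self.points.copy()
        pts[mask] *= -1.0
        return DirectionSet(pts, unit_tol=self.unit_tol)

    @classmethod
    def from_array(cls, points, unit_tol: float = 1e-6,
                   normalize: bool = False) -> "DirectionSet":
        return cls(points, unit_tol=unit_tol, normalize=normalize)


@dataclass(frozen=True)
class TensorCoeffs:
    """Distinct entries of an even-order symmetric diffusion tensor.

    ``coeffs`` follows the package monomial ordering (order 4: the first
    slot multiplies ``z^4``, the last ``x^4``).  Units are diffusivity,
    typically mm^2/s.
    """

    order: int
    coeffs: np.ndarray

    def __post_init__(self) -> None:
        _check_order(self.order)
        c = np.asarray(self.coeffs, dtype=float).ravel()
        m = n_coefficients(self.order)
        if c.size != m:
            raise ValueError(
                f"order-{self.order} tensor needs {m} coefficients, got {c.size}"
            )
        c.flags.writeable = False
        object.__setattr__(self, "coeffs", c)

    def adc(self, g) -> np.ndarray | float:
        """Evaluate the ADC profile ``d(g) = t . a(g)`` at unit vector(s)."""
        return adc(self, g)


@dataclass(frozen=True)
class AcquisitionParams:
    """Stejskal-Tanner acquisition settings.

    b : diffusion weighting in s/mm^2; S0 : unweighted signal (arbitrary
    units); snr : S0/sigma of the Gaussian noise channels underlying the
    Rician magnitude signal.
    """

    b: float = 1500.0
    S0: float = 1.0
    snr: float = 12.5

    def __post_init__(self) -> None:
        if not (self.b > 0 and self.S0 > 0 and self.snr > 0):
            raise ValueError("b, S0 and snr must all be positive")

    @property
    def sigma(self) -> float:
        return self.S0 / self.snr


def monomial_vector(g, order: int = 4) -> np.ndarray:
    """The monomial vector ``a(g)`` for a unit direction ``g``.

    Raises ``ValueError`` if ``g`` is not unit within 1e-6 or the order is
    unsupported.
    """
    _check_order(order)
    g = np.asarray(g, dtype=float).ravel()
    if g.size != 3:
        raise ValueError("g must be a 3-vector")
    nrm = np.linalg.norm(g)
    if abs(nrm - 1.0) > 1e-6:
        raise ValueError(f"g has norm {nrm:.8g}; expected a unit vector")
    exps = monomial_exponents(order)
    return monomial_weights(order) * np.prod(g[None, :] ** exps, axis=1)


def design_matrix(dirs: DirectionSet, order: int = 4) -> np.ndarray:
    """The ``N x m`` design matrix with rows ``a(g_i)``."""
    _check_order(order)
    pts = dirs.points
    exps = monomial_exponents(order)
    # (N, m): product over the three coordinates of point^exponent
    mono = np.prod(pts[:, None, :] ** exps[None, :, :], axis=2)
    return mono * monomial_weights(order)[None, :]


def adc(t: TensorCoeffs, g) -> np.ndarray | float:
    """ADC profile values ``d(g) = t . a(g)`` for one or many unit vectors."""
    garr = np.atleast_2d(np.asarray(g, dtype=float))
    ds = DirectionSet(garr, unit_tol=1e-6)
    vals = design_matrix(ds, t.order) @ t.coeffs
    return float(vals[0]) if np.asarray(g).ndim == 1 else vals


def fit_tensor(log_signals, dirs: DirectionSet, order: int = 4) -> TensorCoeffs:
    """Least-squares tensor estimate from normalized log-attenuations.

    ``log_signals[i]`` is ``-ln(S(g_i)/S0)/b``.  Solves
    ``min_t || s - G t ||^2`` with the closed form ``(G'G)^-1 G' s``.
    """
    s = np.asarray(log_signals, dtype=float).ravel()
    if s.size != len(dirs):
        raise ValueError(f"{s.size} signals for {len(dirs)} directions")
    G = design_matrix(dirs, order)
    m = G.shape[1]
    rank = np.linalg.matrix_rank(G)
    if rank < m:
        raise SingularDesignError(
            f"design of {len(dirs)} directions has rank {rank} < {m}: the "
            f"order-{order} tensor is not identifiable"
        )
    coef, *_ = np.linalg.lstsq(G, s, rcond=None)
    return TensorCoeffs(order, coef)


def embed_second_order(D) -> TensorCoeffs:
    """Embed a symmetric 3x3 tensor ``D`` as an order-4 coefficient vector.

    Uses the identity ``g'Dg = (g'Dg)(g'g)`` on the sphere, so the returned
    ``t`` satisfies ``a(g) . t = g'Dg`` for every unit ``g``.
    """
    D = np.asarray(D, dtype=float)
    if D.shape != (3, 3):
        raise ValueError("D must be 3x3")
    if np.max(np.abs(D - D.T)) > 1e-9:
        raise ValueError("D must be symmetric to 1e-9")
    d11, d22, d33 = D[0, 0], D[1, 1], D[2, 2]
    d12, d13, d23 = D[0, 1], D[0, 2], D[1, 2]
    t = [
        d33, 0.5 * d23, (d33 + d22) / 6.0, 0.5 * d23, d22,
        0.5 * d13, d12 / 6.0, d13 / 6.0, 0.5 * d12,
        (d33 + d11) / 6.0, d23 / 6.0, (d11 + d22) / 6.0,
        0.5 * d13, 0.5 * d12, d11,
    ]
    return TensorCoeffs(4, np.array(t))


@dataclass(frozen=True)
class ConditionNumbers:
    """Condition numbers of a design: ``kappa_G`` is the singular-value
    ratio of G, ``kappa_M = kappa_G**2`` the eigenvalue ratio of
    ``M = G'G``.  ``singular`` flags a rank-deficient design (both values
    are then ``inf``)."""

    kappa_G: float
    kappa_M: float
    singular: bool = False


def condition_numbers(dirs: DirectionSet, order: int = 4) -> ConditionNumbers:
    """Compute ``kappa(G)`` and ``kappa(M)`` of a direction set."""
    G = design_matrix(dirs, order)
    sv = np.linalg.svd(G, compute_uv=False)
    m = G.shape[1]
    if G.shape[0] < m or sv[m - 1] <= sv[0] * np.finfo(float).eps * max(G.shape):
        return ConditionNumbers(np.inf, np.inf, singular=True)
    kG = sv[0] / sv[m - 1]
    return ConditionNumbers(float(kG), float(kG * kG), singular=False)
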