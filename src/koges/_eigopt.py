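"""Smoothed extremal-eigenvalue optimization over affine matrix families.

The K-optimal design problems reduce to minimizing ``lambda_max(M(q))``
subject to ``lambda_min(M(q)) >= 1`` (plus optional linear constraints),
where ``M(q) = sum_j q_j M_j`` is affine.  Extremal eigenvalues are convex
(resp. concave) but nonsmooth exactly where K-optimal solutions live
(clustered eigenvalues), so we optimize exponential soft-max surrogates

    smax_mu(M) =  mu * log sum_a exp(lambda_a / mu)   >= lambda_max
    smin_mu(M) = -mu * log sum_a exp(-lambda_a / mu)  <= lambda_min

with exact gradients (softmax-weighted spectral projectors) and drive the
temperature ``mu`` to zero by continuation.  Since ``smin_mu <= lambda_min``
the constraint ``smin_mu >= 1`` is conservative, and ``smax_mu`` upper
bounds the objective, so every iterate certifies a feasible condition
number; the smoothing gap per stage is at most ``mu * log m``.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

__all__ = ["smoothed_max", "smoothed_min", "minimize_lmax", "maximize_lmin"]


def _eig(mats, q):
    M = np.tensordot(q, mats, axes=1)
    lam, V = np.linalg.eigh(M)
    return lam, V


def _soft_extremum(mats, q, mu, sign):
    """Soft max (sign=+1) or soft min (sign=-1) eigenvalue and gradient."""
    lam, V = _eig(mats, q)
    z = sign * lam / mu
    zmax = z.max()
    e = np.exp(z - zmax)
    s = e.sum()
    val = sign * mu * (zmax + np.log(s))
    w = e / s
    W = (V * w) @ V.T
    grad = mats.reshape(mats.shape[0], -1) @ W.ravel()
    return val, grad


def smoothed_max(mats, q, mu):
    """Soft maximum eigenvalue of ``M(q)`` and its gradient w.r.t. ``q``."""
    return _soft_extremum(mats, q, mu, +1.0)


def smoothed_min(mats, q, mu):
    """Soft minimum eigenvalue of ``M(q)`` and its gradient w.r.t. ``q``."""
    return _soft_extremum(mats, q, mu, -1.0)


_MU_LADDER = (1e-1, 3e-2, 1e-2, 3e-3, 1e-3, 3e-4, 1e-4, 3e-5, 1e-5, 3e-6, 1e-6)


def minimize_lmax(
    mats: np.ndarray,
    q0: np.ndarray,
    *,
    lin_eq: tuple[np.ndarray, float] | None = None,
    mu_ladder=_MU_LADDER,
    maxiter: int = 150,
):
    """Minimize ``lambda_max(M(q))`` s.t. ``lambda_min(M(q)) >= 1``.

    Parameters
    ----------
    mats : (J, m, m) basis matrices.
    q0 : strictly feasible start (rescaled internally so lambda_min > 1).
    lin_eq : optional ``(u, N)`` enforcing ``u @ q == N``; when present the
        start is not rescaled (the constraint fixes the scale).

    Returns ``(q, info)``; the returned point is the continuation iterate
    with the best exact condition number (rescaling -- of ``q``, or of the
    caller's ``c`` -- absorbs sub-1e-3 slack in the lambda_min
    constraint, so kappa is the honest figure of merit across stages).
    """
    mats = np.ascontiguousarray(mats)
    q = np.asarray(q0, dtype=float).copy()
    lam, _ = _eig(mats, q)
    scale = max(abs(lam[-1]), 1.0)
    if lin_eq is None and lam[0] > 0:
        q /= lam[0] * 0.8  # start strictly inside lambda_min >= 1
        lam, _ = _eig(mats, q)
        scale = abs(lam[-1])

    def merit(qq):
        lam_, _ = _eig(mats, qq)
        if lam_[0] <= 0:
            return np.inf
        if lin_eq is not None and lam_[0] < 1.0 - 1e-3:
            return np.inf
        return lam_[-1] / lam_[0]

    best_q, best_merit = q.copy(), merit(q)
    stages = []
    for mu_rel in mu_ladder:
        mu = mu_rel * scale
        cache: dict[bytes, tuple[float, np.ndarray]] = {}

        def con(qq, mu=mu, cache=cache):
            key = qq.tobytes()
            hit = cache.get(key)
            if hit is None:
                v, g = smoothed_min(mats, qq, mu)
                hit = (v - 1.0, g)
                if len(cache) > 64:
                    cache.clear()
                cache[key] = hit
            return hit

        constraints = [
            {"type": "ineq", "fun": lambda qq: con(qq)[0],
             "jac": lambda qq: con(qq)[1]},
        ]
        if lin_eq is not None:
            u, tot = lin_eq
            constraints.append(
                {"type": "eq", "fun": lambda qq: u @ qq - tot,
                 "jac": lambda qq: u}
            )
        res = minimize(
            lambda qq, mu=mu: smoothed_max(mats, qq, mu),
            q,
            jac=True,
            method="SLSQP",
            constraints=constraints,
            options={"maxiter": maxiter, "ftol": 1e-14},
        )
        if np.all(np.isfinite(res.x)):
            q = res.x
            m_new = merit(q)
            if m_new <= best_merit + 1e-14:
                best_q, best_merit = q.copy(), m_new
        lam, _ = _eig(mats, q)
        stages.append({"mu": mu, "status": res.status, "nit": res.nit,
                       "lmin": lam[0], "lmax": lam[-1]})
    q = best_q
    lam, _ = _eig(mats, q)
    info = {
        "lmin": float(lam[0]),
        "lmax": float(lam[-1]),
        "stages": stages,
    }
    return q, info


def maximize_lmin(
    mats: np.ndarray,
    q0: np.ndarray,
    *,
    lin_eq: tuple[np.ndarray, float],
    mu_ladder=_MU_LADDER,
    maxiter: int = 150,
):
    """Maximize ``lambda_min(M(q))`` s.t. ``u @ q == N``.

    Used to decide feasibility of the fixed-c LMI: with ``u'q = N`` fixed,
    ``I <= c M(q)`` is satisfiable iff ``c * max lambda_min >= 1``.
    """
    mats = np.ascontiguousarray(mats)
    q = np.asarray(q0, dtype=float).copy()
    lam, _ = _eig(mats, q)
    scale = max(abs(lam[-1]), 1.0)
    u, tot = lin_eq
    cons = [{"type": "eq", "fun": lambda qq: u @ qq - tot, "jac": lambda qq: u}]
    best_q, best_lmin = q.copy(), lam[0]
    for mu_rel in mu_ladder:
        mu = mu_rel * scale

        def negsmin(qq, mu=mu):
            v, g = smoothed_min(mats, qq, mu)
            return -v, -g

        res = minimize(negsmin, q, jac=True, method="SLSQP",
                       constraints=cons,
                       options={"maxiter": maxiter, "ftol": 1e-14})
        if np.all(np.isfinite(res.x)):
            q = res.x
            lam, _ = _eig(mats, q)
            if lam[0] > best_lmin and abs(u @ q - tot) <= 1e-6 * abs(tot):
                best_q, best_lmin = q.copy(), lam[0]
    return best_q, float(best_lmin)
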