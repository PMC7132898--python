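"""Deterministic centred multivariate-normal box probabilities (k <= 3).

The versatile tests need P(|N_1| <= z, ..., |N_k| <= z) for a correlated
standard normal vector, to absolute accuracy ~1e-9, tens of thousands of
times per simulation study.  General-purpose quasi-Monte-Carlo integrators
are too slow and not bit-reproducible, so the probability is computed in
closed form: Owen's T function gives the bivariate CDF, and the trivariate
case conditions on the first component and integrates the conditional
bivariate box with Gauss-Legendre quadrature (the integrand is analytic).

Components correlated at |rho| ~ 1 with another are redundant inside a
symmetric box (|N_a| = |N_b| almost surely) and are dropped first; this is
the numerically delicate case in practice, e.g. logrank vs early weights
under a low event rate where the weights barely deviate from 1.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

__all__ = ["symmetric_box_probability"]

_RHO_TOL = 1e-9

_GAUSS_CACHE: dict = {}


def _leggauss(nodes: int):
    if nodes not in _GAUSS_CACHE:
        _GAUSS_CACHE[nodes] = np.polynomial.legendre.leggauss(nodes)
    return _GAUSS_CACHE[nodes]


def _phi2(h, k, rho):
    """Bivariate standard normal CDF P(X <= h, Y <= k), vectorized.

    Owen (1956): Phi2 = (Phi(h) + Phi(k))/2 - T(h, a_h) - T(k, a_k) - beta,
    beta = 1/2 when hk < 0 (or hk = 0 with h + k < 0).
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    out = np.empty(h.shape, dtype=float)

    near = np.abs(rho) >= 1.0 - _RHO_TOL
    if np.any(near):
        pos = near & (rho > 0)
        out[pos] = ndtr(np.minimum(h, k))[pos]
        neg = near & (rho <= 0)
        out[neg] = np.maximum(0.0, ndtr(h) + ndtr(k) - 1.0)[neg]

    gen = ~near
    if np.any(gen):
        hg, kg, rg = h[gen], k[gen], rho[gen]
        s = np.sqrt(1.0 - rg * rg)
        with np.errstate(divide="ignore", invalid="ignore"):
            ah = (kg - rg * hg) / (hg * s)
            ak = (hg - rg * kg) / (kg * s)
        # limits at h -> 0: a -> sign(k) * inf, T(0, +-inf) = +-1/4
        ah = np.where(hg == 0.0, np.sign(kg) * np.inf, ah)
        ak = np.where(kg == 0.0, np.sign(hg) * np.inf, ak)
        both_zero = (hg == 0.0) & (kg == 0.0)
        val = (
            0.5 * (ndtr(hg) + ndtr(kg))
            - owens_t(hg, np.where(np.isfinite(ah), ah, np.sign(ah)))
            - owens_t(kg, np.where(np.isfinite(ak), ak, np.sign(ak)))
        )
        # owens_t(x, +-inf): recompute exactly where a was infinite
        inf_h = ~np.isfinite(ah)
        if np.any(inf_h):
            val[inf_h] = (
                0.5 * (ndtr(hg) + ndtr(kg))
                - np.sign(ah) * _owens_t_inf(hg)
                - owens_t(kg, ak)
            )[inf_h]
        inf_k = ~np.isfinite(ak)
        if np.any(inf_k):
            val[inf_k] = (
                0.5 * (ndtr(hg) + ndtr(kg))
                - owens_t(hg, ah)
                - np.sign(ak) * _owens_t_inf(kg)
            )[inf_k]
        beta = np.where(
            (hg * kg < 0) | ((hg * kg == 0) & (hg + kg < 0)), 0.5, 0.0
        )
        val = val - beta
        val[both_zero] = 0.25 + np.arcsin(np.clip(rg, -1, 1))[both_zero] / (
            2 * np.pi
        )
        out[gen] = val
    return np.clip(out, 0.0, 1.0)


def _owens_t_inf(h):
    """T(h, +inf) = Phi(-|h|)/2."""
    return 0.5 * ndtr(-np.abs(np.asarray(h, dtype=float)))


def _box2(lo2, hi2, lo3, hi3, rho):
    """P(lo2 < X < hi2, lo3 < Y < hi3) for bivariate correlation rho."""
    return (
        _phi2(hi2, hi3, rho)
        - _phi2(lo2, hi3, rho)
        - _phi2(hi2, lo3, rho)
        + _phi2(lo2, lo3, rho)
    )


def symmetric_box_probability(z: float, corr: np.ndarray, nodes: int = 96) -> float:
    """P(|N_i| <= z for all i), N ~ MVN(0, corr), for k in {1, 2, 3}."""
    if z <= 0:
        return 0.0
    corr = np.atleast_2d(np.asarray(corr, dtype=float))
    k = corr.shape[0]
    # drop components that duplicate an earlier one inside the symmetric box
    keep = []
    for i in range(k):
        if all(abs(corr[i, j]) < 1.0 - _RHO_TOL for j in keep):
            keep.append(i)
    corr = corr[np.ix_(keep, keep)]
    k = len(keep)

    if k == 1:
        return float(2.0 * ndtr(z) - 1.0)
    if k == 2:
        return float(_box2(-z, z, -z, z, corr[0, 1]))
    if k != 3:
        raise ValueError("supports up to 3 components")

    r12, r13, r23 = corr[0, 1], corr[0, 2], corr[1, 2]
    s2 = np.sqrt(1.0 - r12 * r12)
    s3 = np.sqrt(1.0 - r13 * r13)
    rc = np.clip((r23 - r12 * r13) / (s2 * s3), -1.0, 1.0)
    x, w = _leggauss(nodes)
    x = x * z
    w = w * z
    dens = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    inner = _box2(
        (-z - r12 * x) / s2,
        (z - r12 * x) / s2,
        (-z - r13 * x) / s3,
        (z - r13 * x) / s3,
        rc,
    )
    return float(np.clip(np.sum(w * dens * inner), 0.0, 1.0))
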