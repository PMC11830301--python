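"""Deterministic bivariate-normal probabilities.

The liability-threshold machinery needs the standard bivariate normal CDF
to ~1e-12 so that tetrachoric root-finding and threshold solving are exact
and reproducible.  We use Plackett's identity in the angular variable,

    Phi2(h, k, rho) = Phi(h) Phi(k)
        + 1/(2 pi) * int_0^{asin(rho)} exp(-(h^2 + k^2 - 2 h k sin t)
                                           / (2 cos^2 t)) dt,

whose integrand is analytic on the open interval for every |rho| <= 1, and
evaluate the integral by composite Gauss-Legendre quadrature with extra
panels packed towards the endpoint when |rho| is close to 1 (where the
integrand develops a boundary layer of width ~|h-k|).  Everything is
vectorised over (h, k) for a common rho.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

__all__ = ["bvn_cdf", "bvn_sf", "bvn_rect", "bvn_pdf"]

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)


def _panels(alpha: float) -> list[tuple[float, float]]:
    """Quadrature panels for [0, alpha] (alpha may be negative)."""
    a = abs(alpha)
    sgn = 1.0 if alpha >= 0 else -1.0
    cut = 1.1780972450961724  # asin(0.925)
    if a <= cut:
        edges = [0.0, a]
    else:
        # geometric refinement towards the endpoint
        rem = a - cut
        edges = [0.0, cut, cut + rem * 0.6, cut + rem * 0.9, cut + rem * 0.99, a]
    return [(sgn * lo, sgn * hi) for lo, hi in zip(edges[:-1], edges[1:])]


def bvn_cdf(h, k, rho: float):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    h, k broadcastable arrays (infinities allowed); rho a scalar in [-1, 1].
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    rho = float(rho)
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation {rho} outside [-1, 1]")

    if rho == 1.0:
        return ndtr(np.minimum(h, k))
    if rho == -1.0:
        return np.maximum(ndtr(h) + ndtr(k) - 1.0, 0.0)

    out = ndtr(h) * ndtr(k)
    if rho != 0.0:
        alpha = float(np.arcsin(rho))
        finite = np.isfinite(h) & np.isfinite(k)
        if np.any(finite):
            hf = h[finite]
            kf = k[finite]
            acc = np.zeros(hf.shape, dtype=float)
            for lo, hi in _panels(alpha):
                mid = 0.5 * (lo + hi)
                half = 0.5 * (hi - lo)
                t = mid + half * _GL_NODES  # (n,)
                sint = np.sin(t)
                cos2 = np.cos(t) ** 2
                # (n, m) integrand
                num = hf[None, :] ** 2 + kf[None, :] ** 2 - 2.0 * sint[:, None] * (hf * kf)[None, :]
                vals = np.exp(-num / (2.0 * cos2[:, None]))
                acc += half * (_GL_WEIGHTS @ vals)
            corr = np.zeros(h.shape, dtype=float)
            corr[finite] = acc / (2.0 * np.pi)
            out = out + corr
    return np.clip(out, 0.0, 1.0)


def bvn_sf(h, k, rho: float):
    """Upper orthant P(X > h, Y > k)."""
    return bvn_cdf(-np.asarray(h, dtype=float), -np.asarray(k, dtype=float), rho)


def bvn_rect(lo1, hi1, lo2, hi2, rho: float):
    """P(lo1 < X <= hi1, lo2 < Y <= hi2)."""
    p = (
        bvn_cdf(hi1, hi2, rho)
        - bvn_cdf(lo1, hi2, rho)
        - bvn_cdf(hi1, lo2, rho)
        + bvn_cdf(lo1, lo2, rho)
    )
    return np.clip(p, 0.0, 1.0)


def bvn_pdf(h, k, rho: float):
    """Standard bivariate normal density."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    om = 1.0 - rho * rho
    return np.exp(-(h * h - 2.0 * rho * h * k + k * k) / (2.0 * om)) / (
        2.0 * np.pi * np.sqrt(om)
    )
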