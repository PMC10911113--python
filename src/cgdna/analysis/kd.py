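"""Molar dissociation constant from a radial PMF.

The bound-state volume integral

    1/K_d = N_A * Integral_0^b 4 pi r^2 exp(-beta F(r)) dr

(with the volume converted from A^3 to litres) gives K_d in mol/L.
``b`` is the distance at which the PMF reaches its limiting value of
zero; distances below the sampled range (hard-core region) contribute
nothing.
"""

from __future__ import annotations

import numpy as np

from ..units import KB, N_AVOGADRO, A3_TO_L
from .wham import PmfProfile


def kd_from_pmf(profile: PmfProfile, temperature: float | None = None) -> float:
    """Dissociation constant (mol/L) by trapezoid quadrature on the
    profile grid, restricted to r <= b."""
    t = profile.temperature if temperature is None else temperature
    beta = 1.0 / (KB * t)
    r = np.asarray(profile.r, float)
    f = np.asarray(profile.f, float)
    if not np.any(f <= 0.0):
        raise ValueError("PMF never reaches zero: b undefined")
    mask = r <= profile.b
    if mask.sum() < 2:
        raise ValueError("PMF grid has no support below b")
    rr, ff = r[mask], f[mask]
    integrand = 4.0 * np.pi * rr ** 2 * np.exp(-beta * ff)
    vol = np.trapezoid(integrand, rr)          # A^3
    inv_kd = N_AVOGADRO * vol * A3_TO_L        # L/mol
    if inv_kd <= 0 or not np.isfinite(inv_kd):
        return np.inf
    return float(1.0 / inv_kd)
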