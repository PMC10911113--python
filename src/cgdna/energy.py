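"""Closed-form pair and bonded potentials (reference implementations).

These scalar/vectorised functions define every term of the CG energy
function; the simulation kernels in :mod:`cgdna._kernels` implement the
same expressions in compiled form and are tested against these and
against numerical gradients.

Conventions (fixed for the whole package):

* harmonic bond      U = K (r - r0)^2            (no 1/2 prefactor)
* angle              U = K (cos th - cos th0)^2
* 12-10 attraction   U = delta [5 (s/r)^12 - 6 (s/r)^10], minimum -delta at r = s
* WCA                U = 4 eps [(s/r)^12 - (s/r)^6] + eps for r < 2^(1/6) s
* Debye-Hueckel      U = k_e q_i q_j exp(-r/kappa) / (eps_r r), cut at 3.5 kappa
* HPS                Ashbaugh-Hatch split of the LJ potential at 2^(1/6) s

All cutoffs are plain truncation.
"""

from __future__ import annotations

import numpy as np

from .parameters import DnaParameterSet, HpsParameterSet, ElectrostaticsContext
from .units import COULOMB

TWO_16 = 2.0 ** (1.0 / 6.0)


def u_harmonic_bond(r, k: float = 50.0, r0: float = 5.5):
    """Harmonic bond energy K (r - r0)^2, kcal/mol."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("bond length must be positive")
    return k * (r - r0) ** 2


def u_cosine_sq_angle(theta_deg, k: float = 40.0, theta0_deg: float = 180.0):
    """Cosine-squared angle energy K (cos th - cos th0)^2, kcal/mol."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    return k * (np.cos(th) - np.cos(np.deg2rad(theta0_deg))) ** 2


def u_lj1210(r, sigma: float, delta: float, cutoff: float):
    """12-10 Lennard-Jones attraction used for stacking and H-bonding."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = np.asarray(r, dtype=float)
    x = sigma / r
    u = delta * (5.0 * x ** 12 - 6.0 * x ** 10)
    return np.where(r < cutoff, u, 0.0)


def u_wca(r, eps: float = 4.0, sigma: float = 5.5):
    """Weeks-Chandler-Andersen purely repulsive excluded volume."""
    r = np.asarray(r, dtype=float)
    x = sigma / r
    u = 4.0 * eps * (x ** 12 - x ** 6) + eps
    return np.where(r < TWO_16 * sigma, u, 0.0)


def u_debye_huckel(qi: float, qj: float, r, ctx: ElectrostaticsContext):
    """Screened Coulomb energy between two point charges."""
    r = np.asarray(r, dtype=float)
    u = COULOMB * qi * qj * np.exp(-r / ctx.kappa) / (ctx.eps_r * r)
    return np.where(r < ctx.cutoff, u, 0.0)


def u_hps(r, sigma: float, lam: float, eps: float = 0.2,
          cutoff: float = np.inf):
    """Ashbaugh-Hatch hydropathy-scaled LJ pair energy.

    ``U_LJ + (1 - lambda) eps`` inside the LJ minimum (r <= 2^(1/6)
    sigma), ``lambda U_LJ`` outside; lambda = 0 gives a purely repulsive
    WCA-like potential, lambda = 1 plain LJ.
    """
    r = np.asarray(r, dtype=float)
    x = sigma / r
    ulj = 4.0 * eps * (x ** 12 - x ** 6)
    u = np.where(r <= TWO_16 * sigma, ulj + (1.0 - lam) * eps, lam * ulj)
    return np.where(r < cutoff, u, 0.0)


def u_hps_pair(kind_i: str, sp_i: str, kind_j: str, sp_j: str, r,
               params: HpsParameterSet):
    """HPS energy between two species, with arithmetic mixing.

    Dummy HB beads interact with eps = 0 (identically zero energy).
    """
    sig, lam, eps = params.pair_params(kind_i, sp_i, kind_j, sp_j)
    if eps == 0.0:
        return np.zeros_like(np.asarray(r, dtype=float))
    return u_hps(r, sig, lam, eps, cutoff=params.cutoff)


def u_stack_pair(base_i: str, base_j: str, r, params: DnaParameterSet):
    sig, dlt = params.stack_params(base_i, base_j)
    return u_lj1210(r, sig, dlt, params.r_stack)


def u_hb_pair(sp_i: str, sp_j: str, r, params: DnaParameterSet):
    sig, dlt, rc = params.hb_params(sp_i, sp_j)
    return u_lj1210(r, sig, dlt, rc)
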