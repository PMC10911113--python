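"""Numba kernels: energies, forces, and the BAOAB Langevin driver.

Everything here works on flat packed arrays produced by
:class:`cgdna.forcefield.ForceField`; the public API lives there.  All
pair terms use the orthorhombic minimum-image convention (a box edge of
0 disables periodicity along that axis).
"""

import numpy as np
from numba import njit

SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)
ENERGY_TO_MVSQ = 418.4  # kcal/mol -> amu A^2/ps^2


@njit(cache=True, inline="always")
def _mi(d, edge):
    if edge > 0.0:
        d -= edge * np.rint(d / edge)
    return d


@njit(cache=True)
def forces_energy(pos, box,
                  b_i, b_j, b_kc, b_r0,
                  a_i, a_j, a_k, a_kc, a_c0,
                  s_i, s_j, s_sig, s_dlt, s_rc,
                  h_i, h_j, h_sig, h_dlt, h_rc,
                  w_i, w_j, w_eps, w_sig,
                  d_i, d_j, d_qq, d_pref, d_kappa, d_rc,
                  p_i, p_j, p_sig, p_lam, p_eps, p_rc,
                  f):
    """Accumulate forces into ``f`` (zeroed here) and return the tuple
    (bond, angle, stacking, hbond, excluded, electrostatics, hps) of
    energies in kcal/mol."""
    f[:] = 0.0
    e_bond = 0.0
    e_angle = 0.0
    e_stack = 0.0
    e_hb = 0.0
    e_ex = 0.0
    e_el = 0.0
    e_hps = 0.0

    # --- harmonic bonds: U = K (r - r0)^2 ---
    for n in range(b_i.shape[0]):
        i, j = b_i[n], b_j[n]
        dx = _mi(pos[i, 0] - pos[j, 0], box[0])
        dy = _mi(pos[i, 1] - pos[j, 1], box[1])
        dz = _mi(pos[i, 2] - pos[j, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - b_r0[n]
        e_bond += b_kc[n] * dr * dr
        if r > 0.0:
            g = -2.0 * b_kc[n] * dr / r
            f[i, 0] += g * dx
            f[i, 1] += g * dy
            f[i, 2] += g * dz
            f[j, 0] -= g * dx
            f[j, 1] -= g * dy
            f[j, 2] -= g * dz

    # --- angles: U = K (cos th - cos th0)^2, apex a_j ---
    for n in range(a_i.shape[0]):
        i, j, k = a_i[n], a_j[n], a_k[n]
        ax = _mi(pos[i, 0] - pos[j, 0], box[0])
        ay = _mi(pos[i, 1] - pos[j, 1], box[1])
        az = _mi(pos[i, 2] - pos[j, 2], box[2])
        bx = _mi(pos[k, 0] - pos[j, 0], box[0])
        by = _mi(pos[k, 1] - pos[j, 1], box[1])
        bz = _mi(pos[k, 2] - pos[j, 2], box[2])
        na = np.sqrt(ax * ax + ay * ay + az * az)
        nb = np.sqrt(bx * bx + by * by + bz * bz)
        inv = 1.0 / (na * nb)
        c = (ax * bx + ay * by + az * bz) * inv
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        dc = c - a_c0[n]
        e_angle += a_kc[n] * dc * dc
        pref = -2.0 * a_kc[n] * dc
        # dU/dri = pref' * dc/dri with dc/dri = b*inv - c*a/na^2
        ia2 = c / (na * na)
        ib2 = c / (nb * nb)
        gix = pref * (bx * inv - ia2 * ax)
        giy = pref * (by * inv - ia2 * ay)
        giz = pref * (bz * inv - ia2 * az)
        gkx = pref * (ax * inv - ib2 * bx)
        gky = pref * (ay * inv - ib2 * by)
        gkz = pref * (az * inv - ib2 * bz)
        f[i, 0] += gix
        f[i, 1] += giy
        f[i, 2] += giz
        f[k, 0] += gkx
        f[k, 1] += gky
        f[k, 2] += gkz
        f[j, 0] -= gix + gkx
        f[j, 1] -= giy + gky
        f[j, 2] -= giz + gkz

    # --- 12-10 stacking ---
    for n in range(s_i.shape[0]):
        i, j = s_i[n], s_j[n]
        dx = _mi(pos[i, 0] - pos[j, 0], box[0])
        dy = _mi(pos[i, 1] - pos[j, 1], box[1])
        dz = _mi(pos[i, 2] - pos[j, 2], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < s_rc[n] * s_rc[n]:
            r = np.sqrt(r2)
            x2 = (s_sig[n] / r) ** 2
            x10 = x2 ** 5
            x12 = x10 * x2
            e_stack += s_dlt[n] * (5.0 * x12 - 6.0 * x10)
            g = -60.0 * s_dlt[n] * (x10 - x12) / r2
            f[i, 0] += g * dx
            f[i, 1] += g * dy
            f[i, 2] += g * dz
            f[j, 0] -= g * dx
            f[j, 1] -= g * dy
            f[j, 2] -= g * dz

    # --- 12-10 hydrogen bonding ---
    for n in range(h_i.shape[0]):
        i, j = h_i[n], h_j[n]
        dx = _mi(pos[i, 0] - pos[j, 0], box[0])
        dy = _mi(pos[i, 1] - pos[j, 1], box[1])
        dz = _mi(pos[i, 2] - pos[j, 2], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < h_rc[n] * h_rc[n]:
            r = np.sqrt(r2)
            x2 = (h_sig[n] / r) ** 2
            x10 = x2 ** 5
            x12 = x10 * x2
            e_hb += h_dlt[n] * (5.0 * x12 - 6.0 * x10)
            g = -60.0 * h_dlt[n] * (x10 - x12) / r2
            f[i, 0] += g * dx
            f[i, 1] += g * dy
            f[i, 2] += g * dz
            f[j, 0] -= g * dx
            f[j, 1] -= g * dy
            f[j, 2] -= g * dz

    # --- WCA excluded volume ---
    for n in range(w_i.shape[0]):
        i, j = w_i[n], w_j[n]
        dx = _mi(pos[i, 0] - pos[j, 0], box[0])
        dy = _mi(pos[i, 1] - pos[j, 1], box[1])
        dz = _mi(pos[i, 2] - pos[j, 2], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        rc = SIXTH_ROOT_2 * w_sig[n]
        if r2 < rc * rc:
            x2 = w_sig[n] * w_sig[n] / r2
            x6 = x2 * x2 * x2
            x12 = x6 * x6
            e_ex += 4.0 * w_eps[n] * (x12 - x6) + w_eps[n]
            g = 4.0 * w_eps[n] * (12.0 * x12 - 6.0 * x6) / r2
            f[i, 0] += g * dx
            f[i, 1] += g * dy
            f[i, 2] += g * dz
            f[j, 0] -= g * dx
            f[j, 1] -= g * dy
            f[j, 2] -= g * dz

    # --- Debye-Hueckel ---
    for n in range(d_i.shape[0]):
        i, j = d_i[n], d_j[n]
        dx = _mi(pos[i, 0] - pos[j, 0], box[0])
        dy = _mi(pos[i, 1] - pos[j, 1], box[1])
        dz = _mi(pos[i, 2] - pos[j, 2], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < d_rc * d_rc:
            r = np.sqrt(r2)
            u = d_pref * d_qq[n] * np.exp(-r / d_kappa) / r
            e_el += u
            g = u * (1.0 / d_kappa + 1.0 / r) / r
            f[i, 0] += g * dx
            f[i, 1] += g * dy
            f[i, 2] += g * dz
            f[j, 0] -= g * dx
            f[j, 1] -= g * dy
            f[j, 2] -= g * dz

    # --- HPS (Ashbaugh-Hatch) ---
    for n in range(p_i.shape[0]):
        i, j = p_i[n], p_j[n]
        dx = _mi(pos[i, 0] - pos[j, 0], box[0])
        dy = _mi(pos[i, 1] - pos[j, 1], box[1])
        dz = _mi(pos[i, 2] - pos[j, 2], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < p_rc * p_rc:
            sig = p_sig[n]
            x2 = sig * sig / r2
            x6 = x2 * x2 * x2
            x12 = x6 * x6
            ulj = 4.0 * p_eps[n] * (x12 - x6)
            dulj = 4.0 * p_eps[n] * (12.0 * x12 - 6.0 * x6) / r2  # = -dU/dr / r
            rcut = SIXTH_ROOT_2 * sig
            if r2 <= rcut * rcut:
                e_hps += ulj + (1.0 - p_lam[n]) * p_eps[n]
                g = dulj
            else:
                e_hps += p_lam[n] * ulj
                g = p_lam[n] * dulj
            f[i, 0] += g * dx
            f[i, 1] += g * dy
            f[i, 2] += g * dz
            f[j, 0] -= g * dx
            f[j, 1] -= g * dy
            f[j, 2] -= g * dz

    return e_bond, e_angle, e_stack, e_hb, e_ex, e_el, e_hps


@njit(cache=True)
def _com(pos, grp, mass):
    cx = cy = cz = 0.0
    mt = 0.0
    for n in range(grp.shape[0]):
        i = grp[n]
        cx += mass[i] * pos[i, 0]
        cy += mass[i] * pos[i, 1]
        cz += mass[i] * pos[i, 2]
        mt += mass[i]
    return cx / mt, cy / mt, cz / mt, mt


@njit(cache=True)
def restraint_energy_forces(pos, mass, ga, gb, ku, d0, f):
    """COM-COM harmonic restraint U = k_u (d - d0)^2 (adds into f)."""
    ax, ay, az, ma = _com(pos, ga, mass)
    bx, by, bz, mb = _com(pos, gb, mass)
    dx = ax - bx
    dy = ay - by
    dz = az - bz
    d = np.sqrt(dx * dx + dy * dy + dz * dz)
    if d < 1e-12:
        return 0.0, 0.0
    dd = d - d0
    g = -2.0 * ku * dd / d
    for n in range(ga.shape[0]):
        i = ga[n]
        w = mass[i] / ma
        f[i, 0] += g * w * dx
        f[i, 1] += g * w * dy
        f[i, 2] += g * w * dz
    for n in range(gb.shape[0]):
        i = gb[n]
        w = mass[i] / mb
        f[i, 0] -= g * w * dx
        f[i, 1] -= g * w * dy
        f[i, 2] -= g * w * dz
    return ku * dd * dd, d


@njit(cache=True)
def baoab_run(pos, vel, mass, box,
              b_i, b_j, b_kc, b_r0,
              a_i, a_j, a_k, a_kc, a_c0,
              s_i, s_j, s_sig, s_dlt, s_rc,
              h_i, h_j, h_sig, h_dlt, h_rc,
              w_i, w_j, w_eps, w_sig,
              d_i, d_j, d_qq, d_pref, d_kappa, d_rc,
              p_i, p_j, p_sig, p_lam, p_eps, p_rc,
              dt, gamma, kt, n_steps, stride, gen,
              ga, gb, ku, d0,
              out_pos, out_epot, out_ekin, out_cv, save_pos):
    """BAOAB Langevin integration; returns -1 on success or the step
    index at which the integration blew up (non-finite coordinates or a
    per-step displacement beyond 3 A).

    ``dt`` in ps, ``gamma`` in 1/ps, ``kt`` = k_B T in kcal/mol.
    Samples are recorded every ``stride`` steps (sample s covers step
    (s+1)*stride - 1).
    """
    nb = pos.shape[0]
    f = np.zeros((nb, 3))
    restrained = ga.shape[0] > 0 and gb.shape[0] > 0

    e = forces_energy(pos, box,
                      b_i, b_j, b_kc, b_r0, a_i, a_j, a_k, a_kc, a_c0,
                      s_i, s_j, s_sig, s_dlt, s_rc, h_i, h_j, h_sig, h_dlt, h_rc,
                      w_i, w_j, w_eps, w_sig, d_i, d_j, d_qq, d_pref, d_kappa, d_rc,
                      p_i, p_j, p_sig, p_lam, p_eps, p_rc, f)
    if restrained:
        restraint_energy_forces(pos, mass, ga, gb, ku, d0, f)

    c1 = np.exp(-gamma * dt)
    half = 0.5 * dt
    acc = np.empty(nb)
    sig_v = np.empty(nb)
    for i in range(nb):
        acc[i] = ENERGY_TO_MVSQ / mass[i]
        sig_v[i] = np.sqrt((1.0 - c1 * c1) * kt * ENERGY_TO_MVSQ / mass[i])

    max_disp = 3.0
    isample = 0
    for step in range(n_steps):
        for i in range(nb):
            for d in range(3):
                vel[i, d] += half * f[i, d] * acc[i]
                pos[i, d] += half * vel[i, d]
        if gamma > 0.0:
            for i in range(nb):
                for d in range(3):
                    vel[i, d] = c1 * vel[i, d] + sig_v[i] * gen.standard_normal()
        for i in range(nb):
            for d in range(3):
                pos[i, d] += half * vel[i, d]

        e = forces_energy(pos, box,
                          b_i, b_j, b_kc, b_r0, a_i, a_j, a_k, a_kc, a_c0,
                          s_i, s_j, s_sig, s_dlt, s_rc,
                          h_i, h_j, h_sig, h_dlt, h_rc,
                          w_i, w_j, w_eps, w_sig,
                          d_i, d_j, d_qq, d_pref, d_kappa, d_rc,
                          p_i, p_j, p_sig, p_lam, p_eps, p_rc, f)
        e_r = 0.0
        cv = 0.0
        if restrained:
            e_r, cv = restraint_energy_forces(pos, mass, ga, gb, ku, d0, f)

        for i in range(nb):
            for d in range(3):
                vel[i, d] += half * f[i, d] * acc[i]

        if (step + 1) % stride == 0:
            # sanity: blow-up detection at sampling points
            vmax = 0.0
            ok = True
            for i in range(nb):
                for d in range(3):
                    v = abs(vel[i, d])
                    if v > vmax:
                        vmax = v
                    if not np.isfinite(pos[i, d]):
                        ok = False
            if (not ok) or vmax * dt > max_disp:
                return step
            ek = 0.0
            for i in range(nb):
                ek += mass[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
            ek = 0.5 * ek / ENERGY_TO_MVSQ
            if isample < out_epot.shape[0]:
                out_epot[isample] = (e[0] + e[1] + e[2] + e[3] + e[4] + e[5]
                                     + e[6] + e_r)
                out_ekin[isample] = ek
                out_cv[isample] = cv
                if save_pos:
                    for i in range(nb):
                        for d in range(3):
                            out_pos[isample, i, d] = pos[i, d]
                isample += 1
    return -1
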