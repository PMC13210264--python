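"""Numba kernels: pair/bonded forces and the BAOAB Langevin update.

All kernels operate on flat numpy arrays prepared by :class:`gofold.energy.GoSystem`.
Energies in kcal/mol, distances in Å, masses in amu, time in ps.  ``AKMA``
(418.4) converts kcal/mol to amu·Å²/ps² inside the integrator.
"""

from __future__ import annotations

import numpy as np
from numba import njit

AKMA = 418.4

# truncation radii, in units of sigma (native) / sigma_rep (repulsive)
NATIVE_CUT_MULT = 3.0
REP_CUT_MULT = 3.0


@njit(cache=True)
def force_kernel(
    pos,
    nat_i, nat_j, nat_sigma,
    nn_i, nn_j, nn_sigma,
    bond_i, bond_j, bond_r0,
    ang_i, ang_j, ang_k, ang_theta0, ang_kcos,
    dih_i, dih_j, dih_k, dih_l, dih_phi0,
    eps_native, eps_nonnative, sigma_rep,
    k_bond, k_angle, k_dihedral,
    use_sbm_form,
    forces,
):
    """Accumulate forces into ``forces`` (zeroed here); return energy terms.

    Returns (e_native, e_nonnative, e_bond, e_angle, e_dihedral, min_nn_r).
    ``min_nn_r`` is the smallest non-native pair distance seen, used by the
    caller to detect singular overlaps.
    """
    n = pos.shape[0]
    for a in range(n):
        forces[a, 0] = 0.0
        forces[a, 1] = 0.0
        forces[a, 2] = 0.0

    e_nat = 0.0
    e_nn = 0.0
    e_bond = 0.0
    e_ang = 0.0
    e_dih = 0.0
    min_nn_r = 1.0e30

    # ---- native contacts: 4*eps*[(s/r)^12 - (s/r)^10] (printed 12-10 form)
    # or eps*[5(s/r)^12 - 6(s/r)^10] (standard SBM form, minimum at r = s)
    for p in range(nat_i.shape[0]):
        i = nat_i[p]
        j = nat_j[p]
        s = nat_sigma[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        if r > NATIVE_CUT_MULT * s:
            continue
        a2 = (s / r) * (s / r)
        a10 = a2 * a2 * a2 * a2 * a2
        a12 = a10 * a2
        if use_sbm_form:
            e_nat += eps_native * (5.0 * a12 - 6.0 * a10)
            dv_dr = eps_native * (-60.0 * a12 + 60.0 * a10) / r
        else:
            e_nat += 4.0 * eps_native * (a12 - a10)
            dv_dr = 4.0 * eps_native * (-12.0 * a12 + 10.0 * a10) / r
        f = -dv_dr / r
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz

    # ---- non-native repulsion: 4*eps*(sigma_ij/r)^12 with per-pair radius
    # sigma_ij = min(sigma_rep, 0.8 * native distance), so the native state
    # is not strained by excluded volume
    rep_cut = REP_CUT_MULT * sigma_rep
    for p in range(nn_i.shape[0]):
        i = nn_i[p]
        j = nn_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > rep_cut * rep_cut:
            continue
        r = np.sqrt(r2)
        if r < min_nn_r:
            min_nn_r = r
        if r < 1.0e-12:
            continue  # caller raises on min_nn_r
        srep = nn_sigma[p]
        a2 = (srep / r) * (srep / r)
        a12 = a2 * a2 * a2 * a2 * a2 * a2
        e_nn += 4.0 * eps_nonnative * a12
        dv_dr = -48.0 * eps_nonnative * a12 / r
        f = -dv_dr / r
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz

    # ---- harmonic bonds: k*(r - r0)^2
    for p in range(bond_i.shape[0]):
        i = bond_i[p]
        j = bond_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[p]
        e_bond += k_bond * dr * dr
        if r > 1.0e-12:
            f = -2.0 * k_bond * dr / r
            forces[i, 0] += f * dx
            forces[i, 1] += f * dy
            forces[i, 2] += f * dz
            forces[j, 0] -= f * dx
            forces[j, 1] -= f * dy
            forces[j, 2] -= f * dz

    # ---- angles: harmonic k*(theta - theta0)^2 for ordinary angles;
    # near-linear native angles (ang_kcos > 0) use the curvature-matched
    # cosine-harmonic kc*(cos theta - cos theta0)^2, whose force stays
    # bounded through the colinear geometry
    for p in range(ang_i.shape[0]):
        i = ang_i[p]
        j = ang_j[p]
        k = ang_k[p]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if nu < 1.0e-12 or nv < 1.0e-12:
            continue
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        kc = ang_kcos[p]
        if kc > 0.0:
            c0 = np.cos(ang_theta0[p])
            dc = c - c0
            e_ang += kc * dc * dc
            coef = -2.0 * kc * dc
            # grad_i cos = (v_hat - c*u_hat)/nu ; grad_k symmetric
            fix = coef * (vx / nv - c * ux / nu) / nu
            fiy = coef * (vy / nv - c * uy / nu) / nu
            fiz = coef * (vz / nv - c * uz / nu) / nu
            fkx = coef * (ux / nu - c * vx / nv) / nv
            fky = coef * (uy / nu - c * vy / nv) / nv
            fkz = coef * (uz / nu - c * vz / nv) / nv
        else:
            theta = np.arccos(c)
            dth = theta - ang_theta0[p]
            e_ang += k_angle * dth * dth
            s2 = 1.0 - c * c
            if s2 < 1.0e-12:
                continue  # colinear: energy finite, force guarded to zero
            sin_t = np.sqrt(s2)
            coef = -2.0 * k_angle * dth / sin_t
            fix = coef * (c * ux / nu - vx / nv) / nu
            fiy = coef * (c * uy / nu - vy / nv) / nu
            fiz = coef * (c * uz / nu - vz / nv) / nu
            fkx = coef * (c * vx / nv - ux / nu) / nv
            fky = coef * (c * vy / nv - uy / nu) / nv
            fkz = coef * (c * vz / nv - uz / nu) / nv
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz

    # ---- periodic dihedrals: k*(1 - cos(phi - phi0))
    for p in range(dih_i.shape[0]):
        i = dih_i[p]
        j = dih_j[p]
        k = dih_k[p]
        l = dih_l[p]
        # r_ij, r_kj, r_kl
        ax = pos[i, 0] - pos[j, 0]
        ay = pos[i, 1] - pos[j, 1]
        az = pos[i, 2] - pos[j, 2]
        bx = pos[k, 0] - pos[j, 0]
        by = pos[k, 1] - pos[j, 1]
        bz = pos[k, 2] - pos[j, 2]
        cx = pos[k, 0] - pos[l, 0]
        cy = pos[k, 1] - pos[l, 1]
        cz = pos[k, 2] - pos[l, 2]
        # m = a x b, n = b x c
        mx = ay * bz - az * by
        my = az * bx - ax * bz
        mz = ax * by - ay * bx
        nx = by * cz - bz * cy
        ny = bz * cx - bx * cz
        nz = bx * cy - by * cx
        m2 = mx * mx + my * my + mz * mz
        n2 = nx * nx + ny * ny + nz * nz
        nb = np.sqrt(bx * bx + by * by + bz * bz)
        if m2 < 1.0e-12 or n2 < 1.0e-12 or nb < 1.0e-12:
            continue  # colinear triple: skip (guarded)
        # signed dihedral
        cross_mn_x = my * nz - mz * ny
        cross_mn_y = mz * nx - mx * nz
        cross_mn_z = mx * ny - my * nx
        y = (cross_mn_x * bx + cross_mn_y * by + cross_mn_z * bz) / nb
        x = mx * nx + my * ny + mz * nz
        phi = np.arctan2(y, x)
        dphi = phi - dih_phi0[p]
        e_dih += k_dihedral * (1.0 - np.cos(dphi))
        dv_dphi = k_dihedral * np.sin(dphi)
        # standard analytic dihedral forces
        fi = -dv_dphi * nb / m2
        fl = dv_dphi * nb / n2
        fix = fi * mx
        fiy = fi * my
        fiz = fi * mz
        flx = fl * nx
        fly = fl * ny
        flz = fl * nz
        pfac = (ax * bx + ay * by + az * bz) / (nb * nb)
        qfac = (cx * bx + cy * by + cz * bz) / (nb * nb)
        fjx = pfac * fix - qfac * flx - fix
        fjy = pfac * fiy - qfac * fly - fiy
        fjz = pfac * fiz - qfac * flz - fiz
        fkx = qfac * flx - pfac * fix - flx
        fky = qfac * fly - pfac * fiy - fly
        fkz = qfac * flz - pfac * fiz - flz
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[j, 0] += fjx
        forces[j, 1] += fjy
        forces[j, 2] += fjz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[l, 0] += flx
        forces[l, 1] += fly
        forces[l, 2] += flz

    return e_nat, e_nn, e_bond, e_ang, e_dih, min_nn_r


@njit(cache=True)
def count_formed(pos, nat_i, nat_j, thresholds):
    """Number of native contacts with r_ij < threshold (= lambda * sigma)."""
    count = 0
    for p in range(nat_i.shape[0]):
        i = nat_i[p]
        j = nat_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx * dx + dy * dy + dz * dz < thresholds[p] * thresholds[p]:
            count += 1
    return count


@njit(cache=True)
def baoab_chunk(
    pos, vel, forces, inv_mass, sigma_v,
    n_steps, dt, c1, c2, noise,
    nat_i, nat_j, nat_sigma,
    nn_i, nn_j, nn_sigma,
    bond_i, bond_j, bond_r0,
    ang_i, ang_j, ang_k, ang_theta0, ang_kcos,
    dih_i, dih_j, dih_k, dih_l, dih_phi0,
    eps_native, eps_nonnative, sigma_rep,
    k_bond, k_angle, k_dihedral,
    use_sbm_form,
):
    """Advance ``n_steps`` of BAOAB Langevin in place; return ok flag.

    ``forces`` must hold the forces at the entry positions.  ``sigma_v`` is
    sqrt(kB*T*AKMA/m) per atom (thermal velocity scale, Å/ps); ``c1``, ``c2``
    the Ornstein-Uhlenbeck coefficients exp(-gamma*dt) and sqrt(1-c1^2).
    With c1=1, c2=0 the update reduces to velocity Verlet (NVE).
    Returns False when a non-finite coordinate appears (caller reports the
    global step index).
    """
    n = pos.shape[0]
    half_dt = 0.5 * dt
    for step in range(n_steps):
        # B: half kick
        for a in range(n):
            fac = half_dt * AKMA * inv_mass[a]
            vel[a, 0] += fac * forces[a, 0]
            vel[a, 1] += fac * forces[a, 1]
            vel[a, 2] += fac * forces[a, 2]
        # A: half drift
        for a in range(n):
            pos[a, 0] += half_dt * vel[a, 0]
            pos[a, 1] += half_dt * vel[a, 1]
            pos[a, 2] += half_dt * vel[a, 2]
        # O: Ornstein-Uhlenbeck
        if c2 > 0.0:
            for a in range(n):
                sv = sigma_v[a] * c2
                vel[a, 0] = c1 * vel[a, 0] + sv * noise[step, a, 0]
                vel[a, 1] = c1 * vel[a, 1] + sv * noise[step, a, 1]
                vel[a, 2] = c1 * vel[a, 2] + sv * noise[step, a, 2]
        # A: half drift
        for a in range(n):
            pos[a, 0] += half_dt * vel[a, 0]
            pos[a, 1] += half_dt * vel[a, 1]
            pos[a, 2] += half_dt * vel[a, 2]
        # B: half kick with new forces
        force_kernel(
            pos,
            nat_i, nat_j, nat_sigma, nn_i, nn_j, nn_sigma,
            bond_i, bond_j, bond_r0,
            ang_i, ang_j, ang_k, ang_theta0, ang_kcos,
            dih_i, dih_j, dih_k, dih_l, dih_phi0,
            eps_native, eps_nonnative, sigma_rep,
            k_bond, k_angle, k_dihedral, use_sbm_form,
            forces,
        )
        for a in range(n):
            fac = half_dt * AKMA * inv_mass[a]
            vel[a, 0] += fac * forces[a, 0]
            vel[a, 1] += fac * forces[a, 1]
            vel[a, 2] += fac * forces[a, 2]
        if not np.isfinite(pos[0, 0]):
            return False
    # full finiteness check once per chunk
    for a in range(n):
        for d in range(3):
            if not np.isfinite(pos[a, d]):
                return False
    return True
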