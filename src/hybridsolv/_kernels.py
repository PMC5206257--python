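"""Numba-compiled array kernels for non-bonded and bonded sweeps.

These mirror the per-pair formulas in :mod:`hybridsolv.forcefield` but operate
on flat arrays for speed; equality of the two routes on whole systems is part
of the test suite.  Everything assumes an orthorhombic periodic box and the
minimum-image convention, which requires box lengths >= 2 * r_cut.
"""

import numpy as np
from numba import njit

from .units import COULOMB_K

_CK = COULOMB_K


def all_pairs(n: int) -> np.ndarray:
    """All i<j index pairs as an (M, 2) int64 array."""
    iu = np.triu_indices(n, k=1)
    return np.ascontiguousarray(np.stack(iu, axis=1).astype(np.int64))


def cell_pairs(pos: np.ndarray, box: np.ndarray, r_cut: float):
    """Candidate pairs from a periodic cell list, or None if the box is too
    small (< 3 cells of size >= r_cut per dimension)."""
    ncell = np.floor(box / r_cut).astype(np.int64)
    if np.any(ncell < 3):
        return None
    frac = (pos / box) % 1.0
    cidx = np.minimum((frac * ncell).astype(np.int64), ncell - 1)
    return _cell_pairs_impl(cidx, ncell)


@njit(cache=True)
def _cell_pairs_impl(cidx, ncell):  # pragma: no cover - exercised via cell_pairs
    n = cidx.shape[0]
    nc = ncell[0] * ncell[1] * ncell[2]
    flat = cidx[:, 0] * ncell[1] * ncell[2] + cidx[:, 1] * ncell[2] + cidx[:, 2]
    order = np.argsort(flat)
    start = np.full(nc + 1, -1, np.int64)
    # bucket boundaries in sorted order
    count = np.zeros(nc + 1, np.int64)
    for k in range(n):
        count[flat[k] + 1] += 1
    for c in range(1, nc + 1):
        count[c] += count[c - 1]
    start = count
    # 13 half-space neighbour offsets + self cell
    offs = np.array([
        [0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
        [1, 1, 0], [1, -1, 0], [1, 0, 1], [1, 0, -1],
        [0, 1, 1], [0, 1, -1], [1, 1, 1], [1, 1, -1],
        [1, -1, 1], [1, -1, -1]], np.int64)
    # worst case bound on number of pairs
    cap = n * (n - 1) // 2
    out = np.empty((cap, 2), np.int64)
    m = 0
    for cx in range(ncell[0]):
        for cy in range(ncell[1]):
            for cz in range(ncell[2]):
                c1 = cx * ncell[1] * ncell[2] + cy * ncell[2] + cz
                for o in range(offs.shape[0]):
                    nx = (cx + offs[o, 0]) % ncell[0]
                    ny = (cy + offs[o, 1]) % ncell[1]
                    nz = (cz + offs[o, 2]) % ncell[2]
                    c2 = nx * ncell[1] * ncell[2] + ny * ncell[2] + nz
                    same = c1 == c2
                    if same and o > 0:
                        continue
                    for p1 in range(start[c1], start[c1 + 1]):
                        i = order[p1]
                        for p2 in range(start[c2], start[c2 + 1]):
                            j = order[p2]
                            if same and j <= i:
                                continue
                            out[m, 0] = i
                            out[m, 1] = j
                            m += 1
    return out[:m].copy()


@njit(cache=True)
def nonbonded_sweep(pairs, pos, box, sigma, eps, charge, mumag, orient,
                    mol, solute, cg, r_cut, lam_f):
    """One sweep over candidate pairs.

    Returns (e_solv_solv, e_solute_solv_unscaled, e_solute_solute, virial,
    f_outer, f_inner, t_outer, t_inner).  Solute-solvent forces and the
    virial are scaled by ``lam_f``; the returned solute-solvent energy is
    unscaled.  Outer forces are the CG-CG non-bonded ones (the slow class of
    the multiple-timestep split), inner forces everything else.
    """
    n = pos.shape[0]
    f_out = np.zeros((n, 3))
    f_in = np.zeros((n, 3))
    t_out = np.zeros((n, 3))
    t_in = np.zeros((n, 3))
    e_ss = 0.0
    e_uv = 0.0
    e_uu = 0.0
    vir = 0.0
    rc2 = r_cut * r_cut

    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        if mol[i] == mol[j]:
            continue
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        r = np.sqrt(r2)

        e = 0.0
        fx = 0.0
        fy = 0.0
        fz = 0.0
        tix = 0.0
        tiy = 0.0
        tiz = 0.0
        tjx = 0.0
        tjy = 0.0
        tjz = 0.0

        # ---- Lennard-Jones, shifted force, Lorentz-Berthelot ----
        eij = np.sqrt(eps[i] * eps[j])
        if eij > 0.0:
            sij = 0.5 * (sigma[i] + sigma[j])
            s6 = (sij * sij / r2) ** 3
            s6c = (sij / r_cut) ** 6
            u = 4.0 * eij * (s6 * s6 - s6)
            uc = 4.0 * eij * (s6c * s6c - s6c)
            dup = -24.0 * eij * (2.0 * s6 * s6 - s6) / r
            dupc = -24.0 * eij * (2.0 * s6c * s6c - s6c) / r_cut
            e += u - uc - (r - r_cut) * dupc
            fr = -(dup - dupc) / r
            fx += fr * dx
            fy += fr * dy
            fz += fr * dz

        # ---- electrostatics ----
        mi = mumag[i]
        mj = mumag[j]
        qi = charge[i]
        qj = charge[j]
        if mi > 0.0 and mj > 0.0:
            # dipole-dipole
            ak = 1.0 / (r2 * r) - 1.0 / r_cut**3 + 3.0 * (r - r_cut) / r_cut**4
            dak = -3.0 / (r2 * r2) + 3.0 / r_cut**4
            bt = 3.0 * ak / r2
            dbt = 3.0 * dak / r2 - 6.0 * ak / (r2 * r)
            uix = mi * orient[i, 0]
            uiy = mi * orient[i, 1]
            uiz = mi * orient[i, 2]
            ujx = mj * orient[j, 0]
            ujy = mj * orient[j, 1]
            ujz = mj * orient[j, 2]
            a = uix * dx + uiy * dy + uiz * dz
            b = ujx * dx + ujy * dy + ujz * dz
            s1 = uix * ujx + uiy * ujy + uiz * ujz
            e += _CK * (s1 * ak - a * b * bt)
            coef_r = _CK * (s1 * dak - a * b * dbt) / r
            gx = coef_r * dx + _CK * (-(uix * b + ujx * a) * bt)
            gy = coef_r * dy + _CK * (-(uiy * b + ujy * a) * bt)
            gz = coef_r * dz + _CK * (-(uiz * b + ujz * a) * bt)
            fx += -gx
            fy += -gy
            fz += -gz
            # torque_i = mu_i x E_i,  E_i = -dU/dmu_i
            eix = -_CK * (ujx * ak - b * dx * bt)
            eiy = -_CK * (ujy * ak - b * dy * bt)
            eiz = -_CK * (ujz * ak - b * dz * bt)
            ejx = -_CK * (uix * ak - a * dx * bt)
            ejy = -_CK * (uiy * ak - a * dy * bt)
            ejz = -_CK * (uiz * ak - a * dz * bt)
            tix += uiy * eiz - uiz * eiy
            tiy += uiz * eix - uix * eiz
            tiz += uix * eiy - uiy * eix
            tjx += ujy * ejz - ujz * ejy
            tjy += ujz * ejx - ujx * ejz
            tjz += ujx * ejy - ujy * ejx
        elif (mi > 0.0 and qj != 0.0) or (mj > 0.0 and qi != 0.0):
            # charge-dipole; sgn handles which end carries the charge
            h = 1.0 / r2 - 1.0 / r_cut**2 + 2.0 * (r - r_cut) / r_cut**3
            dh = -2.0 / (r2 * r) + 2.0 / r_cut**3
            bh = h / r
            dbh = dh / r - h / r2
            if mj > 0.0:
                q = qi
                ux = mj * orient[j, 0]
                uy = mj * orient[j, 1]
                uz = mj * orient[j, 2]
                sgn = 1.0   # r_vec points dipole -> charge
            else:
                q = qj
                ux = mi * orient[i, 0]
                uy = mi * orient[i, 1]
                uz = mi * orient[i, 2]
                sgn = -1.0
            b = ux * dx + uy * dy + uz * dz
            e += sgn * _CK * q * b * bh
            gx = sgn * _CK * q * (ux * bh + b * dbh * dx / r)
            gy = sgn * _CK * q * (uy * bh + b * dbh * dy / r)
            gz = sgn * _CK * q * (uz * bh + b * dbh * dz / r)
            fx += -gx
            fy += -gy
            fz += -gz
            ex = -sgn * _CK * q * dx * bh
            ey = -sgn * _CK * q * dy * bh
            ez = -sgn * _CK * q * dz * bh
            if mj > 0.0:
                tjx += uy * ez - uz * ey
                tjy += uz * ex - ux * ez
                tjz += ux * ey - uy * ex
            else:
                tix += uy * ez - uz * ey
                tiy += uz * ex - ux * ez
                tiz += ux * ey - uy * ex
        elif qi != 0.0 and qj != 0.0:
            u1 = 1.0 / r - 1.0 / r_cut + (r - r_cut) / r_cut**2
            du1 = -1.0 / r2 + 1.0 / r_cut**2
            e += _CK * qi * qj * u1
            fr = -_CK * qi * qj * du1 / r
            fx += fr * dx
            fy += fr * dy
            fz += fr * dz

        # ---- classify and accumulate ----
        mixed = solute[i] != solute[j]
        scale = lam_f if mixed else 1.0
        if mixed:
            e_uv += e
        elif solute[i]:
            e_uu += e
        else:
            e_ss += e
        fx *= scale
        fy *= scale
        fz *= scale
        vir += dx * fx + dy * fy + dz * fz
        if cg[i] and cg[j]:
            f_out[i, 0] += fx
            f_out[i, 1] += fy
            f_out[i, 2] += fz
            f_out[j, 0] -= fx
            f_out[j, 1] -= fy
            f_out[j, 2] -= fz
            t_out[i, 0] += scale * tix
            t_out[i, 1] += scale * tiy
            t_out[i, 2] += scale * tiz
            t_out[j, 0] += scale * tjx
            t_out[j, 1] += scale * tjy
            t_out[j, 2] += scale * tjz
        else:
            f_in[i, 0] += fx
            f_in[i, 1] += fy
            f_in[i, 2] += fz
            f_in[j, 0] -= fx
            f_in[j, 1] -= fy
            f_in[j, 2] -= fz
            t_in[i, 0] += scale * tix
            t_in[i, 1] += scale * tiy
            t_in[i, 2] += scale * tiz
            t_in[j, 0] += scale * tjx
            t_in[j, 1] += scale * tjy
            t_in[j, 2] += scale * tjz

    return e_ss, e_uv, e_uu, vir, f_out, f_in, t_out, t_in


@njit(cache=True)
def bonded_sweep(pos, box, bond_i, bond_j, bond_r0, bond_k, f_acc):
    """Harmonic bonds E = k (r - r0)^2; forces accumulate into ``f_acc``."""
    e = 0.0
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        e += bond_k[b] * dr * dr
        fr = -2.0 * bond_k[b] * dr / r
        f_acc[i, 0] += fr * dx
        f_acc[i, 1] += fr * dy
        f_acc[i, 2] += fr * dz
        f_acc[j, 0] -= fr * dx
        f_acc[j, 1] -= fr * dy
        f_acc[j, 2] -= fr * dz
    return e


@njit(cache=True)
def shake_kernel(pos_new, pos_old, box, con_i, con_j, con_d, inv_mass,
                 tol, max_iter):
    """Iterative SHAKE position correction.

    Corrections act along the pre-step (old) constraint vectors.  Returns
    (n_iterations, worst_constraint, converged_flag); ``pos_new`` is modified
    in place.  ``tol`` bounds |d^2 - d0^2| in A^2.
    """
    nc = con_i.shape[0]
    worst = -1
    for it in range(max_iter):
        done = True
        worst_viol = 0.0
        for c in range(nc):
            i = con_i[c]
            j = con_j[c]
            dx = pos_new[i, 0] - pos_new[j, 0]
            dy = pos_new[i, 1] - pos_new[j, 1]
            dz = pos_new[i, 2] - pos_new[j, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            d2 = dx * dx + dy * dy + dz * dz
            diff = d2 - con_d[c] * con_d[c]
            if np.abs(diff) > worst_viol:
                worst_viol = np.abs(diff)
                worst = c
            if np.abs(diff) > tol:
                done = False
                ox = pos_old[i, 0] - pos_old[j, 0]
                oy = pos_old[i, 1] - pos_old[j, 1]
                oz = pos_old[i, 2] - pos_old[j, 2]
                ox -= box[0] * np.rint(ox / box[0])
                oy -= box[1] * np.rint(oy / box[1])
                oz -= box[2] * np.rint(oz / box[2])
                dot = ox * dx + oy * dy + oz * dz
                g = diff / (2.0 * (inv_mass[i] + inv_mass[j]) * dot)
                pos_new[i, 0] -= g * inv_mass[i] * ox
                pos_new[i, 1] -= g * inv_mass[i] * oy
                pos_new[i, 2] -= g * inv_mass[i] * oz
                pos_new[j, 0] += g * inv_mass[j] * ox
                pos_new[j, 1] += g * inv_mass[j] * oy
                pos_new[j, 2] += g * inv_mass[j] * oz
        if done:
            return it + 1, worst, True
    return max_iter, worst, False


@njit(cache=True)
def _rotate_sites(orient, angvel, dipolar, dt):
    for i in range(orient.shape[0]):
        if not dipolar[i]:
            continue
        wx = angvel[i, 0]
        wy = angvel[i, 1]
        wz = angvel[i, 2]
        w = np.sqrt(wx * wx + wy * wy + wz * wz)
        if w == 0.0:
            continue
        kx = wx / w
        ky = wy / w
        kz = wz / w
        th = w * dt
        c = np.cos(th)
        s = np.sin(th)
        ux = orient[i, 0]
        uy = orient[i, 1]
        uz = orient[i, 2]
        cx = ky * uz - kz * uy
        cy = kz * ux - kx * uz
        cz = kx * uy - ky * ux
        dot = kx * ux + ky * uy + kz * uz
        nx = ux * c + cx * s + kx * dot * (1.0 - c)
        ny = uy * c + cy * s + ky * dot * (1.0 - c)
        nz = uz * c + cz * s + kz * dot * (1.0 - c)
        nrm = np.sqrt(nx * nx + ny * ny + nz * nz)
        orient[i, 0] = nx / nrm
        orient[i, 1] = ny / nrm
        orient[i, 2] = nz / nrm


@njit(cache=True)
def _ang_kick_project(angvel, orient, torque, inertia, dipolar, dt_acc):
    for i in range(angvel.shape[0]):
        if not dipolar[i]:
            continue
        angvel[i, 0] += dt_acc * torque[i, 0] / inertia[i]
        angvel[i, 1] += dt_acc * torque[i, 1] / inertia[i]
        angvel[i, 2] += dt_acc * torque[i, 2] / inertia[i]
        d = (angvel[i, 0] * orient[i, 0] + angvel[i, 1] * orient[i, 1]
             + angvel[i, 2] * orient[i, 2])
        angvel[i, 0] -= d * orient[i, 0]
        angvel[i, 1] -= d * orient[i, 1]
        angvel[i, 2] -= d * orient[i, 2]


@njit(cache=True)
def _rattle_vel(vel, pos, box, con_i, con_j, mass):
    for c in range(con_i.shape[0]):
        i = con_i[c]
        j = con_j[c]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        d2 = dx * dx + dy * dy + dz * dz
        mu = 1.0 / (1.0 / mass[i] + 1.0 / mass[j])
        g = ((vel[i, 0] - vel[j, 0]) * dx + (vel[i, 1] - vel[j, 1]) * dy
             + (vel[i, 2] - vel[j, 2]) * dz) * mu / d2
        vel[i, 0] -= g / mass[i] * dx
        vel[i, 1] -= g / mass[i] * dy
        vel[i, 2] -= g / mass[i] * dz
        vel[j, 0] += g / mass[j] * dx
        vel[j, 1] += g / mass[j] * dy
        vel[j, 2] += g / mass[j] * dz


@njit(cache=True)
def _half_drift(pos, vel, orient, angvel, box, dipolar, mass,
                con_i, con_j, con_d, shake_tol, shake_max_iter, half):
    n = pos.shape[0]
    if con_i.shape[0] > 0:
        old = pos.copy()
        for i in range(n):
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        unc = pos.copy()
        inv_m = 1.0 / mass
        shake_kernel(pos, old, box, con_i, con_j, con_d, inv_m,
                     shake_tol, shake_max_iter)
        for i in range(n):
            vel[i, 0] += (pos[i, 0] - unc[i, 0]) / half
            vel[i, 1] += (pos[i, 1] - unc[i, 1]) / half
            vel[i, 2] += (pos[i, 2] - unc[i, 2]) / half
    else:
        for i in range(n):
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
    _rotate_sites(orient, angvel, dipolar, half)


@njit(cache=True)
def inner_loop(pos, vel, orient, angvel, box,
               sigma, eps, charge, mumag, mol, solute, cg,
               mass, inertia, dipolar,
               pairs_inner, bond_i, bond_j, bond_r0, bond_k,
               con_i, con_j, con_d, shake_tol, shake_max_iter,
               r_cut, lam_f, mts_ratio, dt_i,
               do_thermo, c1, kt, noise_t, noise_r,
               f_in, t_in):
    """The inner (fast-force) part of one impulse-MTS cycle: ``mts_ratio``
    BAOAB steps with recomputation of the non-CG-CG forces between steps.
    All state arrays are updated in place; ``noise_t``/``noise_r`` hold
    pre-drawn standard normals of shape (mts_ratio, n, 3)."""
    n = pos.shape[0]
    half = 0.5 * dt_i
    acc = 1.0e-4
    kick = half * acc
    for k in range(mts_ratio):
        # B
        for i in range(n):
            vel[i, 0] += kick * f_in[i, 0] / mass[i]
            vel[i, 1] += kick * f_in[i, 1] / mass[i]
            vel[i, 2] += kick * f_in[i, 2] / mass[i]
        _ang_kick_project(angvel, orient, t_in, inertia, dipolar, kick)
        # A
        _half_drift(pos, vel, orient, angvel, box, dipolar, mass,
                    con_i, con_j, con_d, shake_tol, shake_max_iter, half)
        # O
        if do_thermo:
            c2f = np.sqrt((1.0 - c1 * c1) * kt * acc)
            for i in range(n):
                c2 = c2f / np.sqrt(mass[i])
                vel[i, 0] = c1 * vel[i, 0] + c2 * noise_t[k, i, 0]
                vel[i, 1] = c1 * vel[i, 1] + c2 * noise_t[k, i, 1]
                vel[i, 2] = c1 * vel[i, 2] + c2 * noise_t[k, i, 2]
                if dipolar[i]:
                    c2r = c2f / np.sqrt(inertia[i])
                    angvel[i, 0] = c1 * angvel[i, 0] + c2r * noise_r[k, i, 0]
                    angvel[i, 1] = c1 * angvel[i, 1] + c2r * noise_r[k, i, 1]
                    angvel[i, 2] = c1 * angvel[i, 2] + c2r * noise_r[k, i, 2]
                    d = (angvel[i, 0] * orient[i, 0] + angvel[i, 1] * orient[i, 1]
                         + angvel[i, 2] * orient[i, 2])
                    angvel[i, 0] -= d * orient[i, 0]
                    angvel[i, 1] -= d * orient[i, 1]
                    angvel[i, 2] -= d * orient[i, 2]
            if con_i.shape[0] > 0:
                _rattle_vel(vel, pos, box, con_i, con_j, mass)
        # A
        _half_drift(pos, vel, orient, angvel, box, dipolar, mass,
                    con_i, con_j, con_d, shake_tol, shake_max_iter, half)
        if k + 1 < mts_ratio:
            out = nonbonded_sweep(pairs_inner, pos, box, sigma, eps, charge,
                                  mumag, orient, mol, solute, cg, r_cut, lam_f)
            for i in range(n):
                f_in[i, 0] = out[4][i, 0] + out[5][i, 0]
                f_in[i, 1] = out[4][i, 1] + out[5][i, 1]
                f_in[i, 2] = out[4][i, 2] + out[5][i, 2]
                t_in[i, 0] = out[6][i, 0] + out[7][i, 0]
                t_in[i, 1] = out[6][i, 1] + out[7][i, 1]
                t_in[i, 2] = out[6][i, 2] + out[7][i, 2]
            if bond_i.shape[0] > 0:
                bonded_sweep(pos, box, bond_i, bond_j, bond_r0, bond_k, f_in)
            # B (closing kick of step k; the opening kick of step k+1
            # reuses the same freshly evaluated forces)
            for i in range(n):
                vel[i, 0] += kick * f_in[i, 0] / mass[i]
                vel[i, 1] += kick * f_in[i, 1] / mass[i]
                vel[i, 2] += kick * f_in[i, 2] / mass[i]
            _ang_kick_project(angvel, orient, t_in, inertia, dipolar, kick)
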