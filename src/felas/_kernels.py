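"""Numba-compiled inner loops of the Langevin engine.

All math here mirrors the scalar reference implementations in
``felas.forcefield``; tests assert the two agree to round-off.  Positions
are kept unwrapped; periodic separations use the minimum-image round trick,
which is valid for displacements of any magnitude.
"""

from __future__ import annotations

import numpy as np
from numba import njit

WCA_RC2 = 2.0 ** (1.0 / 3.0)  # (2^(1/6))^2


@njit(cache=True, fastmath=True)
def build_neighbors(x, box, cutoff2, chain_id, nb_i, nb_j):
    """All-pairs O(N^2) neighbor build, excluding bonded (adjacent) pairs.

    Returns the number of pairs found; the caller must check it against
    capacity (len(nb_i)) and re-allocate on overflow.
    """
    n = x.shape[0]
    count = 0
    cap = nb_i.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if chain_id[i] == chain_id[j] and j - i == 1:
                continue  # bonded pair handled by the FENE term
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            dx -= box[0] * np.round(dx / box[0])
            dy -= box[1] * np.round(dy / box[1])
            dz -= box[2] * np.round(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < cutoff2:
                if count < cap:
                    nb_i[count] = i
                    nb_j[count] = j
                count += 1
    return count


@njit(cache=True, fastmath=True)
def compute_forces(
    x, box, types, epsmat, chain_id,
    nb_i, nb_j, n_pairs,
    fene_k, fene_r0, angle_k, theta0, rc,
    forces, virial,
):
    """Fill forces (N,3) and virial (3,3); return (potential energy, status).

    status: 0 ok, 1 a FENE bond reached R0 (distance clamped to keep the
    arithmetic finite so the caller can abort with diagnostics).
    """
    n = x.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    for a in range(3):
        for b in range(3):
            virial[a, b] = 0.0
    pe = 0.0
    status = 0

    rc2 = rc * rc
    # per-unit-epsilon shift constants of the force-shifted LJ
    uc1 = 4.0 * (rc ** -12 - rc ** -6)
    duc1 = 4.0 * (-12.0 * rc ** -13 + 6.0 * rc ** -7)

    # --- non-bonded pairs ---
    for p in range(n_pairs):
        i = nb_i[p]
        j = nb_j[p]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        dx -= box[0] * np.round(dx / box[0])
        dy -= box[1] * np.round(dy / box[1])
        dz -= box[2] * np.round(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        eps = epsmat[types[i], types[j]]
        if eps > 0.0:
            if r2 >= rc2:
                continue
            r = np.sqrt(r2)
            sr6 = 1.0 / (r2 * r2 * r2)
            u = 4.0 * eps * (sr6 * sr6 - sr6)
            dudr = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
            pe += u - eps * uc1 - (r - rc) * eps * duc1
            fmag = -(dudr - eps * duc1)
        else:
            if r2 >= WCA_RC2:
                continue
            r = np.sqrt(r2)
            sr6 = 1.0 / (r2 * r2 * r2)
            pe += 4.0 * (sr6 * sr6 - sr6) + 1.0
            fmag = -(4.0 * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r)
        fx = fmag * dx / r
        fy = fmag * dy / r
        fz = fmag * dz / r
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0, 0] += dx * fx
        virial[1, 1] += dy * fy
        virial[2, 2] += dz * fz
        virial[0, 1] += dx * fy
        virial[1, 2] += dy * fz
        virial[0, 2] += dx * fz

    # --- FENE bonds (+ unit-epsilon WCA core between bonded beads) ---
    r02 = fene_r0 * fene_r0
    for i in range(n - 1):
        if chain_id[i] != chain_id[i + 1]:
            continue
        j = i + 1
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        dx -= box[0] * np.round(dx / box[0])
        dy -= box[1] * np.round(dy / box[1])
        dz -= box[2] * np.round(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= 0.998 * r02:
            status = 1
            r2 = 0.998 * r02
        r = np.sqrt(r2)
        pe += -0.5 * fene_k * r02 * np.log(1.0 - r2 / r02)
        fmag = -fene_k * r / (1.0 - r2 / r02)  # attractive
        if r2 < WCA_RC2:
            sr6 = 1.0 / (r2 * r2 * r2)
            pe += 4.0 * (sr6 * sr6 - sr6) + 1.0
            fmag += -(4.0 * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r)
        fx = fmag * dx / r
        fy = fmag * dy / r
        fz = fmag * dz / r
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0, 0] += dx * fx
        virial[1, 1] += dy * fy
        virial[2, 2] += dz * fz
        virial[0, 1] += dx * fy
        virial[1, 2] += dy * fz
        virial[0, 2] += dx * fz

    # --- harmonic angles on consecutive triplets ---
    if angle_k > 0.0:
        for b in range(1, n - 1):
            if chain_id[b - 1] != chain_id[b] or chain_id[b] != chain_id[b + 1]:
                continue
            a = b - 1
            c = b + 1
            ux = x[a, 0] - x[b, 0]
            uy = x[a, 1] - x[b, 1]
            uz = x[a, 2] - x[b, 2]
            vx = x[c, 0] - x[b, 0]
            vy = x[c, 1] - x[b, 1]
            vz = x[c, 2] - x[b, 2]
            ux -= box[0] * np.round(ux / box[0])
            uy -= box[1] * np.round(uy / box[1])
            uz -= box[2] * np.round(uz / box[2])
            vx -= box[0] * np.round(vx / box[0])
            vy -= box[1] * np.round(vy / box[1])
            vz -= box[2] * np.round(vz / box[2])
            ru = np.sqrt(ux * ux + uy * uy + uz * uz)
            rv = np.sqrt(vx * vx + vy * vy + vz * vz)
            ct = (ux * vx + uy * vy + uz * vz) / (ru * rv)
            if ct > 1.0:
                ct = 1.0
            if ct < -1.0:
                ct = -1.0
            theta = np.arccos(ct)
            dtheta = theta - theta0
            pe += angle_k * dtheta * dtheta
            st = np.sqrt(1.0 - ct * ct)
            if st < 1e-8:
                st = 1e-8
            coef = 2.0 * angle_k * dtheta / st
            # d(cos theta)/d r_a and /d r_c
            dax = vx / (ru * rv) - ct * ux / (ru * ru)
            day = vy / (ru * rv) - ct * uy / (ru * ru)
            daz = vz / (ru * rv) - ct * uz / (ru * ru)
            dcx = ux / (ru * rv) - ct * vx / (rv * rv)
            dcy = uy / (ru * rv) - ct * vy / (rv * rv)
            dcz = uz / (ru * rv) - ct * vz / (rv * rv)
            fax = coef * dax
            fay = coef * day
            faz = coef * daz
            fcx = coef * dcx
            fcy = coef * dcy
            fcz = coef * dcz
            forces[a, 0] += fax
            forces[a, 1] += fay
            forces[a, 2] += faz
            forces[c, 0] += fcx
            forces[c, 1] += fcy
            forces[c, 2] += fcz
            forces[b, 0] -= fax + fcx
            forces[b, 1] -= fay + fcy
            forces[b, 2] -= faz + fcz
            virial[0, 0] += ux * fax + vx * fcx
            virial[1, 1] += uy * fay + vy * fcy
            virial[2, 2] += uz * faz + vz * fcz
            virial[0, 1] += ux * fay + vx * fcy
            virial[1, 2] += uy * faz + vy * fcz
            virial[0, 2] += ux * faz + vx * fcz

    return pe, status


@njit(cache=True, fastmath=True)
def _cap_forces(forces, force_cap):
    for i in range(forces.shape[0]):
        fm = np.sqrt(
            forces[i, 0] ** 2 + forces[i, 1] ** 2 + forces[i, 2] ** 2
        )
        if fm > force_cap:
            s = force_cap / fm
            forces[i, 0] *= s
            forces[i, 1] *= s
            forces[i, 2] *= s


@njit(cache=True, fastmath=True)
def run_langevin(
    x, v, box, types, epsmat, chain_id,
    fene_k, fene_r0, angle_k, theta0, rc,
    dt, gamma, kT, mass, n_steps, seed, skin, force_cap,
    traj_stride, stress_stride, t0,
    traj_times, traj_pos, stress_out, log_out,
    nb_i, nb_j, x_ref, forces, virial,
):
    """BAOAB Langevin integration of ``n_steps`` steps, in place.

    Records unwrapped frames every ``traj_stride`` steps and stress/log rows
    every ``stress_stride`` steps (stride 0 disables a channel).  Returns
    (status, n_frames, n_stress): status 0 ok, 1 bond overextension,
    2 neighbor-capacity overflow, 3 non-finite coordinates.
    """
    n = x.shape[0]
    np.random.seed(seed)
    volume = box[0] * box[1] * box[2]
    cutoff = rc + skin
    cutoff2 = cutoff * cutoff
    half_skin2 = (0.5 * skin) * (0.5 * skin)

    c1 = np.exp(-gamma * dt / mass)
    c2 = np.sqrt(kT * (1.0 - c1 * c1) / mass)

    n_pairs = build_neighbors(x, box, cutoff2, chain_id, nb_i, nb_j)
    if n_pairs > nb_i.shape[0]:
        return 2, 0, 0
    for i in range(n):
        for d in range(3):
            x_ref[i, d] = x[i, d]
    pe, status = compute_forces(
        x, box, types, epsmat, chain_id, nb_i, nb_j, n_pairs,
        fene_k, fene_r0, angle_k, theta0, rc, forces, virial,
    )
    if force_cap > 0.0:
        _cap_forces(forces, force_cap)

    n_frames = 0
    n_stress = 0
    for step in range(n_steps):
        # B
        for i in range(n):
            for d in range(3):
                v[i, d] += 0.5 * dt * forces[i, d] / mass
        # A
        for i in range(n):
            for d in range(3):
                x[i, d] += 0.5 * dt * v[i, d]
        # O
        if gamma > 0.0:
            for i in range(n):
                for d in range(3):
                    v[i, d] = c1 * v[i, d] + c2 * np.random.normal(0.0, 1.0)
        # A
        for i in range(n):
            for d in range(3):
                x[i, d] += 0.5 * dt * v[i, d]

        # neighbor-list refresh on displacement criterion
        max_d2 = 0.0
        for i in range(n):
            d2 = 0.0
            for d in range(3):
                dd = x[i, d] - x_ref[i, d]
                d2 += dd * dd
            if d2 > max_d2:
                max_d2 = d2
        if max_d2 > half_skin2:
            n_pairs = build_neighbors(x, box, cutoff2, chain_id, nb_i, nb_j)
            if n_pairs > nb_i.shape[0]:
                return 2, n_frames, n_stress
            for i in range(n):
                for d in range(3):
                    x_ref[i, d] = x[i, d]

        pe, st_f = compute_forces(
            x, box, types, epsmat, chain_id, nb_i, nb_j, n_pairs,
            fene_k, fene_r0, angle_k, theta0, rc, forces, virial,
        )
        if st_f != 0 and force_cap <= 0.0:
            return 1, n_frames, n_stress
        if force_cap > 0.0:
            _cap_forces(forces, force_cap)
        # B
        for i in range(n):
            for d in range(3):
                v[i, d] += 0.5 * dt * forces[i, d] / mass

        if not np.isfinite(x[0, 0]):
            return 3, n_frames, n_stress

        t = t0 + (step + 1) * dt
        if traj_stride > 0:
            if (step + 1) % traj_stride == 0 and n_frames < traj_pos.shape[0]:
                traj_times[n_frames] = t
                for i in range(n):
                    for d in range(3):
                        traj_pos[n_frames, i, d] = x[i, d]
                n_frames += 1
        if stress_stride > 0:
            if (step + 1) % stress_stride == 0 and n_stress < stress_out.shape[0]:
                ke = 0.0
                kxx = 0.0
                kyy = 0.0
                kzz = 0.0
                kxy = 0.0
                kyz = 0.0
                kxz = 0.0
                for i in range(n):
                    kxx += mass * v[i, 0] * v[i, 0]
                    kyy += mass * v[i, 1] * v[i, 1]
                    kzz += mass * v[i, 2] * v[i, 2]
                    kxy += mass * v[i, 0] * v[i, 1]
                    kyz += mass * v[i, 1] * v[i, 2]
                    kxz += mass * v[i, 0] * v[i, 2]
                ke = 0.5 * (kxx + kyy + kzz)
                sxx = (kxx + virial[0, 0]) / volume
                syy = (kyy + virial[1, 1]) / volume
                szz = (kzz + virial[2, 2]) / volume
                sxy = (kxy + virial[0, 1]) / volume
                syz = (kyz + virial[1, 2]) / volume
                sxz = (kxz + virial[0, 2]) / volume
                stress_out[n_stress, 0] = t
                stress_out[n_stress, 1] = sxy
                stress_out[n_stress, 2] = syz
                stress_out[n_stress, 3] = sxz
                stress_out[n_stress, 4] = sxx - syy
                stress_out[n_stress, 5] = syy - szz
                stress_out[n_stress, 6] = sxx - szz
                log_out[n_stress, 0] = t
                log_out[n_stress, 1] = ke
                log_out[n_stress, 2] = pe
                log_out[n_stress, 3] = 2.0 * ke / (3.0 * n)
                n_stress += 1

    return 0, n_frames, n_stress
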