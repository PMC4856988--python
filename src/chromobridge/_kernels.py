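"""Numba kernels for the Brownian/Langevin dynamics engine.

Everything here works in reduced units (sigma = 1 for a chromatin bead,
k_BT = 1, bead friction gamma = 1 so the bead diffusion time is the time
unit).  Positions are stored *unwrapped*; the periodic box only enters
through minimum-image displacements, which is exact because every
interaction range is far below half the box edge.

Error handling is by return code (numba-friendly): 0 = ok,
1 = FENE bond overstretched (info carries the bond ends and the step),
2 = non-finite coordinate, 3 = pair-list capacity overflow,
4 = placement failure during initialization.
"""

from __future__ import annotations

import numpy as np
from numba import njit

WCA_CUT = 2.0 ** (1.0 / 6.0)

OK = 0
ERR_BOND = 1
ERR_NONFINITE = 2
ERR_CAPACITY = 3
ERR_PLACEMENT = 4

INTEGRATOR_BAOAB = 0
INTEGRATOR_EM = 1


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, fastmath=True)
def build_pairs(pos, L, rlist, pair_i, pair_j):
    """Fill pair arrays with all pairs at minimum-image distance <= rlist.

    Returns the number of pairs, or -1 on capacity overflow.  Uses a cell
    list when the box accommodates >= 3 cells per edge, else brute force.
    """
    n = pos.shape[0]
    rl2 = rlist * rlist
    cap = pair_i.shape[0]
    ncell = int(L / rlist)
    npairs = 0
    if ncell < 3:
        for i in range(n):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                dx -= L * np.floor(dx / L + 0.5)
                dy -= L * np.floor(dy / L + 0.5)
                dz -= L * np.floor(dz / L + 0.5)
                if dx * dx + dy * dy + dz * dz <= rl2:
                    if npairs >= cap:
                        return -1
                    pair_i[npairs] = i
                    pair_j[npairs] = j
                    npairs += 1
        return npairs
    csz = L / ncell
    head = np.full(ncell * ncell * ncell, -1, np.int64)
    nxt = np.empty(n, np.int64)
    ccoord = np.empty((n, 3), np.int64)
    for i in range(n):
        cx = int((pos[i, 0] - L * np.floor(pos[i, 0] / L)) / csz)
        cy = int((pos[i, 1] - L * np.floor(pos[i, 1] / L)) / csz)
        cz = int((pos[i, 2] - L * np.floor(pos[i, 2] / L)) / csz)
        if cx >= ncell:
            cx = ncell - 1
        if cy >= ncell:
            cy = ncell - 1
        if cz >= ncell:
            cz = ncell - 1
        c = (cx * ncell + cy) * ncell + cz
        ccoord[i, 0] = cx
        ccoord[i, 1] = cy
        ccoord[i, 2] = cz
        nxt[i] = head[c]
        head[c] = i
    for i in range(n):
        cx = ccoord[i, 0]
        cy = ccoord[i, 1]
        cz = ccoord[i, 2]
        for ox in range(-1, 2):
            ax = (cx + ox) % ncell
            for oy in range(-1, 2):
                ay = (cy + oy) % ncell
                for oz in range(-1, 2):
                    az = (cz + oz) % ncell
                    j = head[(ax * ncell + ay) * ncell + az]
                    while j != -1:
                        if j < i:
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            dx -= L * np.floor(dx / L + 0.5)
                            dy -= L * np.floor(dy / L + 0.5)
                            dz -= L * np.floor(dz / L + 0.5)
                            if dx * dx + dy * dy + dz * dz <= rl2:
                                if npairs >= cap:
                                    return -1
                                pair_i[npairs] = j
                                pair_j[npairs] = i
                                npairs += 1
                        j = nxt[j]
    return npairs


@njit(cache=True)
def _is_bonded(code, bond_codes):
    lo = 0
    hi = bond_codes.shape[0]
    while lo < hi:
        mid = (lo + hi) // 2
        v = bond_codes[mid]
        if v == code:
            return True
        if v < code:
            lo = mid + 1
        else:
            hi = mid
    return False


@njit(cache=True, fastmath=True)
def rebuild_pairs(wpos, L, rlist, head, nxt, ccoord, nbr_table, ncell,
                  diam, species_of, eps_fb, bond_codes, pair_i, pair_j,
                  pair_eps, pair_sij2, pair_f, pair_b, pair_sp):
    """Cell-list Verlet rebuild with per-pair parameters baked in.

    For each pair within ``rlist`` stores the particle ids, the pair's
    attraction epsilon (0 for pure sterics), sigma_ij^2, and — for
    factor–bead pairs — the factor/bead ids and factor species (for the
    valence-capped control).  Returns pair count or -1 on overflow.
    """
    n = wpos.shape[0]
    rl2 = rlist * rlist
    cap = pair_i.shape[0]
    csz = L / ncell
    inv_csz = 1.0 / csz
    nc3 = ncell * ncell * ncell
    for c in range(nc3):
        head[c] = -1
    for i in range(n):
        cx = int(wpos[i, 0] * inv_csz)
        cy = int(wpos[i, 1] * inv_csz)
        cz = int(wpos[i, 2] * inv_csz)
        if cx >= ncell:
            cx = ncell - 1
        if cy >= ncell:
            cy = ncell - 1
        if cz >= ncell:
            cz = ncell - 1
        c = (cx * ncell + cy) * ncell + cz
        ccoord[i] = c
        nxt[i] = head[c]
        head[c] = i
    npairs = 0
    for i in range(n):
        ci = ccoord[i]
        for k in range(27):
            nb = nbr_table[ci, k]
            if nb < 0:
                break
            j = head[nb]
            while j != -1:
                if j < i:
                    dx = wpos[i, 0] - wpos[j, 0]
                    dy = wpos[i, 1] - wpos[j, 1]
                    dz = wpos[i, 2] - wpos[j, 2]
                    if dx > 0.5 * L:
                        dx -= L
                    elif dx < -0.5 * L:
                        dx += L
                    if dy > 0.5 * L:
                        dy -= L
                    elif dy < -0.5 * L:
                        dy += L
                    if dz > 0.5 * L:
                        dz -= L
                    elif dz < -0.5 * L:
                        dz += L
                    if dx * dx + dy * dy + dz * dz <= rl2:
                        if npairs >= cap:
                            return -1
                        pair_i[npairs] = i
                        pair_j[npairs] = j
                        si = species_of[i]
                        sj = species_of[j]
                        eps = 0.0
                        f = -1
                        b = -1
                        sp = -1
                        if _is_bonded(j * n + i if j < i else i * n + j,
                                      bond_codes):
                            sp = -2  # bonded: sterics live in the bond term
                        elif si >= 0 and sj < 0:
                            eps = eps_fb[si, j]
                            f = i
                            b = j
                            sp = si
                        elif sj >= 0 and si < 0:
                            eps = eps_fb[sj, i]
                            f = j
                            b = i
                            sp = sj
                        pair_eps[npairs] = eps
                        sij = 0.5 * (diam[i] + diam[j])
                        pair_sij2[npairs] = sij * sij
                        pair_f[npairs] = f
                        pair_b[npairs] = b
                        pair_sp[npairs] = sp
                        npairs += 1
                j = nxt[j]
    return npairs


@njit(cache=True, fastmath=True)
def _select_partners(wpos, L, capped, pair_eps, pair_sij2, pair_f, pair_b,
                     pair_sp, pair_i, pair_j, npairs, rc_attr2, partner,
                     best_r2):
    """For valence-capped factor species, pick the nearest cognate bead.

    Only that bead receives the attractive interaction this step, which
    caps the factor's simultaneous cognate contacts at one (the monovalent
    control).
    """
    n = partner.shape[0]
    for i in range(n):
        partner[i] = -1
        best_r2[i] = 1e30
    for p in range(npairs):
        sp = pair_sp[p]
        if sp < 0 or not capped[sp] or pair_eps[p] <= 0.0:
            continue
        i = pair_i[p]
        j = pair_j[p]
        dx = wpos[i, 0] - wpos[j, 0]
        dy = wpos[i, 1] - wpos[j, 1]
        dz = wpos[i, 2] - wpos[j, 2]
        if dx > 0.5 * L:
            dx -= L
        elif dx < -0.5 * L:
            dx += L
        if dy > 0.5 * L:
            dy -= L
        elif dy < -0.5 * L:
            dy += L
        if dz > 0.5 * L:
            dz -= L
        elif dz < -0.5 * L:
            dz += L
        r2 = dx * dx + dy * dy + dz * dz
        f = pair_f[p]
        if r2 < rc_attr2 * pair_sij2[p] and r2 < best_r2[f]:
            best_r2[f] = r2
            partner[f] = pair_b[p]


@njit(cache=True, fastmath=True)
def compute_forces(wpos, L, capped, any_capped,
                   bonds, kfene, r0, angles, kb_angle, eps_wca, rc_attr2,
                   wca_cut2, diam_b, bond_wca_eps, pair_i, pair_j, pair_eps,
                   pair_sij2, pair_f, pair_b, pair_sp, npairs, partner,
                   best_r2, forces, fcap):
    """Accumulate all forces into ``forces``; returns (code, a, b)."""
    n = wpos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    if any_capped:
        _select_partners(wpos, L, capped, pair_eps, pair_sij2, pair_f,
                         pair_b, pair_sp, pair_i, pair_j, npairs, rc_attr2,
                         partner, best_r2)
    # non-bonded
    halfL = 0.5 * L
    for p in range(npairs):
        i = pair_i[p]
        j = pair_j[p]
        dx = wpos[i, 0] - wpos[j, 0]
        dy = wpos[i, 1] - wpos[j, 1]
        dz = wpos[i, 2] - wpos[j, 2]
        if dx > halfL:
            dx -= L
        elif dx < -halfL:
            dx += L
        if dy > halfL:
            dy -= L
        elif dy < -halfL:
            dy += L
        if dz > halfL:
            dz -= L
        elif dz < -halfL:
            dz += L
        r2 = dx * dx + dy * dy + dz * dz
        if r2 <= 0.0:
            return ERR_NONFINITE, i, j
        if pair_sp[p] == -2:
            continue
        eps = pair_eps[p]
        if any_capped and eps > 0.0:
            sp = pair_sp[p]
            if sp >= 0 and capped[sp] and partner[pair_f[p]] != pair_b[p]:
                eps = 0.0
        sij2 = pair_sij2[p]
        fr = 0.0
        if eps > 0.0:
            if r2 < rc_attr2 * sij2:
                s2 = sij2 / r2
                s6 = s2 * s2 * s2
                fr = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
        else:
            if r2 < wca_cut2 * sij2:
                s2 = sij2 / r2
                s6 = s2 * s2 * s2
                fr = 24.0 * eps_wca * (2.0 * s6 * s6 - s6) / r2
        if fr != 0.0:
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz
    # FENE bonds
    r02 = r0 * r0
    for b in range(bonds.shape[0]):
        ia = bonds[b, 0]
        ib = bonds[b, 1]
        dx = wpos[ia, 0] - wpos[ib, 0]
        dy = wpos[ia, 1] - wpos[ib, 1]
        dz = wpos[ia, 2] - wpos[ib, 2]
        if dx > halfL:
            dx -= L
        elif dx < -halfL:
            dx += L
        if dy > halfL:
            dy -= L
        elif dy < -halfL:
            dy += L
        if dz > halfL:
            dz -= L
        elif dz < -halfL:
            dz += L
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r02 or not np.isfinite(r2):
            return ERR_BOND, ia, ib
        fr = -kfene / (1.0 - r2 / r02)
        sij = 0.5 * (diam_b[ia] + diam_b[ib])
        if r2 < WCA_CUT * WCA_CUT * sij * sij:
            s2 = sij * sij / r2
            s6 = s2 * s2 * s2
            fr += 24.0 * bond_wca_eps * (2.0 * s6 * s6 - s6) / r2
        forces[ia, 0] += fr * dx
        forces[ia, 1] += fr * dy
        forces[ia, 2] += fr * dz
        forces[ib, 0] -= fr * dx
        forces[ib, 1] -= fr * dy
        forces[ib, 2] -= fr * dz
    # Kratky-Porod angles
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        b1x = wpos[j, 0] - wpos[i, 0]
        b1y = wpos[j, 1] - wpos[i, 1]
        b1z = wpos[j, 2] - wpos[i, 2]
        b2x = wpos[k, 0] - wpos[j, 0]
        b2y = wpos[k, 1] - wpos[j, 1]
        b2z = wpos[k, 2] - wpos[j, 2]
        if b1x > halfL:
            b1x -= L
        elif b1x < -halfL:
            b1x += L
        if b1y > halfL:
            b1y -= L
        elif b1y < -halfL:
            b1y += L
        if b1z > halfL:
            b1z -= L
        elif b1z < -halfL:
            b1z += L
        if b2x > halfL:
            b2x -= L
        elif b2x < -halfL:
            b2x += L
        if b2z > halfL:
            b2z -= L
        elif b2z < -halfL:
            b2z += L
        if b2y > halfL:
            b2y -= L
        elif b2y < -halfL:
            b2y += L
        n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        inv12 = 1.0 / (n1 * n2)
        c = (b1x * b2x + b1y * b2y + b1z * b2z) * inv12
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        kb = kb_angle[a]
        # dc/db1 and dc/db2
        g1x = b2x * inv12 - c * b1x / (n1 * n1)
        g1y = b2y * inv12 - c * b1y / (n1 * n1)
        g1z = b2z * inv12 - c * b1z / (n1 * n1)
        g2x = b1x * inv12 - c * b2x / (n2 * n2)
        g2y = b1y * inv12 - c * b2y / (n2 * n2)
        g2z = b1z * inv12 - c * b2z / (n2 * n2)
        # U = kb (1 - c):  F_i = -kb * dc/db1, F_k = kb * dc/db2
        forces[i, 0] -= kb * g1x
        forces[i, 1] -= kb * g1y
        forces[i, 2] -= kb * g1z
        forces[k, 0] += kb * g2x
        forces[k, 1] += kb * g2y
        forces[k, 2] += kb * g2z
        forces[j, 0] += kb * (g1x - g2x)
        forces[j, 1] += kb * (g1y - g2y)
        forces[j, 2] += kb * (g1z - g2z)
    if fcap > 0.0:
        for i in range(n):
            fm2 = (forces[i, 0] * forces[i, 0] + forces[i, 1] * forces[i, 1]
                   + forces[i, 2] * forces[i, 2])
            if fm2 > fcap * fcap:
                s = fcap / np.sqrt(fm2)
                forces[i, 0] *= s
                forces[i, 1] *= s
                forces[i, 2] *= s
    return OK, -1, -1


@njit(cache=True, fastmath=True)
def _max_disp2(pos, ref):
    m = 0.0
    for i in range(pos.shape[0]):
        dx = pos[i, 0] - ref[i, 0]
        dy = pos[i, 1] - ref[i, 1]
        dz = pos[i, 2] - ref[i, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > m:
            m = d2
    return m


@njit(cache=True, fastmath=True)
def run_chunk(pos, vel, L, diam, species_of, eps_fb, capped, any_capped,
              bonds, bond_codes, bond_wca_eps, kfene, r0, angles, kb_angle,
              eps_wca, rc_attr,
              dt, kT, gamma0, integrator, n_steps, step_offset,
              sample_stride, frames, frame_fill, skin, rlist,
              ncell, nbr_table, head, nxt, ccoord,
              pair_i, pair_j, pair_eps, pair_sij2, pair_f, pair_b, pair_sp,
              partner, best_r2, forces, ref, wpos, noise, fcap):
    """Integrate ``n_steps`` steps, storing frames at the global stride.

    ``noise`` is an (n_steps, n, 3) block of standard normals generated by
    the caller (empty when kT == 0); all other scratch arrays are
    preallocated by the caller and reused across chunks.  Returns
    (code, info_a, info_b, failing_step, frames_written).
    """
    n = pos.shape[0]
    rc_attr2 = rc_attr * rc_attr
    wca_cut2 = WCA_CUT * WCA_CUT
    for i in range(n):
        wpos[i, 0] = pos[i, 0] - L * np.floor(pos[i, 0] / L)
        wpos[i, 1] = pos[i, 1] - L * np.floor(pos[i, 1] / L)
        wpos[i, 2] = pos[i, 2] - L * np.floor(pos[i, 2] / L)
    npairs = rebuild_pairs(wpos, L, rlist, head, nxt, ccoord, nbr_table,
                           ncell, diam, species_of, eps_fb, bond_codes,
                           pair_i, pair_j, pair_eps, pair_sij2, pair_f,
                           pair_b, pair_sp)
    if npairs < 0:
        return ERR_CAPACITY, -1, -1, step_offset, 0
    for i in range(n):
        ref[i, 0] = pos[i, 0]
        ref[i, 1] = pos[i, 1]
        ref[i, 2] = pos[i, 2]
    code, ea, eb = compute_forces(wpos, L, capped, any_capped, bonds, kfene,
                                  r0, angles, kb_angle, eps_wca, rc_attr2,
                                  wca_cut2, diam, bond_wca_eps, pair_i,
                                  pair_j, pair_eps, pair_sij2, pair_f,
                                  pair_b, pair_sp, npairs, partner, best_r2,
                                  forces, fcap)
    if code != OK:
        return code, ea, eb, step_offset, 0
    # per-particle friction and BAOAB coefficients (mass = 1)
    gam = np.empty(n)
    c1 = np.empty(n)
    c2 = np.empty(n)
    amp = np.empty(n)
    for i in range(n):
        gam[i] = gamma0 * diam[i]
        c1[i] = np.exp(-gam[i] * dt)
        c2[i] = np.sqrt(kT * (1.0 - c1[i] * c1[i]))
        amp[i] = np.sqrt(2.0 * kT * dt / gam[i])
    half = 0.5 * dt
    thresh2 = 0.25 * skin * skin
    written = 0
    have_noise = noise.shape[0] > 0
    for s in range(n_steps):
        if integrator == INTEGRATOR_BAOAB:
            for i in range(n):
                vx = vel[i, 0] + half * forces[i, 0]
                vy = vel[i, 1] + half * forces[i, 1]
                vz = vel[i, 2] + half * forces[i, 2]
                pos[i, 0] += half * vx
                pos[i, 1] += half * vy
                pos[i, 2] += half * vz
                if have_noise:
                    vx = c1[i] * vx + c2[i] * noise[s, i, 0]
                    vy = c1[i] * vy + c2[i] * noise[s, i, 1]
                    vz = c1[i] * vz + c2[i] * noise[s, i, 2]
                else:
                    vx = c1[i] * vx
                    vy = c1[i] * vy
                    vz = c1[i] * vz
                pos[i, 0] += half * vx
                pos[i, 1] += half * vy
                pos[i, 2] += half * vz
                vel[i, 0] = vx
                vel[i, 1] = vy
                vel[i, 2] = vz
                wpos[i, 0] = pos[i, 0] - L * np.floor(pos[i, 0] / L)
                wpos[i, 1] = pos[i, 1] - L * np.floor(pos[i, 1] / L)
                wpos[i, 2] = pos[i, 2] - L * np.floor(pos[i, 2] / L)
        else:  # Euler-Maruyama, overdamped
            for i in range(n):
                mob = dt / gam[i]
                if have_noise:
                    pos[i, 0] += mob * forces[i, 0] + amp[i] * noise[s, i, 0]
                    pos[i, 1] += mob * forces[i, 1] + amp[i] * noise[s, i, 1]
                    pos[i, 2] += mob * forces[i, 2] + amp[i] * noise[s, i, 2]
                else:
                    pos[i, 0] += mob * forces[i, 0]
                    pos[i, 1] += mob * forces[i, 1]
                    pos[i, 2] += mob * forces[i, 2]
                wpos[i, 0] = pos[i, 0] - L * np.floor(pos[i, 0] / L)
                wpos[i, 1] = pos[i, 1] - L * np.floor(pos[i, 1] / L)
                wpos[i, 2] = pos[i, 2] - L * np.floor(pos[i, 2] / L)
        if _max_disp2(pos, ref) > thresh2:
            npairs = rebuild_pairs(wpos, L, rlist, head, nxt, ccoord,
                                   nbr_table, ncell, diam, species_of,
                                   eps_fb, bond_codes, pair_i, pair_j,
                                   pair_eps, pair_sij2, pair_f, pair_b,
                                   pair_sp)
            if npairs < 0:
                return ERR_CAPACITY, -1, -1, step_offset + s, written
            for i in range(n):
                ref[i, 0] = pos[i, 0]
                ref[i, 1] = pos[i, 1]
                ref[i, 2] = pos[i, 2]
        code, ea, eb = compute_forces(wpos, L, capped, any_capped, bonds,
                                      kfene, r0, angles, kb_angle, eps_wca,
                                      rc_attr2, wca_cut2, diam, bond_wca_eps,
                                      pair_i, pair_j, pair_eps, pair_sij2,
                                      pair_f, pair_b, pair_sp, npairs,
                                      partner, best_r2, forces, fcap)
        if code != OK:
            return code, ea, eb, step_offset + s, written
        if integrator == INTEGRATOR_BAOAB:
            for i in range(n):
                vel[i, 0] += half * forces[i, 0]
                vel[i, 1] += half * forces[i, 1]
                vel[i, 2] += half * forces[i, 2]
        gstep = step_offset + s + 1
        if sample_stride > 0 and gstep % sample_stride == 0:
            if frame_fill + written < frames.shape[0]:
                for i in range(n):
                    frames[frame_fill + written, i, 0] = pos[i, 0]
                    frames[frame_fill + written, i, 1] = pos[i, 1]
                    frames[frame_fill + written, i, 2] = pos[i, 2]
                written += 1
    return OK, -1, -1, step_offset + n_steps, written


@njit(cache=True, fastmath=True)
def total_energy(pos, L, diam, species_of, eps_fb, bonds, bond_codes,
                 kfene, r0, angles, kb_angle, eps_wca, rc_attr,
                 bond_wca_eps):
    """Brute-force total potential energy in kT (for tests/diagnostics)."""
    n = pos.shape[0]
    u = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if _is_bonded(i * n + j, bond_codes):
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= L * np.floor(dx / L + 0.5)
            dy -= L * np.floor(dy / L + 0.5)
            dz -= L * np.floor(dz / L + 0.5)
            r2 = dx * dx + dy * dy + dz * dz
            sij = 0.5 * (diam[i] + diam[j])
            si = species_of[i]
            sj = species_of[j]
            eps = 0.0
            if si >= 0 and sj < 0:
                eps = eps_fb[si, j]
            elif sj >= 0 and si < 0:
                eps = eps_fb[sj, i]
            if eps > 0.0:
                rc = rc_attr * sij
                if r2 < rc * rc:
                    s6 = (sij * sij / r2) ** 3
                    sc6 = (sij / rc) ** 6
                    u += 4.0 * eps * (s6 * s6 - s6) - 4.0 * eps * (sc6 * sc6 - sc6)
            else:
                rc = WCA_CUT * sij
                if r2 < rc * rc:
                    s6 = (sij * sij / r2) ** 3
                    u += 4.0 * eps_wca * (s6 * s6 - s6) + eps_wca
    r02 = r0 * r0
    for b in range(bonds.shape[0]):
        ia = bonds[b, 0]
        ib = bonds[b, 1]
        dx = pos[ia, 0] - pos[ib, 0]
        dy = pos[ia, 1] - pos[ib, 1]
        dz = pos[ia, 2] - pos[ib, 2]
        dx -= L * np.floor(dx / L + 0.5)
        dy -= L * np.floor(dy / L + 0.5)
        dz -= L * np.floor(dz / L + 0.5)
        r2 = dx * dx + dy * dy + dz * dz
        u += -0.5 * kfene * r02 * np.log(1.0 - r2 / r02)
        sij = 0.5 * (diam[ia] + diam[ib])
        if r2 < WCA_CUT * WCA_CUT * sij * sij:
            s6 = (sij * sij / r2) ** 3
            u += 4.0 * bond_wca_eps * (s6 * s6 - s6) + bond_wca_eps
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        b1x = pos[j, 0] - pos[i, 0]
        b1y = pos[j, 1] - pos[i, 1]
        b1z = pos[j, 2] - pos[i, 2]
        b2x = pos[k, 0] - pos[j, 0]
        b2y = pos[k, 1] - pos[j, 1]
        b2z = pos[k, 2] - pos[j, 2]
        n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        c = (b1x * b2x + b1y * b2y + b1z * b2z) / (n1 * n2)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        u += kb_angle[a] * (1.0 - c)
    return u


@njit(cache=True)
def _cell_index(x, y, z, L, csz, ncell):
    cx = int((x - L * np.floor(x / L)) / csz)
    cy = int((y - L * np.floor(y / L)) / csz)
    cz = int((z - L * np.floor(z / L)) / csz)
    if cx >= ncell:
        cx = ncell - 1
    if cy >= ncell:
        cy = ncell - 1
    if cz >= ncell:
        cz = ncell - 1
    return (cx * ncell + cy) * ncell + cz, cx, cy, cz


@njit(cache=True, fastmath=True)
def _too_close(pos, count, x, y, z, L, csz, ncell, cells, cell_count,
               min_dist2):
    _, cx, cy, cz = _cell_index(x, y, z, L, csz, ncell)
    for ox in range(-1, 2):
        ax = (cx + ox) % ncell
        for oy in range(-1, 2):
            ay = (cy + oy) % ncell
            for oz in range(-1, 2):
                az = (cz + oz) % ncell
                c = (ax * ncell + ay) * ncell + az
                for k in range(cell_count[c]):
                    j = cells[c, k]
                    dx = x - pos[j, 0]
                    dy = y - pos[j, 1]
                    dz = z - pos[j, 2]
                    dx -= L * np.floor(dx / L + 0.5)
                    dy -= L * np.floor(dy / L + 0.5)
                    dz -= L * np.floor(dz / L + 0.5)
                    if dx * dx + dy * dy + dz * dz < min_dist2:
                        return True
    return False


@njit(cache=True)
def _cell_insert(idx, x, y, z, L, csz, ncell, cells, cell_count):
    c, _, _, _ = _cell_index(x, y, z, L, csz, ncell)
    k = cell_count[c]
    if k >= cells.shape[1]:
        return False
    cells[c, k] = idx
    cell_count[c] = k + 1
    return True


@njit(cache=True)
def _cell_remove(idx, x, y, z, L, csz, ncell, cells, cell_count):
    c, _, _, _ = _cell_index(x, y, z, L, csz, ncell)
    for k in range(cell_count[c]):
        if cells[c, k] == idx:
            cells[c, k] = cells[c, cell_count[c] - 1]
            cell_count[c] -= 1
            return


@njit(cache=True)
def place_system(fiber_sizes, n_factors, L, bond_len, min_dist, seed):
    """Grow self-avoiding random-walk fibers, then scatter factors.

    Returns (code, positions): fibers first (concatenated, each grown from
    a random origin), then factors placed uniformly avoiding overlap below
    ``min_dist``.  Backtracks on dead ends; gives up after a bounded number
    of attempts (code 4 = over-dense configuration).
    """
    np.random.seed(seed)
    n_beads = 0
    for s in range(fiber_sizes.shape[0]):
        n_beads += fiber_sizes[s]
    n = n_beads + n_factors
    pos = np.zeros((n, 3))
    ncell = int(L / min_dist)
    if ncell > 64:
        ncell = 64
    if ncell < 3:
        ncell = 3
    csz = L / ncell
    cells = np.full((ncell * ncell * ncell, 64), -1, np.int32)
    cell_count = np.zeros(ncell * ncell * ncell, np.int32)
    md2 = min_dist * min_dist
    idx = 0
    budget = 200 * n + 100000
    for s in range(fiber_sizes.shape[0]):
        start = idx
        placed = 0
        while placed < fiber_sizes[s]:
            if budget <= 0:
                return ERR_PLACEMENT, pos
            if placed == 0:
                x = np.random.random() * L
                y = np.random.random() * L
                z = np.random.random() * L
                if _too_close(pos, idx, x, y, z, L, csz, ncell, cells,
                              cell_count, md2):
                    budget -= 1
                    continue
            else:
                ok = False
                x = 0.0
                y = 0.0
                z = 0.0
                for _try in range(60):
                    u = 2.0 * np.random.random() - 1.0
                    phi = 2.0 * np.pi * np.random.random()
                    rxy = np.sqrt(1.0 - u * u)
                    px = pos[idx - 1, 0] + bond_len * rxy * np.cos(phi)
                    py = pos[idx - 1, 1] + bond_len * rxy * np.sin(phi)
                    pz = pos[idx - 1, 2] + bond_len * u
                    if not _too_close(pos, idx, px, py, pz, L, csz, ncell,
                                      cells, cell_count, md2):
                        x = px
                        y = py
                        z = pz
                        ok = True
                        break
                    budget -= 1
                if not ok:
                    # dead end: backtrack up to 10 beads of this fiber
                    nback = 10
                    if placed < nback:
                        nback = placed
                    for _ in range(nback):
                        idx -= 1
                        placed -= 1
                        _cell_remove(idx, pos[idx, 0], pos[idx, 1],
                                     pos[idx, 2], L, csz, ncell, cells,
                                     cell_count)
                    if placed == 0 and idx > start:
                        idx = start
                    continue
            pos[idx, 0] = x
            pos[idx, 1] = y
            pos[idx, 2] = z
            if not _cell_insert(idx, x, y, z, L, csz, ncell, cells,
                                cell_count):
                return ERR_PLACEMENT, pos
            idx += 1
            placed += 1
    for f in range(n_factors):
        done = False
        for _try in range(10000):
            x = np.random.random() * L
            y = np.random.random() * L
            z = np.random.random() * L
            if not _too_close(pos, idx, x, y, z, L, csz, ncell, cells,
                              cell_count, md2):
                pos[idx, 0] = x
                pos[idx, 1] = y
                pos[idx, 2] = z
                if not _cell_insert(idx, x, y, z, L, csz, ncell, cells,
                                    cell_count):
                    return ERR_PLACEMENT, pos
                idx += 1
                done = True
                break
        if not done:
            return ERR_PLACEMENT, pos
    return OK, pos
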