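"""Compiled inner loops: cell-list neighbour search, force evaluation and
the BAOAB Langevin integrator.  Everything here is numba ``@njit`` code
operating on plain arrays; the friendly interfaces live in ``engine``.

Conventions: positions in sigma, energies in kBT, single global NumPy RNG
stream seeded once per run, noise drawn bead-by-bead in fixed index order so
runs are bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# squared distance below which pair forces are evaluated at the clamp
# distance (0.3 sigma) instead — survives random initial overlaps
_R2_FLOOR = 0.09


@njit(cache=True, fastmath=True)
def build_pairs(pos, rlist2, Rc, pairs):
    """Half neighbour list (i<j) of pairs within sqrt(rlist2), via a cell list.

    Returns the number of pairs, or -1 if the ``pairs`` buffer is too small.
    """
    n = pos.shape[0]
    rlist = np.sqrt(rlist2)
    lo = -(Rc + 2.0)
    box = 2.0 * (Rc + 2.0)
    ncell = int(box / rlist)
    npair = 0
    if ncell < 3 or n < 64:
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                if dx * dx + dy * dy + dz * dz < rlist2:
                    if npair >= pairs.shape[0]:
                        return -1
                    pairs[npair, 0] = i
                    pairs[npair, 1] = j
                    npair += 1
        return npair

    cw = box / ncell
    head = np.full(ncell * ncell * ncell, -1, np.int32)
    nxt = np.empty(n, np.int32)
    cix = np.empty(n, np.int32)
    ciy = np.empty(n, np.int32)
    ciz = np.empty(n, np.int32)
    for i in range(n):
        ix = int((pos[i, 0] - lo) / cw)
        iy = int((pos[i, 1] - lo) / cw)
        iz = int((pos[i, 2] - lo) / cw)
        if ix < 0:
            ix = 0
        if iy < 0:
            iy = 0
        if iz < 0:
            iz = 0
        if ix >= ncell:
            ix = ncell - 1
        if iy >= ncell:
            iy = ncell - 1
        if iz >= ncell:
            iz = ncell - 1
        cix[i], ciy[i], ciz[i] = ix, iy, iz
        c = (ix * ncell + iy) * ncell + iz
        nxt[i] = head[c]
        head[c] = i

    for i in range(n):
        for ax in range(cix[i] - 1, cix[i] + 2):
            if ax < 0 or ax >= ncell:
                continue
            for ay in range(ciy[i] - 1, ciy[i] + 2):
                if ay < 0 or ay >= ncell:
                    continue
                for az in range(ciz[i] - 1, ciz[i] + 2):
                    if az < 0 or az >= ncell:
                        continue
                    j = head[(ax * ncell + ay) * ncell + az]
                    while j >= 0:
                        if j > i:
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            if dx * dx + dy * dy + dz * dz < rlist2:
                                if npair >= pairs.shape[0]:
                                    return -1
                                pairs[npair, 0] = i
                                pairs[npair, 1] = j
                                npair += 1
                        j = nxt[j]
    return npair


@njit(cache=True, fastmath=True)
def eval_forces(pos, species, eps_tab, rc2_tab, vcut_tab, bonds, angles,
                ks, k_bend, Rc, pairs, npair, forces, want_energy, n_poly):
    """Accumulate bond + angle + pair + wall forces; return (PE, n_clamped).

    Directly bonded (1-2) polymer pairs are excluded from the non-bonded
    term, so the bond-length distribution peaks at sigma.  PE is only
    meaningful when ``want_energy`` is True (cut-and-shifted pair energies).
    ``n_clamped`` counts pair/wall evaluations clamped at the 0.3-sigma
    floor.
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    pe = 0.0
    nclamp = 0

    # bonds: V = ks (r - 1)^2
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            r = 1e-12
        fmag = -2.0 * ks * (r - 1.0) / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz
        if want_energy:
            pe += ks * (r - 1.0) ** 2

    # angles: V = k_bend (1 + cos theta), theta at the middle bead
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        ax = pos[i, 0] - pos[j, 0]
        ay = pos[i, 1] - pos[j, 1]
        az = pos[i, 2] - pos[j, 2]
        bx = pos[k, 0] - pos[j, 0]
        by = pos[k, 1] - pos[j, 1]
        bz = pos[k, 2] - pos[j, 2]
        la2 = ax * ax + ay * ay + az * az
        lb2 = bx * bx + by * by + bz * bz
        la = np.sqrt(la2)
        lb = np.sqrt(lb2)
        if la < 1e-12 or lb < 1e-12:
            continue
        ct = (ax * bx + ay * by + az * bz) / (la * lb)
        if ct > 1.0:
            ct = 1.0
        if ct < -1.0:
            ct = -1.0
        if want_energy:
            pe += k_bend * (1.0 + ct)
        # F_i = -k * d(ct)/d r_i ; F_k analogous; F_j closes the triple
        fix = -k_bend * (bx / (la * lb) - ct * ax / la2)
        fiy = -k_bend * (by / (la * lb) - ct * ay / la2)
        fiz = -k_bend * (bz / (la * lb) - ct * az / la2)
        fkx = -k_bend * (ax / (la * lb) - ct * bx / lb2)
        fky = -k_bend * (ay / (la * lb) - ct * by / lb2)
        fkz = -k_bend * (az / (la * lb) - ct * bz / lb2)
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz

    # non-bonded pairs: truncated & shifted LJ
    for p in range(npair):
        i = pairs[p, 0]
        j = pairs[p, 1]
        if j - i == 1 and j < n_poly:
            continue  # 1-2 exclusion: handled by the bond term
        si = species[i]
        sj = species[j]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2_tab[si, sj]:
            continue
        if r2 < _R2_FLOOR:
            r2 = _R2_FLOOR
            nclamp += 1
        e = eps_tab[si, sj]
        inv2 = 1.0 / r2
        sr6 = inv2 * inv2 * inv2
        fr = 24.0 * e * (2.0 * sr6 * sr6 - sr6) * inv2
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz
        if want_energy:
            pe += 4.0 * e * (sr6 * sr6 - sr6) - vcut_tab[si, sj]

    # confining wall: WCA on the distance to the sphere surface
    for i in range(n):
        rr = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
        d = Rc - rr
        if d < 1.122462048309373:
            if d < 0.3:
                d = 0.3
                nclamp += 1
            inv2 = 1.0 / (d * d)
            sr6 = inv2 * inv2 * inv2
            g = 24.0 * (2.0 * sr6 * sr6 - sr6) / d
            if rr > 1e-12:
                forces[i, 0] -= g * pos[i, 0] / rr
                forces[i, 1] -= g * pos[i, 1] / rr
                forces[i, 2] -= g * pos[i, 2] / rr
            if want_energy:
                pe += 4.0 * (sr6 * sr6 - sr6) + 1.0
    return pe, nclamp


@njit(cache=True, fastmath=True)
def langevin_run(pos, vel, species, eps_tab, rc2_tab, vcut_tab, bonds, angles,
                 ks, k_bend, Rc, kBT, gamma, mass, dt, n_steps, seed, fcap,
                 save_every, frames, frame_steps, temps, pes, skin, rc_max,
                 n_poly):
    """BAOAB Langevin integration; fills ``frames``/``temps``/``pes`` in place.

    Returns (n_frames_written, n_clamped_total, n_rebuilds, status) where
    status 0 = ok, 1 = non-finite forces/positions (aborted, last good frame
    already stored), 2 = pair buffer overflow.
    """
    n = pos.shape[0]
    rlist = rc_max + skin
    rlist2 = rlist * rlist
    half_skin2 = (0.5 * skin) ** 2
    pairs = np.empty((n * 140 + 2048, 2), np.int32)
    ref = pos.copy()

    np.random.seed(seed)
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kBT / mass)
    forces = np.empty((n, 3))

    npair = build_pairs(pos, rlist2, Rc, pairs)
    if npair < 0:
        return 0, 0, 0, 2
    pe, nclamp_tot = eval_forces(pos, species, eps_tab, rc2_tab, vcut_tab,
                                 bonds, angles, ks, k_bend, Rc, pairs, npair,
                                 forces, False, n_poly)
    nrebuild = 0
    nframe = 0
    hdt = 0.5 * dt

    for step in range(1, n_steps + 1):
        # B half-kick, with optional per-bead force cap
        for i in range(n):
            fx = forces[i, 0]
            fy = forces[i, 1]
            fz = forces[i, 2]
            if fcap > 0.0:
                fm = np.sqrt(fx * fx + fy * fy + fz * fz)
                if fm > fcap:
                    s = fcap / fm
                    fx *= s
                    fy *= s
                    fz *= s
            vel[i, 0] += hdt * fx / mass
            vel[i, 1] += hdt * fy / mass
            vel[i, 2] += hdt * fz / mass
        # A half-drift
        for i in range(n):
            pos[i, 0] += hdt * vel[i, 0]
            pos[i, 1] += hdt * vel[i, 1]
            pos[i, 2] += hdt * vel[i, 2]
        # O: exact Ornstein-Uhlenbeck step
        for i in range(n):
            vel[i, 0] = c1 * vel[i, 0] + c2 * np.random.normal()
            vel[i, 1] = c1 * vel[i, 1] + c2 * np.random.normal()
            vel[i, 2] = c1 * vel[i, 2] + c2 * np.random.normal()
        # A half-drift
        for i in range(n):
            pos[i, 0] += hdt * vel[i, 0]
            pos[i, 1] += hdt * vel[i, 1]
            pos[i, 2] += hdt * vel[i, 2]

        # neighbour-list freshness: rebuild at half-skin displacement
        maxd2 = 0.0
        for i in range(n):
            dx = pos[i, 0] - ref[i, 0]
            dy = pos[i, 1] - ref[i, 1]
            dz = pos[i, 2] - ref[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > half_skin2:
            npair = build_pairs(pos, rlist2, Rc, pairs)
            if npair < 0:
                return nframe, nclamp_tot, nrebuild, 2
            ref[:, :] = pos
            nrebuild += 1

        sample = step % save_every == 0 or step == n_steps
        pe, ncl = eval_forces(pos, species, eps_tab, rc2_tab, vcut_tab, bonds,
                              angles, ks, k_bend, Rc, pairs, npair, forces,
                              sample, n_poly)
        nclamp_tot += ncl
        # B half-kick
        for i in range(n):
            fx = forces[i, 0]
            fy = forces[i, 1]
            fz = forces[i, 2]
            if fcap > 0.0:
                fm = np.sqrt(fx * fx + fy * fy + fz * fz)
                if fm > fcap:
                    s = fcap / fm
                    fx *= s
                    fy *= s
                    fz *= s
            vel[i, 0] += hdt * fx / mass
            vel[i, 1] += hdt * fy / mass
            vel[i, 2] += hdt * fz / mass

        if sample and nframe < frames.shape[0]:
            if not np.isfinite(pe):
                return nframe, nclamp_tot, nrebuild, 1
            ke = 0.0
            for i in range(n):
                ke += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            frames[nframe, :, :] = pos
            frame_steps[nframe] = step
            temps[nframe] = mass * ke / (3.0 * n) if n > 0 else 0.0
            pes[nframe] = pe
            nframe += 1
    return nframe, nclamp_tot, nrebuild, 0
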