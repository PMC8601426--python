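"""Numba kernels for DPD force evaluation and time integration.

The non-bonded force between beads i and j (r < r_c, minimum image) is the
standard soft-DPD triple

    F_C = a_ij * (1 - r/r_c) * e_ij
    F_D = -gamma * (1 - r/r_c)^2 * (e_ij . v_ij) * e_ij
    F_R = sigma * (1 - r/r_c) * theta_ij / sqrt(dt) * e_ij

with sigma = sqrt(2 * gamma * kT). The random variate theta_ij is produced
by a counter-based hash keyed on (seed, step, i, j), so the same pair draws
the same number on both endpoints and the stream does not depend on the
order in which pairs are visited. Bonds are harmonic, U = (k/2)(r - l0)^2,
evaluated on the raw (real-space) bond vector so chains remain contiguous
in real space and cannot silently thread through periodic images.

Positions are kept unwrapped; periodic images enter only through the
minimum-image convention of the non-bonded forces and the cell binning
(pos mod L).
"""

import math

import numpy as np
from numba import njit, uint64

SQRT3 = math.sqrt(3.0)
TWO_PI = 2.0 * math.pi

_C1 = uint64(0x9E3779B97F4A7C15)
_C2 = uint64(0xBF58476D1CE4E5B9)
_C3 = uint64(0x94D049BB133111EB)
_C4 = uint64(0xD6E8FEB86659FD93)
_C5 = uint64(0xFF51AFD7ED558CCD)
_C6 = uint64(0xC4CEB9FE1A85EC53)


@njit(inline="always", cache=True)
def _mix(x):
    x = (x ^ (x >> uint64(33))) * _C5
    x = (x ^ (x >> uint64(29))) * _C6
    return x ^ (x >> uint64(32))


@njit(inline="always", cache=True)
def _pair_key(seed, step, i, j):
    x = uint64(seed) * _C2 ^ uint64(step) * _C1
    x = _mix(x)
    x = x ^ uint64(i) * _C3 ^ uint64(j) * _C4
    return _mix(x)


@njit(inline="always", cache=True)
def _u01(x):
    # 53-bit mantissa -> uniform in [0, 1)
    return (x >> uint64(11)) * (1.0 / 9007199254740992.0)


@njit(inline="always", cache=True)
def _theta(seed, step, i, j, gaussian):
    x = _pair_key(seed, step, i, j)
    if gaussian:
        u1 = _u01(x)
        u2 = _u01(_mix(x ^ _C1))
        if u1 < 1e-300:
            u1 = 1e-300
        return math.sqrt(-2.0 * math.log(u1)) * math.cos(TWO_PI * u2)
    return SQRT3 * (2.0 * _u01(x) - 1.0)


@njit(inline="always", cache=True)
def _min_image(d, L):
    return d - L * math.floor(d / L + 0.5)


@njit(inline="always", cache=True, fastmath=True)
def _pair_force(
    pos, vel, species, a_mat, rc, gamma, sigma, inv_sqrt_dt, L,
    seed, step, gaussian, i, j, f,
):
    dx = _min_image(pos[i, 0] - pos[j, 0], L)
    dy = _min_image(pos[i, 1] - pos[j, 1], L)
    dz = _min_image(pos[i, 2] - pos[j, 2], L)
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= rc * rc or r2 == 0.0:
        return
    r = math.sqrt(r2)
    w = 1.0 - r / rc
    ex = dx / r
    ey = dy / r
    ez = dz / r
    aij = a_mat[species[i], species[j]]
    fm = aij * w
    if gamma > 0.0:
        vx = vel[i, 0] - vel[j, 0]
        vy = vel[i, 1] - vel[j, 1]
        vz = vel[i, 2] - vel[j, 2]
        rv = ex * vx + ey * vy + ez * vz
        fm -= gamma * w * w * rv
    if sigma > 0.0:
        if i < j:
            th = _theta(seed, step, i, j, gaussian)
        else:
            th = _theta(seed, step, j, i, gaussian)
        fm += sigma * w * th * inv_sqrt_dt
    f[i, 0] += fm * ex
    f[i, 1] += fm * ey
    f[i, 2] += fm * ez
    f[j, 0] -= fm * ex
    f[j, 1] -= fm * ey
    f[j, 2] -= fm * ez


@njit(cache=True, fastmath=True)
def nonbonded_forces(
    pos, vel, species, a_mat, rc, gamma, sigma, dt, L,
    seed, step, gaussian, f,
):
    """Accumulate non-bonded DPD forces into ``f`` (not zeroed here)."""
    n = pos.shape[0]
    inv_sqrt_dt = 1.0 / math.sqrt(dt)
    ncell = int(L / rc)
    if ncell < 3 or n < 64:
        for i in range(n):
            for j in range(i + 1, n):
                _pair_force(
                    pos, vel, species, a_mat, rc, gamma, sigma,
                    inv_sqrt_dt, L, seed, step, gaussian, i, j, f,
                )
        return
    # linked-cell pass: counting-sort beads by cell into contiguous arrays
    # (cache-friendly), then scan each cell against the 13-offset half
    # stencil. Coordinates are wrapped into [0, L) first, so the minimum
    # image reduces to a single conditional shift.
    ncell3 = ncell * ncell * ncell
    inv_cell = ncell / L
    half_l = 0.5 * L
    cellid = np.empty(n, dtype=np.int64)
    start = np.zeros(ncell3 + 1, dtype=np.int64)
    sx = np.empty(n, dtype=np.float64)
    sy = np.empty(n, dtype=np.float64)
    sz = np.empty(n, dtype=np.float64)
    for idx in range(n):
        wx = pos[idx, 0] % L
        wy = pos[idx, 1] % L
        wz = pos[idx, 2] % L
        cx = int(wx * inv_cell) % ncell
        cy = int(wy * inv_cell) % ncell
        cz = int(wz * inv_cell) % ncell
        c = (cx * ncell + cy) * ncell + cz
        cellid[idx] = c
        sx[idx] = wx
        sy[idx] = wy
        sz[idx] = wz
        start[c + 1] += 1
    for c in range(ncell3):
        start[c + 1] += start[c]
    order = np.empty(n, dtype=np.int64)
    fill = start[:-1].copy()
    for idx in range(n):
        c = cellid[idx]
        order[fill[c]] = idx
        fill[c] += 1
    px = np.empty(n, dtype=np.float64)
    py = np.empty(n, dtype=np.float64)
    pz = np.empty(n, dtype=np.float64)
    vx = np.empty(n, dtype=np.float64)
    vy = np.empty(n, dtype=np.float64)
    vz = np.empty(n, dtype=np.float64)
    sp = np.empty(n, dtype=np.int8)
    fx = np.zeros(n, dtype=np.float64)
    fy = np.zeros(n, dtype=np.float64)
    fz = np.zeros(n, dtype=np.float64)
    for k in range(n):
        idx = order[k]
        px[k] = sx[idx]
        py[k] = sy[idx]
        pz[k] = sz[idx]
        vx[k] = vel[idx, 0]
        vy[k] = vel[idx, 1]
        vz[k] = vel[idx, 2]
        sp[k] = species[idx]
    rc2 = rc * rc
    offs = np.array(
        [
            (1, 0, 0), (1, 1, 0), (1, -1, 0), (0, 1, 0),
            (1, 0, 1), (1, 1, 1), (1, -1, 1), (0, 1, 1),
            (1, 0, -1), (1, 1, -1), (1, -1, -1), (0, 1, -1),
            (0, 0, 1),
        ],
        dtype=np.int64,
    )
    for cx in range(ncell):
        for cy in range(ncell):
            for cz in range(ncell):
                c = (cx * ncell + cy) * ncell + cz
                c0 = start[c]
                c1 = start[c + 1]
                for no in range(14):
                    if no == 13:
                        d0 = c0
                        d1 = c1
                        same = True
                    else:
                        c2x = (cx + offs[no, 0]) % ncell
                        c2y = (cy + offs[no, 1]) % ncell
                        c2z = (cz + offs[no, 2]) % ncell
                        c2 = (c2x * ncell + c2y) * ncell + c2z
                        d0 = start[c2]
                        d1 = start[c2 + 1]
                        same = False
                    for a in range(c0, c1):
                        b0 = a + 1 if same else d0
                        for b in range(b0, d1):
                            dx = px[a] - px[b]
                            if dx > half_l:
                                dx -= L
                            elif dx < -half_l:
                                dx += L
                            dy = py[a] - py[b]
                            if dy > half_l:
                                dy -= L
                            elif dy < -half_l:
                                dy += L
                            dz = pz[a] - pz[b]
                            if dz > half_l:
                                dz -= L
                            elif dz < -half_l:
                                dz += L
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 >= rc2 or r2 == 0.0:
                                continue
                            r = math.sqrt(r2)
                            w = 1.0 - r / rc
                            inv_r = 1.0 / r
                            ex = dx * inv_r
                            ey = dy * inv_r
                            ez = dz * inv_r
                            fm = a_mat[sp[a], sp[b]] * w
                            if gamma > 0.0:
                                rv = (
                                    ex * (vx[a] - vx[b])
                                    + ey * (vy[a] - vy[b])
                                    + ez * (vz[a] - vz[b])
                                )
                                fm -= gamma * w * w * rv
                            if sigma > 0.0:
                                ia = order[a]
                                ib = order[b]
                                if ia < ib:
                                    th = _theta(seed, step, ia, ib, gaussian)
                                else:
                                    th = _theta(seed, step, ib, ia, gaussian)
                                fm += sigma * w * th * inv_sqrt_dt
                            fx[a] += fm * ex
                            fy[a] += fm * ey
                            fz[a] += fm * ez
                            fx[b] -= fm * ex
                            fy[b] -= fm * ey
                            fz[b] -= fm * ez
    for k in range(n):
        idx = order[k]
        f[idx, 0] += fx[k]
        f[idx, 1] += fy[k]
        f[idx, 2] += fz[k]


@njit(cache=True, fastmath=True)
def bond_forces(pos, bonds, k, l0, max_stretch, f):
    """Accumulate harmonic-bond forces into ``f`` (not zeroed here).

    Raw bond vectors, no periodic wrapping: a bond always pulls its
    endpoints together in real space. The restoring force is capped at
    the extension ``max_stretch`` (truncated harmonic), so the grossly
    overstretched restraint bonds of a fresh reconstruction start pull at
    a constant, integrable force instead of exploding.
    """
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r == 0.0:
            continue
        stretch = r - l0
        if stretch > max_stretch:
            stretch = max_stretch
        fm = -k * stretch / r
        f[i, 0] += fm * dx
        f[i, 1] += fm * dy
        f[i, 2] += fm * dz
        f[j, 0] -= fm * dx
        f[j, 1] -= fm * dy
        f[j, 2] -= fm * dz


@njit(cache=True)
def bond_lengths(pos, bonds):
    out = np.empty(bonds.shape[0], dtype=np.float64)
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        out[b] = math.sqrt(dx * dx + dy * dy + dz * dz)
    return out


@njit(cache=True)
def _total_forces(
    pos, vel, species, a_mat, rc, gamma, sigma, dt, L,
    seed, step, gaussian, bonds, bond_k, bond_l0, bond_cap, f,
):
    f[:] = 0.0
    nonbonded_forces(
        pos, vel, species, a_mat, rc, gamma, sigma, dt, L,
        seed, step, gaussian, f,
    )
    if bonds.shape[0] > 0:
        bond_forces(pos, bonds, bond_k, bond_l0, bond_cap, f)


@njit(cache=True, fastmath=True)
def run(
    pos, vel, species, a_mat, rc, gamma, sigma, lam, dt, L,
    bonds, bond_k, bond_l0, bond_cap, n_steps, seed, step0, gaussian,
):
    """Modified velocity-Verlet DPD loop; mutates pos and vel in place.

    Returns (status, steps_done, mean_kinetic_temperature) where status is
    0 on success and 1 if a bead moved more than L/2 in one step (unstable
    integration). The temperature average runs over the post-step
    velocities of all executed steps, with 3N - 3 degrees of freedom.
    """
    n = pos.shape[0]
    f = np.zeros((n, 3), dtype=np.float64)
    fnew = np.zeros((n, 3), dtype=np.float64)
    vpred = np.empty((n, 3), dtype=np.float64)
    _total_forces(
        pos, vel, species, a_mat, rc, gamma, sigma, dt, L,
        seed, step0, gaussian, bonds, bond_k, bond_l0, bond_cap, f,
    )
    half_dt2 = 0.5 * dt * dt
    t_acc = 0.0
    dof = 3.0 * n - 3.0
    for s in range(n_steps):
        step = step0 + s + 1
        maxd2 = 0.0
        for i in range(n):
            dx = dt * vel[i, 0] + half_dt2 * f[i, 0]
            dy = dt * vel[i, 1] + half_dt2 * f[i, 1]
            dz = dt * vel[i, 2] + half_dt2 * f[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxd2:
                maxd2 = d2
            pos[i, 0] += dx
            pos[i, 1] += dy
            pos[i, 2] += dz
            vpred[i, 0] = vel[i, 0] + lam * dt * f[i, 0]
            vpred[i, 1] = vel[i, 1] + lam * dt * f[i, 1]
            vpred[i, 2] = vel[i, 2] + lam * dt * f[i, 2]
        if maxd2 > 0.25 * L * L:
            return 1, s, t_acc / max(s, 1)
        _total_forces(
            pos, vpred, species, a_mat, rc, gamma, sigma, dt, L,
            seed, step, gaussian, bonds, bond_k, bond_l0, bond_cap, fnew,
        )
        ke2 = 0.0
        for i in range(n):
            vel[i, 0] += 0.5 * dt * (f[i, 0] + fnew[i, 0])
            vel[i, 1] += 0.5 * dt * (f[i, 1] + fnew[i, 1])
            vel[i, 2] += 0.5 * dt * (f[i, 2] + fnew[i, 2])
            ke2 += (
                vel[i, 0] * vel[i, 0]
                + vel[i, 1] * vel[i, 1]
                + vel[i, 2] * vel[i, 2]
            )
            f[i, 0] = fnew[i, 0]
            f[i, 1] = fnew[i, 1]
            f[i, 2] = fnew[i, 2]
        t_acc += ke2 / dof
    return 0, n_steps, t_acc / max(n_steps, 1)
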