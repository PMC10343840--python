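"""Numba kernels: neighbour search, pairwise DPD forces, bonded springs.

Two properties are engineered in, beyond raw speed:

* The random force uses a counter-based hash RNG keyed on
  ``(seed, step counter, i, j)``, so the pair noise is a pure function of the
  pair and the step.  Newton's third law holds exactly for the stochastic
  force, and a run can be restarted from a checkpoint bit-for-bit.
* Pair forces are accumulated in ascending ``(i, j)`` order regardless of how
  the pairs were found (a counting sort groups them), so the cell-list path
  and the all-pairs brute-force path return bitwise-identical force arrays.

Minimum-image displacements use branch corrections (positions are wrapped
into ``[0, box)``, so one box shift suffices); the identical expression is
used in every kernel to keep the two neighbour paths bit-compatible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_M1 = np.uint64(0xBF58476D1CE4E5B9)
_M2 = np.uint64(0x94D049BB133111EB)
_GOLD = np.uint64(0x9E3779B97F4A7C15)
_TWO_PI = 2.0 * np.pi


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> np.uint64(30))) * _M1
    z = (z ^ (z >> np.uint64(27))) * _M2
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _pair_normal(seed, counter, i, j):
    """Standard-normal variate, a pure function of (seed, counter, i, j)."""
    z = _mix64(np.uint64(seed) ^ (np.uint64(counter) * _GOLD))
    z = _mix64(z ^ (np.uint64(i) * _M1) ^ (np.uint64(j) * _M2))
    a = _mix64(z)
    b = _mix64(a ^ _GOLD)
    u1 = (np.float64(a >> np.uint64(11)) + 1.0) * (2.0 ** -53)
    u2 = np.float64(b >> np.uint64(11)) * (2.0 ** -53)
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(_TWO_PI * u2)


@njit(cache=True, inline="always")
def _mic(d, box, half):
    if d > half:
        return d - box
    if d < -half:
        return d + box
    return d


@njit(cache=True)
def brute_pairs(pos, box, r_cut):
    """All pairs with minimum-image distance < r_cut, ascending (i, j)."""
    n = pos.shape[0]
    cap = 16 * n + 1024
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    m = 0
    rc2 = r_cut * r_cut
    half = 0.5 * box
    for i in range(n):
        for j in range(i + 1, n):
            dx = _mic(pos[i, 0] - pos[j, 0], box, half)
            dy = _mic(pos[i, 1] - pos[j, 1], box, half)
            dz = _mic(pos[i, 2] - pos[j, 2], box, half)
            if dx * dx + dy * dy + dz * dz < rc2:
                if m >= cap:
                    raise RuntimeError("pair capacity exceeded")
                pi[m] = i
                pj[m] = j
                m += 1
    return pi[:m], pj[:m]


@njit(cache=True)
def _sort_pairs(pi, pj, n):
    """Counting sort by i, then insertion sort of j inside each i group."""
    m = pi.shape[0]
    counts = np.zeros(n + 1, dtype=np.int64)
    for k in range(m):
        counts[pi[k] + 1] += 1
    for i in range(n):
        counts[i + 1] += counts[i]
    out_i = np.empty(m, dtype=np.int64)
    out_j = np.empty(m, dtype=np.int64)
    fill = counts[:-1].copy()
    for k in range(m):
        s = fill[pi[k]]
        out_i[s] = pi[k]
        out_j[s] = pj[k]
        fill[pi[k]] += 1
    for i in range(n):
        a0, a1 = counts[i], counts[i + 1]
        for u in range(a0 + 1, a1):
            key = out_j[u]
            v = u - 1
            while v >= a0 and out_j[v] > key:
                out_j[v + 1] = out_j[v]
                v -= 1
            out_j[v + 1] = key
    return out_i, out_j


@njit(cache=True)
def cell_pairs(pos, box, r_cut):
    """Interacting pairs via a linked-cell grid rebuilt from scratch,
    returned in ascending (i, j) order.

    Falls back to the O(n^2) scan when the box holds fewer than 3 cells per
    edge (neighbour shells would alias).
    """
    n = pos.shape[0]
    ncell = int(box / r_cut)
    if ncell < 3:
        return brute_pairs(pos, box, r_cut)
    inv = ncell / box
    rc2 = r_cut * r_cut
    half = 0.5 * box

    cell = np.empty(n, dtype=np.int64)
    for k in range(n):
        cx = int(pos[k, 0] * inv)
        cy = int(pos[k, 1] * inv)
        cz = int(pos[k, 2] * inv)
        if cx >= ncell:
            cx = ncell - 1
        elif cx < 0:
            cx = 0
        if cy >= ncell:
            cy = ncell - 1
        elif cy < 0:
            cy = 0
        if cz >= ncell:
            cz = ncell - 1
        elif cz < 0:
            cz = 0
        cell[k] = (cx * ncell + cy) * ncell + cz

    ntot = ncell * ncell * ncell
    counts = np.zeros(ntot + 1, dtype=np.int64)
    for k in range(n):
        counts[cell[k] + 1] += 1
    for c in range(ntot):
        counts[c + 1] += counts[c]
    order = np.empty(n, dtype=np.int64)
    fill = counts[:-1].copy()
    for k in range(n):
        c = cell[k]
        order[fill[c]] = k
        fill[c] += 1

    # half-shell neighbour offsets (13) — each cell pair visited once
    offs = np.array([
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
        (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ], dtype=np.int64)

    cap = 16 * n + 1024
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    m = 0
    for cx in range(ncell):
        for cy in range(ncell):
            for cz in range(ncell):
                c = (cx * ncell + cy) * ncell + cz
                a0, a1 = counts[c], counts[c + 1]
                for u in range(a0, a1):
                    i = order[u]
                    xi0 = pos[i, 0]
                    yi0 = pos[i, 1]
                    zi0 = pos[i, 2]
                    for v in range(u + 1, a1):
                        j = order[v]
                        dx = _mic(xi0 - pos[j, 0], box, half)
                        dy = _mic(yi0 - pos[j, 1], box, half)
                        dz = _mic(zi0 - pos[j, 2], box, half)
                        if dx * dx + dy * dy + dz * dz < rc2:
                            if m >= cap:
                                raise RuntimeError("pair capacity exceeded")
                            if i < j:
                                pi[m] = i
                                pj[m] = j
                            else:
                                pi[m] = j
                                pj[m] = i
                            m += 1
                for o in range(13):
                    bx = (cx + offs[o, 0]) % ncell
                    by = (cy + offs[o, 1]) % ncell
                    bz = (cz + offs[o, 2]) % ncell
                    d = (bx * ncell + by) * ncell + bz
                    b0, b1 = counts[d], counts[d + 1]
                    for u in range(a0, a1):
                        i = order[u]
                        xi0 = pos[i, 0]
                        yi0 = pos[i, 1]
                        zi0 = pos[i, 2]
                        for v in range(b0, b1):
                            j = order[v]
                            dx = _mic(xi0 - pos[j, 0], box, half)
                            dy = _mic(yi0 - pos[j, 1], box, half)
                            dz = _mic(zi0 - pos[j, 2], box, half)
                            if dx * dx + dy * dy + dz * dz < rc2:
                                if m >= cap:
                                    raise RuntimeError("pair capacity exceeded")
                                if i < j:
                                    pi[m] = i
                                    pj[m] = j
                                else:
                                    pi[m] = j
                                    pj[m] = i
                                m += 1
    return _sort_pairs(pi[:m], pj[:m], n)


@njit(cache=True)
def accumulate_pair_forces(pos, vel, species, a_mat, gamma, sigma, dt,
                           box, r_cut, seed, counter, pi, pj, forces):
    """Sum conservative + dissipative + random pair forces into ``forces``.

    Pairs must be pre-sorted ascending in (i, j).  Returns the conservative
    pair virial sum(F_C . r_ij) and the number of exactly-overlapping pairs
    (zero force applied, soft potential permits them).
    """
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    rc2 = r_cut * r_cut
    half = 0.5 * box
    virial_c = 0.0
    n_overlap = 0
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = _mic(pos[i, 0] - pos[j, 0], box, half)
        dy = _mic(pos[i, 1] - pos[j, 1], box, half)
        dz = _mic(pos[i, 2] - pos[j, 2], box, half)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        r = np.sqrt(r2)
        if r < 1e-12:
            n_overlap += 1
            continue
        ex = dx / r
        ey = dy / r
        ez = dz / r
        w = 1.0 - r / r_cut
        fc = a_mat[species[i], species[j]] * w
        dvx = vel[i, 0] - vel[j, 0]
        dvy = vel[i, 1] - vel[j, 1]
        dvz = vel[i, 2] - vel[j, 2]
        rv = ex * dvx + ey * dvy + ez * dvz
        fd = -gamma * w * w * rv
        xi = _pair_normal(seed, counter, i, j)
        fr = sigma * w * xi * inv_sqrt_dt
        fs = fc + fd + fr
        forces[i, 0] += fs * ex
        forces[i, 1] += fs * ey
        forces[i, 2] += fs * ez
        forces[j, 0] -= fs * ex
        forces[j, 1] -= fs * ey
        forces[j, 2] -= fs * ez
        virial_c += fc * r
    return virial_c, n_overlap


@njit(cache=True)
def accumulate_spring_forces(pos, bonds, c_spring, box, forces):
    """Harmonic springs with zero equilibrium length; returns the spring
    virial sum(F_S . r_ij) (negative: bonds are purely attractive)."""
    virial = 0.0
    half = 0.5 * box
    for k in range(bonds.shape[0]):
        i = bonds[k, 0]
        j = bonds[k, 1]
        dx = _mic(pos[j, 0] - pos[i, 0], box, half)
        dy = _mic(pos[j, 1] - pos[i, 1], box, half)
        dz = _mic(pos[j, 2] - pos[i, 2], box, half)
        forces[i, 0] += c_spring * dx
        forces[i, 1] += c_spring * dy
        forces[i, 2] += c_spring * dz
        forces[j, 0] -= c_spring * dx
        forces[j, 1] -= c_spring * dy
        forces[j, 2] -= c_spring * dz
        virial -= c_spring * (dx * dx + dy * dy + dz * dz)
    return virial


@njit(cache=True)
def pair_force_components(pos, vel, species, a_mat, gamma, sigma, dt,
                          box, r_cut, seed, counter, pi, pj,
                          f_cons, f_diss, f_rand):
    """Diagnostic variant filling the three pairwise components separately."""
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    rc2 = r_cut * r_cut
    half = 0.5 * box
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = _mic(pos[i, 0] - pos[j, 0], box, half)
        dy = _mic(pos[i, 1] - pos[j, 1], box, half)
        dz = _mic(pos[i, 2] - pos[j, 2], box, half)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        r = np.sqrt(r2)
        if r < 1e-12:
            continue
        ex = dx / r
        ey = dy / r
        ez = dz / r
        w = 1.0 - r / r_cut
        fc = a_mat[species[i], species[j]] * w
        dvx = vel[i, 0] - vel[j, 0]
        dvy = vel[i, 1] - vel[j, 1]
        dvz = vel[i, 2] - vel[j, 2]
        rv = ex * dvx + ey * dvy + ez * dvz
        fd = -gamma * w * w * rv
        fr = sigma * w * _pair_normal(seed, counter, i, j) * inv_sqrt_dt
        f_cons[i, 0] += fc * ex
        f_cons[i, 1] += fc * ey
        f_cons[i, 2] += fc * ez
        f_cons[j, 0] -= fc * ex
        f_cons[j, 1] -= fc * ey
        f_cons[j, 2] -= fc * ez
        f_diss[i, 0] += fd * ex
        f_diss[i, 1] += fd * ey
        f_diss[i, 2] += fd * ez
        f_diss[j, 0] -= fd * ex
        f_diss[j, 1] -= fd * ey
        f_diss[j, 2] -= fd * ez
        f_rand[i, 0] += fr * ex
        f_rand[i, 1] += fr * ey
        f_rand[i, 2] += fr * ez
        f_rand[j, 0] -= fr * ex
        f_rand[j, 1] -= fr * ey
        f_rand[j, 2] -= fr * ez
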