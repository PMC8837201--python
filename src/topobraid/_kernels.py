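"""Numba kernels for the simulation engines and trajectory geometry.

Everything here operates on plain float64 arrays in reduced units.  The
energy model duplicated in these kernels is cross-checked against the
numpy reference implementation in :mod:`topobraid.units` by the test
suite.  Layout convention: two chains are stored contiguously, beads
``0..n1-1`` (chain 0, bottom to top) then ``n1..n1+n2-1`` (chain 1).
"""

from __future__ import annotations

import numpy as np
from numba import njit

WCA_CUT = 2.0 ** (1.0 / 6.0)
WCA_CUT2 = WCA_CUT * WCA_CUT


# ---------------------------------------------------------------------------
# pair terms
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _wca(r2):
    if r2 >= WCA_CUT2:
        return 0.0
    sr6 = 1.0 / (r2 * r2 * r2)
    return 4.0 * (sr6 * sr6 - sr6) + 1.0


@njit(cache=True, inline="always")
def _dh(r, pref, lam):
    return pref / r * np.exp(-r / lam)


@njit(cache=True, inline="always")
def _fene(r2, k_fene, r0):
    x = r2 / (r0 * r0)
    if x >= 1.0:
        return 1.0e30  # exploded bond sentinel
    return -0.5 * k_fene * r0 * r0 * np.log(1.0 - x)


@njit(cache=True, inline="always")
def _bend(pos, i, j, k, k_bend):
    ax = pos[i, 0] - pos[j, 0]
    ay = pos[i, 1] - pos[j, 1]
    az = pos[i, 2] - pos[j, 2]
    bx = pos[k, 0] - pos[j, 0]
    by = pos[k, 1] - pos[j, 1]
    bz = pos[k, 2] - pos[j, 2]
    na = np.sqrt(ax * ax + ay * ay + az * az)
    nb = np.sqrt(bx * bx + by * by + bz * bz)
    ct = (ax * bx + ay * by + az * bz) / (na * nb)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return k_bend * (1.0 + ct)


@njit(cache=True)
def total_energy_kernel(pos, cid, k_fene, r0, k_bend, use_dh, dh_pref,
                        dh_lam, dh_cut, wca_sig2):
    """Reference total energy for cross-checking (O(n^2)).

    ``wca_sig2`` is the squared excluded-volume diameter of non-bonded
    pairs (bonded pairs keep diameter 1)."""
    n = pos.shape[0]
    e = 0.0
    for i in range(n - 1):
        if cid[i] == cid[i + 1]:
            d = pos[i + 1] - pos[i]
            e += _fene(d[0] * d[0] + d[1] * d[1] + d[2] * d[2], k_fene, r0)
    for i in range(1, n - 1):
        if cid[i - 1] == cid[i] and cid[i] == cid[i + 1]:
            e += _bend(pos, i - 1, i, i + 1, k_bend)
    dh_cut2 = dh_cut * dh_cut
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            bonded = (j == i + 1) and (cid[i] == cid[j])
            if bonded:
                e += _wca(r2)
            else:
                e += _wca(r2 / wca_sig2)
            if use_dh and r2 < dh_cut2 and not bonded:
                e += _dh(np.sqrt(r2), dh_pref, dh_lam)
    return e


# ---------------------------------------------------------------------------
# projected crossings
# ---------------------------------------------------------------------------

# Topology bookkeeping projects onto the xz-plane (depth = y).  A
# projection transverse to the force axis is generic for braided
# tethers: along z the legs of a braid are near-collinear and endpoint
# sweeps make the open-chain crossing sum flicker.
TOPO_U = 0   # first in-plane coordinate
TOPO_V = 2   # second in-plane coordinate
TOPO_W = 1   # depth coordinate (over/under)


@njit(cache=True, inline="always")
def _seg_cross_sign(pos, a0, a1, b0, b1, cu, cv, cw):
    """Signed crossing of segments (a0,a1) and (b0,b1) projected onto the
    (cu, cv) plane with depth cw; 0 if the projections do not intersect.

    Sign: s = sign((cu,cv)-cross of d_over, d_under), 'over' = larger cw.
    """
    p0x, p0y = pos[a0, cu], pos[a0, cv]
    p1x, p1y = pos[a1, cu], pos[a1, cv]
    q0x, q0y = pos[b0, cu], pos[b0, cv]
    q1x, q1y = pos[b1, cu], pos[b1, cv]
    dax, day = p1x - p0x, p1y - p0y
    dbx, dby = q1x - q0x, q1y - q0y
    den = dax * dby - day * dbx
    if den == 0.0:
        return 0
    t = ((q0x - p0x) * dby - (q0y - p0y) * dbx) / den
    u = ((q0x - p0x) * day - (q0y - p0y) * dax) / den
    if t < 0.0 or t >= 1.0 or u < 0.0 or u >= 1.0:
        return 0
    za = pos[a0, cw] + t * (pos[a1, cw] - pos[a0, cw])
    zb = pos[b0, cw] + u * (pos[b1, cw] - pos[b0, cw])
    s = 1 if den > 0.0 else -1
    if za > zb:
        return -s
    return s


@njit(cache=True)
def crossing_sum(pos, n1, n):
    """Signed sum of inter-chain crossings in the topology projection."""
    total = 0
    for a in range(n1 - 1):
        for b in range(n1, n - 1):
            total += _seg_cross_sign(pos, a, a + 1, b, b + 1,
                                     TOPO_U, TOPO_V, TOPO_W)
    return total


@njit(cache=True)
def _crossing_contrib(pos, lo, hi, o_lo, o_hi):
    """Signed crossings of segments [lo, hi] (by lower bead index) of one
    chain against all segments [o_lo, o_hi-1] of the other chain."""
    total = 0
    for a in range(lo, hi + 1):
        for b in range(o_lo, o_hi):
            total += _seg_cross_sign(pos, a, a + 1, b, b + 1,
                                     TOPO_U, TOPO_V, TOPO_W)
    return total


@njit(cache=True)
def frames_crossing_sums(frames, n1):
    n_frames = frames.shape[0]
    n = frames.shape[1]
    out = np.empty(n_frames, dtype=np.int64)
    for f in range(n_frames):
        out[f] = crossing_sum(frames[f], n1, n)
    return out


# ---------------------------------------------------------------------------
# segment-segment closest approach
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _seg_seg(pos, a0, a1, b0, b1):
    """Closest approach of segments; returns (dist2, s, t)."""
    ux = pos[a1, 0] - pos[a0, 0]
    uy = pos[a1, 1] - pos[a0, 1]
    uz = pos[a1, 2] - pos[a0, 2]
    vx = pos[b1, 0] - pos[b0, 0]
    vy = pos[b1, 1] - pos[b0, 1]
    vz = pos[b1, 2] - pos[b0, 2]
    wx = pos[a0, 0] - pos[b0, 0]
    wy = pos[a0, 1] - pos[b0, 1]
    wz = pos[a0, 2] - pos[b0, 2]
    a = ux * ux + uy * uy + uz * uz
    b = ux * vx + uy * vy + uz * vz
    c = vx * vx + vy * vy + vz * vz
    d = ux * wx + uy * wy + uz * wz
    e = vx * wx + vy * wy + vz * wz
    den = a * c - b * b
    if den > 1e-12 * a * c + 1e-300:
        s = (b * e - c * d) / den
    else:
        s = 0.0
    if s < 0.0:
        s = 0.0
    elif s > 1.0:
        s = 1.0
    if c > 0.0:
        t = (b * s + e) / c
    else:
        t = 0.0
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    # re-clamp s for the clamped t
    if a > 0.0:
        s = (b * t - d) / a
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
    dx = wx + s * ux - t * vx
    dy = wy + s * uy - t * vy
    dz = wz + s * uz - t * vz
    return dx * dx + dy * dy + dz * dz, s, t


@njit(cache=True)
def min_interchain_kernel(pos, n1, n):
    best = 1.0e300
    ba = -1
    bb = -1
    bs = 0.0
    bt = 0.0
    for a in range(n1 - 1):
        for b in range(n1, n - 1):
            d2, s, t = _seg_seg(pos, a, a + 1, b, b + 1)
            if d2 < best:
                best = d2
                ba = a
                bb = b
                bs = s
                bt = t
    return np.sqrt(best), ba, bb, bs, bt


@njit(cache=True)
def closest_approach_series(frames, n1):
    """Per-frame global inter-chain closest approach.

    Returns arrays (dist, seg_a, seg_b, s, t)."""
    nf = frames.shape[0]
    n = frames.shape[1]
    dist = np.empty(nf)
    sega = np.empty(nf, dtype=np.int64)
    segb = np.empty(nf, dtype=np.int64)
    ss = np.empty(nf)
    tt = np.empty(nf)
    for f in range(nf):
        d, a, b, s, t = min_interchain_kernel(frames[f], n1, n)
        dist[f] = d
        sega[f] = a
        segb[f] = b
        ss[f] = s
        tt[f] = t
    return dist, sega, segb, ss, tt


# ---------------------------------------------------------------------------
# Brownian dynamics
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _build_verlet(pos, n, rlist2, pairs, cid):
    np_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx * dx + dy * dy + dz * dz < rlist2:
                if np_pairs < pairs.shape[0]:
                    pairs[np_pairs, 0] = i
                    pairs[np_pairs, 1] = j
                np_pairs += 1
    return np_pairs


@njit(cache=True, fastmath=True)
def _bd_forces(pos, cid, n, f, pairs, n_pairs, k_fene, r0, k_bend,
               use_dh, dh_pref, dh_lam, dh_cut2, wca_sig2):
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    r02 = r0 * r0
    # FENE
    for i in range(n - 1):
        if cid[i] != cid[i + 1]:
            continue
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r02:
            return -(i + 1)  # exploded bond at bead i+1
        mag = k_fene / (1.0 - r2 / r02)
        f[i, 0] += mag * dx
        f[i, 1] += mag * dy
        f[i, 2] += mag * dz
        f[i + 1, 0] -= mag * dx
        f[i + 1, 1] -= mag * dy
        f[i + 1, 2] -= mag * dz
    # bending
    for j in range(1, n - 1):
        if cid[j - 1] != cid[j] or cid[j] != cid[j + 1]:
            continue
        ax = pos[j - 1, 0] - pos[j, 0]
        ay = pos[j - 1, 1] - pos[j, 1]
        az = pos[j - 1, 2] - pos[j, 2]
        bx = pos[j + 1, 0] - pos[j, 0]
        by = pos[j + 1, 1] - pos[j, 1]
        bz = pos[j + 1, 2] - pos[j, 2]
        na = np.sqrt(ax * ax + ay * ay + az * az)
        nb = np.sqrt(bx * bx + by * by + bz * bz)
        ct = (ax * bx + ay * by + az * bz) / (na * nb)
        gax = (bx / nb - ct * ax / na) / na
        gay = (by / nb - ct * ay / na) / na
        gaz = (bz / nb - ct * az / na) / na
        gbx = (ax / na - ct * bx / nb) / nb
        gby = (ay / na - ct * by / nb) / nb
        gbz = (az / na - ct * bz / nb) / nb
        f[j - 1, 0] -= k_bend * gax
        f[j - 1, 1] -= k_bend * gay
        f[j - 1, 2] -= k_bend * gaz
        f[j + 1, 0] -= k_bend * gbx
        f[j + 1, 1] -= k_bend * gby
        f[j + 1, 2] -= k_bend * gbz
        f[j, 0] += k_bend * (gax + gbx)
        f[j, 1] += k_bend * (gay + gby)
        f[j, 2] += k_bend * (gaz + gbz)
    # pair terms over the Verlet list
    for p in range(n_pairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        bonded = (j == i + 1) and (cid[i] == cid[j])
        s2 = 1.0 if bonded else wca_sig2
        mag = 0.0
        if r2 < WCA_CUT2 * s2:
            rs2 = r2 / s2
            sr6 = 1.0 / (rs2 * rs2 * rs2)
            mag += 24.0 * (2.0 * sr6 * sr6 - sr6) / r2
        if use_dh and r2 < dh_cut2 and not bonded:
            r = np.sqrt(r2)
            mag += dh_pref * np.exp(-r / dh_lam) * (1.0 / (r2 * r) + 1.0 / (dh_lam * r2))
        if mag != 0.0:
            f[i, 0] += mag * dx
            f[i, 1] += mag * dy
            f[i, 2] += mag * dz
            f[j, 0] -= mag * dx
            f[j, 1] -= mag * dy
            f[j, 2] -= mag * dz
    return 0


@njit(cache=True, fastmath=True)
def run_bd_kernel(pos, cid, n1, anchors_bot, top_xy, f_red, k_anchor,
                  k_fene, r0, k_bend, use_dh, dh_pref, dh_lam, dh_cut,
                  dt, gamma, noise_scale, n_steps, sample_every, seed,
                  frames, overdamped, mass, wca_sig2, max_step):
    """Langevin/Brownian integration of the two-tether system.

    ``overdamped`` selects plain Euler-Maruyama (requires a small
    timestep for the stiff FENE+WCA bond); otherwise an underdamped
    BAOAB Langevin step with unit mass and friction ``gamma`` is used,
    which is stable at the standard 0.01 tau timestep and samples the
    same Boltzmann ensemble.  Bottom beads are tethered by 3-D harmonic
    springs, top beads by x/y springs plus a constant +z force per
    chain.  Returns (status, step): status 0 = ok, <0 = exploded bond
    index at the reported step.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    f = np.zeros((n, 3))
    skin = 1.0
    dh_cut2 = dh_cut * dh_cut
    rcut = WCA_CUT * max(1.0, np.sqrt(wca_sig2))
    if use_dh and dh_cut > rcut:
        rcut = dh_cut
    rlist2 = (rcut + skin) * (rcut + skin)
    cap = n * 120 + 1024
    pairs = np.empty((cap, 2), dtype=np.int64)
    n_pairs = _build_verlet(pos, n, rlist2, pairs, cid)
    if n_pairs > cap:
        return -999999, 0
    ref = pos.copy()
    tops = np.empty(2, dtype=np.int64)
    tops[0] = n1 - 1
    tops[1] = n - 1
    bots = np.empty(2, dtype=np.int64)
    bots[0] = 0
    bots[1] = n1
    amp = noise_scale * np.sqrt(2.0 * dt / gamma)
    inv_g = dt / gamma
    # BAOAB coefficients (kT = 1)
    vel = np.zeros((n, 3))
    c1 = np.exp(-gamma * dt / mass)
    c2 = noise_scale * np.sqrt((1.0 - c1 * c1) / mass)
    # noise drawn in chunks (scalar normal() calls dominate otherwise)
    noise_chunk = 64
    noise = np.random.standard_normal(noise_chunk * n * 3)
    noise_i = 0
    frame_i = 0
    for step in range(n_steps):
        # displacement-triggered rebuild
        maxd2 = 0.0
        for i in range(n):
            dx = pos[i, 0] - ref[i, 0]
            dy = pos[i, 1] - ref[i, 1]
            dz = pos[i, 2] - ref[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > (0.5 * skin) * (0.5 * skin):
            n_pairs = _build_verlet(pos, n, rlist2, pairs, cid)
            if n_pairs > cap:
                return -999999, step
            for i in range(n):
                ref[i, 0] = pos[i, 0]
                ref[i, 1] = pos[i, 1]
                ref[i, 2] = pos[i, 2]
        status = _bd_forces(pos, cid, n, f, pairs, n_pairs, k_fene, r0,
                            k_bend, use_dh, dh_pref, dh_lam, dh_cut2,
                            wca_sig2)
        if status < 0:
            return status, step
        # anchors and external force
        for c in range(2):
            b = bots[c]
            f[b, 0] += k_anchor * (anchors_bot[c, 0] - pos[b, 0])
            f[b, 1] += k_anchor * (anchors_bot[c, 1] - pos[b, 1])
            f[b, 2] += k_anchor * (anchors_bot[c, 2] - pos[b, 2])
            t = tops[c]
            f[t, 0] += k_anchor * (top_xy[c, 0] - pos[t, 0])
            f[t, 1] += k_anchor * (top_xy[c, 1] - pos[t, 1])
            f[t, 2] += f_red
        # soft walls: glass surface below, magnet-held bead above (the
        # braid cannot slip over the attachment assembly)
        z_ceil = 0.5 * (pos[tops[0], 2] + pos[tops[1], 2]) + 2.0
        for i in range(n):
            if pos[i, 2] < -0.25:
                f[i, 2] += k_anchor * (-0.25 - pos[i, 2])
            elif pos[i, 2] > z_ceil and i != tops[0] and i != tops[1]:
                f[i, 2] -= k_anchor * (pos[i, 2] - z_ceil)
        if noise_i + 3 * n > noise.shape[0]:
            noise = np.random.standard_normal(noise_chunk * n * 3)
            noise_i = 0
        # displacement clamp: tames steep relaxation of a freshly
        # built conformation; never active at equilibrium where
        # per-step moves are ~0.01-0.05 sigma
        if overdamped:
            for i in range(n):
                dx0 = f[i, 0] * inv_g + amp * noise[noise_i]
                dy0 = f[i, 1] * inv_g + amp * noise[noise_i + 1]
                dz0 = f[i, 2] * inv_g + amp * noise[noise_i + 2]
                noise_i += 3
                d2 = dx0 * dx0 + dy0 * dy0 + dz0 * dz0
                if d2 > max_step * max_step:
                    sc = max_step / np.sqrt(d2)
                    dx0 *= sc
                    dy0 *= sc
                    dz0 *= sc
                pos[i, 0] += dx0
                pos[i, 1] += dy0
                pos[i, 2] += dz0
        else:
            # BAOAB with merged half-kicks (one force eval per step):
            # B(full kick) A(dt/2) O A(dt/2)
            for i in range(n):
                x0 = pos[i, 0]
                y0 = pos[i, 1]
                z0 = pos[i, 2]
                for d in range(3):
                    v = vel[i, d] + dt * f[i, d] / mass
                    x_half = pos[i, d] + 0.5 * dt * v
                    v = c1 * v + c2 * noise[noise_i]
                    noise_i += 1
                    pos[i, d] = x_half + 0.5 * dt * v
                    vel[i, d] = v
                dx0 = pos[i, 0] - x0
                dy0 = pos[i, 1] - y0
                dz0 = pos[i, 2] - z0
                d2 = dx0 * dx0 + dy0 * dy0 + dz0 * dz0
                if d2 > max_step * max_step:
                    sc = max_step / np.sqrt(d2)
                    pos[i, 0] = x0 + dx0 * sc
                    pos[i, 1] = y0 + dy0 * sc
                    pos[i, 2] = z0 + dz0 * sc
                    vel[i, 0] *= sc
                    vel[i, 1] *= sc
                    vel[i, 2] *= sc
        if (step + 1) % sample_every == 0:
            if frame_i < frames.shape[0]:
                for i in range(n):
                    frames[frame_i, i, 0] = pos[i, 0]
                    frames[frame_i, i, 1] = pos[i, 1]
                    frames[frame_i, i, 2] = pos[i, 2]
                frame_i += 1
    return 0, n_steps


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _in_moved(i, lo1, hi1, lo2, hi2):
    if lo1 <= i <= hi1:
        return True
    if lo2 >= 0 and lo2 <= i <= hi2:
        return True
    return False


@njit(cache=True)
def _boundary_energy(pos, cid, n, lo1, hi1, lo2, hi2, k_fene, r0, k_bend,
                     use_dh, dh_pref, dh_lam, dh_cut2, wca_sig2):
    """Energy of all interactions crossing the moved-set boundary.

    The moved set is one or two contiguous bead ranges that move rigidly,
    so interactions internal to the set cancel in differences.  Bonded
    pairs carry FENE + WCA at diameter 1; non-bonded pairs WCA at
    ``sqrt(wca_sig2)``."""
    e = 0.0
    # bonds with exactly one end moved
    for i in range(n - 1):
        if cid[i] != cid[i + 1]:
            continue
        mi = _in_moved(i, lo1, hi1, lo2, hi2)
        mj = _in_moved(i + 1, lo1, hi1, lo2, hi2)
        if mi != mj:
            dx = pos[i + 1, 0] - pos[i, 0]
            dy = pos[i + 1, 1] - pos[i, 1]
            dz = pos[i + 1, 2] - pos[i, 2]
            r2b = dx * dx + dy * dy + dz * dz
            e += _fene(r2b, k_fene, r0) + _wca(r2b)
    # angles with 1 or 2 (not 0 or 3) beads moved
    for j in range(1, n - 1):
        if cid[j - 1] != cid[j] or cid[j] != cid[j + 1]:
            continue
        cnt = 0
        if _in_moved(j - 1, lo1, hi1, lo2, hi2):
            cnt += 1
        if _in_moved(j, lo1, hi1, lo2, hi2):
            cnt += 1
        if _in_moved(j + 1, lo1, hi1, lo2, hi2):
            cnt += 1
        if cnt == 1 or cnt == 2:
            e += _bend(pos, j - 1, j, j + 1, k_bend)
    # nonbonded moved-vs-unmoved
    for i in range(n):
        if not _in_moved(i, lo1, hi1, lo2, hi2):
            continue
        for j in range(n):
            if _in_moved(j, lo1, hi1, lo2, hi2):
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            bonded = (abs(i - j) == 1) and (cid[i] == cid[j])
            if not bonded:
                e += _wca(r2 / wca_sig2)
                if use_dh and r2 < dh_cut2:
                    e += _dh(np.sqrt(r2), dh_pref, dh_lam)
    return e


@njit(cache=True)
def _walls_ok(pos, n, lo, hi, ta, tb):
    """Hard walls: glass slide below z=-1, bead assembly 2 sigma above
    the mean top-attachment height (non-attachment beads only)."""
    z_ceil = 0.5 * (pos[ta, 2] + pos[tb, 2]) + 2.0
    for i in range(lo, hi + 1):
        if pos[i, 2] < -0.25:
            return False
        if i != ta and i != tb and pos[i, 2] > z_ceil:
            return False
    return True


@njit(cache=True)
def _bonds_ok(pos, cid, n, lo, hi, r0):
    """Bonds touching moved range stay below R0."""
    r02 = r0 * r0
    a = lo - 1 if lo > 0 else 0
    b = hi + 1 if hi < n - 1 else n - 1
    for i in range(a, b):
        if cid[i] != cid[i + 1]:
            continue
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        if dx * dx + dy * dy + dz * dz >= r02:
            return False
    return True


@njit(cache=True)
def run_mc_kernel(pos, cid, n1, f_red, beta, k_fene, r0, k_bend,
                  use_dh, dh_pref, dh_lam, dh_cut,
                  disp_max, crank_max, link_dz_max,
                  w_disp, w_crank, n_sweeps, sample_every, n_burn,
                  check_topology, seed, frames, wca_sig2):
    """Metropolis MC of the anchored braid.

    Moves: single-bead displacement, crankshaft rotation about the chord
    through two beads of one chain, and a rigid vertical move of the two
    top attachment beads carrying the -F dz work term (force f_red acts
    on each chain's top bead).  Endpoint beads never move laterally.
    Returns (n_accept, n_attempt, n_topo_reject, frames_filled).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    n2 = n - n1
    dh_cut2 = dh_cut * dh_cut
    n_acc = 0
    n_att = 0
    n_topo = 0
    frame_i = 0
    old = np.empty((n, 3))
    moves_per_sweep = n
    for sweep in range(n_sweeps):
        for _m in range(moves_per_sweep):
            u = np.random.random()
            n_att += 1
            if u < w_disp:
                # ---- single-bead displacement (interior beads only)
                while True:
                    k = int(np.random.random() * n)
                    if k != 0 and k != n1 - 1 and k != n1 and k != n - 1:
                        break
                lo, hi = k, k
                e_old = _boundary_energy(pos, cid, n, lo, hi, -1, -1,
                                         k_fene, r0, k_bend, use_dh,
                                         dh_pref, dh_lam, dh_cut2, wca_sig2)
                c_old = 0
                if check_topology:
                    if k < n1:
                        c_old = _crossing_contrib(pos, max(0, k - 1),
                                                  min(k, n1 - 2), n1, n - 1)
                    else:
                        c_old = _crossing_contrib(pos, max(n1, k - 1),
                                                  min(k, n - 2), 0, n1 - 1)
                old[0, 0] = pos[k, 0]
                old[0, 1] = pos[k, 1]
                old[0, 2] = pos[k, 2]
                pos[k, 0] += disp_max * (2.0 * np.random.random() - 1.0)
                pos[k, 1] += disp_max * (2.0 * np.random.random() - 1.0)
                pos[k, 2] += disp_max * (2.0 * np.random.random() - 1.0)
                ok = (_bonds_ok(pos, cid, n, lo, hi, r0)
                      and _walls_ok(pos, n, lo, hi, n1 - 1, n - 1))
                acc = False
                if ok:
                    e_new = _boundary_energy(pos, cid, n, lo, hi, -1, -1,
                                             k_fene, r0, k_bend, use_dh,
                                             dh_pref, dh_lam, dh_cut2, wca_sig2)
                    de = (e_new - e_old) * beta
                    if de <= 0.0 or np.random.random() < np.exp(-de):
                        acc = True
                if acc and check_topology:
                    if k < n1:
                        c_new = _crossing_contrib(pos, max(0, k - 1),
                                                  min(k, n1 - 2), n1, n - 1)
                    else:
                        c_new = _crossing_contrib(pos, max(n1, k - 1),
                                                  min(k, n - 2), 0, n1 - 1)
                    if c_new != c_old:
                        acc = False
                        n_topo += 1
                if acc:
                    n_acc += 1
                else:
                    pos[k, 0] = old[0, 0]
                    pos[k, 1] = old[0, 1]
                    pos[k, 2] = old[0, 2]
            elif u < w_disp + w_crank:
                # ---- crankshaft about the chord through beads (i, j)
                c = 0 if np.random.random() < 0.5 else 1
                base = 0 if c == 0 else n1
                nc = n1 if c == 0 else n2
                if nc < 4:
                    continue
                i = int(np.random.random() * (nc - 2))
                span = 2 + int(np.random.random() * (nc - i - 2))
                j = i + span
                if j > nc - 1:
                    j = nc - 1
                gi = base + i
                gj = base + j
                lo, hi = gi + 1, gj - 1
                if hi < lo:
                    continue
                ax = pos[gj, 0] - pos[gi, 0]
                ay = pos[gj, 1] - pos[gi, 1]
                az = pos[gj, 2] - pos[gi, 2]
                an = np.sqrt(ax * ax + ay * ay + az * az)
                if an < 1e-12:
                    continue
                ax /= an
                ay /= an
                az /= an
                ang = crank_max * (2.0 * np.random.random() - 1.0)
                ca = np.cos(ang)
                sa = np.sin(ang)
                e_old = _boundary_energy(pos, cid, n, lo, hi, -1, -1,
                                         k_fene, r0, k_bend, use_dh,
                                         dh_pref, dh_lam, dh_cut2, wca_sig2)
                c_old = 0
                if check_topology:
                    if c == 0:
                        c_old = _crossing_contrib(pos, max(0, lo - 1),
                                                  min(hi, n1 - 2), n1, n - 1)
                    else:
                        c_old = _crossing_contrib(pos, max(n1, lo - 1),
                                                  min(hi, n - 2), 0, n1 - 1)
                for idx in range(lo, hi + 1):
                    old[idx - lo, 0] = pos[idx, 0]
                    old[idx - lo, 1] = pos[idx, 1]
                    old[idx - lo, 2] = pos[idx, 2]
                    # Rodrigues rotation about axis through pos[gi]
                    px = pos[idx, 0] - pos[gi, 0]
                    py = pos[idx, 1] - pos[gi, 1]
                    pz = pos[idx, 2] - pos[gi, 2]
                    dot = px * ax + py * ay + pz * az
                    cx = ay * pz - az * py
                    cy = az * px - ax * pz
                    cz = ax * py - ay * px
                    rx = px * ca + cx * sa + ax * dot * (1.0 - ca)
                    ry = py * ca + cy * sa + ay * dot * (1.0 - ca)
                    rz = pz * ca + cz * sa + az * dot * (1.0 - ca)
                    pos[idx, 0] = pos[gi, 0] + rx
                    pos[idx, 1] = pos[gi, 1] + ry
                    pos[idx, 2] = pos[gi, 2] + rz
                ok = (_bonds_ok(pos, cid, n, lo, hi, r0)
                      and _walls_ok(pos, n, lo, hi, n1 - 1, n - 1))
                acc = False
                if ok:
                    e_new = _boundary_energy(pos, cid, n, lo, hi, -1, -1,
                                             k_fene, r0, k_bend, use_dh,
                                             dh_pref, dh_lam, dh_cut2, wca_sig2)
                    de = (e_new - e_old) * beta
                    if de <= 0.0 or np.random.random() < np.exp(-de):
                        acc = True
                if acc and check_topology:
                    if c == 0:
                        c_new = _crossing_contrib(pos, max(0, lo - 1),
                                                  min(hi, n1 - 2), n1, n - 1)
                    else:
                        c_new = _crossing_contrib(pos, max(n1, lo - 1),
                                                  min(hi, n - 2), 0, n1 - 1)
                    if c_new != c_old:
                        acc = False
                        n_topo += 1
                if acc:
                    n_acc += 1
                else:
                    for idx in range(lo, hi + 1):
                        pos[idx, 0] = old[idx - lo, 0]
                        pos[idx, 1] = old[idx - lo, 1]
                        pos[idx, 2] = old[idx - lo, 2]
            else:
                # ---- rigid vertical move of the top attachment pair
                dz = link_dz_max * (2.0 * np.random.random() - 1.0)
                ta = n1 - 1
                tb = n - 1
                e_old = _boundary_energy(pos, cid, n, ta, ta, tb, tb,
                                         k_fene, r0, k_bend, use_dh,
                                         dh_pref, dh_lam, dh_cut2, wca_sig2)
                c_old = 0
                if check_topology:
                    c_old = (_crossing_contrib(pos, n1 - 2, n1 - 2, n1, n - 1)
                             + _crossing_contrib(pos, n - 2, n - 2, 0, n1 - 1))
                pos[ta, 2] += dz
                pos[tb, 2] += dz
                ok = (_bonds_ok(pos, cid, n, ta, ta, r0)
                      and _bonds_ok(pos, cid, n, tb, tb, r0)
                      and _walls_ok(pos, n, 0, n - 1, ta, tb))
                acc = False
                if ok:
                    e_new = _boundary_energy(pos, cid, n, ta, ta, tb, tb,
                                             k_fene, r0, k_bend, use_dh,
                                             dh_pref, dh_lam, dh_cut2, wca_sig2)
                    # external work: U_ext = -f_red * z for each top bead
                    de = (e_new - e_old - 2.0 * f_red * dz) * beta
                    if de <= 0.0 or np.random.random() < np.exp(-de):
                        acc = True
                if acc and check_topology:
                    c_new = (_crossing_contrib(pos, n1 - 2, n1 - 2, n1, n - 1)
                             + _crossing_contrib(pos, n - 2, n - 2, 0, n1 - 1))
                    if c_new != c_old:
                        acc = False
                        n_topo += 1
                if acc:
                    n_acc += 1
                else:
                    pos[ta, 2] -= dz
                    pos[tb, 2] -= dz
        if sweep >= n_burn and (sweep + 1 - n_burn) % sample_every == 0:
            if frame_i < frames.shape[0]:
                for i in range(n):
                    frames[frame_i, i, 0] = pos[i, 0]
                    frames[frame_i, i, 1] = pos[i, 1]
                    frames[frame_i, i, 2] = pos[i, 2]
                frame_i += 1
    return n_acc, n_att, n_topo, frame_i
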