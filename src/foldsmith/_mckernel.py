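"""Numba-compiled inner loop of the fragment-insertion Monte Carlo.

The trajectory kernel operates on flat arrays prepared by the assembler:
torsions (n, 3), backbone N/CA/C coordinates (n, 3, 3), per-residue letter
codes and sampling dispersions, and the objective's precomputed index
arrays.  It runs the annealed move loop (3-mer redraws early, single-residue
nudges late, ramped clash weight, cold quench) and returns control at
checkpoints so the caller can run the full filter battery; the caller
re-enters the kernel to continue the same trajectory.

All geometry here mirrors the reference implementations in
:mod:`foldsmith.geometry`; the kernel exists purely for speed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# letter codes
A, B, E, G, O = 0, 1, 2, 3, 4

# status codes returned by the kernel
RUNNING = 0
CHECKPOINT = 1
ABANDONED = 2
FINISHED = 3

BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7

CA_CLASH_SQ = 3.7 * 3.7
ATOM_CLASH_SQ = 2.5 * 2.5
PAIR_TARGET = 4.9

# sampling centers per letter code: phi, psi, default sd
CENTERS = np.array(
    [
        [-63.0, -42.0, 10.0],
        [-135.0, 135.0, 20.0],
        [75.0, 170.0, 20.0],
        [75.0, -10.0, 20.0],
        [-75.0, 160.0, 20.0],
    ]
)


@njit(cache=True, inline="always")
def _wrap(a):
    a = a % 360.0
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


@njit(cache=True, inline="always")
def _classify(phi, psi, omega):
    if abs(_wrap(omega)) < 90.0:
        return O
    psi = _wrap(psi)
    if _wrap(phi) < 0.0:
        if -75.0 <= psi < 50.0:
            return A
        return B
    if -100.0 <= psi < 100.0:
        return G
    return E


@njit(cache=True)
def _sample_letter(letter, sd):
    cphi = CENTERS[letter, 0]
    cpsi = CENTERS[letter, 1]
    if sd <= 0.0:
        sd = CENTERS[letter, 2]
    omega_center = 0.0 if letter == O else 180.0
    for _ in range(1000):
        phi = _wrap(cphi + sd * np.random.standard_normal())
        psi = _wrap(cpsi + sd * np.random.standard_normal())
        omega = _wrap(omega_center + 3.0 * np.random.standard_normal())
        if phi == -180.0:
            phi = 180.0
        if _classify(phi, psi, omega) == letter:
            return phi, psi, omega
    return cphi, cpsi, omega_center


@njit(cache=True, inline="always")
def _place_atom(ax, ay, az, bx, by, bz, cx, cy, cz, bond, angle, torsion):
    ang = np.radians(angle)
    tor = np.radians(torsion)
    d0 = -bond * np.cos(ang)
    d1 = bond * np.sin(ang) * np.cos(tor)
    d2 = bond * np.sin(ang) * np.sin(tor)
    bcx = cx - bx
    bcy = cy - by
    bcz = cz - bz
    inv = 1.0 / np.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx *= inv
    bcy *= inv
    bcz *= inv
    abx = bx - ax
    aby = by - ay
    abz = bz - az
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    inv = 1.0 / np.sqrt(nx * nx + ny * ny + nz * nz)
    nx *= inv
    ny *= inv
    nz *= inv
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    return (
        cx + bcx * d0 + mx * d1 + nx * d2,
        cy + bcy * d0 + my * d1 + ny * d2,
        cz + bcz * d0 + mz * d1 + nz * d2,
    )


@njit(cache=True)
def _place_range(tors, bb, start, stop):
    for i in range(start, stop):
        psi = tors[i, 1]
        omega = tors[i, 2]
        n_next = _place_atom(
            bb[i, 0, 0], bb[i, 0, 1], bb[i, 0, 2],
            bb[i, 1, 0], bb[i, 1, 1], bb[i, 1, 2],
            bb[i, 2, 0], bb[i, 2, 1], bb[i, 2, 2],
            BOND_C_N, ANGLE_CA_C_N, psi,
        )
        bb[i + 1, 0, 0] = n_next[0]
        bb[i + 1, 0, 1] = n_next[1]
        bb[i + 1, 0, 2] = n_next[2]
        ca_next = _place_atom(
            bb[i, 1, 0], bb[i, 1, 1], bb[i, 1, 2],
            bb[i, 2, 0], bb[i, 2, 1], bb[i, 2, 2],
            bb[i + 1, 0, 0], bb[i + 1, 0, 1], bb[i + 1, 0, 2],
            BOND_N_CA, ANGLE_C_N_CA, omega,
        )
        bb[i + 1, 1, 0] = ca_next[0]
        bb[i + 1, 1, 1] = ca_next[1]
        bb[i + 1, 1, 2] = ca_next[2]
        c_next = _place_atom(
            bb[i, 2, 0], bb[i, 2, 1], bb[i, 2, 2],
            bb[i + 1, 0, 0], bb[i + 1, 0, 1], bb[i + 1, 0, 2],
            bb[i + 1, 1, 0], bb[i + 1, 1, 1], bb[i + 1, 1, 2],
            BOND_CA_C, ANGLE_N_CA_C, tors[i + 1, 0],
        )
        bb[i + 1, 2, 0] = c_next[0]
        bb[i + 1, 2, 1] = c_next[1]
        bb[i + 1, 2, 2] = c_next[2]


@njit(cache=True)
def _frame_basis(triad, out):
    ux = triad[1, 0] - triad[0, 0]
    uy = triad[1, 1] - triad[0, 1]
    uz = triad[1, 2] - triad[0, 2]
    wx = triad[2, 0] - triad[1, 0]
    wy = triad[2, 1] - triad[1, 1]
    wz = triad[2, 2] - triad[1, 2]
    inv = 1.0 / np.sqrt(ux * ux + uy * uy + uz * uz)
    e1x, e1y, e1z = ux * inv, uy * inv, uz * inv
    tx = uy * wz - uz * wy
    ty = uz * wx - ux * wz
    tz = ux * wy - uy * wx
    inv = 1.0 / np.sqrt(tx * tx + ty * ty + tz * tz)
    e3x, e3y, e3z = tx * inv, ty * inv, tz * inv
    e2x = e3y * e1z - e3z * e1y
    e2y = e3z * e1x - e3x * e1z
    e2z = e3x * e1y - e3y * e1x
    out[0, 0], out[0, 1], out[0, 2] = e1x, e1y, e1z
    out[1, 0], out[1, 1], out[1, 2] = e2x, e2y, e2z
    out[2, 0], out[2, 1], out[2, 2] = e3x, e3y, e3z


@njit(cache=True)
def apply_move(tors, bb, p, span, n):
    """Re-place residues p..p+span, then rigidly transform the tail."""
    q = p + span - 1
    stop = min(q + 1, n - 1)
    if p > 0:
        c_new = _place_atom(
            bb[p - 1, 2, 0], bb[p - 1, 2, 1], bb[p - 1, 2, 2],
            bb[p, 0, 0], bb[p, 0, 1], bb[p, 0, 2],
            bb[p, 1, 0], bb[p, 1, 1], bb[p, 1, 2],
            BOND_CA_C, ANGLE_N_CA_C, tors[p, 0],
        )
        bb[p, 2, 0] = c_new[0]
        bb[p, 2, 1] = c_new[1]
        bb[p, 2, 2] = c_new[2]
    has_tail = stop + 1 < n
    old_frame = np.empty((3, 3))
    if has_tail:
        for r in range(3):
            for c in range(3):
                old_frame[r, c] = bb[stop, r, c]
    _place_range(tors, bb, p, stop)
    if has_tail:
        m_old = np.empty((3, 3))
        m_new = np.empty((3, 3))
        _frame_basis(old_frame, m_old)
        _frame_basis(bb[stop], m_new)
        rot = m_old.T @ m_new
        ox, oy, oz = old_frame[1, 0], old_frame[1, 1], old_frame[1, 2]
        nx, ny, nz = bb[stop, 1, 0], bb[stop, 1, 1], bb[stop, 1, 2]
        for i in range(stop + 1, n):
            for a in range(3):
                x = bb[i, a, 0] - ox
                y = bb[i, a, 1] - oy
                z = bb[i, a, 2] - oz
                bb[i, a, 0] = x * rot[0, 0] + y * rot[1, 0] + z * rot[2, 0] + nx
                bb[i, a, 1] = x * rot[0, 1] + y * rot[1, 1] + z * rot[2, 1] + ny
                bb[i, a, 2] = x * rot[0, 2] + y * rot[1, 2] + z * rot[2, 2] + nz


@njit(cache=True)
def _oxygens(bb, o_out):
    n = bb.shape[0]
    for i in range(n):
        u1x = bb[i, 1, 0] - bb[i, 2, 0]
        u1y = bb[i, 1, 1] - bb[i, 2, 1]
        u1z = bb[i, 1, 2] - bb[i, 2, 2]
        inv = 1.0 / np.sqrt(u1x * u1x + u1y * u1y + u1z * u1z)
        u1x *= inv
        u1y *= inv
        u1z *= inv
        if i + 1 < n:
            nx = bb[i + 1, 0, 0]
            ny = bb[i + 1, 0, 1]
            nz = bb[i + 1, 0, 2]
        else:
            nx = bb[i, 2, 0] - u1x
            ny = bb[i, 2, 1] - u1y
            nz = bb[i, 2, 2] - u1z
        u2x = nx - bb[i, 2, 0]
        u2y = ny - bb[i, 2, 1]
        u2z = nz - bb[i, 2, 2]
        inv = 1.0 / np.sqrt(u2x * u2x + u2y * u2y + u2z * u2z)
        u2x *= inv
        u2y *= inv
        u2z *= inv
        bx = u1x + u2x
        by = u1y + u2y
        bz = u1z + u2z
        norm = np.sqrt(bx * bx + by * by + bz * bz)
        if norm < 1e-9:
            norm = 1.0
        bb_scale = 1.231 / norm
        o_out[i, 0] = bb[i, 2, 0] - bx * bb_scale
        o_out[i, 1] = bb[i, 2, 1] - by * bb_scale
        o_out[i, 2] = bb[i, 2, 2] - bz * bb_scale


@njit(cache=True)
def _bend(ca, lo, hi):
    m = hi - lo
    if m < 8:
        return 0.0
    n_est = m - 3
    k = min(4, max(1, n_est // 2))
    d1x = d1y = d1z = 0.0
    d2x = d2y = d2z = 0.0
    for w in range(n_est):
        i = lo + w + 1
        a1x = ca[i - 1, 0] - 2.0 * ca[i, 0] + ca[i + 1, 0]
        a1y = ca[i - 1, 1] - 2.0 * ca[i, 1] + ca[i + 1, 1]
        a1z = ca[i - 1, 2] - 2.0 * ca[i, 2] + ca[i + 1, 2]
        a2x = ca[i, 0] - 2.0 * ca[i + 1, 0] + ca[i + 2, 0]
        a2y = ca[i, 1] - 2.0 * ca[i + 1, 1] + ca[i + 2, 1]
        a2z = ca[i, 2] - 2.0 * ca[i + 1, 2] + ca[i + 2, 2]
        cx = a1y * a2z - a1z * a2y
        cy = a1z * a2x - a1x * a2z
        cz = a1x * a2y - a1y * a2x
        norm = np.sqrt(cx * cx + cy * cy + cz * cz)
        if norm < 1e-12:
            continue
        cx /= norm
        cy /= norm
        cz /= norm
        if w < k:
            d1x += cx
            d1y += cy
            d1z += cz
        if w >= n_est - k:
            d2x += cx
            d2y += cy
            d2z += cz
    n1 = np.sqrt(d1x * d1x + d1y * d1y + d1z * d1z)
    n2 = np.sqrt(d2x * d2x + d2y * d2y + d2z * d2z)
    if n1 < 1e-12 or n2 < 1e-12:
        return 0.0
    cosang = (d1x * d2x + d1y * d2y + d1z * d2z) / (n1 * n2)
    if cosang > 1.0:
        cosang = 1.0
    elif cosang < -1.0:
        cosang = -1.0
    return np.degrees(np.arccos(cosang))


@njit(cache=True)
def terms(
    bb, o_buf, mobile_lo, with_atoms,
    mean_mat,
    c_ai, c_bi, c_target, c_sd, c_bw, c_harm,
    pair_i, pair_j,
    so_a1, so_a2, so_b1, so_b2, so_want,
    sheet_off, sheet_gids,
    helix_lo, helix_hi,
    hp_g1, hp_g2, hp_a1, hp_a2, hp_b1, hp_b2, hp_want,
    hs_hg, hs_off, hs_gids,
):
    """(clash count, other-terms score); mirrors _Objective.terms."""
    n = bb.shape[0]
    ca = bb[:, 1, :]
    clashes = 0
    for i in range(mobile_lo, n):
        for j in range(i - 1):
            dx = ca[i, 0] - ca[j, 0]
            dy = ca[i, 1] - ca[j, 1]
            dz = ca[i, 2] - ca[j, 2]
            if dx * dx + dy * dy + dz * dz < CA_CLASH_SQ:
                clashes += 1
    if with_atoms:
        _oxygens(bb, o_buf)
        for i in range(mobile_lo, n):
            for j in range(i - 1):
                # quick reject on CA distance before the 16 atom pairs
                dx = ca[i, 0] - ca[j, 0]
                dy = ca[i, 1] - ca[j, 1]
                dz = ca[i, 2] - ca[j, 2]
                if dx * dx + dy * dy + dz * dz > 120.0:
                    continue
                for ai in range(4):
                    if ai < 3:
                        ax, ay, az = bb[i, ai, 0], bb[i, ai, 1], bb[i, ai, 2]
                    else:
                        ax, ay, az = o_buf[i, 0], o_buf[i, 1], o_buf[i, 2]
                    for aj in range(4):
                        if aj < 3:
                            bx, by, bz = bb[j, aj, 0], bb[j, aj, 1], bb[j, aj, 2]
                        else:
                            bx, by, bz = o_buf[j, 0], o_buf[j, 1], o_buf[j, 2]
                        dx = ax - bx
                        dy = ay - by
                        dz = az - bz
                        if dx * dx + dy * dy + dz * dz < ATOM_CLASH_SQ:
                            clashes += 1
    score = 0.0
    n_groups = mean_mat.shape[0]
    means = np.zeros((n_groups, 3))
    for g in range(n_groups):
        for i in range(n):
            w = mean_mat[g, i]
            if w != 0.0:
                means[g, 0] += w * ca[i, 0]
                means[g, 1] += w * ca[i, 1]
                means[g, 2] += w * ca[i, 2]
    for k in range(len(c_ai)):
        dx = ca[c_ai[k], 0] - ca[c_bi[k], 0]
        dy = ca[c_ai[k], 1] - ca[c_bi[k], 1]
        dz = ca[c_ai[k], 2] - ca[c_bi[k], 2]
        dist = np.sqrt(dx * dx + dy * dy + dz * dz)
        if c_harm[k]:
            dev = abs(dist - c_target[k]) - c_sd[k]
        else:
            dev = max((c_target[k] - c_bw[k]) - dist, dist - (c_target[k] + c_bw[k]))
        if dev > 0.0:
            dev /= c_sd[k]
            if dev <= 2.0:
                score += dev * dev
            else:
                score += 4.0 + 4.0 * (dev - 2.0)
    for k in range(len(pair_i)):
        dx = ca[pair_i[k], 0] - ca[pair_j[k], 0]
        dy = ca[pair_i[k], 1] - ca[pair_j[k], 1]
        dz = ca[pair_i[k], 2] - ca[pair_j[k], 2]
        dist = np.sqrt(dx * dx + dy * dy + dz * dz)
        dev = abs(dist - PAIR_TARGET) - 0.4
        if dev > 0.0:
            if dev <= 1.5:
                score += (dev / 0.5) ** 2
            else:
                score += 9.0 + 6.0 * (dev - 1.5)
    for k in range(len(so_a1)):
        v1x = ca[so_a2[k], 0] - ca[so_a1[k], 0]
        v1y = ca[so_a2[k], 1] - ca[so_a1[k], 1]
        v1z = ca[so_a2[k], 2] - ca[so_a1[k], 2]
        v2x = ca[so_b2[k], 0] - ca[so_b1[k], 0]
        v2y = ca[so_b2[k], 1] - ca[so_b1[k], 1]
        v2z = ca[so_b2[k], 2] - ca[so_b1[k], 2]
        dot = v1x * v2x + v1y * v2y + v1z * v2z
        norm = np.sqrt(
            (v1x * v1x + v1y * v1y + v1z * v1z)
            * (v2x * v2x + v2y * v2y + v2z * v2z)
        )
        dot = dot / (norm + 1e-9) * so_want[k]
        if dot < 0.5:
            score += 5.0 * (0.5 - dot)
    for s in range(len(sheet_off) - 1):
        lo = sheet_off[s]
        hi = sheet_off[s + 1]
        for k in range(lo, hi - 2):
            g0 = sheet_gids[k]
            g1 = sheet_gids[k + 1]
            g2 = sheet_gids[k + 2]
            ux = means[g1, 0] - means[g0, 0]
            uy = means[g1, 1] - means[g0, 1]
            uz = means[g1, 2] - means[g0, 2]
            vx = means[g2, 0] - means[g1, 0]
            vy = means[g2, 1] - means[g1, 1]
            vz = means[g2, 2] - means[g1, 2]
            dot = ux * vx + uy * vy + uz * vz
            norm = np.sqrt(
                (ux * ux + uy * uy + uz * uz) * (vx * vx + vy * vy + vz * vz)
            )
            cosang = dot / (norm + 1e-9)
            if cosang < 0.3:
                score += 8.0 * (0.3 - cosang)
    for k in range(len(helix_lo)):
        bend = _bend(ca, helix_lo[k], helix_hi[k])
        if bend > 10.0:
            score += (bend - 10.0) ** 2 / 5.0
    for k in range(len(hp_g1)):
        dx = means[hp_g1[k], 0] - means[hp_g2[k], 0]
        dy = means[hp_g1[k], 1] - means[hp_g2[k], 1]
        dz = means[hp_g1[k], 2] - means[hp_g2[k], 2]
        dist = np.sqrt(dx * dx + dy * dy + dz * dz)
        dev = abs(dist - 10.0) - 2.0
        if dev > 0.0:
            score += dev * dev
        v1x = ca[hp_a2[k], 0] - ca[hp_a1[k], 0]
        v1y = ca[hp_a2[k], 1] - ca[hp_a1[k], 1]
        v1z = ca[hp_a2[k], 2] - ca[hp_a1[k], 2]
        v2x = ca[hp_b2[k], 0] - ca[hp_b1[k], 0]
        v2y = ca[hp_b2[k], 1] - ca[hp_b1[k], 1]
        v2z = ca[hp_b2[k], 2] - ca[hp_b1[k], 2]
        dot = v1x * v2x + v1y * v2y + v1z * v2z
        norm = np.sqrt(
            (v1x * v1x + v1y * v1y + v1z * v1z)
            * (v2x * v2x + v2y * v2y + v2z * v2z)
        )
        dot = dot / (norm + 1e-9) * hp_want[k]
        if dot < 0.3:
            score += 5.0 * (0.3 - dot)
    for k in range(len(hs_hg)):
        smx = smy = smz = 0.0
        cnt = 0
        for idx in range(hs_off[k], hs_off[k + 1]):
            g = hs_gids[idx]
            smx += means[g, 0]
            smy += means[g, 1]
            smz += means[g, 2]
            cnt += 1
        smx /= cnt
        smy /= cnt
        smz /= cnt
        dx = means[hs_hg[k], 0] - smx
        dy = means[hs_hg[k], 1] - smy
        dz = means[hs_hg[k], 2] - smz
        dist = np.sqrt(dx * dx + dy * dy + dz * dz)
        dev = abs(dist - 9.0) - 2.0
        if dev > 0.0:
            score += dev * dev
    return clashes, score


@njit(cache=True)
def run_trajectory(
    seed, tors, bb, letters, ss_sd, loop_weighted, mobile_lo, n_ctx,
    n_moves, start_move, temp_high, temp_low, check_every,
    mean_mat,
    c_ai, c_bi, c_target, c_sd, c_bw, c_harm,
    pair_i, pair_j,
    so_a1, so_a2, so_b1, so_b2, so_want,
    sheet_off, sheet_gids,
    helix_lo, helix_hi,
    hp_g1, hp_g2, hp_a1, hp_a2, hp_b1, hp_b2, hp_want,
    hs_hg, hs_off, hs_gids,
):
    """Run (or resume) one annealed trajectory in place.

    Returns (next_move, status).  ``tors`` and ``bb`` are mutated; on a
    CHECKPOINT return the caller evaluates the filters and may re-enter
    with ``start_move = next_move``.
    """
    n = bb.shape[0]
    o_buf = np.empty((n, 3))
    if start_move == 0:
        np.random.seed(seed)
    n_mobile = n - mobile_lo
    # cumulative move-selection weights over mobile positions
    wsum = 0.0
    cumw = np.empty(n_mobile)
    for k in range(n_mobile):
        wsum += loop_weighted[mobile_lo + k]
        cumw[k] = wsum
    atoms_phase = start_move >= max(1, n_moves) // 2
    state_c, state_s = terms(
        bb, o_buf, mobile_lo, atoms_phase, mean_mat,
        c_ai, c_bi, c_target, c_sd, c_bw, c_harm, pair_i, pair_j,
        so_a1, so_a2, so_b1, so_b2, so_want, sheet_off, sheet_gids,
        helix_lo, helix_hi, hp_g1, hp_g2, hp_a1, hp_a2, hp_b1, hp_b2, hp_want,
        hs_hg, hs_off, hs_gids,
    )
    saved_tail = np.empty_like(bb)
    old_t = np.empty((3, 3))
    for move in range(start_move, n_moves):
        progress = move / max(1, n_moves - 1)
        if progress < 0.7:
            t = temp_high * (temp_low / temp_high) ** (progress / 0.7)
        else:
            t = 0.05
        clash_w = 8.0 + 12.0 * min(1.0, 1.5 * progress)
        if not atoms_phase and progress >= 0.5:
            atoms_phase = True
            state_c, state_s = terms(
                bb, o_buf, mobile_lo, True, mean_mat,
                c_ai, c_bi, c_target, c_sd, c_bw, c_harm, pair_i, pair_j,
                so_a1, so_a2, so_b1, so_b2, so_want, sheet_off, sheet_gids,
                helix_lo, helix_hi, hp_g1, hp_g2, hp_a1, hp_a2, hp_b1, hp_b2,
                hp_want, hs_hg, hs_off, hs_gids,
            )
            if 10.0 * state_c + state_s > 250.0:
                return n_moves, ABANDONED
        # pick a mobile position by weight
        u = np.random.random() * wsum
        k = np.searchsorted(cumw, u)
        if k >= n_mobile:
            k = n_mobile - 1
        p = mobile_lo + k
        small = np.random.random() < (0.2 + 0.7 * progress)
        if small:
            span = 1
        else:
            span = min(3, n - p)
        for r in range(span):
            for c in range(3):
                old_t[r, c] = tors[p + r, c]
        for i in range(n):
            for a in range(3):
                for c in range(3):
                    saved_tail[i, a, c] = bb[i, a, c]
        if small:
            phi0 = tors[p, 0]
            psi0 = tors[p, 1]
            om0 = tors[p, 2]
            ok = False
            for _ in range(4):
                phi2 = _wrap(phi0 + 5.0 * np.random.standard_normal())
                psi2 = _wrap(psi0 + 5.0 * np.random.standard_normal())
                om2 = _wrap(om0 + 1.0 * np.random.standard_normal())
                if _classify(phi2, psi2, om2) == letters[p]:
                    ok = True
                    break
            if ok:
                if not ((p == n_ctx - 1 and n_ctx > 0) or (p == 0 and n_ctx == 0)):
                    tors[p, 0] = phi2
                tors[p, 1] = psi2
                tors[p, 2] = om2
        else:
            for kk in range(p, p + span):
                phi, psi, omega = _sample_letter(letters[kk], ss_sd[kk])
                if kk > 0 and not (kk == n_ctx - 1 and n_ctx > 0):
                    tors[kk, 0] = phi
                tors[kk, 1] = psi
                tors[kk, 2] = omega
        apply_move(tors, bb, p, span, n)
        new_c, new_s = terms(
            bb, o_buf, mobile_lo, atoms_phase, mean_mat,
            c_ai, c_bi, c_target, c_sd, c_bw, c_harm, pair_i, pair_j,
            so_a1, so_a2, so_b1, so_b2, so_want, sheet_off, sheet_gids,
            helix_lo, helix_hi, hp_g1, hp_g2, hp_a1, hp_a2, hp_b1, hp_b2, hp_want,
            hs_hg, hs_off, hs_gids,
        )
        d_score = (clash_w * new_c + new_s) - (clash_w * state_c + state_s)
        if d_score <= 0.0 or np.random.random() < np.exp(-d_score / t):
            state_c, state_s = new_c, new_s
        else:
            for r in range(span):
                for c in range(3):
                    tors[p + r, c] = old_t[r, c]
            for i in range(n):
                for a in range(3):
                    for c in range(3):
                        bb[i, a, c] = saved_tail[i, a, c]
        score = 20.0 * state_c + state_s
        if progress >= 0.75 and score > 250.0 and move % 50 == 0:
            return n_moves, ABANDONED
        if atoms_phase and score < 40.0 and (move + 1) % check_every == 0:
            return move + 1, CHECKPOINT
    return n_moves, FINISHED


@njit(cache=True)
def polish(
    seed, tors, bb, letters, loop_weighted, mobile_lo, n_ctx, n_iter,
    mean_mat,
    c_ai, c_bi, c_target, c_sd, c_bw, c_harm,
    pair_i, pair_j,
    so_a1, so_a2, so_b1, so_b2, so_want,
    sheet_off, sheet_gids,
    helix_lo, helix_hi,
    hp_g1, hp_g2, hp_a1, hp_a2, hp_b1, hp_b2, hp_want,
    hs_hg, hs_off, hs_gids,
):
    """Greedy small-move quench after acceptance."""
    n = bb.shape[0]
    o_buf = np.empty((n, 3))
    np.random.seed(seed)
    n_mobile = n - mobile_lo
    wsum = 0.0
    cumw = np.empty(n_mobile)
    for k in range(n_mobile):
        wsum += loop_weighted[mobile_lo + k]
        cumw[k] = wsum
    state_c, state_s = terms(
        bb, o_buf, mobile_lo, True, mean_mat,
        c_ai, c_bi, c_target, c_sd, c_bw, c_harm, pair_i, pair_j,
        so_a1, so_a2, so_b1, so_b2, so_want, sheet_off, sheet_gids,
        helix_lo, helix_hi, hp_g1, hp_g2, hp_a1, hp_a2, hp_b1, hp_b2, hp_want,
        hs_hg, hs_off, hs_gids,
    )
    saved_tail = np.empty_like(bb)
    for _ in range(n_iter):
        u = np.random.random() * wsum
        k = np.searchsorted(cumw, u)
        if k >= n_mobile:
            k = n_mobile - 1
        p = mobile_lo + k
        phi0, psi0, om0 = tors[p, 0], tors[p, 1], tors[p, 2]
        ok = False
        for _ in range(4):
            phi2 = _wrap(phi0 + 3.0 * np.random.standard_normal())
            psi2 = _wrap(psi0 + 3.0 * np.random.standard_normal())
            om2 = _wrap(om0 + 1.0 * np.random.standard_normal())
            if _classify(phi2, psi2, om2) == letters[p]:
                ok = True
                break
        if not ok:
            continue
        for i in range(n):
            for a in range(3):
                for c in range(3):
                    saved_tail[i, a, c] = bb[i, a, c]
        if not ((p == n_ctx - 1 and n_ctx > 0) or (p == 0 and n_ctx == 0)):
            tors[p, 0] = phi2
        tors[p, 1] = psi2
        tors[p, 2] = om2
        apply_move(tors, bb, p, 1, n)
        new_c, new_s = terms(
            bb, o_buf, mobile_lo, True, mean_mat,
            c_ai, c_bi, c_target, c_sd, c_bw, c_harm, pair_i, pair_j,
            so_a1, so_a2, so_b1, so_b2, so_want, sheet_off, sheet_gids,
            helix_lo, helix_hi, hp_g1, hp_g2, hp_a1, hp_a2, hp_b1, hp_b2, hp_want,
            hs_hg, hs_off, hs_gids,
        )
        if 20.0 * new_c + new_s < 20.0 * state_c + state_s:
            state_c, state_s = new_c, new_s
        else:
            tors[p, 0], tors[p, 1], tors[p, 2] = phi0, psi0, om0
            for i in range(n):
                for a in range(3):
                    for c in range(3):
                        bb[i, a, c] = saved_tail[i, a, c]
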