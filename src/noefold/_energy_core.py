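"""Numba-compiled inner loops of the annealing engine.

The energy model is a sum of non-negative penalty terms; this module holds
the flat-array kernel computing total energy + analytic gradient, and the
Langevin annealing loop.  Everything here is deterministic given its
inputs (the noise sequence is generated by the caller).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def energy_grad(x,
                bond_i, bond_j, bond_d0, k_bond,
                ang_i, ang_j, ang_k, ang_t0, k_angle,
                imp_a, imp_b, imp_c, imp_d, imp_t0, k_improper,
                mem_a, mem_b, mem_cid, n_dist, dist_upper, dist_lower,
                dist_weight, k_distance,
                dih_a, dih_b, dih_c, dih_d, dih_center, dih_width, k_dihedral,
                hb_h, hb_n, hb_o, hb_ho, hb_no, hb_weight,
                rep_i, rep_j, rep_rmin, k_repulsion):
    n = x.shape[0]
    grad = np.zeros((n, 3))
    energy = 0.0

    # bonds: k (d - d0)^2
    for t in range(bond_i.shape[0]):
        i = bond_i[t]
        j = bond_j[t]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d < 1e-9:
            d = 1e-9
        diff = d - bond_d0[t]
        energy += k_bond * diff * diff
        c = 2.0 * k_bond * diff / d
        grad[i, 0] += c * dx
        grad[i, 1] += c * dy
        grad[i, 2] += c * dz
        grad[j, 0] -= c * dx
        grad[j, 1] -= c * dy
        grad[j, 2] -= c * dz

    # angles: k (theta - theta0)^2
    for t in range(ang_i.shape[0]):
        i = ang_i[t]
        j = ang_j[t]
        k = ang_k[t]
        ux = x[i, 0] - x[j, 0]
        uy = x[i, 1] - x[j, 1]
        uz = x[i, 2] - x[j, 2]
        vx = x[k, 0] - x[j, 0]
        vy = x[k, 1] - x[j, 1]
        vz = x[k, 2] - x[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if nu < 1e-9:
            nu = 1e-9
        if nv < 1e-9:
            nv = 1e-9
        uhx, uhy, uhz = ux / nu, uy / nu, uz / nu
        vhx, vhy, vhz = vx / nv, vy / nv, vz / nv
        cosang = uhx * vhx + uhy * vhy + uhz * vhz
        if cosang > 1.0:
            cosang = 1.0
        elif cosang < -1.0:
            cosang = -1.0
        theta = np.arccos(cosang)
        sin = np.sqrt(1.0 - cosang * cosang)
        if sin < 1e-6:
            sin = 1e-6
        delta = theta - ang_t0[t]
        energy += k_angle * delta * delta
        coef = 2.0 * k_angle * delta
        cu = coef / (nu * sin)
        cv = coef / (nv * sin)
        gix = cu * (cosang * uhx - vhx)
        giy = cu * (cosang * uhy - vhy)
        giz = cu * (cosang * uhz - vhz)
        gkx = cv * (cosang * vhx - uhx)
        gky = cv * (cosang * vhy - uhy)
        gkz = cv * (cosang * vhz - uhz)
        grad[i, 0] += gix
        grad[i, 1] += giy
        grad[i, 2] += giz
        grad[k, 0] += gkx
        grad[k, 1] += gky
        grad[k, 2] += gkz
        grad[j, 0] -= gix + gkx
        grad[j, 1] -= giy + gky
        grad[j, 2] -= giz + gkz

    # impropers / omega: harmonic on wrapped deviation
    for t in range(imp_a.shape[0]):
        _dihedral_term(x, grad, imp_a[t], imp_b[t], imp_c[t], imp_d[t],
                       imp_t0[t], 0.0, k_improper)
        energy += _dihedral_energy(x, imp_a[t], imp_b[t], imp_c[t], imp_d[t],
                                   imp_t0[t], 0.0, k_improper)

    # distance restraints with r^-6 effective distance over members
    if n_dist > 0:
        sums = np.zeros(n_dist)
        dmem = np.empty(mem_a.shape[0])
        for t in range(mem_a.shape[0]):
            i = mem_a[t]
            j = mem_b[t]
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d < 1e-6:
                d = 1e-6
            dmem[t] = d
            sums[mem_cid[t]] += d ** (-6.0)
        viol = np.zeros(n_dist)
        deff = np.zeros(n_dist)
        for cdx in range(n_dist):
            de = sums[cdx] ** (-1.0 / 6.0)
            deff[cdx] = de
            over = de - dist_upper[cdx]
            under = dist_lower[cdx] - de
            if over > 0.0:
                viol[cdx] = over
            elif under > 0.0:
                viol[cdx] = -under
            energy += dist_weight[cdx] * k_distance * viol[cdx] * viol[cdx]
        for t in range(mem_a.shape[0]):
            cdx = mem_cid[t]
            if viol[cdx] == 0.0:
                continue
            i = mem_a[t]
            j = mem_b[t]
            d = dmem[t]
            de = deff[cdx]
            coef = (2.0 * dist_weight[cdx] * k_distance * viol[cdx]
                    * (de / d) ** 7.0 / d)
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            grad[i, 0] += coef * dx
            grad[i, 1] += coef * dy
            grad[i, 2] += coef * dz
            grad[j, 0] -= coef * dx
            grad[j, 1] -= coef * dy
            grad[j, 2] -= coef * dz

    # flat-bottom backbone dihedral restraints
    for t in range(dih_a.shape[0]):
        _dihedral_term(x, grad, dih_a[t], dih_b[t], dih_c[t], dih_d[t],
                       dih_center[t], dih_width[t], k_dihedral)
        energy += _dihedral_energy(x, dih_a[t], dih_b[t], dih_c[t], dih_d[t],
                                   dih_center[t], dih_width[t], k_dihedral)

    # hydrogen bonds: flat-bottom upper limits on H..O and N..O
    for t in range(hb_h.shape[0]):
        for pair in range(2):
            if pair == 0:
                i = hb_h[t]
                tgt = hb_ho[t]
            else:
                i = hb_n[t]
                tgt = hb_no[t]
            j = hb_o[t]
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d < 1e-9:
                d = 1e-9
            v = d - tgt
            if v > 0.0:
                energy += hb_weight * v * v
                c = 2.0 * hb_weight * v / d
                grad[i, 0] += c * dx
                grad[i, 1] += c * dy
                grad[i, 2] += c * dz
                grad[j, 0] -= c * dx
                grad[j, 1] -= c * dy
                grad[j, 2] -= c * dz

    # soft-sphere repulsion
    for t in range(rep_i.shape[0]):
        i = rep_i[t]
        j = rep_j[t]
        dx = x[i, 0] - x[j, 0]
        rmin = rep_rmin[t]
        if dx > rmin or dx < -rmin:
            continue
        dy = x[i, 1] - x[j, 1]
        if dy > rmin or dy < -rmin:
            continue
        dz = x[i, 2] - x[j, 2]
        if dz > rmin or dz < -rmin:
            continue
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d >= rmin:
            continue
        if d < 1e-9:
            d = 1e-9
        overlap = rmin - d
        energy += k_repulsion * overlap * overlap
        c = -2.0 * k_repulsion * overlap / d
        grad[i, 0] += c * dx
        grad[i, 1] += c * dy
        grad[i, 2] += c * dz
        grad[j, 0] -= c * dx
        grad[j, 1] -= c * dy
        grad[j, 2] -= c * dz

    return energy, grad


@njit(cache=True, inline="always")
def _wrap(angle):
    while angle > np.pi:
        angle -= 2.0 * np.pi
    while angle < -np.pi:
        angle += 2.0 * np.pi
    return angle


@njit(cache=True)
def _dihedral_value(x, a, b, c, d):
    b1x = x[b, 0] - x[a, 0]
    b1y = x[b, 1] - x[a, 1]
    b1z = x[b, 2] - x[a, 2]
    b2x = x[c, 0] - x[b, 0]
    b2y = x[c, 1] - x[b, 1]
    b2z = x[c, 2] - x[b, 2]
    b3x = x[d, 0] - x[c, 0]
    b3y = x[d, 1] - x[c, 1]
    b3z = x[d, 2] - x[c, 2]
    n1x = b1y * b2z - b1z * b2y
    n1y = b1z * b2x - b1x * b2z
    n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y
    n2y = b2z * b3x - b2x * b3z
    n2z = b2x * b3y - b2y * b3x
    nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
    if nb2 < 1e-9:
        nb2 = 1e-9
    m1x = (n1y * b2z - n1z * b2y) / nb2
    m1y = (n1z * b2x - n1x * b2z) / nb2
    m1z = (n1x * b2y - n1y * b2x) / nb2
    xc = n1x * n2x + n1y * n2y + n1z * n2z
    yc = m1x * n2x + m1y * n2y + m1z * n2z
    return np.arctan2(yc, xc)


@njit(cache=True)
def _dihedral_energy(x, a, b, c, d, center, width, k):
    phi = _dihedral_value(x, a, b, c, d)
    delta = _wrap(phi - center)
    excess = abs(delta) - width
    if excess <= 0.0:
        return 0.0
    return k * excess * excess


@njit(cache=True)
def _dihedral_term(x, grad, a, b, c, d, center, width, k):
    """Accumulate the gradient of a flat-bottom dihedral penalty."""
    b1x = x[b, 0] - x[a, 0]
    b1y = x[b, 1] - x[a, 1]
    b1z = x[b, 2] - x[a, 2]
    b2x = x[c, 0] - x[b, 0]
    b2y = x[c, 1] - x[b, 1]
    b2z = x[c, 2] - x[b, 2]
    b3x = x[d, 0] - x[c, 0]
    b3y = x[d, 1] - x[c, 1]
    b3z = x[d, 2] - x[c, 2]
    n1x = b1y * b2z - b1z * b2y
    n1y = b1z * b2x - b1x * b2z
    n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y
    n2y = b2z * b3x - b2x * b3z
    n2z = b2x * b3y - b2y * b3x
    nb2sq = b2x * b2x + b2y * b2y + b2z * b2z
    nb2 = np.sqrt(nb2sq)
    if nb2 < 1e-9:
        nb2 = 1e-9
        nb2sq = 1e-18
    m1x = (n1y * b2z - n1z * b2y) / nb2
    m1y = (n1z * b2x - n1x * b2z) / nb2
    m1z = (n1x * b2y - n1y * b2x) / nb2
    xc = n1x * n2x + n1y * n2y + n1z * n2z
    yc = m1x * n2x + m1y * n2y + m1z * n2z
    phi = np.arctan2(yc, xc)
    delta = _wrap(phi - center)
    excess = abs(delta) - width
    if excess <= 0.0:
        return
    dV = 2.0 * k * excess * (1.0 if delta > 0.0 else -1.0)
    sq1 = n1x * n1x + n1y * n1y + n1z * n1z
    sq2 = n2x * n2x + n2y * n2y + n2z * n2z
    if sq1 < 1e-12:
        sq1 = 1e-12
    if sq2 < 1e-12:
        sq2 = 1e-12
    gax = nb2 / sq1 * n1x
    gay = nb2 / sq1 * n1y
    gaz = nb2 / sq1 * n1z
    gdx = -nb2 / sq2 * n2x
    gdy = -nb2 / sq2 * n2y
    gdz = -nb2 / sq2 * n2z
    s12 = (b1x * b2x + b1y * b2y + b1z * b2z) / nb2sq
    s32 = (b3x * b2x + b3y * b2y + b3z * b2z) / nb2sq
    gbx = -(1.0 + s12) * gax + s32 * gdx
    gby = -(1.0 + s12) * gay + s32 * gdy
    gbz = -(1.0 + s12) * gaz + s32 * gdz
    gcx = s12 * gax - (1.0 + s32) * gdx
    gcy = s12 * gay - (1.0 + s32) * gdy
    gcz = s12 * gaz - (1.0 + s32) * gdz
    grad[a, 0] += dV * gax
    grad[a, 1] += dV * gay
    grad[a, 2] += dV * gaz
    grad[b, 0] += dV * gbx
    grad[b, 1] += dV * gby
    grad[b, 2] += dV * gbz
    grad[c, 0] += dV * gcx
    grad[c, 1] += dV * gcy
    grad[c, 2] += dV * gcz
    grad[d, 0] += dV * (-gax - gbx - gcx)
    grad[d, 1] += dV * (-gay - gby - gcy)
    grad[d, 2] += dV * (-gaz - gbz - gcz)


@njit(cache=True)
def langevin(x0, noise, temps, lr, grad_clip,
             bond_i, bond_j, bond_d0, k_bond,
             ang_i, ang_j, ang_k, ang_t0, k_angle,
             imp_a, imp_b, imp_c, imp_d, imp_t0, k_improper,
             mem_a, mem_b, mem_cid, n_dist, dist_upper, dist_lower,
             dist_weight, k_distance,
             dih_a, dih_b, dih_c, dih_d, dih_center, dih_width, k_dihedral,
             hb_h, hb_n, hb_o, hb_ho, hb_no, hb_weight,
             rep_i, rep_j, rep_rmin, k_repulsion):
    """Overdamped Langevin dynamics with a per-step temperature schedule."""
    x = x0.copy()
    n = x.shape[0]
    for step in range(temps.shape[0]):
        e, grad = energy_grad(x,
                              bond_i, bond_j, bond_d0, k_bond,
                              ang_i, ang_j, ang_k, ang_t0, k_angle,
                              imp_a, imp_b, imp_c, imp_d, imp_t0, k_improper,
                              mem_a, mem_b, mem_cid, n_dist, dist_upper,
                              dist_lower, dist_weight, k_distance,
                              dih_a, dih_b, dih_c, dih_d, dih_center,
                              dih_width, k_dihedral,
                              hb_h, hb_n, hb_o, hb_ho, hb_no, hb_weight,
                              rep_i, rep_j, rep_rmin, k_repulsion)
        amp = np.sqrt(2.0 * lr * temps[step])
        for i in range(n):
            for j in range(3):
                g = grad[i, j]
                if g > grad_clip:
                    g = grad_clip
                elif g < -grad_clip:
                    g = -grad_clip
                x[i, j] += -lr * g + amp * noise[step, i, j]
    return x
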