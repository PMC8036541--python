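"""Numba-compiled inner loops for the particle-system Monte Carlo sweep.

Only the sequential single-particle Metropolis sweep lives here; full-energy
evaluations and rigid-body chain moves stay on the vectorised numpy path in
:mod:`tigersim.toy_systems`.
"""

from __future__ import annotations

import math

from numba import njit


@njit(cache=True, fastmath=False)
def _dihedral_deg(coords, a, b, c, d):
    b0x = coords[b, 0] - coords[a, 0]
    b0y = coords[b, 1] - coords[a, 1]
    b0z = coords[b, 2] - coords[a, 2]
    b1x = coords[c, 0] - coords[b, 0]
    b1y = coords[c, 1] - coords[b, 1]
    b1z = coords[c, 2] - coords[b, 2]
    b2x = coords[d, 0] - coords[c, 0]
    b2y = coords[d, 1] - coords[c, 1]
    b2z = coords[d, 2] - coords[c, 2]
    # n1 = b0 x b1, n2 = b1 x b2
    n1x = b0y * b1z - b0z * b1y
    n1y = b0z * b1x - b0x * b1z
    n1z = b0x * b1y - b0y * b1x
    n2x = b1y * b2z - b1z * b2y
    n2y = b1z * b2x - b1x * b2z
    n2z = b1x * b2y - b1y * b2x
    nb1 = math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
    u1x, u1y, u1z = b1x / nb1, b1y / nb1, b1z / nb1
    # m1 = n1 x u1
    m1x = n1y * u1z - n1z * u1y
    m1y = n1z * u1x - n1x * u1z
    m1z = n1x * u1y - n1y * u1x
    x = n1x * n2x + n1y * n2y + n1z * n2z
    y = m1x * n2x + m1y * n2y + m1z * n2z
    ang = math.degrees(math.atan2(-y, x))
    if ang == -180.0:
        ang = 180.0
    return ang


@njit(cache=True, fastmath=False)
def _particle_energy_kernel(
    coords, i, box, use_mi,
    depth, r02, shift, excl,
    bondp, bondn, bond_k, bond_len,
    quads, theta0, kdih, pquads, pquadn,
    pairs, d0, flat, kdist, ppairs, ppairn,
):
    n = coords.shape[0]
    e = 0.0
    xi, yi, zi = coords[i, 0], coords[i, 1], coords[i, 2]
    for j in range(n):
        if j == i or excl[i, j]:
            continue
        dx = xi - coords[j, 0]
        dy = yi - coords[j, 1]
        dz = zi - coords[j, 2]
        if use_mi:
            dx -= box * math.floor(dx / box + 0.5)
            dy -= box * math.floor(dy / box + 0.5)
            dz -= box * math.floor(dz / box + 0.5)
        r2 = dx * dx + dy * dy + dz * dz
        r02ij = r02[i, j]
        if r2 < 4.0 * r02ij:
            dep = depth[i, j]
            a2 = 0.36 * r02ij
            s2 = (r02ij + a2) / (r2 + a2)
            s6 = s2 * s2 * s2
            e += abs(dep) * s6 * s6 - 2.0 * dep * s6 - shift[i, j]
    for bi in range(bondn[i]):
        j = bondp[i, bi]
        dx = xi - coords[j, 0]
        dy = yi - coords[j, 1]
        dz = zi - coords[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        e += bond_k * (r - bond_len) * (r - bond_len)
    for qi in range(pquadn[i]):
        q = pquads[i, qi]
        ang = _dihedral_deg(coords, quads[q, 0], quads[q, 1], quads[q, 2], quads[q, 3])
        delta = (ang - theta0[q] + 180.0) % 360.0 - 180.0
        e += kdih[q] * delta * delta
    for pi in range(ppairn[i]):
        p = ppairs[i, pi]
        a, b = pairs[p, 0], pairs[p, 1]
        dx = coords[a, 0] - coords[b, 0]
        dy = coords[a, 1] - coords[b, 1]
        dz = coords[a, 2] - coords[b, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        delta = abs(r - d0[p]) - flat[p]
        if delta > 0.0:
            e += kdist[p] * delta * delta
    return e


@njit(cache=True, fastmath=False)
def particle_sweep(
    coords, box, use_mi,
    depth, r02, shift, excl,
    bondp, bondn, bond_k, bond_len,
    quads, theta0, kdih, pquads, pquadn,
    pairs, d0, flat, kdist, ppairs, ppairn,
    beta, disp, logu,
):
    """Sequential Metropolis sweep over all particles; mutates coords in place.

    Returns ``(energy_delta, n_accepted)``.
    """
    n = coords.shape[0]
    acc = 0
    de_total = 0.0
    for i in range(n):
        e_old = _particle_energy_kernel(
            coords, i, box, use_mi, depth, r02, shift, excl,
            bondp, bondn, bond_k, bond_len,
            quads, theta0, kdih, pquads, pquadn,
            pairs, d0, flat, kdist, ppairs, ppairn,
        )
        ox, oy, oz = coords[i, 0], coords[i, 1], coords[i, 2]
        coords[i, 0] = ox + disp[i, 0]
        coords[i, 1] = oy + disp[i, 1]
        coords[i, 2] = oz + disp[i, 2]
        e_new = _particle_energy_kernel(
            coords, i, box, use_mi, depth, r02, shift, excl,
            bondp, bondn, bond_k, bond_len,
            quads, theta0, kdih, pquads, pquadn,
            pairs, d0, flat, kdist, ppairs, ppairn,
        )
        if logu[i] < -beta * (e_new - e_old):
            de_total += e_new - e_old
            acc += 1
        else:
            coords[i, 0] = ox
            coords[i, 1] = oy
            coords[i, 2] = oz
    return de_total, acc
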