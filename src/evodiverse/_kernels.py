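"""Numba-compiled numerical kernels.

These are the hot inner loops of sampling: rebuilding Cartesian backbone
coordinates from internal coordinates (NeRF-style sequential placement) and
computing the pairwise terms of the coarse-grained score. Everything here is
plain array-in/array-out; all bookkeeping lives in the public modules.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Geometry parameter vector layout (lengths in Angstrom, angles in radians):
#   0 d(N-CA)   1 d(CA-C)   2 d(C-N)    3 d(C-O)    4 d(CA-CEN)
#   5 a(N-CA-C) 6 a(CA-C-N) 7 a(C-N-CA) 8 a(CA-C-O) 9 a(N-CA-CEN)
#   10 torsion(C, N, CA, CEN)
N_GEOM_PARAMS = 11

# Atom row indices within a residue's (5, 3) coordinate block.
ATOM_N, ATOM_CA, ATOM_C, ATOM_O, ATOM_CEN = 0, 1, 2, 3, 4


@njit(cache=True)
def _place(a, b, c, r, theta, chi, out):
    """Place atom D bonded to c with |cD|=r, angle(b,c,D)=theta and
    torsion(a,b,c,D)=chi. Standard three-atom frame construction."""
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    nbc = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx / nbc, bcy / nbc, bcz / nbc
    # n = ab x bc (plane normal), m = n x bc
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    ct, st = math.cos(theta), math.sin(theta)
    cc, sc = math.cos(chi), math.sin(chi)
    dx = -r * ct
    dy = r * st * cc
    dz = r * st * sc
    out[0] = c[0] + dx * bcx + dy * mx + dz * nx
    out[1] = c[1] + dx * bcy + dy * my + dz * ny
    out[2] = c[2] + dx * bcz + dy * mz + dz * nz


@njit(cache=True)
def rebuild_chain(dihedrals_rad, geom):
    """Sequential internal->Cartesian rebuild.

    dihedrals_rad: (l, 3) array of (phi, psi, omega) in radians; phi[0],
    psi[-1] and omega[-1] are stored but geometrically inert. geom: the
    11-vector documented above. Returns (l, 5, 3) coordinates ordered
    N, CA, C, O, CEN, with residue 1 anchored in a canonical frame.
    """
    l = dihedrals_rad.shape[0]
    coords = np.empty((l, 5, 3))
    d_n_ca, d_ca_c, d_c_n, d_c_o, d_ca_cen = geom[0], geom[1], geom[2], geom[3], geom[4]
    a_n_ca_c, a_ca_c_n, a_c_n_ca = geom[5], geom[6], geom[7]
    a_ca_c_o, a_n_ca_cen, t_cen = geom[8], geom[9], geom[10]

    # Anchor: N1 at origin, CA1 on +x, C1 in the xy plane.
    coords[0, ATOM_N, 0] = 0.0
    coords[0, ATOM_N, 1] = 0.0
    coords[0, ATOM_N, 2] = 0.0
    coords[0, ATOM_CA, 0] = d_n_ca
    coords[0, ATOM_CA, 1] = 0.0
    coords[0, ATOM_CA, 2] = 0.0
    coords[0, ATOM_C, 0] = d_n_ca - d_ca_c * math.cos(a_n_ca_c)
    coords[0, ATOM_C, 1] = d_ca_c * math.sin(a_n_ca_c)
    coords[0, ATOM_C, 2] = 0.0

    for i in range(1, l):
        psi_prev = dihedrals_rad[i - 1, 1]
        omega_prev = dihedrals_rad[i - 1, 2]
        phi_i = dihedrals_rad[i, 0]
        _place(coords[i - 1, ATOM_N], coords[i - 1, ATOM_CA], coords[i - 1, ATOM_C],
               d_c_n, a_ca_c_n, psi_prev, coords[i, ATOM_N])
        _place(coords[i - 1, ATOM_CA], coords[i - 1, ATOM_C], coords[i, ATOM_N],
               d_n_ca, a_c_n_ca, omega_prev, coords[i, ATOM_CA])
        _place(coords[i - 1, ATOM_C], coords[i, ATOM_N], coords[i, ATOM_CA],
               d_ca_c, a_n_ca_c, phi_i, coords[i, ATOM_C])

    for i in range(l):
        psi_i = dihedrals_rad[i, 1]
        # Carbonyl O is anti to the next backbone N (torsion psi + pi).
        _place(coords[i, ATOM_N], coords[i, ATOM_CA], coords[i, ATOM_C],
               d_c_o, a_ca_c_o, psi_i + math.pi, coords[i, ATOM_O])
        # Side-chain centroid in a fixed frame off the N-CA bond.
        _place(coords[i, ATOM_C], coords[i, ATOM_N], coords[i, ATOM_CA],
               d_ca_cen, a_n_ca_cen, t_cen, coords[i, ATOM_CEN])
    return coords


@njit(cache=True)
def energy_components(coords, dihedrals_deg, r_clash, hb_min, hb_max, s_cut,
                      basins, basin_radius):
    """Raw (unweighted) score components for one conformation.

    Returns (steric, hb_sr, hb_lr, rg, n_off_basin):
      steric      sum of ((r_clash - d)/r_clash)^2 over CA-CA and CEN-CEN
                  pairs with sequence separation >= 2 and d < r_clash
      hb_sr/hb_lr -1 per realized O(i)...N(j) hydrogen bond with |i-j| >= 3
                  and hb_min <= d <= hb_max, split at sequence separation
                  s_cut. Donors and acceptors saturate: candidate pairs are
                  matched greedily by increasing distance with each O and
                  each N used at most once
      rg          radius of gyration of the CA trace
      n_off_basin residues whose (phi, psi) lies outside every basin
                  (wrapped Euclidean distance > basin_radius degrees)
    """
    l = coords.shape[0]
    steric = 0.0
    for i in range(l):
        for j in range(i + 2, l):
            for atom in (ATOM_CA, ATOM_CEN):
                dx = coords[i, atom, 0] - coords[j, atom, 0]
                dy = coords[i, atom, 1] - coords[j, atom, 1]
                dz = coords[i, atom, 2] - coords[j, atom, 2]
                d = math.sqrt(dx * dx + dy * dy + dz * dz)
                if d < r_clash:
                    t = (r_clash - d) / r_clash
                    steric += t * t

    # Candidate donor-acceptor pairs inside the distance window.
    cap = l * 8
    cand_d = np.empty(cap)
    cand_i = np.empty(cap, np.int64)
    cand_j = np.empty(cap, np.int64)
    nc = 0
    for i in range(l):
        for j in range(l):
            sep = j - i if j > i else i - j
            if sep < 3:
                continue
            dx = coords[i, ATOM_O, 0] - coords[j, ATOM_N, 0]
            dy = coords[i, ATOM_O, 1] - coords[j, ATOM_N, 1]
            dz = coords[i, ATOM_O, 2] - coords[j, ATOM_N, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if hb_min <= d <= hb_max:
                if nc < cap:
                    cand_d[nc] = d
                    cand_i[nc] = i
                    cand_j[nc] = j
                    nc += 1
    # Greedy matching by increasing distance: each acceptor O(i) and each
    # donor N(j) realizes at most one hydrogen bond.
    hb_sr = 0.0
    hb_lr = 0.0
    if nc > 0:
        order = np.argsort(cand_d[:nc])
        used_o = np.zeros(l, np.bool_)
        used_n = np.zeros(l, np.bool_)
        for k in range(nc):
            idx = order[k]
            i = cand_i[idx]
            j = cand_j[idx]
            if used_o[i] or used_n[j]:
                continue
            used_o[i] = True
            used_n[j] = True
            sep = j - i if j > i else i - j
            if sep <= s_cut:
                hb_sr -= 1.0
            else:
                hb_lr -= 1.0

    cx = 0.0
    cy = 0.0
    cz = 0.0
    for i in range(l):
        cx += coords[i, ATOM_CA, 0]
        cy += coords[i, ATOM_CA, 1]
        cz += coords[i, ATOM_CA, 2]
    cx /= l
    cy /= l
    cz /= l
    ssq = 0.0
    for i in range(l):
        dx = coords[i, ATOM_CA, 0] - cx
        dy = coords[i, ATOM_CA, 1] - cy
        dz = coords[i, ATOM_CA, 2] - cz
        ssq += dx * dx + dy * dy + dz * dz
    rg = math.sqrt(ssq / l)

    n_off = 0
    nb = basins.shape[0]
    for i in range(l):
        inside = False
        for k in range(nb):
            dphi = abs(dihedrals_deg[i, 0] - basins[k, 0]) % 360.0
            if dphi > 180.0:
                dphi = 360.0 - dphi
            dpsi = abs(dihedrals_deg[i, 1] - basins[k, 1]) % 360.0
            if dpsi > 180.0:
                dpsi = 360.0 - dpsi
            if math.sqrt(dphi * dphi + dpsi * dpsi) <= basin_radius:
                inside = True
                break
        if not inside:
            n_off += 1
    return steric, hb_sr, hb_lr, rg, n_off
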