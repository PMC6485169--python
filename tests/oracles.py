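"""Independent reference implementations used only to cross-check the
package. Each oracle deliberately uses a different algorithm or formulation
than the code under test."""

import numpy as np
from scipy.spatial.transform import Rotation


# ---------------------------------------------------------------- geometry

def torsion_oracle(p0, p1, p2, p3):
    """Signed dihedral via the explicit cross-product ("praxeolitic")
    formulation: project b0 and b2 onto the plane normal to b1."""
    p0, p1, p2, p3 = map(np.asarray, (p0, p1, p2, p3))
    b0 = -(p1 - p0)
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return np.degrees(np.arctan2(y, x))


def trans_dipeptide_ca_ca(geom):
    """CA(i)-CA(i+1) distance for an omega = 180 peptide by explicit
    placement of the four in-plane atoms CA-C-N-CA using 2-D turtle
    geometry (independent of the package's internal-coordinate builder)."""
    import math
    pts = [np.zeros(2)]
    heading = 0.0
    for length, ang in ((geom.d_ca_c, geom.ang_ca_c_n),
                        (geom.d_c_n, geom.ang_c_n_ca),
                        (geom.d_n_ca, None)):
        pts.append(pts[-1] + length * np.array([math.cos(heading),
                                                math.sin(heading)]))
        if ang is not None:
            turn = math.pi - math.radians(ang)
            heading += turn if len(pts) % 2 == 0 else -turn
    # walk CA -> C (turn at C) -> N (turn at N) -> CA
    return float(np.linalg.norm(pts[-1] - pts[0]))


def rebuild_oracle(sequence, dihedrals_deg, geom):
    """Full from-scratch backbone re-placement using scipy Rotations: build
    each residue frame by explicit axis-angle composition instead of the
    package's closed-form frame construction. Returns only N/CA/C."""
    import math

    def place(a, b, c, r, theta, chi):
        bc = c - b
        bc = bc / np.linalg.norm(bc)
        n = np.cross(b - a, bc)
        n = n / np.linalg.norm(n)
        # start from the extension of b->c, bend by (pi - theta) about n,
        # then twist by chi about bc
        d = bc * r
        d = Rotation.from_rotvec(n * (math.pi - math.radians(theta))).apply(d)
        d = Rotation.from_rotvec(bc * math.radians(chi)).apply(d)
        return c + d

    l = len(sequence)
    geom_d = dict(d_n_ca=geom.d_n_ca, d_ca_c=geom.d_ca_c, d_c_n=geom.d_c_n)
    n = np.zeros((l, 3))
    ca = np.zeros((l, 3))
    c = np.zeros((l, 3))
    n[0] = (0.0, 0.0, 0.0)
    ca[0] = (geom_d["d_n_ca"], 0.0, 0.0)
    t = math.radians(geom.ang_n_ca_c)
    c[0] = ca[0] + geom_d["d_ca_c"] * np.array([-math.cos(t), math.sin(t), 0.0])
    for i in range(1, l):
        phi, _, _ = dihedrals_deg[i]
        _, psi_prev, omega_prev = dihedrals_deg[i - 1]
        n[i] = place(n[i - 1], ca[i - 1], c[i - 1], geom_d["d_c_n"],
                     geom.ang_ca_c_n, psi_prev)
        ca[i] = place(ca[i - 1], c[i - 1], n[i], geom_d["d_n_ca"],
                      geom.ang_c_n_ca, omega_prev)
        c[i] = place(c[i - 1], n[i], ca[i], geom_d["d_ca_c"],
                     geom.ang_n_ca_c, phi)
    return n, ca, c


# --------------------------------------------------------------- energetics

def energy_components_oracle(coords, dihedrals_deg, model):
    """Vectorized numpy recomputation of the raw score components (the
    package kernel is a scalar numba loop)."""
    ca = coords[:, 1, :]
    cen = coords[:, 4, :]
    o = coords[:, 3, :]
    nn = coords[:, 0, :]
    l = len(ca)
    idx = np.arange(l)
    sep = np.abs(idx[:, None] - idx[None, :])

    steric = 0.0
    for atoms in (ca, cen):
        d = np.linalg.norm(atoms[:, None, :] - atoms[None, :, :], axis=2)
        mask = np.triu(sep >= 2) & (d < model.r_clash)
        steric += float((((model.r_clash - d[mask]) / model.r_clash) ** 2).sum())

    d_on = np.linalg.norm(o[:, None, :] - nn[None, :, :], axis=2)
    window = (sep >= 3) & (d_on >= model.hb_min) & (d_on <= model.hb_max)
    pairs = sorted(zip(d_on[window], *np.nonzero(window)))
    used_o, used_n = set(), set()
    hb_sr = hb_lr = 0.0
    for d, i, j in pairs:
        if i in used_o or j in used_n:
            continue
        used_o.add(i)
        used_n.add(j)
        if abs(i - j) <= model.s_cut:
            hb_sr -= 1.0
        else:
            hb_lr -= 1.0

    rg = float(np.sqrt(((ca - ca.mean(0)) ** 2).sum(axis=1).mean()))

    basins = np.array([(-57.0, -47.0), (-120.0, 120.0), (60.0, 45.0)])
    n_off = 0
    for phi, psi, _ in dihedrals_deg:
        diff = np.abs(np.array([phi, psi]) - basins)
        diff = np.minimum(diff % 360.0, 360.0 - diff % 360.0)
        if not np.any(np.linalg.norm(diff, axis=1) <= model.basin_radius):
            n_off += 1
    return steric, hb_sr, hb_lr, rg, n_off


# ---------------------------------------------------------------- selection

def peel_fronts_oracle(mat):
    """Non-dominated fronts by literal repeated peeling (remove the
    non-dominated set, repeat)."""
    mat = np.asarray(mat, float)
    remaining = list(range(len(mat)))
    fronts = []
    while remaining:
        front = []
        for i in remaining:
            if not any(np.all(mat[j] < mat[i]) for j in remaining if j != i):
                front.append(i)
        fronts.append(tuple(front))
        remaining = [i for i in remaining if i not in front]
    return fronts


def pr_pc_oracle(mat):
    mat = np.asarray(mat, float)
    n = len(mat)
    pr = np.zeros(n, int)
    pc = np.zeros(n, int)
    for i in range(n):
        for j in range(n):
            if i != j and np.all(mat[j] < mat[i]):
                pr[i] += 1
            if i != j and np.all(mat[i] < mat[j]):
                pc[i] += 1
    return pr, pc


def crowding_oracle(mat):
    mat = np.asarray(mat, float)
    n, m = mat.shape
    dist = np.zeros(n)
    for k in range(m):
        order = np.argsort(mat[:, k], kind="stable")
        dist[order[0]] = dist[order[-1]] = np.inf
        span = mat[order[-1], k] - mat[order[0], k]
        for pos in range(1, n - 1):
            i = order[pos]
            if np.isinf(dist[i]) or span == 0:
                continue
            dist[i] += (mat[order[pos + 1], k] - mat[order[pos - 1], k]) / span
    return dist


def select_evo_diverse_oracle(mat, totals, n):
    """Straight-line reimplementation of the printed front + crowding rule;
    returns selected indices into the combined population."""
    fronts = peel_fronts_oracle(mat)
    chosen = []
    for front in fronts:
        if len(chosen) + len(front) <= n:
            chosen.extend(front)
            if len(chosen) == n:
                break
        else:
            sub = np.asarray(mat)[list(front)]
            dist = crowding_oracle(sub)
            order = sorted(range(len(front)), key=lambda i: (-dist[i], i))
            chosen.extend(front[i] for i in order[: n - len(chosen)])
            break
    return chosen


def select_mea_oracle(mat, totals, n):
    return sorted(range(len(totals)), key=lambda i: (totals[i], i))[:n]


def select_mea_pr_oracle(mat, totals, n):
    pr, _ = pr_pc_oracle(mat)
    return sorted(range(len(totals)), key=lambda i: (pr[i], totals[i], i))[:n]


def select_mea_prpc_oracle(mat, totals, n):
    pr, pc = pr_pc_oracle(mat)
    return sorted(range(len(totals)),
                  key=lambda i: (pr[i], -pc[i], totals[i], i))[:n]


# ------------------------------------------------------------------ metrics

def horn_superpose_rmsd(p, q):
    """Least RMSD by Horn's closed-form quaternion method (largest
    eigenvalue of the 4x4 cross-covariance matrix)."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    pc = p - p.mean(0)
    qc = q - q.mean(0)
    m = pc.T @ qc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = float((pc ** 2).sum() + (qc ** 2).sum())
    msd = max(0.0, (e0 - 2.0 * lam) / len(p))
    return float(np.sqrt(msd))


def _kabsch_np(p, q):
    pc, qc = p.mean(0), q.mean(0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, qc - rot @ pc


def tm_gdt_oracle(p, q):
    """Brute-force TM-score and GDT_TS over every seed window of lengths
    L, L/2, L/4, with the same within-cutoff refinement rule as the
    package but written independently."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    length = len(p)
    d0 = max(0.5, 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8) if length > 15 else 0.5

    def refine_track(cut, score_fn):
        best = 0.0
        windows = set()
        for wl in {max(4, min(w, length)) for w in (length, length // 2, length // 4)}:
            for s in range(length - wl + 1):
                windows.add((s, wl))
        for s, wl in sorted(windows):
            idx = list(range(s, s + wl))
            for _ in range(20):
                rot, tr = _kabsch_np(p[idx], q[idx])
                moved = p @ rot.T + tr
                d = np.linalg.norm(moved - q, axis=1)
                best = max(best, score_fn(d))
                new = [i for i in range(length) if d[i] <= cut]
                if len(new) < 3:
                    new = sorted(np.argsort(d, kind="stable")[:3])
                if new == idx:
                    break
                idx = new
        return best

    tm = refine_track(d0, lambda d: float(np.mean(1.0 / (1.0 + (d / d0) ** 2))))
    gdt = float(np.mean([refine_track(c, lambda d, c=c: float(np.mean(d <= c)))
                         for c in (1.0, 2.0, 4.0, 8.0)]))
    return tm, gdt
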