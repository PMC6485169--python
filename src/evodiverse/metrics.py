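"""Structure-comparison metrics against a known native structure.

CA least-RMSD via Kabsch superposition, TM-score and GDT_TS. TM and GDT
both maximize over rigid superpositions; since the global optimum is not
computable in closed form, both use the standard deterministic heuristic:
superpositions seeded from every contiguous CA window of lengths L, L/2 and
L/4, each refined by iteratively re-superposing on the residues that score
well under the current fit. No randomness is involved, so all metric values
are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)


def _ca(x) -> np.ndarray:
    """Accept a Conformation or an (L, 3) coordinate array."""
    if hasattr(x, "ca"):
        return np.asarray(x.ca, dtype=float)
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise InputError(f"expected (L, 3) coordinates, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid motion x -> rotation @ x + translation, with the
    resulting coordinate RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch(p, q) -> Superposition:
    """Least-RMSD rigid superposition of point set p onto q (SVD method).

    Returns the proper rotation (det +1, reflections excluded) and
    translation minimizing the coordinate RMSD.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise InputError(f"point sets differ in shape: {p.shape} vs {q.shape}")
    if p.ndim != 2 or p.shape[1] != 3 or len(p) < 3:
        raise InputError("need >= 3 three-dimensional points")
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = qc - rot @ pc
    diff = (p @ rot.T + trans) - q
    rmsd = float(np.sqrt((diff * diff).sum() / len(p)))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


def lrmsd_ca(model, native) -> float:
    """CA least-RMSD after optimal superposition; symmetric in arguments."""
    p = _ca(model)
    q = _ca(native)
    if p.shape != q.shape:
        raise InputError(f"length mismatch: {len(p)} vs {len(q)}")
    return kabsch(p, q).rmsd


def tm_d0(length: int) -> float:
    """TM-score distance scale; clamped at 0.5 A for short chains."""
    if length <= 15:
        return 0.5
    return max(0.5, 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8)


def _seed_windows(length: int):
    """Deterministic seed windows of lengths L, L/2 and L/4 (floor, min 4)."""
    seen = set()
    for wl in (length, length // 2, length // 4):
        wl = max(4, min(wl, length))
        for start in range(0, length - wl + 1):
            key = (start, wl)
            if key not in seen:
                seen.add(key)
                yield start, wl


def _searched_superpositions(p, q, include_cut, max_iter=20):
    """Yield candidate superpositions of p onto q.

    Each seed window gives an initial Kabsch fit which is refined by
    repeatedly re-superposing on the residues currently within
    ``include_cut`` Angstrom (at least the 3 closest residues are always
    kept), until the included set stabilizes.
    """
    length = len(p)
    for start, wl in _seed_windows(length):
        idx = np.arange(start, start + wl)
        for _ in range(max_iter):
            sup = kabsch(p[idx], q[idx])
            yield sup
            d = np.linalg.norm(sup.apply(p) - q, axis=1)
            new_idx = np.flatnonzero(d <= include_cut)
            if len(new_idx) < 3:
                new_idx = np.argsort(d, kind="stable")[:3]
                new_idx.sort()
            if np.array_equal(new_idx, idx):
                break
            idx = new_idx


def tm_score(model, native) -> float:
    """Template-modeling score in [0, 1]; 1 is a perfect match.

    TM = max over superpositions of (1/L) sum_i 1 / (1 + (d_i / d0)^2) with
    d0 = max(0.5, 1.24 (L - 15)^(1/3) - 1.8); the refinement re-superposes
    on residues within d0.
    """
    p = _ca(model)
    q = _ca(native)
    if p.shape != q.shape:
        raise InputError(f"length mismatch: {len(p)} vs {len(q)}")
    length = len(p)
    d0 = tm_d0(length)
    best = 0.0
    for sup in _searched_superpositions(p, q, include_cut=d0):
        d2 = ((sup.apply(p) - q) ** 2).sum(axis=1)
        best = max(best, float(np.mean(1.0 / (1.0 + d2 / d0 ** 2))))
    return best


def gdt_ts(model, native) -> float:
    """Global distance test (total score) in [0, 1].

    Mean over cutoffs 1, 2, 4, 8 A of the maximal fraction of CA atoms
    within the cutoff, each cutoff maximized independently over its own
    seeded search (refinement re-superposes on residues within the cutoff).
    """
    p = _ca(model)
    q = _ca(native)
    if p.shape != q.shape:
        raise InputError(f"length mismatch: {len(p)} vs {len(q)}")
    fractions = []
    for cut in GDT_CUTOFFS:
        best = 0.0
        for sup in _searched_superpositions(p, q, include_cut=cut):
            d = np.linalg.norm(sup.apply(p) - q, axis=1)
            best = max(best, float(np.mean(d <= cut)))
        fractions.append(best)
    return float(np.mean(fractions))
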