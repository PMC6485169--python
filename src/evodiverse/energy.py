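"""Staged coarse-grained scoring of centroid-level conformations.

Fragment-assembly protocols stage their search through increasingly
detailed scoring functions: a steric-only stage to randomize chains without
self-collisions, a stage that additionally rewards secondary structure, and
a stage that drives compaction, with the full score finally decomposed into
three optimization objectives (short-range hydrogen bonding, long-range
hydrogen bonding, everything else). This module provides minimal,
self-consistent analogs of those stages:

``steric``
    soft quadratic repulsion between CA-CA and CEN-CEN pairs closer than a
    clash radius (sequence separation >= 2), always >= 0;
``score1``
    steric plus a square-well backbone hydrogen-bond term: -1 a.u. for each
    realized O(i)...N(j) bond with |i - j| >= 3 whose distance falls inside
    a fixed window. There is no angular term, but donors and acceptors
    saturate (each backbone N donates at most one bond, each O accepts at
    most one; candidates are matched greedily by distance) — without
    saturation the well's optimum is a maximally dense collapsed blob
    rather than any hydrogen-bond network a backbone can realize;
``score3``
    score1 plus a compactness penalty w_rg * max(0, Rg - Rg0(l))^2 with
    Rg0(l) = 2.2 * l^0.38 Angstrom, the empirical radius-of-gyration scaling
    of globular chains (compaction enters the search only at this stage);
``objectives``
    the three-way decomposition whose components sum to the total energy:
    hydrogen bonds split at a sequence-separation cutoff into short- and
    long-range objectives, and a third objective collecting steric,
    compactness and a torsion-preference penalty for residues outside the
    canonical Ramachandran basins.

All values are in arbitrary units (a.u.): the analogs preserve the role of
each stage, not any particular force field's numbers, and every comparison
made with them is internal. Every scoring call of any stage counts as one
energy evaluation against the sampling budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import BudgetExhausted, InputError
from .fragments import RAMACHANDRAN_BASINS

_BASINS = np.asarray(RAMACHANDRAN_BASINS)


@dataclass(frozen=True)
class ObjectiveVector:
    """The three optimization objectives; their sum is the total energy."""

    e_sr_hb: float
    e_lr_hb: float
    e_other: float

    def __post_init__(self):
        if not all(math.isfinite(v) for v in self.as_tuple()):
            raise InputError("objective components must be finite")

    def as_tuple(self):
        return (self.e_sr_hb, self.e_lr_hb, self.e_other)

    def as_array(self) -> np.ndarray:
        return np.array(self.as_tuple())

    @property
    def total(self) -> float:
        return self.e_sr_hb + self.e_lr_hb + self.e_other


class ScoreModel:
    """Weights, cutoffs and the evaluation counter for all score stages.

    Parameters
    ----------
    w_steric, w_hb, w_rg, w_torsion:
        non-negative stage weights (a.u.). ``w_rg`` upweights compaction
        relative to the earlier stages (score0/score1 carry no compactness
        term at all); its default is calibrated so that the compactness
        penalty dominates for genuinely stretched-out chains yet does not
        overwhelm the hydrogen-bond reward near the target radius — with a
        much larger value the score3 optimum is a collapsed bundle rather
        than any native-like topology.
    r_clash:
        clash radius in Angstrom for the steric term.
    hb_min, hb_max:
        O...N distance window (Angstrom) of the hydrogen-bond well.
    s_cut:
        sequence-separation cutoff splitting short-range from long-range
        hydrogen bonds; the default 4 keeps helical i,i+3 / i,i+4 bonds
        short-range.
    basin_radius:
        radius (degrees) around each canonical (phi, psi) basin center
        inside which a residue pays no torsion penalty.
    max_evaluations:
        optional hard cap; a scoring call past the cap raises
        :class:`BudgetExhausted` (used by the engine's budget guard).
    """

    def __init__(self, w_steric=1.0, w_hb=1.0, w_rg=0.3, w_torsion=0.1,
                 r_clash=4.0, hb_min=2.6, hb_max=3.4, s_cut=4,
                 rg_coeff=2.2, rg_exp=0.38, basin_radius=30.0,
                 max_evaluations=None):
        for name, v in (("w_steric", w_steric), ("w_hb", w_hb),
                        ("w_rg", w_rg), ("w_torsion", w_torsion)):
            if v < 0:
                raise InputError(f"{name} must be non-negative, got {v}")
        if not 0 < hb_min < hb_max:
            raise InputError("hydrogen-bond window must satisfy 0 < min < max")
        if r_clash <= 0:
            raise InputError("clash radius must be positive")
        self.w_steric = float(w_steric)
        self.w_hb = float(w_hb)
        self.w_rg = float(w_rg)
        self.w_torsion = float(w_torsion)
        self.r_clash = float(r_clash)
        self.hb_min = float(hb_min)
        self.hb_max = float(hb_max)
        self.s_cut = int(s_cut)
        self.rg_coeff = float(rg_coeff)
        self.rg_exp = float(rg_exp)
        self.basin_radius = float(basin_radius)
        self.max_evaluations = max_evaluations
        self._count = 0

    @classmethod
    def from_config(cls, cfg: dict) -> "ScoreModel":
        """Build from the ``energy:`` section of a YAML run configuration."""
        return cls(**cfg)

    def params(self) -> dict:
        return {k: getattr(self, k) for k in (
            "w_steric", "w_hb", "w_rg", "w_torsion", "r_clash", "hb_min",
            "hb_max", "s_cut", "rg_coeff", "rg_exp", "basin_radius")}

    @property
    def evaluations(self) -> int:
        """Scoring calls (any stage) since construction; non-decreasing."""
        return self._count

    def rg0(self, l: int) -> float:
        """Target radius of gyration for a compact chain of length l."""
        return self.rg_coeff * l ** self.rg_exp

    def _components(self, conformation):
        if self.max_evaluations is not None and self._count >= self.max_evaluations:
            raise BudgetExhausted(
                f"evaluation budget of {self.max_evaluations} exhausted")
        self._count += 1
        return _kernels.energy_components(
            conformation.coords, conformation.dihedrals, self.r_clash,
            self.hb_min, self.hb_max, self.s_cut, _BASINS, self.basin_radius)

    def steric(self, conformation) -> float:
        """Unweighted soft steric repulsion (score0 stage); >= 0."""
        st, *_ = self._components(conformation)
        return st

    def score1(self, conformation) -> float:
        """Steric plus hydrogen-bond well (secondary-structure stage)."""
        st, hb_sr, hb_lr, _, _ = self._components(conformation)
        return self.w_steric * st + self.w_hb * (hb_sr + hb_lr)

    def score3(self, conformation) -> float:
        """score1 terms plus the (upweighted) compactness penalty."""
        st, hb_sr, hb_lr, rg, _ = self._components(conformation)
        return (self.w_steric * st + self.w_hb * (hb_sr + hb_lr)
                + self.w_rg * self._rg_penalty(rg, len(conformation)))

    def objectives(self, conformation) -> ObjectiveVector:
        """Three-objective decomposition of the full score."""
        st, hb_sr, hb_lr, rg, n_off = self._components(conformation)
        e_other = (self.w_steric * st
                   + self.w_rg * self._rg_penalty(rg, len(conformation))
                   + self.w_torsion * n_off)
        return ObjectiveVector(self.w_hb * hb_sr, self.w_hb * hb_lr, e_other)

    def _rg_penalty(self, rg, l):
        excess = rg - self.rg0(l)
        return excess * excess if excess > 0 else 0.0


def evaluations(model: ScoreModel) -> int:
    """Evaluation count of a model (functional accessor)."""
    return model.evaluations
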