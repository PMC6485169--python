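"""Synthetic toy targets so every pipeline stage runs with no external data.

Each target carries a sequence, a native conformation built from canonical
secondary-structure dihedrals, and a topology tag. Together with the
synthetic fragment libraries of :mod:`evodiverse.fragments` this gives a
fully self-contained, desk-scale stand-in for real benchmark proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import Conformation
from .errors import InputError

HELIX = (-57.0, -47.0)
STRAND = (-120.0, 120.0)

#: Four-residue chain-reversal turn used by the hairpin topology
#: ((phi, psi) per turn residue); tuned once so the two strand arms run
#: antiparallel and within pairing distance after rebuild.
TURN = ((135.5, 85.9), (-80.0, -38.9), (-128.3, -90.5), (-52.5, -66.3))

MIN_LENGTH = 12


@dataclass(frozen=True)
class ToyTarget:
    """A named synthetic target: sequence, native structure, topology."""

    name: str
    sequence: str
    native: Conformation
    topology: str

    def __post_init__(self):
        if len(self.native) != len(self.sequence):
            raise InputError("native length does not match sequence")


def _phi_psi_blocks(topology: str, length: int):
    if topology == "helix":
        return [HELIX] * length
    if topology == "hairpin":
        arm = (length - len(TURN)) // 2
        rest = length - len(TURN) - arm
        return [STRAND] * arm + list(TURN) + [STRAND] * rest
    if topology == "mixed":
        # Alternating helix/strand blocks joined by turns.
        blocks = []
        helix_len = max(8, length // 3)
        blocks += [HELIX] * helix_len
        blocks += list(TURN)
        arm = (length - len(blocks) - len(TURN)) // 2
        blocks += [STRAND] * arm
        blocks += list(TURN)
        blocks += [STRAND] * (length - len(blocks))
        return blocks[:length]
    raise InputError(f"unknown topology {topology!r}; "
                     f"expected helix | hairpin | mixed")


_TOPOLOGY_RESIDUE = {"helix": "A", "hairpin": "V", "mixed": "L"}


def make_toy_native(topology: str, length: int, rng=None) -> ToyTarget:
    """Build a deterministic toy target of the given topology and length.

    helix: every residue at the canonical alpha basin (-57, -47, 180);
    hairpin: two antiparallel strand arms joined by a 4-residue turn;
    mixed: helix and strand blocks joined by turns. ``rng`` is accepted for
    interface symmetry but the construction is deterministic.
    """
    if length < MIN_LENGTH:
        raise InputError(f"toy targets need length >= {MIN_LENGTH}, got {length}")
    phi_psi = _phi_psi_blocks(topology, length)
    dih = np.array([[p, s, 180.0] for p, s in phi_psi])
    sequence = _TOPOLOGY_RESIDUE[topology] * length
    native = Conformation(sequence, dih)
    return ToyTarget(name=f"{topology}-{length}", sequence=sequence,
                     native=native, topology=topology)


def default_suite():
    """The fixed desk-scale target panel: helix-20, helix-30, hairpin-24,
    mixed-40; identical contents on every call."""
    return [
        make_toy_native("helix", 20),
        make_toy_native("helix", 30),
        make_toy_native("hairpin", 24),
        make_toy_native("mixed", 40),
    ]
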