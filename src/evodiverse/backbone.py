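"""Dihedral-space backbone representation and PDB/FASTA I/O.

A conformation is parameterized by per-residue backbone dihedrals
(phi, psi, omega); Cartesian coordinates of the reduced-atom chain
(N, CA, C, O and a single side-chain centroid CEN per residue) are a pure,
deterministic function of the dihedrals and a fixed ideal geometry. The
first residue is anchored in a canonical frame so rebuilds are reproducible
and all downstream scoring is rigid-motion invariant by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa

from . import _kernels
from .errors import FormatError, InputError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}

ATOM_NAMES = ("N", "CA", "C", "O", "CEN")


def normalize_angle(angle):
    """Map an angle in degrees to the half-open interval (-180, 180]."""
    return np.mod(np.asarray(angle, dtype=float) - 180.0, -360.0) + 180.0


@dataclass(frozen=True)
class BackboneGeometry:
    """Ideal trans-peptide geometry constants.

    Bond lengths in Angstrom, bond angles in degrees. The centroid CEN is a
    single pseudo-atom placed off the N-CA bond in the side-chain (CB)
    direction, independent of residue identity.
    """

    d_n_ca: float = 1.458
    d_ca_c: float = 1.525
    d_c_n: float = 1.329
    d_c_o: float = 1.231
    d_ca_cen: float = 1.53
    ang_n_ca_c: float = 111.2
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.8
    ang_n_ca_cen: float = 110.5
    torsion_cen: float = -122.6
    omega_default: float = 180.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.startswith("d_") and not v > 0:
                raise InputError(f"bond length {f.name} must be positive, got {v}")
            if f.name.startswith("ang_") and not 0 < v < 180:
                raise InputError(f"bond angle {f.name} must lie in (0, 180), got {v}")

    def as_array(self) -> np.ndarray:
        """Parameter vector consumed by the rebuild kernel (angles in rad)."""
        r = math.radians
        return np.array([
            self.d_n_ca, self.d_ca_c, self.d_c_n, self.d_c_o, self.d_ca_cen,
            r(self.ang_n_ca_c), r(self.ang_ca_c_n), r(self.ang_c_n_ca),
            r(self.ang_ca_c_o), r(self.ang_n_ca_cen), r(self.torsion_cen),
        ])

    def ca_ca_distance(self) -> float:
        """Consecutive CA-CA distance implied by the constants for a trans
        (omega = 180) peptide, from planar trigonometry of the CA-C-N-CA
        unit."""
        a = self.d_ca_c
        b = self.d_c_n
        c = self.d_n_ca
        t1 = math.pi - math.radians(self.ang_ca_c_n)
        t2 = math.pi - math.radians(self.ang_c_n_ca)
        # Walk CA -> C -> N -> CA in the peptide plane (omega = 180 keeps all
        # four atoms coplanar with the turn directions alternating).
        x = a + b * math.cos(t1) + c * math.cos(t1 - t2)
        y = b * math.sin(t1) + c * math.sin(t1 - t2)
        return math.hypot(x, y)


DEFAULT_GEOMETRY = BackboneGeometry()


class Conformation:
    """A protein chain state: sequence + (phi, psi, omega) per residue.

    Coordinates are rebuilt eagerly and deterministically on construction;
    instances are treated as immutable (all move operators return new
    objects). ``dihedrals`` is an (l, 3) float array in degrees, normalized
    to (-180, 180]. ``coords`` is (l, 5, 3) in Angstrom, atoms ordered
    N, CA, C, O, CEN.
    """

    __slots__ = ("sequence", "dihedrals", "coords", "geometry")

    def __init__(self, sequence, dihedrals, geometry=DEFAULT_GEOMETRY):
        if not sequence:
            raise InputError("sequence must be non-empty")
        bad = set(sequence) - set(AMINO_ACIDS)
        if bad:
            raise InputError(f"invalid amino-acid letter(s): {sorted(bad)}")
        dihedrals = np.array(dihedrals, dtype=float)
        if dihedrals.shape != (len(sequence), 3):
            raise InputError(
                f"dihedrals shape {dihedrals.shape} does not match "
                f"sequence length {len(sequence)}")
        if not np.all(np.isfinite(dihedrals)):
            raise InputError("dihedrals must be finite")
        self.sequence = sequence
        self.dihedrals = normalize_angle(dihedrals)
        self.dihedrals.flags.writeable = False
        self.geometry = geometry
        self.coords = _kernels.rebuild_chain(
            np.radians(self.dihedrals), geometry.as_array())
        self.coords.flags.writeable = False

    @classmethod
    def _fast(cls, sequence, dihedrals_normalized, geometry):
        """Internal constructor skipping validation (hot path of the move
        operators; dihedrals must already be normalized)."""
        obj = object.__new__(cls)
        obj.sequence = sequence
        obj.dihedrals = dihedrals_normalized
        obj.dihedrals.flags.writeable = False
        obj.geometry = geometry
        obj.coords = _kernels.rebuild_chain(
            np.radians(dihedrals_normalized), geometry.as_array())
        obj.coords.flags.writeable = False
        return obj

    def __len__(self):
        return len(self.sequence)

    def __repr__(self):
        return f"<Conformation l={len(self)} seq={self.sequence[:8]}...>"

    @property
    def ca(self) -> np.ndarray:
        """(l, 3) CA trace."""
        return self.coords[:, _kernels.ATOM_CA, :]

    def with_dihedrals(self, start: int, block: np.ndarray) -> "Conformation":
        """Return a copy with residues start..start+f-1 (1-based) replaced
        by ``block`` ((f, 3), degrees)."""
        block = np.asarray(block, dtype=float)
        f = block.shape[0]
        if not 1 <= start <= len(self) - f + 1:
            raise InputError(
                f"fragment start {start} outside [1, {len(self) - f + 1}]")
        dih = np.array(self.dihedrals)
        dih[start - 1:start - 1 + f] = normalize_angle(block)
        return Conformation._fast(self.sequence, dih, self.geometry)


def build_extended(sequence, geometry=DEFAULT_GEOMETRY) -> Conformation:
    """Fully extended chain: every (phi, psi, omega) set to 180 degrees."""
    dih = np.full((len(sequence) if sequence else 0, 3), 180.0)
    return Conformation(sequence, dih, geometry)


def rebuild_coordinates(conformation, geometry=None) -> np.ndarray:
    """Recompute coordinates from a conformation's dihedrals.

    Pure and idempotent; with ``geometry`` given, the conformation's own
    constants are overridden for this rebuild only.
    """
    geom = geometry if geometry is not None else conformation.geometry
    return _kernels.rebuild_chain(
        np.radians(conformation.dihedrals), geom.as_array())


def torsion(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) of four points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    y = np.dot(np.cross(n1, n2), b1 / np.linalg.norm(b1))
    ang = math.degrees(math.atan2(y, np.dot(n1, n2)))
    return float(normalize_angle(ang))


def dihedrals_from_coordinates(n, ca, c) -> np.ndarray:
    """Back-compute (phi, psi, omega) from backbone N/CA/C coordinates.

    Terminal angles that are undefined (phi of residue 1, psi/omega of the
    last residue) are set to 180.
    """
    l = len(ca)
    dih = np.full((l, 3), 180.0)
    for i in range(l):
        if i > 0:
            dih[i, 0] = torsion(c[i - 1], n[i], ca[i], c[i])
        if i < l - 1:
            dih[i, 1] = torsion(n[i], ca[i], c[i], n[i + 1])
            dih[i, 2] = torsion(ca[i], c[i], n[i + 1], ca[i + 1])
    return dih


def read_fasta(path):
    """First record of a FASTA file -> (sequence, description)."""
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            raise FormatError(f"non-standard letters in FASTA: {sorted(bad)}")
        return seq, rec.description
    raise FormatError(f"no FASTA records in {path}")


def read_pdb(path, geometry=DEFAULT_GEOMETRY) -> Conformation:
    """Read the first model/chain of a PDB file into a Conformation.

    The sequence and backbone dihedrals are extracted; coordinates are then
    rebuilt in the canonical frame, so the round trip preserves dihedrals
    (not the absolute frame of the input file).
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("x", str(path))
    try:
        model = next(iter(structure))
        chain = next(iter(model))
    except StopIteration:
        raise FormatError(f"no chains in {path}") from None
    seq = []
    n_xyz, ca_xyz, c_xyz = [], [], []
    for res in chain:
        if not is_aa(res, standard=False):
            continue
        resname = res.get_resname().strip()
        one = _THREE_TO_ONE.get(resname)
        if one is None:
            raise FormatError(f"unsupported residue {resname} {res.id[1]}")
        for atom in ("N", "CA", "C"):
            if atom not in res:
                raise FormatError(
                    f"residue {resname} {res.id[1]} is missing backbone "
                    f"atom {atom}")
        seq.append(one)
        n_xyz.append(res["N"].coord)
        ca_xyz.append(res["CA"].coord)
        c_xyz.append(res["C"].coord)
    if not seq:
        raise FormatError(f"no amino-acid residues in {path}")
    n_xyz = np.array(n_xyz, dtype=float)
    ca_xyz = np.array(ca_xyz, dtype=float)
    c_xyz = np.array(c_xyz, dtype=float)
    # A broken chain (missing residue) shows up as an impossible peptide bond.
    for i in range(len(seq) - 1):
        d = np.linalg.norm(n_xyz[i + 1] - c_xyz[i])
        if d > 2.0:
            raise FormatError(
                f"chain break between residues {i + 1} and {i + 2}: "
                f"C-N distance {d:.2f} A")
    dih = dihedrals_from_coordinates(n_xyz, ca_xyz, c_xyz)
    return Conformation("".join(seq), dih, geometry)


def write_pdb(conformations, path):
    """Write one or more conformations as a multi-MODEL PDB file.

    Standard fixed-column ATOM records for N, CA, C, O and the CEN
    pseudo-atom; occupancy 1.00, B-factor 0.00.
    """
    if isinstance(conformations, Conformation):
        conformations = [conformations]
    conformations = list(conformations)
    if not conformations:
        raise InputError("write_pdb requires at least one conformation")
    with open(path, "w") as fh:
        for m, conf in enumerate(conformations, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            serial = 1
            for i, aa in enumerate(conf.sequence):
                resname = _ONE_TO_THREE[aa]
                for a, atom in enumerate(ATOM_NAMES):
                    x, y, z = conf.coords[i, a]
                    name = f" {atom:<3s}" if len(atom) < 4 else atom
                    element = atom[0] if atom != "CEN" else "C"
                    fh.write(
                        f"ATOM  {serial:5d} {name}{'':1s}{resname:>3s} A"
                        f"{i + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n")
                    serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")
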