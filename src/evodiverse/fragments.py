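"""Fragment libraries and fragment-replacement moves.

A fragment library maps every 1-based start position i in [1, l-f+1] to a
list of up to 200 torsion-triple configurations of length f (3 or 9). A
move overwrites the 3*f dihedrals of a window with one configuration drawn
uniformly at random. Libraries are stored in a simple columnar text format
(one header line ``position entry-index`` followed by f ``phi psi omega``
lines per configuration) so test fixtures can be authored and diffed by
hand; synthetic libraries mixing near-native configurations with canonical
Ramachandran-basin decoys replace server-built ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import Conformation, normalize_angle
from .errors import FormatError, InputError

MAX_CONFIGS_PER_POSITION = 200

#: Canonical (phi, psi) basin centers: alpha helix, beta strand, left-handed.
RAMACHANDRAN_BASINS = ((-57.0, -47.0), (-120.0, 120.0), (60.0, 45.0))


@dataclass
class FragmentLibrary:
    """Per-position fragment configurations.

    ``entries[i]`` is an (n_i, f, 3) array of dihedral triples in degrees for
    the window starting at 1-based residue i.
    """

    f: int
    entries: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.f not in (3, 9):
            raise InputError(f"fragment length must be 3 or 9, got {self.f}")
        self.validate()

    def validate(self):
        if not self.entries:
            raise InputError("fragment library has no positions")
        positions = sorted(self.entries)
        if positions[0] != 1 or positions != list(range(1, len(positions) + 1)):
            raise InputError(
                f"library positions must cover [1, l-f+1] contiguously; "
                f"got {positions[:5]}...")
        for pos, cfgs in self.entries.items():
            cfgs = np.asarray(cfgs, dtype=float)
            if cfgs.ndim != 3 or cfgs.shape[1:] != (self.f, 3):
                raise InputError(
                    f"position {pos}: configurations must be (n, {self.f}, 3)")
            if len(cfgs) == 0:
                raise InputError(f"position {pos} has no configurations")
            if len(cfgs) > MAX_CONFIGS_PER_POSITION:
                raise InputError(
                    f"position {pos} has {len(cfgs)} configurations "
                    f"(limit {MAX_CONFIGS_PER_POSITION})")
            self.entries[pos] = normalize_angle(cfgs)

    @property
    def n_positions(self) -> int:
        return len(self.entries)

    @property
    def chain_length(self) -> int:
        """Chain length l implied by the covered interval [1, l-f+1]."""
        return self.n_positions + self.f - 1

    def __eq__(self, other):
        if not isinstance(other, FragmentLibrary) or self.f != other.f:
            return NotImplemented if not isinstance(other, FragmentLibrary) else False
        return (self.entries.keys() == other.entries.keys()
                and all(np.array_equal(self.entries[k], other.entries[k])
                        for k in self.entries))


def load_library(path, f) -> FragmentLibrary:
    """Parse a columnar text fragment file (format documented above)."""
    entries = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_lines = len(lines)

    def err(lineno, msg):
        raise FormatError(f"{path}:{lineno}: {msg}")

    while i < n_lines:
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            err(i, f"expected 'position entry-index' header, got {line!r}")
        try:
            pos, idx = int(parts[0]), int(parts[1])
        except ValueError:
            err(i, f"non-integer header fields in {line!r}")
        if pos < 1:
            err(i, f"positions are 1-based; got {pos}")
        triples = np.empty((f, 3))
        for k in range(f):
            if i >= n_lines:
                err(n_lines, f"truncated configuration at position {pos}")
            row = lines[i].strip().split()
            i += 1
            if len(row) != 3:
                err(i, f"expected 'phi psi omega', got {lines[i - 1].rstrip()!r}")
            try:
                triples[k] = [float(v) for v in row]
            except ValueError:
                err(i, f"malformed angle in {lines[i - 1].rstrip()!r}")
            if not np.all(np.isfinite(triples[k])):
                err(i, "non-finite angle")
        entries.setdefault(pos, []).append(triples)
        if len(entries[pos]) > MAX_CONFIGS_PER_POSITION:
            err(i, f"more than {MAX_CONFIGS_PER_POSITION} configurations "
                   f"at position {pos}")
    if not entries:
        raise FormatError(f"{path}: no fragment configurations found")
    positions = sorted(entries)
    expected = list(range(1, len(positions) + 1))
    if positions != expected:
        missing = sorted(set(expected) - set(positions))
        raise FormatError(f"{path}: position gap; missing {missing[:5]}")
    entries = {p: np.stack(entries[p]) for p in positions}
    return FragmentLibrary(f=f, entries=entries)


def save_library(library: FragmentLibrary, path):
    """Inverse of :func:`load_library`."""
    with open(path, "w") as fh:
        fh.write(f"# fragment library f={library.f}\n")
        for pos in sorted(library.entries):
            for idx, cfg in enumerate(library.entries[pos], start=1):
                fh.write(f"{pos} {idx}\n")
                for phi, psi, omega in cfg:
                    # repr round-trips the float exactly
                    fh.write(f"{float(phi)!r} {float(psi)!r} {float(omega)!r}\n")


def sample_move(conformation: Conformation, library: FragmentLibrary, rng):
    """Draw a fragment-replacement move: a start position uniform on
    [1, l-f+1] and a configuration uniform over the entries at that
    position. The conformation is not modified."""
    l = len(conformation)
    f = library.f
    if l < f:
        raise InputError(f"chain length {l} shorter than fragment length {f}")
    n_pos = l - f + 1
    if library.n_positions < n_pos:
        raise InputError(
            f"library covers {library.n_positions} positions but the chain "
            f"needs {n_pos}")
    start = int(rng.integers(1, n_pos + 1))
    cfgs = library.entries[start]
    config = cfgs[int(rng.integers(len(cfgs)))]
    return start, config


def apply_move(conformation: Conformation, start: int, config) -> Conformation:
    """Replace the dihedrals of the window starting at ``start`` (1-based)
    with ``config``; returns a new conformation with rebuilt coordinates."""
    return conformation.with_dihedrals(start, config)


def make_synthetic_library(native: Conformation, f, n_per_pos=MAX_CONFIGS_PER_POSITION,
                           near_fraction=0.3, noise_deg=10.0, rng=None) -> FragmentLibrary:
    """Generate a library mixing near-native windows with basin decoys.

    At each position, ceil(near_fraction * n_per_pos) configurations are the
    native window's torsions plus Gaussian noise of sd ``noise_deg``; the
    remainder draw each residue's (phi, psi) from one of the canonical
    Ramachandran basins (helix, strand, left-handed) with the same noise, and
    omega = 180 +/- noise (peptide bonds stay near-trans).
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 0 <= near_fraction <= 1:
        raise InputError(f"near_fraction must be in [0, 1], got {near_fraction}")
    if not 1 <= n_per_pos <= MAX_CONFIGS_PER_POSITION:
        raise InputError(
            f"n_per_pos must be in [1, {MAX_CONFIGS_PER_POSITION}], "
            f"got {n_per_pos}")
    l = len(native)
    if l < f:
        raise InputError(f"native length {l} shorter than fragment length {f}")
    n_near = int(np.ceil(near_fraction * n_per_pos))
    basins = np.asarray(RAMACHANDRAN_BASINS)
    entries = {}
    for pos in range(1, l - f + 2):
        window = native.dihedrals[pos - 1:pos - 1 + f]
        cfgs = np.empty((n_per_pos, f, 3))
        if n_near:
            cfgs[:n_near] = window[None, :, :] + rng.normal(
                0.0, noise_deg, size=(n_near, f, 3))
        n_decoy = n_per_pos - n_near
        if n_decoy:
            which = rng.integers(len(basins), size=(n_decoy, f))
            block = np.empty((n_decoy, f, 3))
            block[:, :, :2] = basins[which]
            block[:, :, 2] = 180.0 + rng.normal(0.0, noise_deg,
                                                size=(n_decoy, f))
            cfgs[n_near:] = block
        entries[pos] = normalize_angle(cfgs)
    return FragmentLibrary(f=f, entries=entries)
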