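import numpy as np
import pytest

import evodiverse as ev


@pytest.fixture(scope="session")
def helix12():
    return ev.Conformation("A" * 12, np.tile([-57.0, -47.0, 180.0], (12, 1)))


@pytest.fixture(scope="session")
def helix30_target():
    return ev.make_toy_native("helix", 30)


@pytest.fixture(scope="session")
def toy_libs(helix30_target):
    """Synthetic f=9 / f=3 libraries for the 30-residue helix target at the
    standard desk-scale conditions (30% near-native, 10 degree noise)."""
    rng = np.random.default_rng(12345)
    lib9 = ev.make_synthetic_library(helix30_target.native, 9,
                                     near_fraction=0.3, noise_deg=10.0, rng=rng)
    lib3 = ev.make_synthetic_library(helix30_target.native, 3,
                                     near_fraction=0.3, noise_deg=10.0, rng=rng)
    return lib9, lib3


@pytest.fixture(scope="session")
def small_libs(helix12):
    """Tiny libraries for a 12-residue chain (fast operator tests)."""
    rng = np.random.default_rng(99)
    lib9 = ev.make_synthetic_library(helix12, 9, n_per_pos=20,
                                     near_fraction=0.5, noise_deg=15.0, rng=rng)
    lib3 = ev.make_synthetic_library(helix12, 3, n_per_pos=20,
                                     near_fraction=0.5, noise_deg=15.0, rng=rng)
    return lib9, lib3


def identity_library(conformation, f):
    """Library whose only configuration at each position is the
    conformation's own local torsions (every move is a no-op)."""
    entries = {pos: conformation.dihedrals[pos - 1:pos - 1 + f][None, :, :].copy()
               for pos in range(1, len(conformation) - f + 2)}
    return ev.FragmentLibrary(f=f, entries=entries)
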