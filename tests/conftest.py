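"""Shared fixtures: toy structures, contact maps and assembled systems.

Session-scoped where construction is deterministic and read-only, so the
numba kernels are compiled and fixtures built once per test run.
"""

import numpy as np
import pytest

from gofold import (
    GoParameters,
    GoSystem,
    build_native_contacts,
    desk_parameters,
    make_hairpin,
    make_mini_trna,
)
from gofold.constants import ATOMIC_MASSES
from gofold.structures import AtomRecord, NativeStructure, ResidueSpec


@pytest.fixture(scope="session")
def hairpin():
    structure, partition = make_hairpin(4, 4, seed=0)
    cmap = build_native_contacts(structure)
    return structure, partition, cmap


@pytest.fixture(scope="session")
def mini_trna():
    structure, partition = make_mini_trna(3, seed=0)
    cmap = build_native_contacts(structure)
    return structure, partition, cmap


@pytest.fixture(scope="session")
def hairpin_system(hairpin):
    structure, _, cmap = hairpin
    return GoSystem(structure, cmap, desk_parameters())


@pytest.fixture(scope="session")
def mini_system(mini_trna):
    structure, _, cmap = mini_trna
    return GoSystem(structure, cmap, desk_parameters())


def toy_structure(positions, residue_of_atom, bonds=(), names=None,
                  bases=None):
    """Hand-built NativeStructure for unit tests (bonds given, not inferred)."""
    positions = np.asarray(positions, dtype=float)
    n_res = max(residue_of_atom)
    residues = [ResidueSpec(index=r, base=(bases or {}).get(r, "A"))
                for r in range(1, n_res + 1)]
    for k, (pos, r) in enumerate(zip(positions, residue_of_atom), start=1):
        name = (names or {}).get(k, "P")
        element = next(ch for ch in name if ch.isalpha()).upper()
        residues[r - 1].atoms.append(
            AtomRecord(k, name, element, ATOMIC_MASSES[element], r, pos)
        )
    return NativeStructure(
        residues=residues,
        bonds={(min(i, j), max(i, j)) for i, j in bonds},
    )
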