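"""Native contact map extraction.

A native contact is a pair of heavy atoms within ``cutoff`` (default 4 Å) of
each other in the folded reference structure, excluding covalently coupled
pairs (1-2 and 1-3 neighbours) and, by default, pairs within the same residue.
Each contact stores its native distance σ_ij, the length scale of the
attractive well in the structure-based potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import NativeStructure

__all__ = [
    "ContactPair",
    "ContactMap",
    "build_exclusions",
    "build_native_contacts",
    "write_contact_tsv",
    "read_contact_tsv",
]


@dataclass(frozen=True)
class ContactPair:
    """One native atom pair (1-based indices, i < j) with native distance σ."""

    i: int
    j: int
    sigma: float
    residue_pair: tuple[int, int]


@dataclass
class ContactMap:
    """Ordered native contacts plus the non-bonded exclusion set."""

    contacts: list[ContactPair]
    exclusions: set[tuple[int, int]]
    cutoff: float
    # vectorised views (0-based) kept in sync with `contacts`
    i_idx: np.ndarray = field(default=None, repr=False)
    j_idx: np.ndarray = field(default=None, repr=False)
    sigma: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.i_idx is None:
            self.i_idx = np.array([c.i - 1 for c in self.contacts], dtype=np.int64)
            self.j_idx = np.array([c.j - 1 for c in self.contacts], dtype=np.int64)
            self.sigma = np.array([c.sigma for c in self.contacts], dtype=float)

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    def pairs(self) -> set[tuple[int, int]]:
        return {(c.i, c.j) for c in self.contacts}

    def residue_pairs(self) -> list[tuple[int, int]]:
        return [c.residue_pair for c in self.contacts]


def build_exclusions(structure: NativeStructure) -> set[tuple[int, int]]:
    """All atom pairs separated by one or two covalent bonds (1-2 and 1-3).

    1-4 pairs are deliberately retained as non-bonded: their geometry is
    governed by the dihedral terms.
    """
    adj = structure.adjacency()
    excl: set[tuple[int, int]] = set()
    for i, neighbours in adj.items():
        for j in neighbours:
            if i < j:
                excl.add((i, j))
            for k in adj[j]:
                if k != i and i < k:
                    excl.add((i, k))
                elif k != i and k < i:
                    excl.add((k, i))
    return excl


def build_native_contacts(
    structure: NativeStructure,
    cutoff: float = 4.0,
    exclusions: set[tuple[int, int]] | None = None,
    min_residue_separation: int = 3,
) -> ContactMap:
    """Extract the native contact map from the folded structure.

    Parameters
    ----------
    cutoff
        Heavy-atom distance cutoff in Å (default 4.0).
    exclusions
        Bonded 1-2/1-3 pairs to drop; computed from the bond graph when None.
    min_residue_separation
        Keep only pairs whose residues are at least this far apart in
        sequence.  0 counts every non-excluded pair (including intra-residue
        ones), 1 drops intra-residue pairs, and the default 2 also drops
        nearest-neighbour pairs: with bonded geometry restrained to the
        native structure those are formed in every conformation, which would
        make the Q = 0 unfolded reference unreachable.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if structure.n_atoms < 2:
        raise ValueError("structure must contain at least 2 atoms")
    if exclusions is None:
        exclusions = build_exclusions(structure)

    coords = structure.coordinates()
    res_of = structure.residue_of_atom()
    tree = cKDTree(coords)
    candidate = tree.query_pairs(r=cutoff, output_type="ndarray")  # 0-based, i<j

    contacts: list[ContactPair] = []
    for a, b in candidate:
        i, j = int(a) + 1, int(b) + 1
        if (i, j) in exclusions:
            continue
        if abs(int(res_of[a]) - int(res_of[b])) < min_residue_separation:
            continue
        sigma = float(np.linalg.norm(coords[a] - coords[b]))
        contacts.append(
            ContactPair(i=i, j=j, sigma=sigma,
                        residue_pair=(int(res_of[a]), int(res_of[b])))
        )
    contacts.sort(key=lambda c: (c.i, c.j))
    return ContactMap(contacts=contacts, exclusions=set(exclusions), cutoff=cutoff)


# ---------------------------------------------------------------------------
# TSV export / import
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["i", "j", "residue_i", "residue_j", "sigma_A"]


def write_contact_tsv(cmap: ContactMap, path) -> None:
    """Write the contact list as TSV: i, j, residue_i, residue_j, sigma_A."""
    df = pd.DataFrame(
        {
            "i": [c.i for c in cmap.contacts],
            "j": [c.j for c in cmap.contacts],
            "residue_i": [c.residue_pair[0] for c in cmap.contacts],
            "residue_j": [c.residue_pair[1] for c in cmap.contacts],
            "sigma_A": [c.sigma for c in cmap.contacts],
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# native contact map; cutoff_A={cmap.cutoff:.3f}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_contact_tsv(path) -> ContactMap:
    """Read a contact map TSV written by :func:`write_contact_tsv`.

    The exclusion set is not stored in the TSV and comes back empty.
    """
    with open(path) as fh:
        header = fh.readline()
        cutoff = 4.0
        if header.startswith("#") and "cutoff_A=" in header:
            cutoff = float(header.split("cutoff_A=")[1])
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    contacts = [
        ContactPair(
            i=int(row.i), j=int(row.j), sigma=float(row.sigma_A),
            residue_pair=(int(row.residue_i), int(row.residue_j)),
        )
        for row in df.itertuples()
    ]
    return ContactMap(contacts=contacts, exclusions=set(), cutoff=cutoff)
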