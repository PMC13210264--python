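"""Structure model: atoms, residues, bonds, domains and the m2,2G edit.

A :class:`NativeStructure` is an ordered single-chain heavy-atom model of a
folded RNA.  It is the reference ("native") state from which the contact map
and all bonded equilibria of the structure-based potential are taken.

Conventions: coordinates in Å, 1-based atom and residue indices, heavy atoms
only unless hydrogens are explicitly requested.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .constants import (
    ATOMIC_MASSES,
    BASE_ATOMS,
    RESIDUE_ALIASES,
    RESIDUE_BONDS,
)

logger = logging.getLogger(__name__)

MAX_BOND_LENGTH = 2.0  # Å; every covalent heavy-atom bond must be shorter

__all__ = [
    "AtomRecord",
    "ResidueSpec",
    "NativeStructure",
    "DomainPartition",
    "StructureError",
    "read_structure",
    "write_frame",
    "write_trajectory_pdb",
    "apply_m22g",
    "assign_domains",
    "parse_domain_config",
]


class StructureError(ValueError):
    """Raised for malformed or unsupported input structures."""


@dataclass
class AtomRecord:
    """One heavy atom: global 1-based index, PDB name, element, mass, owner."""

    index: int
    name: str
    element: str
    mass: float
    residue_index: int
    position: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(
                f"atom {self.index} ({self.name}): position must be a finite 3-vector"
            )


@dataclass
class ResidueSpec:
    """One nucleotide (possibly reduced to pseudo-atoms) with its atoms."""

    index: int
    base: str  # one of A, C, G, U, G2M
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    @property
    def base_atoms(self) -> list[AtomRecord]:
        names = BASE_ATOMS.get(self.base, set())
        return [a for a in self.atoms if a.name in names]

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class NativeStructure:
    """Ordered single-chain RNA model with an explicit covalent bond graph."""

    residues: list[ResidueSpec]
    bonds: set[tuple[int, int]]
    chain_id: str = "A"

    # -- flat views ---------------------------------------------------------

    @property
    def atoms(self) -> list[AtomRecord]:
        return [a for r in self.residues for a in r.atoms]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def coordinates(self) -> np.ndarray:
        """(N, 3) array of native coordinates, atom order as stored."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def residue_of_atom(self) -> np.ndarray:
        """1-based residue index per atom, shape (N,)."""
        return np.array([a.residue_index for a in self.atoms], dtype=np.int64)

    def residue(self, index: int) -> ResidueSpec:
        for r in self.residues:
            if r.index == index:
                return r
        raise StructureError(f"no residue with index {index}")

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {a.index: set() for a in self.atoms}
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def validate(self) -> None:
        """Check index ordering and the bond-length invariant (< 2 Å)."""
        coords = {a.index: a.position for a in self.atoms}
        expected = 1
        for a in self.atoms:
            if a.index != expected:
                raise StructureError(
                    f"atom indices must be contiguous from 1; got {a.index} "
                    f"where {expected} expected"
                )
            expected += 1
        for i, j in self.bonds:
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d >= MAX_BOND_LENGTH:
                raise StructureError(
                    f"bond {i}-{j} has native length {d:.2f} Å >= {MAX_BOND_LENGTH} Å"
                )


@dataclass
class DomainPartition:
    """Named, pairwise-disjoint sets of residue indices (e.g. tRNA stem loops)."""

    domains: dict[str, set[int]]

    def __post_init__(self):
        names = list(self.domains)
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                overlap = self.domains[names[a]] & self.domains[names[b]]
                if overlap:
                    raise StructureError(
                        f"domains {names[a]!r} and {names[b]!r} overlap on "
                        f"residues {sorted(overlap)}"
                    )

    def __getitem__(self, name: str) -> set[int]:
        return self.domains[name]

    def __contains__(self, name: str) -> bool:
        return name in self.domains

    def names(self) -> list[str]:
        return sorted(self.domains)


# ---------------------------------------------------------------------------
# Bond inference
# ---------------------------------------------------------------------------

def _infer_bonds(residues: list[ResidueSpec]) -> set[tuple[int, int]]:
    """Infer the covalent bond graph.

    Per residue: apply the base's template adjacency to the atoms present,
    then bridge any remaining disconnected atom groups through their closest
    pair provided it is shorter than 2 Å (this makes reduced pseudo-atom
    residues, which lack the intermediate template atoms, chain up correctly).
    Between consecutive residues: the O3'(i)-P(i+1) phosphodiester link, with
    the same closest-pair fallback for reduced residues.
    """
    bonds: set[tuple[int, int]] = set()

    def add(i: int, j: int) -> None:
        bonds.add((min(i, j), max(i, j)))

    for res in residues:
        template = RESIDUE_BONDS.get(res.base)
        if template is None:
            raise StructureError(f"residue {res.index}: unknown base {res.base!r}")
        by_name = {a.name: a for a in res.atoms}
        local_adj: dict[int, set[int]] = {a.index: set() for a in res.atoms}
        for n1, n2 in template:
            if n1 in by_name and n2 in by_name:
                a, b = by_name[n1], by_name[n2]
                add(a.index, b.index)
                local_adj[a.index].add(b.index)
                local_adj[b.index].add(a.index)
        # bridge disconnected intra-residue components (pseudo-atom residues)
        comps = _components(local_adj)
        while len(comps) > 1:
            best = None
            for ci in range(len(comps)):
                for cj in range(ci + 1, len(comps)):
                    for i in comps[ci]:
                        for j in comps[cj]:
                            d = float(
                                np.linalg.norm(
                                    by_idx(res, i).position - by_idx(res, j).position
                                )
                            )
                            if best is None or d < best[0]:
                                best = (d, i, j, ci, cj)
            d, i, j, ci, cj = best
            if d >= MAX_BOND_LENGTH:
                raise StructureError(
                    f"residue {res.index}: atoms cannot be connected "
                    f"(closest inter-fragment distance {d:.2f} Å); "
                    "a backbone or ring atom is missing"
                )
            add(i, j)
            comps[ci] |= comps[cj]
            del comps[cj]

    # backbone links between consecutive residues
    for prev, nxt in zip(residues, residues[1:]):
        o3 = prev.atom("O3'")
        p = nxt.atom("P")
        if o3 is not None and p is not None:
            add(o3.index, p.index)
            continue
        best = None
        for a in prev.atoms:
            for b in nxt.atoms:
                d = float(np.linalg.norm(a.position - b.position))
                if best is None or d < best[0]:
                    best = (d, a.index, b.index)
        if best is None or best[0] >= MAX_BOND_LENGTH:
            raise StructureError(
                f"residue {prev.index}: missing backbone atom for the link to "
                f"residue {nxt.index} (closest pair "
                f"{best[0]:.2f} Å)" if best else
                f"residue {prev.index}: empty residue"
            )
        add(best[1], best[2])
    return bonds


def by_idx(res: ResidueSpec, index: int) -> AtomRecord:
    for a in res.atoms:
        if a.index == index:
            return a
    raise KeyError(index)


def _components(adj: dict[int, set[int]]) -> list[set[int]]:
    seen: set[int] = set()
    comps = []
    for start in adj:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adj[node] - comp)
        seen |= comp
        comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# PDB input / output (via biotite)
# ---------------------------------------------------------------------------

def _element_of(name: str, element: str) -> str:
    el = element.strip().capitalize()
    if el in ATOMIC_MASSES:
        return el
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise StructureError(f"cannot determine element of atom {name!r}")


def read_structure(pdb_path, include_hydrogens: bool = False) -> NativeStructure:
    """Read a single-chain RNA model from a PDB file.

    Hydrogens are dropped unless ``include_hydrogens`` is set (the contact
    definition and hydrogen-bond criterion are both heavy-atom based).  Bonds
    are inferred from per-base templates plus backbone connectivity.

    Raises
    ------
    StructureError
        For multiple chains, unknown residue names, or residues whose atoms
        cannot be connected into a single covalent graph.
    """
    pdb = PDBFile.read(str(pdb_path))
    arr = pdb.get_structure(model=1)
    chains = sorted(set(arr.chain_id.tolist()))
    if len(chains) > 1:
        raise StructureError(
            f"expected a single chain, found {len(chains)}: {', '.join(chains)}"
        )
    chain_id = chains[0] if chains else "A"

    residues: list[ResidueSpec] = []
    atom_counter = 0
    res_counter = 0
    current_key = None
    current: ResidueSpec | None = None
    for k in range(arr.array_length()):
        name = arr.atom_name[k].strip()
        element = _element_of(name, arr.element[k])
        if element == "H" and not include_hydrogens:
            continue
        key = (int(arr.res_id[k]), arr.res_name[k].strip())
        if key != current_key:
            res_name = arr.res_name[k].strip().upper()
            base = RESIDUE_ALIASES.get(res_name)
            if base is None:
                raise StructureError(
                    f"unknown residue name {res_name!r} at residue {arr.res_id[k]}"
                )
            res_counter += 1
            current = ResidueSpec(index=res_counter, base=base)
            residues.append(current)
            current_key = key
        atom_counter += 1
        current.atoms.append(
            AtomRecord(
                index=atom_counter,
                name=name,
                element=element,
                mass=ATOMIC_MASSES[element],
                residue_index=current.index,
                position=arr.coord[k].astype(float),
            )
        )
    if not residues:
        raise StructureError("no atoms read from file")

    bonds = _infer_bonds(residues)
    structure = NativeStructure(residues=residues, bonds=bonds, chain_id=chain_id)
    structure.validate()
    return structure


def _to_atom_array(structure: NativeStructure, positions: np.ndarray) -> bst.AtomArray:
    atoms = structure.atoms
    arr = bst.AtomArray(len(atoms))
    arr.coord = np.asarray(positions, dtype=np.float32)
    arr.chain_id = np.array([structure.chain_id] * len(atoms))
    arr.res_id = np.array([a.residue_index for a in atoms])
    res_names = {r.index: r.base for r in structure.residues}
    arr.res_name = np.array([res_names[a.residue_index] for a in atoms])
    arr.atom_name = np.array([a.name for a in atoms])
    arr.element = np.array([a.element for a in atoms])
    arr.hetero = np.zeros(len(atoms), dtype=bool)
    return arr


def write_frame(structure: NativeStructure, positions: np.ndarray, path) -> None:
    """Write one coordinate frame as a PDB file (fixed 0.001 Å precision)."""
    positions = np.asarray(positions, dtype=float)
    if positions.shape != (structure.n_atoms, 3):
        raise StructureError(
            f"positions shape {positions.shape} does not match atom count "
            f"{structure.n_atoms}"
        )
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(structure, positions))
    pdb.write(str(path))


def read_trajectory_pdb(path) -> np.ndarray:
    """Read a multi-model PDB back as an (n_frames, N, 3) coordinate array."""
    pdb = PDBFile.read(str(path))
    coord = pdb.get_coord(model=None)
    return np.asarray(coord, dtype=float)


def write_trajectory_pdb(structure: NativeStructure, frames: np.ndarray, path) -> None:
    """Write a stack of frames as a multi-model PDB file."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[1:] != (structure.n_atoms, 3):
        raise StructureError(
            f"frames shape {frames.shape} does not match (n_frames, "
            f"{structure.n_atoms}, 3)"
        )
    template = _to_atom_array(structure, frames[0])
    stack = bst.from_template(template, frames.astype(np.float32))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# m2,2G modification
# ---------------------------------------------------------------------------

def apply_m22g(structure: NativeStructure, residue_index: int) -> NativeStructure:
    """Return a copy with N2,N2-dimethylguanosine at ``residue_index``.

    Two methyl carbons (CM1, CM2) are attached to the exocyclic N2 amine at
    1.45 Å in idealized trigonal in-plane geometry (120° from the C2-N2
    bond, in the best-fit base plane).  All pre-existing atoms keep their
    coordinates, so every pre-existing interatomic distance is unchanged.
    """
    structure = copy.deepcopy(structure)
    res = structure.residue(residue_index)
    if res.base != "G":
        raise StructureError(
            f"residue {residue_index} is {res.base}, not G; m2,2G requires guanosine"
        )
    n2 = res.atom("N2")
    c2 = res.atom("C2")
    if n2 is None or c2 is None:
        raise StructureError(
            f"residue {residue_index} lacks the N2/C2 atoms needed for m2,2G"
        )

    base_coords = np.array([a.position for a in res.base_atoms])
    if len(base_coords) < 3:
        raise StructureError(
            f"residue {residue_index}: at least 3 base atoms needed to fit the plane"
        )
    centered = base_coords - base_coords.mean(axis=0)
    # plane normal = singular vector of the smallest singular value
    normal = np.linalg.svd(centered, full_matrices=False)[2][-1]

    u = c2.position - n2.position
    u = u / np.linalg.norm(u)
    v = np.cross(normal, u)
    v = v / np.linalg.norm(v)
    bond = 1.45
    # 120 degrees away from the C2 direction, symmetric about it, in plane
    pos1 = n2.position + bond * (-0.5 * u + np.sqrt(3.0) / 2.0 * v)
    pos2 = n2.position + bond * (-0.5 * u - np.sqrt(3.0) / 2.0 * v)

    res.base = "G2M"
    insert_at = max(a.index for a in res.atoms)
    # shift global indices of all atoms after the insertion point
    for r in structure.residues:
        for a in r.atoms:
            if a.index > insert_at:
                a.index += 2
    structure.bonds = {
        (i + 2 if i > insert_at else i, j + 2 if j > insert_at else j)
        for i, j in structure.bonds
    }
    cm1 = AtomRecord(insert_at + 1, "CM1", "C", ATOMIC_MASSES["C"],
                     residue_index, pos1)
    cm2 = AtomRecord(insert_at + 2, "CM2", "C", ATOMIC_MASSES["C"],
                     residue_index, pos2)
    res.atoms.extend([cm1, cm2])
    structure.bonds.add((n2.index, cm1.index))
    structure.bonds.add((n2.index, cm2.index))
    structure.validate()
    return structure


# ---------------------------------------------------------------------------
# Domains
# ---------------------------------------------------------------------------

def parse_domain_config(path) -> dict[str, str]:
    """Read a ``name: start-end[,start-end]`` domain config file (YAML-style)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return {str(k): str(v) for k, v in raw.items()}


def _parse_ranges(spec: str) -> set[int]:
    out: set[int] = set()
    for part in str(spec).split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            lo, hi = part.split("-", 1)
            out.update(range(int(lo), int(hi) + 1))
        else:
            out.add(int(part))
    return out


def assign_domains(
    structure: NativeStructure, domain_config: dict[str, str]
) -> DomainPartition:
    """Build a :class:`DomainPartition` from ``name -> "start-end[,...]"`` ranges.

    Residues not named by any range stay unassigned (junction residues are
    allowed).  Overlapping ranges or references to residues that do not exist
    are errors.
    """
    existing = {r.index for r in structure.residues}
    domains: dict[str, set[int]] = {}
    for name, spec in domain_config.items():
        members = _parse_ranges(spec)
        missing = members - existing
        if missing:
            raise StructureError(
                f"domain {name!r} references residues not in the structure: "
                f"{sorted(missing)}"
            )
        for other, other_members in domains.items():
            overlap = members & other_members
            if overlap:
                raise StructureError(
                    f"domains {name!r} and {other!r} overlap on residues "
                    f"{sorted(overlap)}"
                )
        domains[name] = members
    return DomainPartition(domains=domains)
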