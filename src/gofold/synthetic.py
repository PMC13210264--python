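"""Synthetic fixtures: toy folded RNAs, unfolded starts, scripted trajectories.

Every stage of the pipeline is testable on these without any external input:

* :func:`make_hairpin` — an idealized stem-loop with pseudo-atom residues
  (3–5 heavy atoms each: phosphate proxy P, sugar proxy C4', and 1–3 base
  atoms), built so the 4 Å contact rule yields both stacking and cross-strand
  pairing contacts.
* :func:`make_mini_trna` — four stem-loops (asl, dsl, tsl, aas) joined by
  linkers, with the tsl stacked onto the dsl and the variable loop (vl)
  passing over the dsl, so inter-domain native contacts exist (a toy analogue
  of the L-shaped tRNA tertiary fold).
* :func:`make_scripted_trajectory` — frames in which each domain snaps from
  an expanded geometry to native at a prescribed frame, a complete oracle for
  pathway classification.
* :func:`randomize_unfolded` — seeded self-avoiding chain randomization
  (pivot moves about inter-residue backbone bonds) with zero formed native
  contacts; bond lengths and bond angles are preserved exactly.
* :func:`make_nucleotide` — a full-geometry purine nucleotide (planar fused
  rings) for tests of the m2,2G edit and hydrogen-bond counting.

All builders are deterministic per seed.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .constants import ATOMIC_MASSES
from .contacts import ContactMap, build_native_contacts
from .structures import (
    AtomRecord,
    DomainPartition,
    NativeStructure,
    ResidueSpec,
    StructureError,
    _infer_bonds,
)

__all__ = [
    "make_hairpin",
    "make_mini_trna",
    "make_scripted_trajectory",
    "randomize_unfolded",
    "make_nucleotide",
    "make_base_pair",
]

RISE = 3.1          # Å stacking rise between consecutive residues in a stem
PAIR_GAP = 2.5      # Å between innermost base atoms of a base pair; chosen so
                    # the diagonal (cross-strand, next-rung) pairs also fall
                    # inside the 4 Å contact cutoff
MIN_CLEARANCE = 2.05  # Å minimum non-bonded distance asserted at build time

#: pseudo-base atom names per base (innermost last); subsets of the real
#: nucleobase atom sets so that base_atoms and H-bond chemistry resolve.
PSEUDO_BASE = {
    "A": ["N9", "C2", "N1"],
    "G": ["N9", "C2", "N2"],
    "C": ["N1", "C2", "O2"],
    "U": ["N1", "C2", "O4"],
}

# base-atom offsets from C4' along the base direction (local +x), with small
# out-of-plane zigzag so that no bonded triple is colinear
_BASE_STEPS = [
    np.array([1.35, 0.20, -0.25]),
    np.array([1.40, -0.25, 0.20]),
    np.array([1.38, 0.22, -0.20]),
]


def _element_of(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(name)


def _assemble(
    residue_defs: list[tuple[str, list[tuple[str, np.ndarray]]]],
    rng: np.random.Generator,
    jitter: float = 0.01,
) -> NativeStructure:
    """Build a validated NativeStructure from (base, [(atom, xyz), ...]) defs."""
    residues: list[ResidueSpec] = []
    idx = 0
    for r, (base, atoms) in enumerate(residue_defs, start=1):
        spec = ResidueSpec(index=r, base=base)
        for name, xyz in atoms:
            idx += 1
            el = _element_of(name)
            pos = np.asarray(xyz, dtype=float) + rng.normal(0.0, jitter, 3)
            spec.atoms.append(
                AtomRecord(idx, name, el, ATOMIC_MASSES[el], r, pos)
            )
        residues.append(spec)
    bonds = _infer_bonds(residues)
    structure = NativeStructure(residues=residues, bonds=bonds)
    structure.validate()
    _assert_no_clash(structure)
    return structure


def _assert_no_clash(structure: NativeStructure) -> None:
    from .contacts import build_exclusions

    coords = structure.coordinates()
    n = len(coords)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    d[np.tril_indices(n, 0)] = np.inf
    for i, j in build_exclusions(structure):  # 1-2 and 1-3 pairs
        d[i - 1, j - 1] = np.inf
    mn = d.min()
    if mn < MIN_CLEARANCE:
        i, j = np.unravel_index(d.argmin(), d.shape)
        raise StructureError(
            f"fixture geometry bug: non-bonded atoms {i + 1} and {j + 1} at "
            f"{mn:.2f} Å"
        )


# ---------------------------------------------------------------------------
# Hairpin
# ---------------------------------------------------------------------------

def _strand_residue(base: str, n_base: int, p_pos: np.ndarray,
                    up: bool, mirror: bool):
    """One pseudo residue; strand runs +y (up) or −y, base extends ±x."""
    sx = -1.0 if mirror else 1.0
    sy = 1.0 if up else -1.0
    atoms = [("P", p_pos.copy())]
    c4 = p_pos + np.array([sx * 0.7, sy * 1.55, 0.35])
    atoms.append(("C4'", c4.copy()))
    pos = c4.copy()
    for t in range(n_base):
        step = _BASE_STEPS[t].copy()
        step[0] *= sx
        pos = pos + step
        atoms.append((PSEUDO_BASE[base][t], pos.copy()))
    return atoms


def _base_extent(n_base: int) -> float:
    return 0.7 + float(sum(abs(s[0]) for s in _BASE_STEPS[:n_base]))


def _arc_points(a: np.ndarray, b: np.ndarray, bulge: np.ndarray,
                n_points: int, spacing_target: float = 1.7):
    """n_points evenly spaced along a circular arc from a to b bulging
    toward ``bulge``; consecutive spacing kept below 2 Å."""
    chord = float(np.linalg.norm(b - a))
    n_gaps = n_points + 1
    s = max(spacing_target, 1.12 * chord / n_gaps)
    if s > 1.95:
        raise StructureError(
            f"loop of {n_points // 2} residues cannot span a {chord:.1f} Å gap"
        )
    S = s * n_gaps
    theta = brentq(
        lambda th: np.sin(th / 2.0) / (th / 2.0) - chord / S, 1e-6,
        2.0 * np.pi - 1e-6,
    )
    R = S / theta
    u = (b - a) / chord
    w = bulge - np.dot(bulge, u) * u
    w = w / np.linalg.norm(w)
    m = 0.5 * (a + b)
    center = m - R * np.cos(theta / 2.0) * w
    pts = []
    for i in range(1, n_points + 1):
        t = i / n_gaps
        ang = theta * (t - 0.5)
        pts.append(center + R * (np.sin(ang) * u + np.cos(ang) * w))
    return pts, center


def _hairpin_defs(n_bp: int, loop_len: int, n_base: int,
                  strand1_base: str = "G", strand2_base: str = "C",
                  loop_base: str = "U"):
    """Residue definitions of a stem-loop in local coordinates.

    Entry (first P) near the origin heading +y; exit (last C4') near
    (g, 1.55, 0.35) heading −y, where g is the strand separation.
    """
    g = 2.0 * _base_extent(n_base) + PAIR_GAP
    defs = []
    # 5' strand, ascending
    for k in range(n_bp):
        p = np.array([0.0, RISE * k, 0.0])
        defs.append((strand1_base, _strand_residue(strand1_base, n_base, p,
                                                   up=True, mirror=False)))
    # loop along an arc between the two strand tops
    top1_c4 = np.array([0.7, RISE * (n_bp - 1) + 1.55, 0.35])
    top2_p = np.array([g, RISE * n_bp, 0.0])
    pts, center = _arc_points(top1_c4, top2_p, np.array([0.0, 1.0, 0.0]),
                              2 * loop_len)
    for m in range(loop_len):
        p_pos = pts[2 * m]
        c4_pos = pts[2 * m + 1]
        outward = c4_pos - center
        outward = outward / np.linalg.norm(outward)
        atoms = [("P", p_pos.copy()), ("C4'", c4_pos.copy())]
        pos = c4_pos.copy()
        for t in range(n_base):
            pos = pos + 1.39 * outward + np.array([0.0, 0.0, 0.22 * (-1) ** t])
            atoms.append((PSEUDO_BASE[loop_base][t], pos.copy()))
        defs.append((loop_base, atoms))
    # 3' strand, descending, bases mirrored toward the 5' strand
    for m in range(n_bp):
        p = np.array([g, RISE * (n_bp - m), 0.0])
        defs.append((strand2_base, _strand_residue(strand2_base, n_base, p,
                                                   up=False, mirror=True)))
    return defs, g


def make_hairpin(
    n_bp: int, loop_len: int, seed: int = 0, atoms_per_residue: int = 3
) -> tuple[NativeStructure, DomainPartition]:
    """Idealized stem-loop: ``n_bp`` base pairs, ``loop_len`` loop residues.

    Paired residues place their innermost base atoms 3 Å apart, so the native
    contact map holds at least ``n_bp`` cross-strand contacts on top of the
    stacking contacts.  Single domain "stem" covering the paired strands.
    """
    if n_bp < 3 or loop_len < 3:
        raise ValueError("need n_bp >= 3 and loop_len >= 3")
    if not 3 <= atoms_per_residue <= 5:
        raise ValueError("atoms_per_residue must be 3..5")
    rng = np.random.default_rng(seed)
    defs, _ = _hairpin_defs(n_bp, loop_len, atoms_per_residue - 2)
    structure = _assemble(defs, rng)
    stem = set(range(1, n_bp + 1)) | set(
        range(n_bp + loop_len + 1, 2 * n_bp + loop_len + 1)
    )
    partition = DomainPartition(domains={"stem": stem})
    return structure, partition


# ---------------------------------------------------------------------------
# Mini tRNA
# ---------------------------------------------------------------------------

def _transform(defs, rotation: np.ndarray, translation: np.ndarray):
    out = []
    for base, atoms in defs:
        out.append(
            (base, [(n, rotation @ xyz + translation) for n, xyz in atoms])
        )
    return out


def _polyline_linker(start: np.ndarray, waypoints: list[np.ndarray],
                     end: np.ndarray, base: str, n_base: int,
                     obstacles: list[np.ndarray] | None = None):
    """Linker residues along a polyline between two covalent attachment points.

    Backbone atoms are placed by walking the polyline with a fixed Euclidean
    step (chord stepping), so consecutive atoms stay within bonding distance
    even across corners; base atoms extend along the local horizontal
    perpendicular of the walk direction.
    """
    nodes = [np.asarray(start, float)] + [np.asarray(w, float) for w in waypoints] \
        + [np.asarray(end, float)]
    seg = [np.linalg.norm(b - a) for a, b in zip(nodes, nodes[1:])]
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(cum[-1])

    def point(arc):
        arc = min(arc, total)
        i = int(np.searchsorted(cum, arc, side="right") - 1)
        i = min(i, len(seg) - 1)
        t = (arc - cum[i]) / seg[i]
        return nodes[i] + t * (nodes[i + 1] - nodes[i])

    def walk(step):
        """Chord-step the polyline; return backbone points (excl. endpoints)
        and the final gap to the end point."""
        pts = []
        cur = nodes[0]
        arc = 0.0
        while True:
            advanced = False
            while arc < total - 1e-9:
                arc = min(arc + 0.02, total)
                if np.linalg.norm(point(arc) - cur) >= step:
                    advanced = True
                    break
            if not advanced:
                break
            cur = point(arc)
            if np.linalg.norm(cur - nodes[-1]) < 1.15:
                break
            pts.append(cur)
        return pts, float(np.linalg.norm((pts[-1] if pts else nodes[0])
                                         - nodes[-1]))

    chosen = None
    for s in np.linspace(1.25, 1.9, 34):
        pts, gap = walk(s)
        if len(pts) >= 2 and len(pts) % 2 == 0 and 1.15 <= gap <= 1.95:
            chosen = (pts, s)
            break
    if chosen is None:
        raise StructureError(
            f"cannot span a {total:.1f} Å linker with 1.4-1.9 Å backbone steps"
        )
    pts, s = chosen

    def perp_at(p_prev, p_next):
        tangent = p_next - p_prev
        perp = np.cross(tangent, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(tangent, np.array([1.0, 0.0, 0.0]))
        return perp / np.linalg.norm(perp)

    # two side variants (base left/right of the walk) per residue; choose
    # greedily, then run fix-up passes flipping any residue whose base atoms
    # crowd the rest of the linker or the arms (the inside of a curve would
    # fold base atoms onto the downstream backbone)
    n_res = len(pts) // 2
    variants = []
    for m in range(n_res):
        p_pos = pts[2 * m]
        c4_base = pts[2 * m + 1]
        perp0 = perp_at(p_pos, pts[2 * m + 2] if 2 * m + 2 < len(pts)
                        else nodes[-1])
        pair = {}
        for side in (1.0, -1.0):
            perp = side * perp0
            c4_pos = c4_base + 0.3 * perp
            atoms = [("P", p_pos), ("C4'", c4_pos)]
            pos = c4_pos.copy()
            for t in range(n_base):
                pos = pos + 1.39 * perp + np.array([0.0, 0.0,
                                                    0.24 * (-1) ** t])
                atoms.append((PSEUDO_BASE[base][t], pos.copy()))
            pair[side] = atoms
        variants.append(pair)

    fixed = np.array([nodes[0], nodes[-1]] + pts + list(obstacles or []))

    def clearance(m, side, chosen):
        """Min distance of residue m's off-walk atoms to everything else."""
        own = np.array([a for _, a in variants[m][side][1:]])
        other = [fixed]
        for k in range(n_res):
            if k != m:
                other.append(np.array([a for _, a in
                                       variants[k][chosen[k]][1:]]))
        other = np.vstack(other)
        d = np.linalg.norm(own[:, None, :] - other[None, :, :], axis=2)
        # ignore the residue's own walk points and direct neighbours on the
        # walk (bonded / 1-3, handled by the exclusion rules)
        lo = max(0, 2 * m - 1)
        hi = min(len(pts), 2 * m + 3)
        near = np.array([nodes[0]] if m == 0 else []).reshape(-1, 3)
        skip = np.vstack([np.array(pts[lo:hi]), near,
                          np.array([nodes[-1]] if m == n_res - 1 else []
                                   ).reshape(-1, 3)])
        for q in skip:
            d[:, np.linalg.norm(other - q, axis=1) < 1e-9] = np.inf
        return float(d.min())

    chosen = {m: 1.0 for m in range(n_res)}
    for m in range(n_res):
        if clearance(m, -1.0, chosen) > clearance(m, 1.0, chosen):
            chosen[m] = -1.0
    for _ in range(4):
        changed = False
        for m in range(n_res):
            cur = clearance(m, chosen[m], chosen)
            alt = clearance(m, -chosen[m], chosen)
            if alt > cur and cur < MIN_CLEARANCE + 0.1:
                chosen[m] = -chosen[m]
                changed = True
        if not changed:
            break

    return [(base, variants[m][chosen[m]]) for m in range(n_res)]


_ROT_FLIP = np.diag([1.0, -1.0, -1.0])  # pi about the x axis
_IDENT = np.eye(3)


def _first_p(defs):
    return defs[0][1][0][1]


def _last_c4(defs):
    return defs[-1][1][1][1]


def make_mini_trna(
    stem_bp: int = 3, seed: int = 0, atoms_per_residue: int = 3,
    loop_len: int = 4,
) -> tuple[NativeStructure, DomainPartition]:
    """Toy four-arm tRNA: asl, dsl, tsl, aas stem-loops plus a vl linker.

    The tsl arm is stacked 3.6 Å above the dsl arm and the vl passes over the
    dsl, so dsl–tsl and dsl–vl inter-domain native contacts exist (the toy
    analogue of the tertiary elbow).  Chain order: asl → dsl → vl → tsl → aas
    with short unassigned junction linkers between arms; the DomainPartition
    covers all five names.
    """
    if stem_bp < 3:
        raise ValueError("stem_bp must be >= 3")
    if not 3 <= atoms_per_residue <= 5:
        raise ValueError("atoms_per_residue must be 3..5")
    rng = np.random.default_rng(seed)
    n_base = atoms_per_residue - 2
    z_lift = 3.6

    def arm(strand1_base="G", strand2_base="C"):
        return _hairpin_defs(stem_bp, loop_len, n_base,
                             strand1_base, strand2_base)

    asl_defs, g = arm()
    dsl_defs, _ = arm()
    tsl_defs, _ = arm("G", "C")
    aas_defs, _ = arm()

    # asl: pointing -y, to the left of the dsl
    asl_defs = _transform(asl_defs, _ROT_FLIP, np.array([-g - 5.0, -1.5, 0.0]))
    # dsl: at the origin, pointing +y
    dsl_defs = _transform(dsl_defs, _IDENT, np.zeros(3))
    # tsl: stacked directly above the dsl
    tsl_entry = np.array([0.0, 0.0, z_lift])
    tsl_defs = _transform(tsl_defs, _IDENT, tsl_entry)
    # aas: one level higher, pointing -y, to the right
    aas_entry = np.array([g + 4.0, -0.5, 2.0 * z_lift + 0.4])
    aas_defs = _transform(aas_defs, _ROT_FLIP, aas_entry)

    arm_atoms = [xyz for defs in (asl_defs, dsl_defs, tsl_defs, aas_defs)
                 for _, atoms in defs for _, xyz in atoms]
    # linker residues carry a single base proxy regardless of
    # atoms_per_residue: the compact vl curl cannot accommodate long base
    # arms, and junctions are unassigned scaffolding anyway
    jct1 = _polyline_linker(_last_c4(asl_defs), [], _first_p(dsl_defs),
                            "A", 1, obstacles=arm_atoms)
    # vl: drops around the -y side of the dsl/tsl stack, curls through a
    # compact 2 Å-radius loop (giving the variable loop intra-domain contacts
    # across the curl), then approaches the tsl entry from outside the
    # stacked plane
    hook_center = np.array([g - 1.3, -4.5, z_lift / 2.0 + 0.6])
    hook = [
        hook_center + 2.0 * np.array([np.cos(a), np.sin(a), 0.0])
        for a in np.deg2rad(np.arange(25.0, -256.0, -40.0))
    ]
    vl = _polyline_linker(
        _last_c4(dsl_defs),
        [np.array([g + 0.1, -2.3, z_lift / 2.0 + 0.5])] + hook
        + [np.array([1.5, -3.5, z_lift])],
        _first_p(tsl_defs),
        "U", 1, obstacles=arm_atoms,
    )
    jct2 = _polyline_linker(_last_c4(tsl_defs), [], _first_p(aas_defs),
                            "A", 1, obstacles=arm_atoms)

    blocks = [
        ("asl", asl_defs), (None, jct1), ("dsl", dsl_defs), ("vl", vl),
        ("tsl", tsl_defs), (None, jct2), ("aas", aas_defs),
    ]
    defs = []
    domains: dict[str, set[int]] = {"asl": set(), "dsl": set(), "vl": set(),
                                    "tsl": set(), "aas": set()}
    r = 0
    for name, block in blocks:
        for item in block:
            r += 1
            defs.append(item)
            if name is not None:
                domains[name].add(r)
    structure = _assemble(defs, rng)
    return structure, DomainPartition(domains=domains)


# ---------------------------------------------------------------------------
# Scripted trajectories
# ---------------------------------------------------------------------------

def make_scripted_trajectory(
    fixture: tuple[NativeStructure, DomainPartition],
    fold_order: list[str],
    fold_times: list[int],
    n_frames: int,
    seed: int = 0,
    jitter: float = 0.05,
    expansion: float = 3.0,
):
    """Frames in which each domain folds (expanded → native) at its set time.

    Before its fold time a domain's coordinates are scaled by ``expansion``
    about the domain centroid (so its intra-domain Q is 0); over the two
    frames preceding the fold time they interpolate linearly to native, and
    stay native (plus seeded jitter) afterwards.  Each domain's Q therefore
    crosses 0.8 persistently at its fold time ± 2 frames and not before.
    Domains of the partition absent from ``fold_order`` stay expanded for
    the whole trajectory (they never fold); unassigned junction residues
    stay native.

    Returns a :class:`gofold.dynamics.Trajectory` whose Q series is the
    global Q against the fixture's own contact map.
    """
    from .dynamics import Trajectory  # local import to avoid a cycle

    structure, partition = fixture
    if len(fold_order) != len(fold_times):
        raise ValueError("fold_order and fold_times must have equal length")
    if list(fold_times) != sorted(set(fold_times)):
        raise ValueError("fold_times must be strictly increasing")
    if max(fold_times) >= n_frames:
        raise ValueError(
            f"fold_times {fold_times} exceed n_frames = {n_frames}"
        )
    rng = np.random.default_rng(seed)
    native = structure.coordinates()
    res_of = structure.residue_of_atom()

    fold_time_of = dict(zip(fold_order, fold_times))
    frames = np.empty((n_frames, len(native), 3))
    window = 2
    for f in range(n_frames):
        frame = native.copy()
        for name in partition.names():
            atom_mask = np.isin(res_of, list(partition[name]))
            centroid = native[atom_mask].mean(axis=0)
            ft = fold_time_of.get(name)
            if ft is None:
                scale = expansion
            elif f >= ft:
                scale = 1.0
            elif f >= ft - window:
                s = (f - (ft - window)) / window
                scale = expansion + s * (1.0 - expansion)
            else:
                scale = expansion
            frame[atom_mask] = centroid + scale * (native[atom_mask] - centroid)
        if jitter > 0:
            frame += rng.normal(0.0, jitter, frame.shape)
        frames[f] = frame

    cmap = build_native_contacts(structure)
    d = np.linalg.norm(frames[:, cmap.i_idx, :] - frames[:, cmap.j_idx, :],
                       axis=2)
    q = (d < 1.2 * cmap.sigma[None, :]).mean(axis=1)
    return Trajectory(
        frames=frames,
        times=np.arange(n_frames, dtype=float),
        q_series=q,
        stride=1,
        dt=1.0,
        outcome="folded",
        metadata={"seed": seed, "scripted": True,
                  "fold_order": list(fold_order),
                  "fold_times": list(fold_times)},
    )


# ---------------------------------------------------------------------------
# Randomized unfolded starts
# ---------------------------------------------------------------------------

def randomize_unfolded(
    structure: NativeStructure,
    seed: int = 0,
    cmap: ContactMap | None = None,
    lambda_formed: float = 1.2,
    max_sweeps: int = 200,
    min_separation: float = 2.0,
) -> np.ndarray:
    """Self-avoiding randomized coordinates with zero formed native contacts.

    Applies seeded pivot moves: a random rotation of all downstream residues
    about a randomly chosen inter-residue backbone bond.  Pivot moves change
    backbone dihedrals only, so every bond length and bond angle keeps its
    native value exactly; moves that bring any non-bonded pair closer than
    ``min_separation`` are rejected.  Sweeps continue until no native contact
    satisfies the formation criterion (r < λσ).
    """
    coords = structure.coordinates().copy()
    if cmap is None:
        cmap = build_native_contacts(structure)
    rng = np.random.default_rng(seed)

    res_of = structure.residue_of_atom()
    n_res = structure.n_residues
    # pivot bonds: the backbone link between residue r and r+1
    link_bonds = []
    for i, j in structure.bonds:
        ri, rj = res_of[i - 1], res_of[j - 1]
        if abs(ri - rj) == 1:
            link_bonds.append((i - 1, j - 1) if ri < rj else (j - 1, i - 1))
    link_bonds.sort()
    excluded = {(i - 1, j - 1) for i, j in structure.bonds}

    def q_now():
        d = np.linalg.norm(coords[cmap.i_idx] - coords[cmap.j_idx], axis=1)
        return float(np.mean(d < lambda_formed * cmap.sigma))

    best_q = q_now()
    for sweep in range(max_sweeps):
        order = rng.permutation(len(link_bonds))
        for b in order:
            i, j = link_bonds[b]
            downstream = res_of > res_of[i]
            axis = coords[j] - coords[i]
            norm = np.linalg.norm(axis)
            if norm < 1e-9:
                continue
            axis = axis / norm
            angle = rng.uniform(-np.pi, np.pi)
            rot = _rotation_matrix(axis, angle)
            moved = (coords[downstream] - coords[j]) @ rot.T + coords[j]
            # self-avoidance: moved block vs the static block
            static = coords[~downstream]
            dmin = _min_cross_distance(moved, static, downstream, excluded)
            if dmin < min_separation:
                continue
            coords[downstream] = moved
        q = q_now()
        best_q = min(best_q, q)
        if q == 0.0:
            return coords
    raise RuntimeError(
        f"failed to reach Q = 0 within {max_sweeps} sweeps (best Q = {best_q:.3f})"
    )


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def _min_cross_distance(moved, static, downstream_mask, excluded) -> float:
    """Min distance between moved and static atoms, ignoring bonded pairs."""
    d = np.linalg.norm(moved[:, None, :] - static[None, :, :], axis=2)
    moved_pos = {int(g): a for a, g in enumerate(np.flatnonzero(downstream_mask))}
    static_pos = {int(g): b for b, g in enumerate(np.flatnonzero(~downstream_mask))}
    for (i, j) in excluded:
        if downstream_mask[i] != downstream_mask[j]:
            mi, si = (i, j) if downstream_mask[i] else (j, i)
            d[moved_pos[mi], static_pos[si]] = np.inf
    return float(d.min()) if d.size else np.inf


# ---------------------------------------------------------------------------
# Full-geometry nucleotides (planar fused rings)
# ---------------------------------------------------------------------------

def _purine_coords() -> dict[str, np.ndarray]:
    """Idealized planar purine ring (hexagon + fused pentagon), bond ~1.39 Å."""
    edge = 1.39
    r6 = edge  # circumradius of a regular hexagon equals its edge
    hexnames = ["N1", "C2", "N3", "C4", "C5", "C6"]
    coords: dict[str, np.ndarray] = {}
    for k, name in enumerate(hexnames):
        ang = np.deg2rad(90.0 + 60.0 * k)
        coords[name] = r6 * np.array([np.cos(ang), np.sin(ang), 0.0])
    # pentagon fused on the C4-C5 edge
    c4, c5 = coords["C4"], coords["C5"]
    mid = 0.5 * (c4 + c5)
    out = mid / np.linalg.norm(mid)
    r5 = edge / (2.0 * np.sin(np.pi / 5.0))
    a5 = r5 * np.cos(np.pi / 5.0)
    center5 = mid + a5 * out
    ang4 = float(np.arctan2((c4 - center5)[1], (c4 - center5)[0]))
    ang5 = float(np.arctan2((c5 - center5)[1], (c5 - center5)[0]))
    # walk from C4 away from C5: N9, C8, N7 complete the five-membered ring
    step = np.deg2rad(72.0)
    delta = (ang5 - ang4 + np.pi) % (2.0 * np.pi) - np.pi
    sign = -1.0 if delta > 0 else 1.0
    for k, name in enumerate(["N9", "C8", "N7"], start=1):
        ang = ang4 + sign * step * k
        coords[name] = center5 + r5 * np.array([np.cos(ang), np.sin(ang), 0.0])
    return coords


def make_nucleotide(base: str = "G", residue_index: int = 1,
                    origin=(0.0, 0.0, 0.0)) -> NativeStructure:
    """Single full-geometry purine nucleotide (base ring + C1' sugar proxy)."""
    if base not in ("G", "A"):
        raise ValueError("full-geometry builder supports G and A")
    coords = _purine_coords()
    hex_center = np.zeros(3)

    def outward(host, length):
        d = coords[host] - hex_center
        return coords[host] + length * d / np.linalg.norm(d)

    if base == "G":
        coords["O6"] = outward("C6", 1.23)
        coords["N2"] = outward("C2", 1.34)
    else:
        coords["N6"] = outward("C6", 1.34)
    pent_center = (coords["N9"] + coords["C8"] + coords["N7"]
                   + coords["C4"] + coords["C5"]) / 5.0
    d = coords["N9"] - pent_center
    coords["C1'"] = coords["N9"] + 1.47 * d / np.linalg.norm(d)

    origin = np.asarray(origin, dtype=float)
    spec = ResidueSpec(index=residue_index, base=base)
    for i, (name, xyz) in enumerate(coords.items(), start=1):
        el = _element_of(name)
        spec.atoms.append(
            AtomRecord(i, name, el, ATOMIC_MASSES[el], residue_index,
                       xyz + origin)
        )
    bonds = _infer_bonds([spec])
    structure = NativeStructure(residues=[spec], bonds=bonds)
    structure.validate()
    return structure


def make_base_pair(base_a: str = "G", base_b: str = "A",
                   contact_atoms: tuple[str, str] = ("N1", "N1"),
                   distance: float = 2.9) -> NativeStructure:
    """Two full-geometry bases facing each other at a set heavy-atom distance.

    Built for hydrogen-bond counting tests; the two residues are not
    covalently linked, so bonds are assembled per residue only.
    """
    sa = make_nucleotide(base_a, residue_index=1)
    sb = make_nucleotide(base_b, residue_index=2)
    a_atom = sa.residues[0].atom(contact_atoms[0])
    b_atom = sb.residues[0].atom(contact_atoms[1])
    # rotate residue B by pi about y so the bases face each other, then place
    rot = np.diag([-1.0, 1.0, -1.0])
    for atom in sb.residues[0].atoms:
        atom.position = rot @ atom.position
    shift = (a_atom.position + np.array([distance, 0.0, 0.0])) - b_atom.position
    offset = sa.n_atoms
    res_b = sb.residues[0]
    for atom in res_b.atoms:
        atom.position = atom.position + shift
        atom.index += offset
    bonds = set(sa.bonds) | {(i + offset, j + offset) for i, j in sb.bonds}
    structure = NativeStructure(residues=[sa.residues[0], res_b], bonds=bonds)
    structure.validate()
    return structure
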