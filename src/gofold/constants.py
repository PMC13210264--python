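"""Physical constants, residue templates and per-base chemistry tables.

Unit system: energies in kcal/mol, distances in angstrom (Å), masses in amu,
time in ps, temperature in K.  ``AKMA`` converts kcal/mol to amu·Å²/ps² so that
accelerations (kcal/mol/Å divided by amu) come out in Å/ps².
"""

from __future__ import annotations

#: Boltzmann constant, kcal/(mol·K).
KB = 0.0019872041

#: 1 kcal/mol expressed in amu·Å²/ps².
AKMA = 418.4

#: Atomic masses (amu) for the heavy elements found in nucleic acids.
ATOMIC_MASSES = {
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973762,
    "H": 1.008,
    "S": 32.06,
}

# ---------------------------------------------------------------------------
# Covalent adjacency templates (heavy atoms), keyed by residue name.
# Each entry is a tuple of bonded atom-name pairs.  Backbone atoms are shared
# by all residues; the inter-residue link is O3'(i)-P(i+1).
# ---------------------------------------------------------------------------

_BACKBONE_BONDS = [
    ("P", "OP1"), ("P", "OP2"), ("P", "O5'"),
    ("O5'", "C5'"), ("C5'", "C4'"), ("C4'", "O4'"), ("C4'", "C3'"),
    ("C3'", "O3'"), ("C3'", "C2'"), ("C2'", "O2'"), ("C2'", "C1'"),
    ("C1'", "O4'"),
]

_PURINE_RING = [
    ("C1'", "N9"),
    ("N9", "C8"), ("C8", "N7"), ("N7", "C5"),
    ("C5", "C6"), ("C5", "C4"), ("C4", "N9"),
    ("C4", "N3"), ("N3", "C2"), ("C2", "N1"), ("N1", "C6"),
]

_PYRIMIDINE_RING = [
    ("C1'", "N1"),
    ("N1", "C2"), ("C2", "N3"), ("N3", "C4"),
    ("C4", "C5"), ("C5", "C6"), ("C6", "N1"),
]

RESIDUE_BONDS = {
    "A": _BACKBONE_BONDS + _PURINE_RING + [("C6", "N6")],
    "G": _BACKBONE_BONDS + _PURINE_RING + [("C6", "O6"), ("C2", "N2")],
    "G2M": _BACKBONE_BONDS + _PURINE_RING
    + [("C6", "O6"), ("C2", "N2"), ("N2", "CM1"), ("N2", "CM2")],
    "C": _BACKBONE_BONDS + _PYRIMIDINE_RING + [("C2", "O2"), ("C4", "N4")],
    "U": _BACKBONE_BONDS + _PYRIMIDINE_RING + [("C2", "O2"), ("C4", "O4")],
}

#: Nucleobase atoms per residue name (everything that is neither sugar nor
#: phosphate); used for base centers of mass and base-plane fits.
BASE_ATOMS = {
    "A": {"N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"},
    "G": {"N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"},
    "G2M": {"N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4",
            "CM1", "CM2"},
    "C": {"N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"},
    "U": {"N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"},
}

# ---------------------------------------------------------------------------
# Hydrogen-bond chemistry: base heavy-atom donors (N/O carrying at least one
# hydrogen in the base) and acceptors.  N2 of m2,2G is doubly methylated and
# is no longer a donor.
# ---------------------------------------------------------------------------

HB_DONORS = {
    "A": {"N6"},
    "G": {"N1", "N2"},
    "G2M": {"N1"},
    "C": {"N4"},
    "U": {"N3"},
}

HB_ACCEPTORS = {
    "A": {"N1", "N3", "N7"},
    "G": {"O6", "N3", "N7"},
    "G2M": {"O6", "N3", "N7"},
    "C": {"O2", "N3"},
    "U": {"O2", "O4"},
}

#: Residue names recognised by the reader.  Common PDB aliases map onto the
#: canonical single-letter names used throughout.
RESIDUE_ALIASES = {
    "A": "A", "ADE": "A", "RA": "A",
    "C": "C", "CYT": "C", "RC": "C",
    "G": "G", "GUA": "G", "RG": "G",
    "U": "U", "URA": "U", "RU": "U", "URI": "U",
    "G2M": "G2M", "2MG": "G2M", "M2G": "G2M",
}

#: Default tRNA domain ranges (canonical cloverleaf numbering): acceptor stem
#: (aas), D-stem loop (dsl), anticodon stem loop (asl), variable loop (vl),
#: T-stem loop (tsl).  Junction residues 8, 9 and 26 are left unassigned.
DEFAULT_TRNA_DOMAINS = {
    "aas": "1-7,66-76",
    "dsl": "10-25",
    "asl": "27-43",
    "vl": "44-48",
    "tsl": "49-65",
}
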