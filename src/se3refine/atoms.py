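"""Canonical 37-slot heavy-atom vocabulary for the 20 standard amino acids.

Every standard residue's heavy atoms are routed into a fixed, ordered set of
37 canonical PDB v3 atom names ("atom37").  The ordering below is the
published atom37 convention (backbone first: N, CA, C, CB, O, then side-chain
atoms, with the optional C-terminal OXT as the last slot) and is what makes
the one-hot atom-type features reproducible.

Hydrogens are never represented: 37 slots cover heavy atoms only.
"""

from __future__ import annotations

import numpy as np

# Fixed atom37 ordering.  Index into this tuple == one-hot feature index.
ATOM37: tuple[str, ...] = (
    "N", "CA", "C", "CB", "O",
    "CG", "CG1", "CG2", "OG", "OG1", "SG",
    "CD", "CD1", "CD2", "ND1", "ND2", "OD1", "OD2", "SD",
    "CE", "CE1", "CE2", "CE3", "NE", "NE1", "NE2", "OE1", "OE2",
    "CH2", "NH1", "NH2", "OH",
    "CZ", "CZ2", "CZ3", "NZ",
    "OXT",
)

ATOM37_INDEX: dict[str, int] = {name: i for i, name in enumerate(ATOM37)}

N_ATOM_TYPES = 37

# Element symbol per slot (first character of the canonical name works for
# every heavy atom in the table).
ELEMENTS: tuple[str, ...] = tuple(name[0] for name in ATOM37)

# Single-bond covalent radii in Angstrom, used to threshold interatomic
# distances when inferring covalent bonds.
COVALENT_RADII: dict[str, float] = {"C": 0.77, "N": 0.70, "O": 0.66, "S": 1.04}

# Slack added on top of the sum of covalent radii when deciding whether two
# atoms are bonded (accommodates real bond-length variation and double bonds).
DEFAULT_BOND_TOLERANCE = 0.56

AA1 = "ACDEFGHIKLMNPQRSTVWY"
AA1_INDEX: dict[str, int] = {a: i for i, a in enumerate(AA1)}
N_RESIDUE_TYPES = 20

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

# Side-chain heavy atoms per residue (beyond N, CA, C, O; CB listed where
# present).  OXT is additionally valid for every residue when C-terminal.
_SIDE_CHAINS: dict[str, tuple[str, ...]] = {
    "A": ("CB",),
    "R": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "N": ("CB", "CG", "OD1", "ND2"),
    "D": ("CB", "CG", "OD1", "OD2"),
    "C": ("CB", "SG"),
    "Q": ("CB", "CG", "CD", "OE1", "NE2"),
    "E": ("CB", "CG", "CD", "OE1", "OE2"),
    "G": (),
    "H": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "I": ("CB", "CG1", "CG2", "CD1"),
    "L": ("CB", "CG", "CD1", "CD2"),
    "K": ("CB", "CG", "CD", "CE", "NZ"),
    "M": ("CB", "CG", "SD", "CE"),
    "F": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "P": ("CB", "CG", "CD"),
    "S": ("CB", "OG"),
    "T": ("CB", "OG1", "CG2"),
    "W": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "Y": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "V": ("CB", "CG1", "CG2"),
}

# Full valid heavy-atom set per residue.  OXT is included because any residue
# may carry the terminal carboxylate oxygen.
RESIDUE_ATOMS: dict[str, tuple[str, ...]] = {
    aa: ("N", "CA", "C", "O") + _SIDE_CHAINS[aa] + ("OXT",) for aa in AA1
}

# Intra-residue covalent bonds (canonical name pairs).  Backbone N-CA, CA-C,
# C-O, C-OXT and CA-CB are shared; side-chain connectivity is per residue.
_SIDE_BONDS: dict[str, tuple[tuple[str, str], ...]] = {
    "A": (),
    "R": (("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"),
          ("CZ", "NH1"), ("CZ", "NH2")),
    "N": (("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")),
    "D": (("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")),
    "C": (("CB", "SG"),),
    "Q": (("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")),
    "E": (("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")),
    "G": (),
    "H": (("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"),
          ("CE1", "NE2"), ("NE2", "CD2")),
    "I": (("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")),
    "L": (("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")),
    "K": (("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")),
    "M": (("CB", "CG"), ("CG", "SD"), ("SD", "CE")),
    "F": (("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
          ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")),
    "P": (("CB", "CG"), ("CG", "CD"), ("CD", "N")),
    "S": (("CB", "OG"),),
    "T": (("CB", "OG1"), ("CB", "CG2")),
    "W": (("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "NE1"),
          ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"), ("CE2", "CZ2"),
          ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")),
    "Y": (("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
          ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH")),
    "V": (("CB", "CG1"), ("CB", "CG2")),
}


def residue_bonds(aa: str) -> list[tuple[str, str]]:
    """Intra-residue covalent bonds (atom-name pairs) for a 1-letter code."""
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    if aa != "G":
        bonds.append(("CA", "CB"))
    bonds.extend(_SIDE_BONDS[aa])
    return bonds


def atom37_mask(sequence: str) -> np.ndarray:
    """Boolean [n_res, 37] mask of atoms a residue can carry (without OXT)."""
    mask = np.zeros((len(sequence), N_ATOM_TYPES), dtype=bool)
    for i, aa in enumerate(sequence):
        for name in RESIDUE_ATOMS[aa]:
            if name != "OXT":
                mask[i, ATOM37_INDEX[name]] = True
    return mask
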