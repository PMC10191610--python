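"""PDB I/O into the fixed 37-slot atomic representation.

A structure is held as ``ProteinStructure``: a sequence, an
``[n_res, 37, 3]`` coordinate array and an ``[n_res, 37]`` presence mask.
Parsing and serialization go through biotite; this module only routes atoms
into atom37 slots and enforces the representation's invariants (single
chain, standard residues, N/CA/C always present, heavy atoms only).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from os import PathLike

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .atoms import ATOM37, ATOM37_INDEX, N_ATOM_TYPES, THREE_TO_ONE, ONE_TO_THREE, RESIDUE_ATOMS
from .errors import ParseError, ValidationError

_BACKBONE_REQUIRED = ("N", "CA", "C")


@dataclass
class ProteinStructure:
    """Single-chain all-heavy-atom structure in atom37 layout.

    Attributes
    ----------
    sequence : str
        One-letter codes of the 20 standard amino acids.
    coords : ndarray, shape (n_res, 37, 3)
        Coordinates in Angstrom; entries where ``atom_mask`` is False carry
        no meaning.
    atom_mask : ndarray of bool, shape (n_res, 37)
        True where the slot holds a real atom.
    residue_ids : list of int
        Author residue numbers, preserved for output.
    chain_id : str
        Single-character chain identifier.
    """

    sequence: str
    coords: np.ndarray
    atom_mask: np.ndarray
    residue_ids: list[int] = field(default_factory=list)
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.atom_mask = np.asarray(self.atom_mask, dtype=bool)
        n = len(self.sequence)
        if n < 1:
            raise ValidationError("structure must contain at least one residue")
        if self.coords.shape != (n, N_ATOM_TYPES, 3):
            raise ValidationError(
                f"coords shape {self.coords.shape} does not match "
                f"({n}, {N_ATOM_TYPES}, 3)"
            )
        if self.atom_mask.shape != (n, N_ATOM_TYPES):
            raise ValidationError("atom_mask shape does not match sequence length")
        if not self.residue_ids:
            self.residue_ids = list(range(1, n + 1))
        for aa in self.sequence:
            if aa not in RESIDUE_ATOMS:
                raise ValidationError(f"non-standard residue code {aa!r}")
        for idx in range(n):
            if self.atom_mask[idx].any():
                for name in _BACKBONE_REQUIRED:
                    if not self.atom_mask[idx, ATOM37_INDEX[name]]:
                        raise ValidationError(
                            f"residue {idx} ({self.sequence[idx]}"
                            f"{self.residue_ids[idx]}) is missing backbone atom {name}"
                        )

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_atoms(self) -> int:
        return int(self.atom_mask.sum())

    def flat_coords(self) -> np.ndarray:
        """Coordinates of present atoms, shape (n_atoms, 3), residue-major."""
        return self.coords[self.atom_mask]

    def with_flat_coords(self, flat: np.ndarray) -> "ProteinStructure":
        """Return a copy whose present-atom coordinates are replaced."""
        flat = np.asarray(flat, dtype=np.float64)
        if flat.shape != (self.n_atoms, 3):
            raise ValidationError(
                f"expected coordinates of shape ({self.n_atoms}, 3), got {flat.shape}"
            )
        coords = self.coords.copy()
        coords[self.atom_mask] = flat
        return replace(self, coords=coords)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """Apply the rigid motion ``x -> R x + t`` to all coordinates."""
        coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return replace(self, coords=coords)

    def ca_coords(self) -> np.ndarray:
        """Cα coordinates, shape (n_res, 3)."""
        return self.coords[:, ATOM37_INDEX["CA"], :]


def atom_slot(residue: str, atom_name: str) -> int | None:
    """Map a (1-letter residue, canonical atom name) to its atom37 slot.

    Returns ``None`` for atoms outside the residue's valid heavy-atom set
    (e.g. ``("G", "CB")``).
    """
    if residue not in RESIDUE_ATOMS:
        raise ValidationError(f"unknown residue code {residue!r}")
    if atom_name not in RESIDUE_ATOMS[residue]:
        return None
    return ATOM37_INDEX[atom_name]


def read_pdb(path: str | PathLike, chain: str | None = None) -> ProteinStructure:
    """Read one chain of a PDB file into atom37 layout.

    Hydrogens, waters, hetero records, non-standard residues and alternate
    locations other than ''/'A' are dropped.  ``chain`` selects the chain id;
    by default the first chain containing standard residues is used.
    """
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1, altloc="first")
    except Exception as exc:  # biotite raises various parse errors
        raise ParseError(f"could not parse PDB file {path}: {exc}") from exc

    keep = (~arr.hetero) & (arr.element != "H") & (arr.element != "D")
    arr = arr[keep]
    std = np.isin(arr.res_name, list(THREE_TO_ONE))
    arr = arr[std]
    if arr.array_length() == 0:
        raise ParseError(f"{path}: no standard-residue protein chain found")

    chain_ids = np.unique(arr.chain_id)
    if chain is None:
        chain = str(arr.chain_id[0])
    elif chain not in chain_ids:
        raise ParseError(f"{path}: chain {chain!r} not found (have {list(chain_ids)})")
    arr = arr[arr.chain_id == chain]
    if arr.array_length() == 0:
        raise ParseError(f"{path}: chain {chain!r} holds no standard residues")

    starts = bst.get_residue_starts(arr)
    n_res = len(starts)
    seq_chars: list[str] = []
    res_ids: list[int] = []
    coords = np.zeros((n_res, N_ATOM_TYPES, 3), dtype=np.float64)
    mask = np.zeros((n_res, N_ATOM_TYPES), dtype=bool)

    bounds = list(starts) + [arr.array_length()]
    for i in range(n_res):
        lo, hi = bounds[i], bounds[i + 1]
        aa = THREE_TO_ONE[arr.res_name[lo]]
        seq_chars.append(aa)
        res_ids.append(int(arr.res_id[lo]))
        for j in range(lo, hi):
            slot = atom_slot(aa, str(arr.atom_name[j]))
            if slot is None:
                continue
            coords[i, slot] = arr.coord[j]
            mask[i, slot] = True
        for name in _BACKBONE_REQUIRED:
            if not mask[i, ATOM37_INDEX[name]]:
                raise ValidationError(
                    f"{path}: residue {arr.res_name[lo]}{res_ids[-1]} of chain "
                    f"{chain} is missing backbone atom {name}"
                )

    return ProteinStructure(
        sequence="".join(seq_chars),
        coords=coords,
        atom_mask=mask,
        residue_ids=res_ids,
        chain_id=str(chain),
    )


def write_pdb(
    structure: ProteinStructure,
    path: str | PathLike,
    b_factors: np.ndarray | None = None,
) -> None:
    """Write present atoms as standard fixed-column ATOM records.

    ``b_factors`` optionally supplies one value per residue (e.g. a
    per-residue lDDT profile) written into the B-factor column of all the
    residue's atoms.
    """
    if b_factors is not None:
        b_factors = np.nan_to_num(np.asarray(b_factors, dtype=np.float64))
        if b_factors.shape != (structure.n_residues,):
            raise ValidationError("b_factors must hold one value per residue")
    n_atoms = structure.n_atoms
    arr = bst.AtomArray(n_atoms)
    idx = 0
    for i, aa in enumerate(structure.sequence):
        for slot in np.flatnonzero(structure.atom_mask[i]):
            name = ATOM37[slot]
            arr.chain_id[idx] = structure.chain_id
            arr.res_id[idx] = structure.residue_ids[i]
            arr.res_name[idx] = ONE_TO_THREE[aa]
            arr.atom_name[idx] = name
            arr.element[idx] = name[0]
            arr.coord[idx] = structure.coords[i, slot]
            idx += 1
    arr.set_annotation("occupancy", np.ones(n_atoms))
    if b_factors is None:
        arr.set_annotation("b_factor", np.zeros(n_atoms))
    else:
        arr.set_annotation(
            "b_factor", np.repeat(b_factors, structure.atom_mask.sum(axis=1))
        )
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def pair_model_native(
    model: ProteinStructure, native: ProteinStructure
) -> tuple[ProteinStructure, ProteinStructure]:
    """Restrict a model/native pair to their shared residues and atoms.

    Sequences must be identical position by position; per residue the atom
    masks are intersected, so metrics and shift targets are computed only on
    atoms present in both structures.
    """
    if len(model.sequence) != len(native.sequence):
        raise ValidationError(
            f"sequence length mismatch: model {len(model.sequence)} vs "
            f"native {len(native.sequence)}"
        )
    for pos, (a, b) in enumerate(zip(model.sequence, native.sequence)):
        if a != b:
            raise ValidationError(
                f"sequence mismatch at position {pos}: model {a!r} vs native {b!r}"
            )
    shared = model.atom_mask & native.atom_mask
    m = replace(model, atom_mask=shared.copy())
    n = replace(native, atom_mask=shared.copy())
    return m, n
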