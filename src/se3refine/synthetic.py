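"""Synthetic native/initial structure pairs with controllable perturbation.

Training a refiner needs (initial model, native structure) pairs.  This
module builds chemically plausible all-atom "natives" from ideal internal
coordinates (bond lengths/angles from small-molecule averages, φ/ψ set by
secondary-structure type, one idealized rotamer per residue type) and
derives "initial models" by perturbing them: Gaussian backbone-torsion
noise, isotropic Cartesian jitter, and optional rigid displacement of a
contiguous segment.  The construction knows its own covalent topology,
which the graph module's distance-based bond detection can be checked
against.

These fixtures emulate the magnitude and locality of errors in predicted
structural models, not their physical realism: there is no rotamer
diversity, no clash relaxation, and perturbations are statistically simple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atoms import ATOM37_INDEX, N_ATOM_TYPES, AA1, RESIDUE_ATOMS, residue_bonds
from .errors import ValidationError
from .metrics import kabsch_superpose
from .structure import ProteinStructure
from .training import TrainingPair

# Ideal backbone geometry (Å, degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

PHI_PSI = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
}
_COIL_BASINS = ((-57.0, -47.0), (-139.0, 135.0), (-75.0, 145.0))

# Side-chain internal-coordinate templates: one idealized rotamer per
# residue.  Each entry places `atom` bonded to `c` with the stated bond
# length, angle b-c-atom and dihedral a-b-c-atom (degrees).
_SIDE_TEMPLATES: dict[str, tuple[tuple[str, str, str, str, float, float, float], ...]] = {
    "A": (),
    "G": (),
    "S": (("OG", "N", "CA", "CB", 1.417, 110.8, 180.0),),
    "C": (("SG", "N", "CA", "CB", 1.808, 113.8, 180.0),),
    "T": (
        ("OG1", "N", "CA", "CB", 1.433, 109.6, 180.0),
        ("CG2", "N", "CA", "CB", 1.521, 110.5, -60.0),
    ),
    "V": (
        ("CG1", "N", "CA", "CB", 1.527, 110.5, 180.0),
        ("CG2", "N", "CA", "CB", 1.527, 110.5, -60.0),
    ),
    "L": (
        ("CG", "N", "CA", "CB", 1.530, 116.3, 180.0),
        ("CD1", "CA", "CB", "CG", 1.524, 110.7, 180.0),
        ("CD2", "CA", "CB", "CG", 1.525, 110.7, 60.0),
    ),
    "I": (
        ("CG1", "N", "CA", "CB", 1.530, 110.4, 180.0),
        ("CG2", "N", "CA", "CB", 1.530, 110.5, -60.0),
        ("CD1", "CA", "CB", "CG1", 1.513, 113.8, 180.0),
    ),
    "M": (
        ("CG", "N", "CA", "CB", 1.520, 114.0, 180.0),
        ("SD", "CA", "CB", "CG", 1.807, 112.7, 180.0),
        ("CE", "CB", "CG", "SD", 1.789, 100.9, 180.0),
    ),
    "K": (
        ("CG", "N", "CA", "CB", 1.520, 114.0, 180.0),
        ("CD", "CA", "CB", "CG", 1.520, 111.3, 180.0),
        ("CE", "CB", "CG", "CD", 1.520, 111.3, 180.0),
        ("NZ", "CG", "CD", "CE", 1.489, 111.9, 180.0),
    ),
    "R": (
        ("CG", "N", "CA", "CB", 1.520, 114.0, 180.0),
        ("CD", "CA", "CB", "CG", 1.520, 111.3, 180.0),
        ("NE", "CB", "CG", "CD", 1.460, 112.0, 180.0),
        ("CZ", "CG", "CD", "NE", 1.330, 124.2, 180.0),
        ("NH1", "CD", "NE", "CZ", 1.326, 120.0, 0.0),
        ("NH2", "CD", "NE", "CZ", 1.326, 120.0, 180.0),
    ),
    "D": (
        ("CG", "N", "CA", "CB", 1.516, 112.6, 180.0),
        ("OD1", "CA", "CB", "CG", 1.249, 118.4, 0.0),
        ("OD2", "CA", "CB", "CG", 1.249, 118.4, 180.0),
    ),
    "N": (
        ("CG", "N", "CA", "CB", 1.516, 112.6, 180.0),
        ("OD1", "CA", "CB", "CG", 1.231, 120.8, 0.0),
        ("ND2", "CA", "CB", "CG", 1.328, 116.4, 180.0),
    ),
    "E": (
        ("CG", "N", "CA", "CB", 1.520, 114.0, 180.0),
        ("CD", "CA", "CB", "CG", 1.516, 112.6, 180.0),
        ("OE1", "CB", "CG", "CD", 1.249, 118.4, 0.0),
        ("OE2", "CB", "CG", "CD", 1.249, 118.4, 180.0),
    ),
    "Q": (
        ("CG", "N", "CA", "CB", 1.520, 114.0, 180.0),
        ("CD", "CA", "CB", "CG", 1.516, 112.6, 180.0),
        ("OE1", "CB", "CG", "CD", 1.231, 120.8, 0.0),
        ("NE2", "CB", "CG", "CD", 1.328, 116.4, 180.0),
    ),
    "H": (
        ("CG", "N", "CA", "CB", 1.490, 113.8, 180.0),
        ("ND1", "CA", "CB", "CG", 1.378, 122.7, 90.0),
        ("CD2", "CA", "CB", "CG", 1.354, 131.2, -90.0),
        ("CE1", "CD2", "CG", "ND1", 1.320, 109.3, 0.0),
        ("NE2", "ND1", "CG", "CD2", 1.374, 107.0, 0.0),
    ),
    "F": (
        ("CG", "N", "CA", "CB", 1.500, 113.8, 180.0),
        ("CD1", "CA", "CB", "CG", 1.390, 120.8, 90.0),
        ("CD2", "CA", "CB", "CG", 1.390, 120.8, -90.0),
        ("CE1", "CB", "CG", "CD1", 1.390, 120.0, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.390, 120.0, 180.0),
        ("CZ", "CG", "CD1", "CE1", 1.390, 120.0, 0.0),
    ),
    "Y": (
        ("CG", "N", "CA", "CB", 1.500, 113.8, 180.0),
        ("CD1", "CA", "CB", "CG", 1.390, 120.8, 90.0),
        ("CD2", "CA", "CB", "CG", 1.390, 120.8, -90.0),
        ("CE1", "CB", "CG", "CD1", 1.390, 120.0, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.390, 120.0, 180.0),
        ("CZ", "CG", "CD1", "CE1", 1.390, 120.0, 0.0),
        ("OH", "CD1", "CE1", "CZ", 1.376, 119.9, 180.0),
    ),
    "W": (
        ("CG", "N", "CA", "CB", 1.500, 113.6, 180.0),
        ("CD1", "CA", "CB", "CG", 1.365, 126.9, 90.0),
        ("CD2", "CA", "CB", "CG", 1.433, 126.6, -90.0),
        ("NE1", "CD2", "CG", "CD1", 1.375, 110.2, 0.0),
        ("CE2", "CD1", "CG", "CD2", 1.413, 107.2, 0.0),
        ("CE3", "CD1", "CG", "CD2", 1.400, 133.9, 180.0),
        ("CZ2", "CG", "CD2", "CE2", 1.400, 122.4, 180.0),
        ("CZ3", "CG", "CD2", "CE3", 1.390, 118.6, 180.0),
        ("CH2", "CD2", "CE2", "CZ2", 1.370, 117.5, 0.0),
    ),
    "P": (
        ("CG", "N", "CA", "CB", 1.495, 104.5, 30.0),
        ("CD", "CA", "CB", "CG", 1.507, 106.1, -35.0),
    ),
}

# Dihedral C-N-CA-CB placing CB with L-amino-acid chirality.
_CB_DIHEDRAL = -122.6
_CB_LENGTH = 1.522
_CB_ANGLE = 110.4


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    length: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """NeRF placement: position d with |cd| = length, ∠(b,c,d) = angle and
    dihedral(a,b,c,d) = dihedral."""
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        raise ValidationError("degenerate reference atoms in internal-coordinate build")
    n /= norm
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -length * np.cos(ang),
            length * np.sin(ang) * np.cos(dih),
            length * np.sin(ang) * np.sin(dih),
        ]
    )
    return c + np.column_stack([bc, m, n]) @ d2


@dataclass(frozen=True)
class PerturbSpec:
    """How an "initial model" deviates from its native structure.

    cartesian_sigma : isotropic Gaussian jitter per atom coordinate (Å).
    torsion_sigma : standard deviation of backbone φ/ψ noise (degrees).
    block_shift : optional (fraction_of_residues, displacement_Å) rigid
        displacement of one contiguous segment, emulating domain-level error.
    """

    cartesian_sigma: float = 0.5
    torsion_sigma: float = 0.0
    block_shift: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.cartesian_sigma < 0 or self.torsion_sigma < 0:
            raise ValidationError("sigmas must be non-negative")
        if self.block_shift is not None and not (0 <= self.block_shift[0] <= 1):
            raise ValidationError("block fraction must be in [0, 1]")


def _sample_torsions(n: int, geometry: str, rng: np.random.Generator):
    if geometry in PHI_PSI:
        phi, psi = PHI_PSI[geometry]
        return np.full(n, phi), np.full(n, psi)
    if geometry == "coil":
        basins = rng.integers(0, len(_COIL_BASINS), size=n)
        phi = np.array([_COIL_BASINS[b][0] for b in basins]) + rng.normal(0, 10, n)
        psi = np.array([_COIL_BASINS[b][1] for b in basins]) + rng.normal(0, 10, n)
        return phi, psi
    raise ValidationError(f"unknown geometry {geometry!r} (helix|strand|coil)")


def make_native(
    n_residues: int,
    sequence: str | None = None,
    geometry: str = "helix",
    seed: int = 0,
) -> ProteinStructure:
    """Build an idealized all-atom native structure.

    ``sequence`` defaults to a seeded random draw over the 20 standard
    residues; ``geometry`` sets the backbone φ/ψ (ideal helix −57/−47,
    extended strand, or a coil sampled across basins).
    """
    if n_residues < 3:
        raise ValidationError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "".join(rng.choice(list(AA1), size=n_residues))
    if len(sequence) != n_residues:
        raise ValidationError("sequence length does not match n_residues")
    phi, psi = _sample_torsions(n_residues, geometry, rng)

    coords = np.zeros((n_residues, N_ATOM_TYPES, 3))
    mask = np.zeros((n_residues, N_ATOM_TYPES), dtype=bool)

    def put(i, name, pos):
        coords[i, ATOM37_INDEX[name]] = pos
        mask[i, ATOM37_INDEX[name]] = True

    def get(i, name):
        return coords[i, ATOM37_INDEX[name]]

    # backbone
    for i in range(n_residues):
        if i == 0:
            n_pos = np.zeros(3)
            ca = np.array([BOND_N_CA, 0.0, 0.0])
            ang = np.deg2rad(ANGLE_N_CA_C)
            c = ca + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            n_pos = place_atom(
                get(i - 1, "N"), get(i - 1, "CA"), get(i - 1, "C"),
                BOND_C_N, ANGLE_CA_C_N, psi[i - 1],
            )
            ca = place_atom(
                get(i - 1, "CA"), get(i - 1, "C"), n_pos,
                BOND_N_CA, ANGLE_C_N_CA, OMEGA,
            )
            c = place_atom(
                get(i - 1, "C"), n_pos, ca, BOND_CA_C, ANGLE_N_CA_C, phi[i]
            )
        put(i, "N", n_pos)
        put(i, "CA", ca)
        put(i, "C", c)

    # carbonyl O and side chains (need residue i+1's N direction via psi)
    for i in range(n_residues):
        put(
            i, "O",
            place_atom(
                get(i, "N"), get(i, "CA"), get(i, "C"),
                BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0,
            ),
        )
        aa = sequence[i]
        if aa != "G":
            put(
                i, "CB",
                place_atom(
                    get(i, "C"), get(i, "N"), get(i, "CA"),
                    _CB_LENGTH, _CB_ANGLE, _CB_DIHEDRAL,
                ),
            )
        for name, a, b, c3, length, angle, dihedral in _SIDE_TEMPLATES[aa]:
            put(i, name, place_atom(get(i, a), get(i, b), get(i, c3), length, angle, dihedral))

    return ProteinStructure(
        sequence=sequence, coords=coords, atom_mask=mask, chain_id="A"
    )


def known_bond_pairs(structure: ProteinStructure) -> set[tuple[int, int]]:
    """Covalent topology by construction, as unordered flat-atom index pairs.

    Flat indices follow ``ProteinStructure.flat_coords`` ordering
    (residue-major, atom37 slot order).
    """
    flat_index = -np.ones((structure.n_residues, N_ATOM_TYPES), dtype=np.int64)
    flat_index[structure.atom_mask] = np.arange(structure.n_atoms)

    def fi(res: int, name: str) -> int:
        return int(flat_index[res, ATOM37_INDEX[name]])

    pairs: set[tuple[int, int]] = set()
    for i, aa in enumerate(structure.sequence):
        for a, b in residue_bonds(aa):
            if (
                structure.atom_mask[i, ATOM37_INDEX[a]]
                and structure.atom_mask[i, ATOM37_INDEX[b]]
            ):
                x, y = fi(i, a), fi(i, b)
                pairs.add((min(x, y), max(x, y)))
        if structure.atom_mask[i, ATOM37_INDEX["OXT"]]:
            x, y = fi(i, "C"), fi(i, "OXT")
            pairs.add((min(x, y), max(x, y)))
        if i + 1 < structure.n_residues:
            x, y = fi(i, "C"), fi(i + 1, "N")
            pairs.add((min(x, y), max(x, y)))
    return pairs


def _rotate_about_axis(
    coords: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle_rad: float
) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    k_mat = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    rot = (
        np.eye(3)
        + np.sin(angle_rad) * k_mat
        + (1 - np.cos(angle_rad)) * (k_mat @ k_mat)
    )
    return (coords - origin) @ rot.T + origin


def perturb(native: ProteinStructure, spec: PerturbSpec | None = None) -> ProteinStructure:
    """Derive an "initial model": torsion noise, then jitter, then block shift."""
    spec = spec or PerturbSpec()
    rng = np.random.default_rng(spec.seed)
    coords = native.coords.copy()
    mask = native.atom_mask
    n_res = native.n_residues
    i_n, i_ca, i_c, i_o = (ATOM37_INDEX[x] for x in ("N", "CA", "C", "O"))

    if spec.torsion_sigma > 0:
        for i in range(n_res):
            dphi, dpsi = np.deg2rad(
                rng.normal(0, spec.torsion_sigma, size=2)
            )
            # φ: rotate everything downstream of CA_i (side chain, C, O,
            # later residues) about the N-CA axis
            moving = np.zeros((n_res, N_ATOM_TYPES), dtype=bool)
            moving[i] = mask[i]
            moving[i, i_n] = False
            moving[i + 1:] = mask[i + 1:]
            moving[i, i_ca] = False
            sel = moving & mask
            coords[sel] = _rotate_about_axis(
                coords[sel], coords[i, i_ca], coords[i, i_ca] - coords[i, i_n], dphi
            )
            # ψ: rotate O_i and later residues about the CA-C axis
            moving = np.zeros((n_res, N_ATOM_TYPES), dtype=bool)
            moving[i, i_o] = mask[i, i_o]
            moving[i + 1:] = mask[i + 1:]
            sel = moving & mask
            coords[sel] = _rotate_about_axis(
                coords[sel], coords[i, i_c], coords[i, i_c] - coords[i, i_ca], dpsi
            )

    if spec.cartesian_sigma > 0:
        coords[mask] = coords[mask] + rng.normal(
            0, spec.cartesian_sigma, size=(int(mask.sum()), 3)
        )

    if spec.block_shift is not None:
        frac, magnitude = spec.block_shift
        length = max(1, int(round(frac * n_res)))
        start = int(rng.integers(0, n_res - length + 1))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coords[start : start + length] += magnitude * direction

    return ProteinStructure(
        sequence=native.sequence,
        coords=coords,
        atom_mask=mask.copy(),
        residue_ids=list(native.residue_ids),
        chain_id=native.chain_id,
    )


def make_dataset(
    n_pairs: int,
    length_range: tuple[int, int] = (12, 24),
    spec: PerturbSpec | None = None,
    seed: int = 0,
) -> tuple[list[TrainingPair], pd.DataFrame]:
    """Seeded dataset of (native, perturbed initial) training pairs.

    Returns the pairs and a manifest with per-pair sizes and initial-model
    Cα / all-atom RMSD to native (after superposition).
    """
    if n_pairs < 1:
        raise ValidationError("n_pairs must be >= 1")
    spec = spec or PerturbSpec()
    rng = np.random.default_rng(seed)
    geometries = ("helix", "strand", "coil")
    pairs: list[TrainingPair] = []
    rows = []
    for idx in range(n_pairs):
        n_res = int(rng.integers(length_range[0], length_range[1] + 1))
        geometry = geometries[int(rng.integers(0, 3))]
        sub = int(rng.integers(0, 2**31 - 1))
        native = make_native(n_res, geometry=geometry, seed=sub)
        initial = perturb(
            native,
            PerturbSpec(
                cartesian_sigma=spec.cartesian_sigma,
                torsion_sigma=spec.torsion_sigma,
                block_shift=spec.block_shift,
                seed=int(rng.integers(0, 2**31 - 1)),
            ),
        )
        pair = TrainingPair(initial=initial, native=native)
        _, _, rmsd_ca = kabsch_superpose(initial.ca_coords(), native.ca_coords())
        _, _, rmsd_all = kabsch_superpose(initial.flat_coords(), native.flat_coords())
        rows.append(
            {
                "pair": idx,
                "n_residues": n_res,
                "geometry": geometry,
                "rmsd_ca_init": rmsd_ca,
                "rmsd_allatom_init": rmsd_all,
            }
        )
        pairs.append(pair)
    return pairs, pd.DataFrame(rows)
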