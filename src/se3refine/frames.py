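"""Residue-local orthonormal coordinate frames from backbone N, Cα, C.

Each residue defines a right-handed basis with origin at Cα: the y axis
points from Cα to N, z is the unit normal of the C-Cα-N plane
(z = u × y / |u × y| with u the Cα→C unit vector), and x = y × z completes
the basis.  All atoms of a residue share that residue's frame, which is what
makes the relative-position and relative-orientation edge features rigid-
motion invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atoms import ATOM37_INDEX
from .errors import DegenerateFrameError
from .structure import ProteinStructure

_COLLINEAR_TOL = 1e-6


@dataclass(frozen=True)
class ResidueFrame:
    origin: np.ndarray   # Cα position, Å
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def basis(self) -> np.ndarray:
        """Column matrix [x y z]; maps frame coordinates to world."""
        return np.stack([self.x_axis, self.y_axis, self.z_axis], axis=1)


def compute_frame(
    n_pos: np.ndarray,
    ca_pos: np.ndarray,
    c_pos: np.ndarray,
    residue_index: int | None = None,
) -> ResidueFrame:
    """Build the local frame of one residue from its N, Cα and C positions."""
    n_pos = np.asarray(n_pos, dtype=np.float64)
    ca_pos = np.asarray(ca_pos, dtype=np.float64)
    c_pos = np.asarray(c_pos, dtype=np.float64)

    y_raw = n_pos - ca_pos
    u_raw = c_pos - ca_pos
    ny, nu = np.linalg.norm(y_raw), np.linalg.norm(u_raw)
    if ny < _COLLINEAR_TOL or nu < _COLLINEAR_TOL:
        raise DegenerateFrameError(
            f"coincident backbone atoms in residue {residue_index}", residue_index
        )
    y = y_raw / ny
    u = u_raw / nu
    z_raw = np.cross(u, y)
    nz = np.linalg.norm(z_raw)
    if nz < _COLLINEAR_TOL:
        raise DegenerateFrameError(
            f"collinear N, CA, C in residue {residue_index}", residue_index
        )
    z = z_raw / nz
    x = np.cross(y, z)
    return ResidueFrame(origin=ca_pos, x_axis=x, y_axis=y, z_axis=z)


def compute_all_frames(structure: ProteinStructure) -> list[ResidueFrame]:
    """One frame per residue, from the residue's own backbone atoms."""
    i_n, i_ca, i_c = ATOM37_INDEX["N"], ATOM37_INDEX["CA"], ATOM37_INDEX["C"]
    frames = []
    for i in range(structure.n_residues):
        for slot, name in ((i_n, "N"), (i_ca, "CA"), (i_c, "C")):
            if not structure.atom_mask[i, slot]:
                raise DegenerateFrameError(
                    f"residue {i} is missing backbone atom {name}", i
                )
        frames.append(
            compute_frame(
                structure.coords[i, i_n],
                structure.coords[i, i_ca],
                structure.coords[i, i_c],
                residue_index=i,
            )
        )
    return frames
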