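"""All-atom KNN graph with invariant node and edge features.

Nodes are heavy atoms; each node receives directed edges from its k nearest
atoms by Euclidean distance.  Node scalars are a 37-way atom-type one-hot
concatenated with a 20-way residue-type one-hot (57 features).  Each edge
carries 49 scalars, all invariant under rigid motion of the structure:

* 36 Gaussian radial-basis encodings of the interatomic distance, centred at
  0, σ_d, 2σ_d, …, 35σ_d with σ_d = 0.57 Å (grid spans 0–20 Å);
* 1 covalent-bond flag, set when the distance lies between 0.4 Å and the sum
  of the two elements' covalent radii plus a tolerance;
* 3 relative-position components: the source→destination displacement
  expressed in the source residue's local frame;
* 9 relative-orientation components: the destination residue's frame axes
  expressed in the source residue's frame (an orthogonal 3×3, flattened).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .atoms import (
    ATOM37_INDEX,
    COVALENT_RADII,
    DEFAULT_BOND_TOLERANCE,
    ELEMENTS,
    AA1_INDEX,
    N_ATOM_TYPES,
    N_RESIDUE_TYPES,
)
from .errors import ValidationError
from .frames import ResidueFrame, compute_all_frames
from .structure import ProteinStructure

NODE_FEATURE_DIM = N_ATOM_TYPES + N_RESIDUE_TYPES  # 57
EDGE_FEATURE_DIM = 36 + 1 + 3 + 9  # 49

_BACKBONE_SLOTS = tuple(ATOM37_INDEX[n] for n in ("N", "CA", "C", "O"))


@dataclass(frozen=True)
class GraphConfig:
    """Hyperparameters of the graph featurization."""

    k_neighbors: int = 128
    sigma_d: float = 0.57
    n_rbf: int = 36
    bond_lower: float = 0.4
    bond_tolerance: float = DEFAULT_BOND_TOLERANCE
    covalent_radii: dict = field(default_factory=lambda: dict(COVALENT_RADII))
    backbone_only: bool = False
    symmetrize: bool = False

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValidationError("k_neighbors must be >= 1")
        if self.sigma_d <= 0:
            raise ValidationError("sigma_d must be positive")
        if self.n_rbf < 1:
            raise ValidationError("n_rbf must be >= 1")

    @property
    def rbf_centers(self) -> np.ndarray:
        return self.sigma_d * np.arange(self.n_rbf)


@dataclass
class AtomGraph:
    """Directed KNN atom graph with invariant scalar features."""

    node_coords: np.ndarray      # [n, 3] Å
    node_scalars: np.ndarray     # [n, 57]
    node_to_residue: np.ndarray  # [n] residue index per node
    node_slot: np.ndarray        # [n] atom37 slot per node
    src: np.ndarray              # [E] source node of each edge
    dst: np.ndarray              # [E] destination node of each edge
    edge_scalars: np.ndarray     # [E, 49]

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_edges(self) -> int:
        return self.src.shape[0]


def build_knn_edges(coords: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Directed edges (src → dst): each node's min(k, n−1) nearest others.

    Ties in distance are broken by the lower source index, making the edge
    list deterministic.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValidationError("coords must have shape (n, 3)")
    n = coords.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 atoms to build edges")
    if not np.isfinite(coords).all():
        raise ValidationError("non-finite coordinates")
    kk = min(k, n - 1)

    if n <= 2048:
        d = np.linalg.norm(coords[None, :, :] - coords[:, None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        # quantize to 1e-6 Å so exact geometric ties (and their float noise
        # under rigid motion) resolve identically, then stable-sort so ties
        # break by lower source index
        dq = np.round(d * 1e6)
        order = np.argsort(dq, axis=1, kind="stable")[:, :kk]
        dst = np.repeat(np.arange(n), kk)
        src = order.reshape(-1)
    else:
        tree = cKDTree(coords)
        dd, order = tree.query(coords, k=kk + 1)
        # drop self (distance 0 column), keep kk neighbours per node
        src_rows = []
        for i in range(n):
            row = [j for j in order[i] if j != i][:kk]
            src_rows.append(row)
        src = np.asarray(src_rows).reshape(-1)
        dst = np.repeat(np.arange(n), kk)
    return src.astype(np.int64), dst.astype(np.int64)


def rbf_encode(d: float | np.ndarray, cfg: GraphConfig | None = None) -> np.ndarray:
    """Gaussian radial-basis expansion exp(−((d − d′)/σ_d)²) over the grid d′."""
    cfg = cfg or GraphConfig()
    d = np.asarray(d, dtype=np.float64)
    if not np.isfinite(d).all() or (d < 0).any():
        raise ValidationError("distances must be finite and non-negative")
    centers = cfg.rbf_centers
    return np.exp(-(((d[..., None] - centers) / cfg.sigma_d) ** 2))


def covalent_bond_flag(
    d_ij: float | np.ndarray,
    element_i: str | np.ndarray,
    element_j: str | np.ndarray,
    cfg: GraphConfig | None = None,
) -> np.ndarray:
    """1 when 0.4 Å < d < r_i + r_j + tolerance, else 0."""
    cfg = cfg or GraphConfig()
    elems_i = np.atleast_1d(np.asarray(element_i))
    elems_j = np.atleast_1d(np.asarray(element_j))
    for e in np.unique(np.concatenate([elems_i, elems_j])):
        if str(e) not in cfg.covalent_radii:
            raise ValidationError(f"no covalent radius for element {e!r}")
    radius = np.vectorize(lambda e: cfg.covalent_radii[str(e)])
    thresh = radius(elems_i) + radius(elems_j) + cfg.bond_tolerance
    d = np.atleast_1d(np.asarray(d_ij, dtype=np.float64))
    flag = ((d > cfg.bond_lower) & (d < thresh)).astype(np.float64)
    return flag if flag.size > 1 else flag.reshape(())


def relative_position(
    frame_i: ResidueFrame, atom_j: np.ndarray, atom_i: np.ndarray
) -> np.ndarray:
    """Displacement atom_i → atom_j expressed in residue i's local basis."""
    delta = np.asarray(atom_j, dtype=np.float64) - np.asarray(atom_i, dtype=np.float64)
    return frame_i.basis().T @ delta


def relative_orientation(frame_i: ResidueFrame, frame_j: ResidueFrame) -> np.ndarray:
    """Frame j's axes in frame i's basis: [Bᵢᵀxⱼ, Bᵢᵀyⱼ, Bᵢᵀzⱼ] flattened (9,)."""
    m = frame_i.basis().T @ frame_j.basis()
    return m.T.reshape(9)  # stacked columns: q, k, t


def build_graph(structure: ProteinStructure, cfg: GraphConfig | None = None) -> AtomGraph:
    """Featurize a structure into its all-atom (or backbone-only) KNN graph."""
    cfg = cfg or GraphConfig()
    mask = structure.atom_mask
    if cfg.backbone_only:
        restricted = np.zeros_like(mask)
        restricted[:, list(_BACKBONE_SLOTS)] = mask[:, list(_BACKBONE_SLOTS)]
        mask = restricted

    res_idx, slot_idx = np.nonzero(mask)
    if res_idx.size < 2:
        raise ValidationError("structure yields fewer than 2 graph nodes")
    coords = structure.coords[res_idx, slot_idx]

    node_scalars = np.zeros((res_idx.size, NODE_FEATURE_DIM), dtype=np.float64)
    node_scalars[np.arange(res_idx.size), slot_idx] = 1.0
    aa_idx = np.array([AA1_INDEX[structure.sequence[r]] for r in res_idx])
    node_scalars[np.arange(res_idx.size), N_ATOM_TYPES + aa_idx] = 1.0

    src, dst = build_knn_edges(coords, cfg.k_neighbors)
    if cfg.symmetrize:
        pairs = np.unique(
            np.concatenate(
                [np.stack([src, dst], axis=1), np.stack([dst, src], axis=1)], axis=0
            ),
            axis=0,
        )
        src, dst = pairs[:, 0], pairs[:, 1]

    frames = compute_all_frames(structure)
    basis = np.stack([f.basis() for f in frames])  # [n_res, 3, 3]

    delta = coords[dst] - coords[src]
    dist = np.linalg.norm(delta, axis=1)
    rbf = rbf_encode(dist, cfg)  # [E, 36]

    elems = np.array(ELEMENTS)[slot_idx]
    bond = np.asarray(
        covalent_bond_flag(dist, elems[src], elems[dst], cfg), dtype=np.float64
    ).reshape(-1, 1)

    b_src = basis[res_idx[src]]  # [E, 3, 3]
    rel_pos = np.einsum("ewa,ew->ea", b_src, delta)  # Bᵢᵀ (xⱼ − xᵢ)
    m = np.einsum("ewa,ewb->eab", b_src, basis[res_idx[dst]])  # BᵢᵀBⱼ
    rel_ori = m.transpose(0, 2, 1).reshape(-1, 9)  # columns q,k,t stacked

    edge_scalars = np.concatenate([rbf, bond, rel_pos, rel_ori], axis=1)
    assert edge_scalars.shape[1] == EDGE_FEATURE_DIM

    return AtomGraph(
        node_coords=coords,
        node_scalars=node_scalars,
        node_to_residue=res_idx.astype(np.int64),
        node_slot=slot_idx.astype(np.int64),
        src=src,
        dst=dst,
        edge_scalars=edge_scalars,
    )
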