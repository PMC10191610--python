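"""KNN graph construction and the six invariant edge-feature families."""

import numpy as np
import pytest

from se3refine.atoms import ATOM37_INDEX, ELEMENTS
from se3refine.errors import ValidationError
from se3refine.frames import compute_frame
from se3refine.graph import (
    GraphConfig,
    build_graph,
    build_knn_edges,
    covalent_bond_flag,
    rbf_encode,
    relative_orientation,
    relative_position,
)
from se3refine.synthetic import known_bond_pairs, make_native

from conftest import random_rigid


class TestKnnEdges:
    def test_k_capped_at_n_minus_one(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(5, 3))
        src, dst = build_knn_edges(coords, 128)
        assert len(src) == 5 * 4
        assert np.all(np.bincount(dst) == 4)
        assert not np.any(src == dst)

    def test_line_neighbors(self):
        """Brute-force check on four collinear atoms at 0,1,2,3 Å."""
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        src, dst = build_knn_edges(coords, 2)
        incoming0 = sorted(src[dst == 0])
        assert incoming0 == [1, 2]

    def test_rigid_invariance(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(30, 3)) * 5
        src, dst = build_knn_edges(coords, 6)
        rot, t = random_rigid(rng)
        src2, dst2 = build_knn_edges(coords @ rot.T + t, 6)
        assert np.array_equal(src, src2) and np.array_equal(dst, dst2)

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            build_knn_edges(np.zeros((1, 3)), 3)
        with pytest.raises(ValidationError):
            build_knn_edges(np.array([[0.0, 0, np.nan], [1, 0, 0]]), 1)


class TestRbf:
    def test_grid_values(self):
        v = rbf_encode(0.0)
        assert v.shape == (36,)
        assert v[0] == pytest.approx(1.0)
        v = rbf_encode(0.57)
        assert v[1] == pytest.approx(1.0)
        assert v[0] == pytest.approx(np.exp(-1), rel=1e-12)
        assert v[2] == pytest.approx(np.exp(-1), rel=1e-12)
        v = rbf_encode(35 * 0.57)
        assert v[-1] == pytest.approx(1.0)
        # components at far centers underflow to 0.0 in float64
        assert ((v >= 0) & (v <= 1)).all()

    def test_peak_at_nearest_center(self):
        cfg = GraphConfig()
        for d in np.random.default_rng(2).uniform(0, 20, size=50):
            v = rbf_encode(float(d), cfg)
            assert np.argmax(v) == np.argmin(np.abs(cfg.rbf_centers - d))

    def test_invalid_distance(self):
        with pytest.raises(ValidationError):
            rbf_encode(-0.1)
        with pytest.raises(ValidationError):
            rbf_encode(np.nan)


class TestBondFlag:
    def test_lower_cutoff(self):
        assert covalent_bond_flag(0.3, "C", "C") == 0
        assert covalent_bond_flag(0.0, "C", "C") == 0

    def test_cc_bond(self):
        # C-C threshold: 0.77 + 0.77 + 0.56 = 2.10 Å
        assert covalent_bond_flag(1.54, "C", "C") == 1
        assert covalent_bond_flag(2.2, "C", "C") == 0

    def test_unknown_element(self):
        with pytest.raises(ValidationError):
            covalent_bond_flag(1.0, "C", "Zz")

    @pytest.mark.parametrize("geometry,sequence", [
        ("strand", "ACDEFGHIKLMNPQRSTVWY"),
        ("helix", "A" * 10),
    ])
    def test_topology_oracle(self, geometry, sequence):
        """Distance-detected bonds equal the construction topology exactly."""
        s = make_native(len(sequence), sequence=sequence, geometry=geometry, seed=3)
        known = known_bond_pairs(s)
        x = s.flat_coords()
        elems = np.array(ELEMENTS)[np.nonzero(s.atom_mask)[1]]
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        ii, jj = np.triu_indices(len(x), k=1)
        flags = covalent_bond_flag(d[ii, jj], elems[ii], elems[jj])
        detected = {(int(i), int(j)) for i, j, f in zip(ii, jj, flags) if f}
        assert detected == known


class TestRelativeGeometry:
    def test_identity_frame_position(self):
        f = compute_frame([0, 1.46, 0], [0, 0, 0], [1.52, 0, 0])
        p = relative_position(f, np.array([1.0, 2, 3]), np.zeros(3))
        assert np.allclose(p, [1, 2, 3], atol=1e-12)
        assert np.allclose(relative_position(f, np.ones(3), np.ones(3)), 0)

    def test_position_rigid_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            pts = rng.normal(size=(3, 3)) * 3
            f = compute_frame(*pts)
            ai, aj = rng.normal(size=(2, 3))
            p = relative_position(f, aj, ai)
            rot, t = random_rigid(rng)
            f2 = compute_frame(*(pts @ rot.T + t))
            p2 = relative_position(f2, rot @ aj + t, rot @ ai + t)
            assert np.allclose(p, p2, atol=1e-9)

    def test_orientation_identity_and_rotation(self):
        f = compute_frame([0, 1.46, 0], [0, 0, 0], [1.52, 0, 0])
        assert np.allclose(relative_orientation(f, f), np.eye(3).reshape(9), atol=1e-12)
        # frame rotated 90° about z: x -> y, y -> -x
        c, s = 0.0, 1.0
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        from se3refine.frames import ResidueFrame

        g = ResidueFrame(
            origin=np.zeros(3),
            x_axis=rot @ f.x_axis,
            y_axis=rot @ f.y_axis,
            z_axis=rot @ f.z_axis,
        )
        q, k, t = relative_orientation(f, g).reshape(3, 3)
        assert np.allclose(q, [0, 1, 0], atol=1e-12)   # x_j in frame i
        assert np.allclose(k, [-1, 0, 0], atol=1e-12)  # y_j in frame i
        assert np.allclose(t, [0, 0, 1], atol=1e-12)


class TestBuildGraph:
    def test_polyalanine_shapes(self, helix_ala):
        g = build_graph(helix_ala, GraphConfig())
        assert g.n_nodes == 50  # 10 residues x 5 heavy atoms
        assert np.all(np.bincount(g.dst) == 49)
        assert g.node_scalars.shape == (50, 57)
        assert g.edge_scalars.shape == (50 * 49, 49)
        assert np.all(g.node_scalars.sum(axis=1) == 2)  # two one-hots per node

    def test_edge_features_rigid_invariant(self, helix_mixed):
        rng = np.random.default_rng(4)
        g = build_graph(helix_mixed)
        for _ in range(5):
            rot, t = random_rigid(rng)
            g2 = build_graph(helix_mixed.transformed(rot, t))
            assert np.array_equal(g.src, g2.src)
            assert np.array_equal(g.node_scalars, g2.node_scalars)
            assert np.abs(g.edge_scalars - g2.edge_scalars).max() < 1e-7
            assert np.allclose(g2.node_coords, g.node_coords @ rot.T + t)

    def test_orientation_blocks_orthogonal(self, helix_mixed):
        g = build_graph(helix_mixed)
        m = g.edge_scalars[:, 40:].reshape(-1, 3, 3)
        prod = np.einsum("eij,ekj->eik", m, m)
        assert np.abs(prod - np.eye(3)).max() < 1e-6
        assert np.allclose(np.abs(np.linalg.det(m)), 1, atol=1e-6)

    def test_rbf_block_range(self, helix_mixed):
        g = build_graph(helix_mixed)
        rbf = g.edge_scalars[:, :36]
        assert ((rbf >= 0) & (rbf <= 1)).all()
        assert (rbf.max(axis=1) > 0).all()
        assert set(np.unique(g.edge_scalars[:, 36])) <= {0.0, 1.0}

    def test_symmetrize_flag(self):
        s = make_native(6, sequence="AAAAAA", geometry="strand", seed=0)
        g = build_graph(s, GraphConfig(k_neighbors=2, symmetrize=True))
        pairs = set(zip(g.src.tolist(), g.dst.tolist()))
        assert all((b, a) in pairs for a, b in pairs)
        g_dir = build_graph(s, GraphConfig(k_neighbors=2))
        assert g.n_edges >= g_dir.n_edges

    def test_backbone_only_variant(self, helix_mixed):
        g = build_graph(helix_mixed, GraphConfig(backbone_only=True))
        assert g.n_nodes == helix_mixed.n_residues * 4
        allowed = {ATOM37_INDEX[n] for n in ("N", "CA", "C", "O")}
        assert set(g.node_slot) <= allowed
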