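"""SE(3)-equivariant graph transformer predicting per-atom coordinate shifts.

The network carries two kinds of per-node state: type-0 scalars (rotation
invariant) and type-1 vectors (rotating with the input).  Every scalar
entering the computation — node one-hots, the 49 edge features — is rigid-
motion invariant, and every vector is built from coordinate *differences*
(displacements to the neighbourhood centroid, inter-node unit vectors), so
the predicted shifts are exactly translation invariant and rotation
equivariant by construction.

Architecture: linear embeddings of node (57→32) and edge (49→32) scalars,
then two attention blocks (16 channels, 4 heads).  Queries are projections
of node scalars; keys and type-0/type-1 value messages come from an
edge-conditioned ReLU kernel of the edge features and the source node
state, combined with the vector state through degree-≤1 equivariant
operations only (channel mixing of vectors, scalar gating of the inter-node
unit displacement).  Each block ends with an equivariant normalization layer:
layer-norm on scalars, per-node RMS rescaling of vector channels (direction
preserved).  A zero-initialized linear head maps the final vector channels
to one 3-vector per atom, so an untrained model is the identity refiner:
refined = initial + shift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from os import PathLike

import numpy as np

from .autodiff import Tensor, concat, constant, gather, segment_sum
from .errors import ValidationError
from .graph import AtomGraph, GraphConfig, build_graph, EDGE_FEATURE_DIM, NODE_FEATURE_DIM
from .structure import ProteinStructure

_EPS = 1e-8


@dataclass(frozen=True)
class ModelConfig:
    """Width/depth hyperparameters of the refinement network."""

    n_blocks: int = 2
    channels: int = 16
    heads: int = 4
    embed_dim: int = 32
    max_degree: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.channels % self.heads:
            raise ValidationError("channels must be divisible by heads")
        if self.max_degree != 1:
            raise ValidationError("only degree-1 features are supported")


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


def init_params(cfg: ModelConfig) -> dict[str, Tensor]:
    """Seeded parameter initialization; the output head starts at zero."""
    rng = np.random.default_rng(cfg.seed)
    d, c, h = cfg.embed_dim, cfg.channels, cfg.heads
    dk = c // h
    p: dict[str, np.ndarray] = {
        "node_embed_W": _glorot(rng, (NODE_FEATURE_DIM, d)),
        "node_embed_b": np.zeros(d),
        "edge_embed_W": _glorot(rng, (EDGE_FEATURE_DIM, d)),
        "edge_embed_b": np.zeros(d),
        "vec_init_W": _glorot(rng, (1, c)),
    }
    for b in range(cfg.n_blocks):
        p[f"b{b}.Wq"] = _glorot(rng, (d, h * dk))
        p[f"b{b}.Wh"] = _glorot(rng, (2 * d, d))
        p[f"b{b}.bh"] = np.zeros(d)
        p[f"b{b}.Wk"] = _glorot(rng, (d, h * dk))
        p[f"b{b}.Wv0"] = _glorot(rng, (d, c))
        p[f"b{b}.Wo"] = _glorot(rng, (c, d))
        p[f"b{b}.Wg"] = _glorot(rng, (d, c))
        p[f"b{b}.Wvmix"] = _glorot(rng, (c, c))
        p[f"b{b}.Wvout"] = _glorot(rng, (c, c))
        p[f"b{b}.ln_gain"] = np.ones(d)
        p[f"b{b}.ln_bias"] = np.zeros(d)
        p[f"b{b}.vn_gain"] = np.ones(c)
    p["out_W"] = np.zeros((c, 1))
    return {k: Tensor(v, requires_grad=True) for k, v in p.items()}


def _segment_max(x: np.ndarray, idx: np.ndarray, num: int) -> np.ndarray:
    out = np.full((num,) + x.shape[1:], -np.inf)
    np.maximum.at(out, idx, x)
    return out


def _neighbour_centroid_offsets(graph: AtomGraph) -> np.ndarray:
    """Per-node displacement to the centroid of its edge sources, [n, 3, 1]."""
    n = graph.n_nodes
    acc = np.zeros((n, 3))
    np.add.at(acc, graph.dst, graph.node_coords[graph.src])
    counts = np.bincount(graph.dst, minlength=n).astype(np.float64)
    centroid = acc / np.maximum(counts, 1.0)[:, None]
    return (centroid - graph.node_coords)[:, :, None]


def forward(graph: AtomGraph, params: dict[str, Tensor], cfg: ModelConfig) -> Tensor:
    """Full forward pass; returns per-atom shifts as a Tensor [n_atoms, 3]."""
    n, e = graph.n_nodes, graph.n_edges
    h = cfg.heads
    dk = cfg.channels // h
    src, dst = graph.src, graph.dst

    s = constant(graph.node_scalars) @ params["node_embed_W"] + params["node_embed_b"]
    ef = constant(graph.edge_scalars) @ params["edge_embed_W"] + params["edge_embed_b"]

    u0 = constant(_neighbour_centroid_offsets(graph))  # [n, 3, 1]
    v = u0 @ params["vec_init_W"]  # [n, 3, c]

    delta = graph.node_coords[dst] - graph.node_coords[src]
    dist = np.linalg.norm(delta, axis=1, keepdims=True)
    unit = constant((delta / np.maximum(dist, _EPS))[:, :, None])  # [e, 3, 1]

    for b in range(cfg.n_blocks):
        pre = f"b{b}."
        q = (s @ params[pre + "Wq"]).reshape(n, h, dk)
        z = concat([ef, gather(s, src)], axis=-1)  # [e, 2d]
        z = (z @ params[pre + "Wh"] + params[pre + "bh"]).relu()  # edge kernel
        k = (z @ params[pre + "Wk"]).reshape(e, h, dk)
        logits = (gather(q.reshape(n, h * dk), dst).reshape(e, h, dk) * k).sum(
            axis=-1
        ) * (1.0 / np.sqrt(dk))  # [e, h]

        # numerically-stable softmax over each node's incoming edges
        lmax = _segment_max(logits.data, dst, n)
        ex = (logits - constant(lmax[dst])).exp()
        denom = segment_sum(ex, dst, n)
        alpha = ex / gather(denom, dst)  # [e, h]

        m0 = (z @ params[pre + "Wv0"]).reshape(e, h, dk)
        agg0 = segment_sum((alpha.reshape(e, h, 1) * m0), dst, n).reshape(
            n, cfg.channels
        )
        s = s + agg0 @ params[pre + "Wo"]

        gate = z @ params[pre + "Wg"]  # [e, c]
        m1 = gather(v, src) @ params[pre + "Wvmix"] + unit * gate.reshape(e, 1, -1)
        am = alpha.mean(axis=1).reshape(e, 1, 1)
        agg1 = segment_sum(am * m1, dst, n)  # [n, 3, c]
        v = v + agg1 @ params[pre + "Wvout"]

        # equivariant normalization
        mu = s.mean(axis=-1, keepdims=True)
        var = ((s - mu) * (s - mu)).mean(axis=-1, keepdims=True)
        s = (s - mu) / (var + _EPS).sqrt() * params[pre + "ln_gain"] + params[
            pre + "ln_bias"
        ]
        n2 = (v * v).sum(axis=1, keepdims=True)  # [n, 1, c]
        rms = (n2.mean(axis=-1, keepdims=True) + _EPS).sqrt()  # [n, 1, 1]
        v = v / rms * params[pre + "vn_gain"]

    return (v @ params["out_W"]).reshape(n, 3)


class RefinementModel:
    """A configured parameter set with featurize/predict/refine entry points."""

    def __init__(
        self,
        model_cfg: ModelConfig | None = None,
        graph_cfg: GraphConfig | None = None,
        params: dict[str, Tensor] | None = None,
    ):
        self.model_cfg = model_cfg or ModelConfig()
        self.graph_cfg = graph_cfg or GraphConfig()
        self.params = params if params is not None else init_params(self.model_cfg)

    def forward_graph(self, graph: AtomGraph) -> Tensor:
        return forward(graph, self.params, self.model_cfg)

    def predict_shifts(self, structure: ProteinStructure) -> np.ndarray:
        """Per-atom coordinate shifts in Å, [n_graph_atoms, 3]."""
        graph = build_graph(structure, self.graph_cfg)
        return self.forward_graph(graph).data

    def refine(self, structure: ProteinStructure) -> ProteinStructure:
        """Refined structure: initial coordinates plus predicted shifts."""
        graph = build_graph(structure, self.graph_cfg)
        shifts = self.forward_graph(graph).data
        if self.graph_cfg.backbone_only:
            flat = structure.coords[structure.atom_mask].copy()
            # map graph nodes back into the full flat-atom ordering
            full_idx = np.flatnonzero(structure.atom_mask.reshape(-1))
            node_flat = graph.node_to_residue * structure.atom_mask.shape[1] + graph.node_slot
            pos = np.searchsorted(full_idx, node_flat)
            flat[pos] += shifts
        else:
            flat = structure.flat_coords() + shifts
        return structure.with_flat_coords(flat)

    # -- serialization -----------------------------------------------------
    def save(self, path: str | PathLike) -> None:
        arrays = {k: t.data for k, t in self.params.items()}
        meta = {
            "format_version": 1,
            "model_cfg": asdict(self.model_cfg),
            "graph_cfg": {
                k: v
                for k, v in self.graph_cfg.__dict__.items()
                if k != "covalent_radii"
            },
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | PathLike) -> "RefinementModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format_version") != 1:
                raise ValidationError("unsupported checkpoint format version")
            model_cfg = ModelConfig(**meta["model_cfg"])
            graph_cfg = GraphConfig(**meta["graph_cfg"])
            params = {
                k: Tensor(data[k], requires_grad=True)
                for k in data.files
                if k != "__meta__"
            }
        expected = set(init_params(model_cfg))
        if set(params) != expected:
            raise ValidationError("checkpoint parameters do not match its config")
        return cls(model_cfg=model_cfg, graph_cfg=graph_cfg, params=params)


def ensemble_refine(
    models: list[RefinementModel], structure: ProteinStructure
) -> list[ProteinStructure]:
    """One refined structure per ensemble member (paper protocol: five)."""
    return [m.refine(structure) for m in models]
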