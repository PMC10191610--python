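"""scikit-learn style estimator wrapping graph featurization + network + Adam.

``SE3Refiner`` is the package's main entry point: construct with
hyperparameters, ``fit`` on a list of (initial, native) training pairs,
then ``predict`` per-atom coordinate shifts or ``transform`` structures
into refined structures.  It follows the sklearn estimator contract
(``get_params``/``set_params``, fitted attributes with a trailing
underscore), so it composes with sklearn model-selection utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .autodiff import constant
from .errors import ValidationError
from .graph import GraphConfig, build_graph
from .network import ModelConfig, RefinementModel, forward
from .structure import ProteinStructure
from .training import Adam, TrainingPair, crop, DEFAULT_LR


def _as_pair(item) -> TrainingPair:
    if isinstance(item, TrainingPair):
        return item
    if isinstance(item, (tuple, list)) and len(item) == 2:
        return TrainingPair(initial=item[0], native=item[1])
    raise ValidationError(
        "training examples must be TrainingPair or (initial, native) tuples"
    )


class SE3Refiner(TransformerMixin, BaseEstimator):
    """All-atom structure refiner built on an SE(3)-equivariant transformer.

    Parameters
    ----------
    n_blocks, channels, heads, embed_dim
        Network width/depth (defaults: 2 blocks, 16 channels, 4 heads,
        embedding 32).
    k_neighbors
        Incoming edges per atom in the KNN graph (default 128; capped at
        n_atoms − 1 for small structures).
    backbone_only
        Restrict the graph to N, CA, C, O atoms (backbone refinement
        variant).
    lr, beta1, beta2, weight_decay
        Adam hyperparameters (β₁ = 0.9, β₂ = 0.999, weight decay 0.001).
    max_epochs, early_stop_patience
        Epoch budget (50) and early-stopping patience on validation loss
        (5); early stopping is active only when validation data is given.
    crop_len
        Contiguous-window crop applied to structures longer than this many
        residues (1500).
    seed
        Seeds parameter initialization, shuffling and crop windows.
    """

    def __init__(
        self,
        n_blocks: int = 2,
        channels: int = 16,
        heads: int = 4,
        embed_dim: int = 32,
        k_neighbors: int = 128,
        backbone_only: bool = False,
        lr: float = DEFAULT_LR,
        beta1: float = 0.9,
        beta2: float = 0.999,
        weight_decay: float = 0.001,
        max_epochs: int = 50,
        early_stop_patience: int = 5,
        crop_len: int = 1500,
        seed: int = 0,
    ):
        self.n_blocks = n_blocks
        self.channels = channels
        self.heads = heads
        self.embed_dim = embed_dim
        self.k_neighbors = k_neighbors
        self.backbone_only = backbone_only
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.crop_len = crop_len
        self.seed = seed

    # ------------------------------------------------------------------
    def _configs(self) -> tuple[ModelConfig, GraphConfig]:
        return (
            ModelConfig(
                n_blocks=self.n_blocks,
                channels=self.channels,
                heads=self.heads,
                embed_dim=self.embed_dim,
                seed=self.seed,
            ),
            GraphConfig(
                k_neighbors=self.k_neighbors, backbone_only=self.backbone_only
            ),
        )

    def _pair_loss(self, model: RefinementModel, pair: TrainingPair, cache: dict):
        """Forward pass returning (loss Tensor, target array)."""
        key = id(pair)
        if key not in cache:
            graph = build_graph(pair.initial, model.graph_cfg)
            target = pair.target_shifts
            if model.graph_cfg.backbone_only:
                flat_slots = pair.initial.atom_mask.copy()
                sel = np.zeros(int(flat_slots.sum()), dtype=bool)
                full_idx = np.flatnonzero(flat_slots.reshape(-1))
                node_flat = (
                    graph.node_to_residue * flat_slots.shape[1] + graph.node_slot
                )
                sel[np.searchsorted(full_idx, node_flat)] = True
                target = target[sel]
            cache[key] = (graph, target)
        graph, target = cache[key]
        pred = forward(graph, model.params, model.model_cfg)
        diff = pred - constant(target)
        return (diff * diff).mean(), target

    # ------------------------------------------------------------------
    def fit(self, X, y=None, validation_data=None):
        """Train on (initial, native) pairs.

        Parameters
        ----------
        X : list of TrainingPair or (initial, native) tuples
        validation_data : optional list of pairs used for early stopping
            and model selection.
        """
        pairs = [_as_pair(p) for p in X]
        if not pairs:
            raise ValidationError("no training pairs given")
        val_pairs = [_as_pair(p) for p in validation_data] if validation_data else []

        model_cfg, graph_cfg = self._configs()
        model = RefinementModel(model_cfg=model_cfg, graph_cfg=graph_cfg)
        opt = Adam(
            model.params,
            lr=self.lr,
            beta1=self.beta1,
            beta2=self.beta2,
            weight_decay=self.weight_decay,
        )
        rng = np.random.default_rng(self.seed)
        cache: dict = {}
        trace: list[dict] = []
        best_val = np.inf
        best_params = None
        stall = 0

        for epoch in range(self.max_epochs):
            order = rng.permutation(len(pairs))
            train_losses = []
            for i in order:
                pair = pairs[i]
                if pair.initial.n_residues > self.crop_len:
                    pair = crop(pair, self.crop_len, rng)
                    loss, _ = self._pair_loss(model, pair, {})
                else:
                    loss, _ = self._pair_loss(model, pair, cache)
                opt.zero_grad()
                loss.backward()
                opt.step()
                train_losses.append(float(loss.data))

            val_loss = np.nan
            if val_pairs:
                vls = []
                for pair in val_pairs:
                    loss, _ = self._pair_loss(model, pair, cache)
                    vls.append(float(loss.data))
                val_loss = float(np.mean(vls))
                if val_loss < best_val:
                    best_val = val_loss
                    best_params = {k: p.data.copy() for k, p in model.params.items()}
                    stall = 0
                else:
                    stall += 1
            trace.append(
                {
                    "epoch": epoch,
                    "train_loss": float(np.mean(train_losses)),
                    "val_loss": val_loss,
                }
            )
            if val_pairs and stall >= self.early_stop_patience:
                break

        if best_params is not None:
            for k, p in model.params.items():
                p.data = best_params[k]
        self.model_ = model
        self.history_ = pd.DataFrame(trace)
        self.best_val_loss_ = (
            best_val if val_pairs else float(trace[-1]["train_loss"])
        )
        self.n_epochs_ = len(trace)
        return self

    # ------------------------------------------------------------------
    def _require_fitted(self) -> RefinementModel:
        if not hasattr(self, "model_"):
            # allow zero-shot use with fresh (identity) parameters
            model_cfg, graph_cfg = self._configs()
            return RefinementModel(model_cfg=model_cfg, graph_cfg=graph_cfg)
        return self.model_

    def predict(self, X):
        """Per-atom shift array for a structure, or a list of such arrays."""
        model = self._require_fitted()
        if isinstance(X, ProteinStructure):
            return model.predict_shifts(X)
        return [model.predict_shifts(s) for s in X]

    def transform(self, X):
        """Refined structure(s): initial coordinates plus predicted shifts."""
        model = self._require_fitted()
        if isinstance(X, ProteinStructure):
            return model.refine(X)
        return [model.refine(s) for s in X]

    refine = transform
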