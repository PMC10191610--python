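"""Shift targets, loss, Adam optimization and cross-validation scaffolding.

The regression target for an (initial, native) pair is the per-atom
coordinate shift after the native structure is rigid-body superposed onto
the initial model over their shared heavy atoms; superposition makes the
target invariant to independent rigid motions of either structure, which is
what lets an equivariant network learn it.  The loss is the mean squared
error over all shift components (Å²).

Training follows the protocol hyperparameters: Adam with β₁ = 0.9,
β₂ = 0.999 and weight decay 0.001, batch size 1, up to 50 epochs with early
stopping after 5 epochs without validation improvement, structures longer
than 1500 residues cropped to a contiguous window.  Cross-validation trains
one model per fold and keeps the checkpoints with the lowest validation
loss for ensemble inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor, constant
from .errors import ValidationError
from .metrics import kabsch_superpose
from .structure import ProteinStructure, pair_model_native

DEFAULT_LR = 1e-3


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol hyperparameters."""

    lr: float = DEFAULT_LR
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.001
    batch_size: int = 1
    max_epochs: int = 50
    early_stop_patience: int = 5
    crop_len: int = 1500
    n_folds: int = 10
    n_select: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_select > self.n_folds:
            raise ValidationError("n_select must not exceed n_folds")
        if self.crop_len < 1:
            raise ValidationError("crop_len must be >= 1")


@dataclass
class TrainingPair:
    """A paired (initial model, native) example with its shift target."""

    initial: ProteinStructure
    native: ProteinStructure
    target_shifts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.initial, self.native = pair_model_native(self.initial, self.native)
        if self.target_shifts is None:
            self.target_shifts = compute_target_shifts(self.initial, self.native)


def compute_target_shifts(
    initial: ProteinStructure, native: ProteinStructure
) -> np.ndarray:
    """Per-atom shifts (Å) from the initial model to the superposed native."""
    m, n = pair_model_native(initial, native)
    mi, ni = m.flat_coords(), n.flat_coords()
    rot, t, _ = kabsch_superpose(ni, mi)  # native onto initial
    return ni @ rot.T + t - mi


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean squared error over all shift components, in Å²."""
    pred, target = np.asarray(pred), np.asarray(target)
    if pred.shape != target.shape:
        raise ValidationError(f"shape mismatch {pred.shape} vs {target.shape}")
    return float(np.mean((pred - target) ** 2))


def crop(pair: TrainingPair, crop_len: int, rng: np.random.Generator) -> TrainingPair:
    """Random contiguous residue window of length ``crop_len`` (if needed)."""
    n = pair.initial.n_residues
    if n <= crop_len:
        return pair
    start = int(rng.integers(0, n - crop_len + 1))
    sl = slice(start, start + crop_len)

    def cut(s: ProteinStructure) -> ProteinStructure:
        return ProteinStructure(
            sequence=s.sequence[sl],
            coords=s.coords[sl],
            atom_mask=s.atom_mask[sl],
            residue_ids=s.residue_ids[sl],
            chain_id=s.chain_id,
        )

    return TrainingPair(initial=cut(pair.initial), native=cut(pair.native))


class Adam:
    """Adam with (coupled) weight decay, operating on a named Tensor dict."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = DEFAULT_LR,
        beta1: float = 0.9,
        beta2: float = 0.999,
        weight_decay: float = 0.001,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.b1, self.b2 = lr, beta1, beta2
        self.wd, self.eps = weight_decay, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            g = g + self.wd * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_fold(pairs, fold_assignment, cfg: TrainConfig | None = None, **estimator_kw):
    """Train one model on the out-of-fold pairs, validating on the fold.

    ``fold_assignment`` is a boolean/index mask selecting the validation
    pairs.  Returns ``(fitted SE3Refiner, history DataFrame)``.
    """
    from .refiner import SE3Refiner  # local import to avoid a cycle

    cfg = cfg or TrainConfig()
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValidationError("need at least 2 pairs to train a fold")
    sel = np.asarray(fold_assignment)
    if sel.size == 0:
        raise ValidationError("fold assignment selects no validation pairs")
    if sel.dtype == bool:
        mask = sel.copy()
    else:
        mask = np.zeros(len(pairs), dtype=bool)
        mask[sel.astype(np.int64)] = True
    val = [p for p, m in zip(pairs, mask) if m]
    train = [p for p, m in zip(pairs, mask) if not m]
    if not val or not train:
        raise ValidationError("fold assignment leaves an empty split")
    est = SE3Refiner(
        lr=cfg.lr,
        beta1=cfg.beta1,
        beta2=cfg.beta2,
        weight_decay=cfg.weight_decay,
        max_epochs=cfg.max_epochs,
        early_stop_patience=cfg.early_stop_patience,
        crop_len=cfg.crop_len,
        seed=cfg.seed,
        **estimator_kw,
    )
    est.fit(train, validation_data=val)
    return est, est.history_


def cross_validate(pairs, cfg: TrainConfig | None = None, **estimator_kw):
    """K-fold cross-validation; returns a list of (estimator, history)."""
    cfg = cfg or TrainConfig()
    pairs = list(pairs)
    if len(pairs) < cfg.n_folds:
        raise ValidationError(
            f"{len(pairs)} pairs cannot be split into {cfg.n_folds} folds"
        )
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(pairs))
    folds = np.array_split(order, cfg.n_folds)
    results = []
    for f, val_idx in enumerate(folds):
        fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + f})
        results.append(train_fold(pairs, val_idx, fold_cfg, **estimator_kw))
    return results


def select_models(fold_results, n_select: int = 5):
    """The n_select fold models with lowest validation loss, ascending.

    Ties are broken by fold index (earlier fold wins).
    """
    if len(fold_results) < n_select:
        raise ValidationError(
            f"need at least {n_select} trained folds, got {len(fold_results)}"
        )
    losses = [est.best_val_loss_ for est, _ in fold_results]
    order = sorted(range(len(losses)), key=lambda i: (losses[i], i))
    return [fold_results[i][0] for i in order[:n_select]]


def history_frame(trace: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(trace, columns=["epoch", "train_loss", "val_loss"])
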