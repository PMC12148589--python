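"""Contrastive training of the projection model against EC-label similarity.

For every mini-batch the pairwise cosine similarities x_ij of the projected
sequences and the pairwise overlap coefficients y_ij of their label sets are
compared, and the loss

    L = Σ_{i<j} (x_ij − y_ij)²

(summed over strict upper-triangle pairs) is minimised with AdamW at a
learning rate of 1e-3, decayed by cosine annealing to a floor of 5e-5.
The batch loss is the plain pair sum, not a per-pair average.  "Trained
until convergence on a hold-out validation set" is operationalised as
best-validation-loss checkpointing with a patience parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._autodiff import Tensor
from .ec_labels import ProteinLabelSet, overlap_coefficient
from .model import EmbeddingMatrix, ModelConfig, ProjectionModel

__all__ = [
    "TrainConfig",
    "TrainResult",
    "pairwise_cosine_matrix",
    "pairwise_label_similarity_matrix",
    "contrastive_loss",
    "train_model",
    "write_loss_trace",
]

# Named epoch presets used at full scale: 150 epochs for the 30%-identity
# training set, 50 for the iteratively clustered ones.
EPOCH_PROFILES = {"full": 150, "clustered": 50}


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (defaults follow the reference recipe)."""

    batch_size: int = 16
    learning_rate: float = 1e-3
    min_learning_rate: float = 5e-5
    epochs: int = 50
    patience: int = 10
    weight_decay: float = 0.01  # AdamW default
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.min_learning_rate <= self.learning_rate):
            raise ValueError("need 0 < min_learning_rate <= learning_rate")
        if self.epochs < 1 or self.batch_size < 2:
            raise ValueError("epochs >= 1 and batch_size >= 2 required")


@dataclass
class TrainResult:
    model: ProjectionModel
    trace: list[dict] = field(default_factory=list)  # epoch rows
    best_epoch: int = -1
    best_val_loss: float = math.inf


def pairwise_cosine_matrix(vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Pairwise cosine similarity of >=2 equal-length vectors."""
    if len(vectors) < 2:
        raise ValueError("need at least two vectors")
    mat = np.asarray([np.asarray(v, dtype=np.float64) for v in vectors])
    norms = np.linalg.norm(mat, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("zero-norm vector has no cosine similarity")
    unit = mat / norms[:, None]
    sims = unit @ unit.T
    np.fill_diagonal(sims, 1.0)
    return sims


def pairwise_label_similarity_matrix(
    labels: Sequence[ProteinLabelSet],
) -> np.ndarray:
    """Pairwise overlap coefficients y_ij of a batch's label sets."""
    if len(labels) < 2:
        raise ValueError("need at least two label sets")
    n = len(labels)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = overlap_coefficient(labels[i], labels[j])
    return out


def contrastive_loss(cosine: np.ndarray, label: np.ndarray) -> float:
    """Σ over strict upper-triangle pairs of (x_ij − y_ij)²."""
    cosine = np.asarray(cosine, dtype=np.float64)
    label = np.asarray(label, dtype=np.float64)
    if cosine.shape != label.shape or cosine.ndim != 2:
        raise ValueError(
            f"similarity matrices must share a square shape, "
            f"got {cosine.shape} vs {label.shape}"
        )
    iu = np.triu_indices(cosine.shape[0], k=1)
    diff = cosine[iu] - label[iu]
    return float(diff @ diff)


def cosine_annealed_lr(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate for ``epoch`` (0-based) under cosine annealing."""
    if cfg.epochs == 1:
        return cfg.learning_rate
    t = epoch / (cfg.epochs - 1)
    return cfg.min_learning_rate + 0.5 * (
        cfg.learning_rate - cfg.min_learning_rate
    ) * (1.0 + math.cos(math.pi * t))


class _AdamW:
    """AdamW with decoupled weight decay (β=(0.9, 0.999), ε=1e-8)."""

    def __init__(self, params: dict[str, Tensor], weight_decay: float):
        self.params = params
        self.wd = weight_decay
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, lr: float) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)


def _pack(items: Sequence[tuple[EmbeddingMatrix, ProteinLabelSet]]):
    lmax = max(e.values.shape[0] for e, _ in items)
    D = items[0][0].values.shape[1]
    batch = np.zeros((len(items), lmax, D))
    mask = np.zeros((len(items), lmax))
    for i, (e, _) in enumerate(items):
        L = e.values.shape[0]
        batch[i, :L] = e.values
        mask[i, :L] = 1.0
    return batch, mask


def _batch_loss_tensor(
    model: ProjectionModel,
    items: Sequence[tuple[EmbeddingMatrix, ProteinLabelSet]],
) -> Tensor:
    batch, mask = _pack(items)
    vectors = model.forward(batch, mask)  # (B, O) unit rows
    cos = vectors @ vectors.swapaxes(0, 1)
    y = pairwise_label_similarity_matrix([ls for _, ls in items])
    ut = np.triu(np.ones_like(y), k=1)
    diff = cos - Tensor(y)
    return (diff * diff * Tensor(ut)).sum()


def _epoch_val_loss(
    model: ProjectionModel,
    items: Sequence[tuple[EmbeddingMatrix, ProteinLabelSet]],
    batch_size: int,
) -> float:
    """Mean per-batch pair loss over fixed, unshuffled validation batches."""
    losses = []
    for s in range(0, len(items), batch_size):
        chunk = items[s : s + batch_size]
        if len(chunk) < 2:
            continue
        batch, mask = _pack(chunk)
        vecs = model.forward(batch, mask).data
        y = pairwise_label_similarity_matrix([ls for _, ls in chunk])
        losses.append(contrastive_loss(vecs @ vecs.T, y))
    if not losses:
        raise ValueError("validation set yields no batch of size >= 2")
    return float(np.mean(losses))


def train_model(
    train_items: Sequence[tuple[EmbeddingMatrix, ProteinLabelSet]],
    val_items: Sequence[tuple[EmbeddingMatrix, ProteinLabelSet]],
    model_config: ModelConfig,
    train_config: TrainConfig,
    progress: bool = False,
) -> TrainResult:
    """Train a projection model; returns the best-validation-loss parameters.

    Each epoch shuffles the training items, forms mini-batches of
    ``batch_size`` (a trailing batch of size 1 is dropped: the pairwise
    loss needs at least one pair), applies one AdamW update per batch on
    the summed pair loss, and records train/validation losses.  Fully
    reproducible given the config seeds.
    """
    if len(train_items) < 2:
        raise ValueError("training needs at least two labelled items")
    for e, ls in list(train_items) + list(val_items):
        if len(ls) == 0:
            raise ValueError(f"item {e.sequence_id!r} has an empty label set")
        if e.dim != model_config.input_dim:
            raise ValueError(
                f"item {e.sequence_id!r} has D={e.dim}, "
                f"model expects {model_config.input_dim}"
            )

    model = ProjectionModel(model_config)
    opt = _AdamW(model.params, train_config.weight_decay)
    rng = np.random.default_rng(train_config.seed)
    result = TrainResult(model)
    best_state = model.state_dict()
    since_best = 0

    for epoch in range(train_config.epochs):
        lr = cosine_annealed_lr(train_config, epoch)
        order = rng.permutation(len(train_items))
        batch_losses = []
        for s in range(0, len(order), train_config.batch_size):
            idx = order[s : s + train_config.batch_size]
            if len(idx) < 2:
                continue
            chunk = [train_items[i] for i in idx]
            model.zero_grad()
            loss = _batch_loss_tensor(model, chunk)
            lval = float(loss.data)
            if not math.isfinite(lval):
                raise ArithmeticError(
                    f"non-finite training loss at epoch {epoch}: {lval}"
                )
            loss.backward()
            opt.step(lr)
            batch_losses.append(lval)
        train_loss = float(np.mean(batch_losses))
        val_loss = (
            _epoch_val_loss(model, val_items, train_config.batch_size)
            if len(val_items) >= 2
            else train_loss
        )
        result.trace.append(
            {"epoch": epoch, "train_loss": train_loss,
             "val_loss": val_loss, "learning_rate": lr}
        )
        if progress:
            import sys

            print(
                f"epoch {epoch:3d}  train {train_loss:.5f}  "
                f"val {val_loss:.5f}  lr {lr:.2e}",
                file=sys.stderr,
            )
        if val_loss < result.best_val_loss:
            result.best_val_loss = val_loss
            result.best_epoch = epoch
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best >= train_config.patience:
                break

    model.load_state_dict(best_state)
    return result


def write_loss_trace(trace: list[dict], path) -> None:
    """Write the per-epoch loss trace as TSV."""
    import pandas as pd

    pd.DataFrame(
        trace, columns=["epoch", "train_loss", "val_loss", "learning_rate"]
    ).to_csv(path, sep="\t", index=False)
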