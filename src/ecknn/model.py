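"""The learnable projection from per-residue embeddings to retrieval vectors.

The map f_θ takes a per-residue embedding matrix of shape (L × D) — by
default D=1280, the per-residue output of a 650M-parameter protein language
model — and produces a single unit-norm vector (default dimension 512)
whose cosine similarities are trained to track EC-label similarity.

Architecture: one transformer encoder layer (multi-head self-attention and
a position-wise feed-forward block, each with a residual connection and a
following layer normalisation), masked mean pooling over residues, then a
two-layer perceptron D → hidden → output with GELU and layer normalisation
at the penultimate layer, and finally explicit unit-norm scaling so that
index dot products are exact cosines.  No positional encoding is added:
the input residue embeddings already encode position, so the map is
permutation-equivariant in the residue axis and the pooled output is
permutation-invariant.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np

from ._autodiff import Tensor, gelu, layer_norm, softmax

__all__ = [
    "EmbeddingMatrix",
    "ModelConfig",
    "ProjectedVector",
    "ProjectionModel",
    "init_projection_model",
    "project",
    "project_batch",
    "save_checkpoint",
    "load_checkpoint",
]

_MASK_NEG = -1e9  # additive attention bias for padded key positions


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Per-residue embedding of one sequence: a finite (L × D) real matrix."""

    sequence_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] < 1:
            raise ValueError(
                f"embedding of {self.sequence_id!r} must be (L>=1, D), got {v.shape}"
            )
        object.__setattr__(self, "values", v)

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the projection network.

    Defaults match the full-scale setting (D=1280 inputs, 20 attention
    heads, 5120 feed-forward width, 1024-unit hidden layer, 512-dim
    output); every dimension is configurable so tests run at small D.
    """

    input_dim: int = 1280
    hidden_dim: int = 1024
    output_dim: int = 512
    attention_heads: int = 20
    feedforward_dim: int = 5120
    seed: int = 0

    def __post_init__(self) -> None:
        dims = (self.input_dim, self.hidden_dim, self.output_dim,
                self.attention_heads, self.feedforward_dim)
        if any(d <= 0 for d in dims):
            raise ValueError(f"all model dimensions must be positive: {self}")
        if self.input_dim % self.attention_heads != 0:
            raise ValueError(
                f"input_dim {self.input_dim} not divisible by "
                f"attention_heads {self.attention_heads}"
            )


@dataclass(frozen=True)
class ProjectedVector:
    """Unit-norm retrieval coordinate of one sequence."""

    sequence_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise ValueError("projected vector must be 1-D")
        n = float(np.linalg.norm(v))
        if abs(n - 1.0) > 1e-6:
            raise ValueError(
                f"projected vector for {self.sequence_id!r} has norm {n}, not 1"
            )
        object.__setattr__(self, "values", v)


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class ProjectionModel:
    """f_θ: per-residue embedding matrices → unit-norm vectors."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        D, H, O, F = (config.input_dim, config.hidden_dim,
                      config.output_dim, config.feedforward_dim)
        p: dict[str, Tensor] = {}
        for name in ("wq", "wk", "wv", "wo"):
            p[name] = Tensor(_xavier(rng, D, D), requires_grad=True)
            p[name[0] + "b" + name[1]] = Tensor(np.zeros(D), requires_grad=True)
        p["ff_w1"] = Tensor(_xavier(rng, D, F), requires_grad=True)
        p["ff_b1"] = Tensor(np.zeros(F), requires_grad=True)
        p["ff_w2"] = Tensor(_xavier(rng, F, D), requires_grad=True)
        p["ff_b2"] = Tensor(np.zeros(D), requires_grad=True)
        for ln in ("ln1", "ln2", "ln3"):
            p[ln + "_g"] = Tensor(np.ones(H if ln == "ln3" else D),
                                  requires_grad=True)
            p[ln + "_b"] = Tensor(np.zeros(H if ln == "ln3" else D),
                                  requires_grad=True)
        p["mlp_w1"] = Tensor(_xavier(rng, D, H), requires_grad=True)
        p["mlp_b1"] = Tensor(np.zeros(H), requires_grad=True)
        p["mlp_w2"] = Tensor(_xavier(rng, H, O), requires_grad=True)
        p["mlp_b2"] = Tensor(np.zeros(O), requires_grad=True)
        self.params = p

    # -- parameter plumbing ------------------------------------------------

    def parameter_vector(self) -> np.ndarray:
        return np.concatenate([self.params[k].data.ravel()
                               for k in sorted(self.params)])

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            if state[k].shape != t.data.shape:
                raise ValueError(f"parameter {k}: shape mismatch")
            t.data = np.array(state[k], dtype=np.float64)

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    # -- forward pass ------------------------------------------------------

    def forward(self, batch: np.ndarray, mask: np.ndarray) -> Tensor:
        """Project a padded batch.

        ``batch`` is (B, L, D); ``mask`` is (B, L) with 1.0 at real residue
        positions and 0.0 at padding.  Padded keys are excluded from
        attention and padded positions from pooling, so each sequence's
        output is independent of how the batch is padded.  Returns a
        (B, output_dim) tensor of unit-norm rows.
        """
        cfg = self.config
        p = self.params
        B, L, D = batch.shape
        if D != cfg.input_dim:
            raise ValueError(f"batch has D={D}, model expects {cfg.input_dim}")
        nh, dh = cfg.attention_heads, cfg.input_dim // cfg.attention_heads

        x = Tensor(batch)
        q = x @ p["wq"] + p["wbq"]
        k = x @ p["wk"] + p["wbk"]
        v = x @ p["wv"] + p["wbv"]

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, L, nh, dh).swapaxes(1, 2)  # (B, nh, L, dh)

        q, k, v = heads(q), heads(k), heads(v)
        scores = (q @ k.swapaxes(2, 3)) * (1.0 / np.sqrt(dh))
        key_bias = np.where(mask[:, None, None, :] > 0.0, 0.0, _MASK_NEG)
        attn = softmax(scores + Tensor(key_bias), axis=-1)
        ctx = (attn @ v).swapaxes(1, 2).reshape(B, L, cfg.input_dim)
        ctx = ctx @ p["wo"] + p["wbo"]

        h = layer_norm(x + ctx, p["ln1_g"], p["ln1_b"])
        ff = gelu(h @ p["ff_w1"] + p["ff_b1"]) @ p["ff_w2"] + p["ff_b2"]
        h = layer_norm(h + ff, p["ln2_g"], p["ln2_b"])

        counts = mask.sum(axis=1, keepdims=True)  # (B, 1), every row >= 1
        pooled = (h * Tensor(mask[:, :, None])).sum(axis=1) * Tensor(1.0 / counts)

        z = gelu(pooled @ p["mlp_w1"] + p["mlp_b1"])
        z = layer_norm(z, p["ln3_g"], p["ln3_b"])
        z = z @ p["mlp_w2"] + p["mlp_b2"]
        sq = (z * z).sum(axis=-1, keepdims=True)
        return z * ((sq + 1e-12) ** -0.5)

    def project_array(self, embs: Sequence[np.ndarray]) -> np.ndarray:
        """Inference-only batched projection of raw (L_i × D) matrices."""
        if not embs:
            return np.zeros((0, self.config.output_dim))
        lmax = max(e.shape[0] for e in embs)
        B = len(embs)
        batch = np.zeros((B, lmax, self.config.input_dim))
        mask = np.zeros((B, lmax))
        for i, e in enumerate(embs):
            batch[i, : e.shape[0]] = e
            mask[i, : e.shape[0]] = 1.0
        return self.forward(batch, mask).data


def init_projection_model(config: ModelConfig) -> ProjectionModel:
    """Construct a projection model with seed-deterministic parameters."""
    return ProjectionModel(config)


def project(model: ProjectionModel, emb: EmbeddingMatrix) -> ProjectedVector:
    """Project a single sequence to its unit-norm retrieval vector."""
    if emb.dim != model.config.input_dim:
        raise ValueError(
            f"embedding {emb.sequence_id!r} has D={emb.dim}, "
            f"model expects {model.config.input_dim}"
        )
    if not np.all(np.isfinite(emb.values)):
        raise ValueError(f"embedding {emb.sequence_id!r} contains non-finite rows")
    vec = model.project_array([emb.values])[0]
    return ProjectedVector(emb.sequence_id, vec)


def project_batch(
    model: ProjectionModel,
    embs: Iterable[EmbeddingMatrix],
    batch_size: int = 64,
) -> list[ProjectedVector]:
    """Project many sequences, order-preserving; equals mapping ``project``."""
    embs = list(embs)
    for e in embs:
        if e.dim != model.config.input_dim:
            raise ValueError(
                f"embedding {e.sequence_id!r} has D={e.dim}, "
                f"model expects {model.config.input_dim}"
            )
        if not np.all(np.isfinite(e.values)):
            raise ValueError(f"embedding {e.sequence_id!r} contains non-finite rows")
    out: list[ProjectedVector] = []
    for start in range(0, len(embs), batch_size):
        chunk = embs[start : start + batch_size]
        mat = model.project_array([e.values for e in chunk])
        out.extend(ProjectedVector(e.sequence_id, row)
                   for e, row in zip(chunk, mat))
    return out


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(model: ProjectionModel, path) -> None:
    """Persist config + parameters; loading restores projections bitwise."""
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    payload["config_json"] = np.array(json.dumps(asdict(model.config)))
    np.savez(path, **payload)


def load_checkpoint(path) -> ProjectionModel:
    with np.load(path, allow_pickle=False) as npz:
        cfg = ModelConfig(**json.loads(str(npz["config_json"])))
        state = {k.split("/", 1)[1]: npz[k] for k in npz.files
                 if k.startswith("param/")}
    model = ProjectionModel(cfg)
    model.load_state_dict(state)
    return model


def small_config(dim: int = 64, seed: int = 0) -> ModelConfig:
    """A reduced-size configuration for desk-scale experiments (D=64)."""
    return ModelConfig(input_dim=dim, hidden_dim=2 * dim, output_dim=dim,
                       attention_heads=4, feedforward_dim=4 * dim, seed=seed)
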