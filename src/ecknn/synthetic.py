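"""Synthetic embedding fixtures with planted hierarchical EC structure.

Real inputs to this tool are per-residue protein-language-model embeddings,
whose raw cosine geometry already correlates loosely with function and
which the contrastive projection sharpens.  The generator emulates exactly
that structure at desk scale: a tree of depth-4 EC codes, one unit
centroid per class built by perturbing its parent's centroid with a
magnitude that shrinks with depth (so between-class cosine similarity
increases with shared-prefix depth, mirroring the overlap coefficient),
and per-sequence (L × D) matrices whose rows are the class centroid plus
residue-level noise.  A configurable fraction of sequences receives a
second EC from a different top class, and a few depth-4 classes can be
held out of training entirely — the stand-in for novel classes used for
refusal calibration and hold-out-class studies.

What it does not emulate: amino-acid sequences themselves, length/
composition biases, class imbalance, or annotation errors of real
databases.  Everything is a pure function of the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import EmbeddingStore
from .ec_labels import ECNumber, ProteinLabelSet, parse_ec, protein_label_set
from .model import EmbeddingMatrix

__all__ = [
    "FixtureConfig",
    "FixtureBundle",
    "sample_ec_tree",
    "make_centroids",
    "generate_dataset",
    "generate_fixture",
    "random_direction_queries",
]


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions of the synthetic benchmark.

    Defaults: 4 top classes branching 3/3/3 (108 depth-4 classes, 4 of
    them held out of training), 30 training + 5 test sequences per class,
    residue counts 20-60, D=64, per-level centroid perturbation scales
    0.6/0.4/0.25/0.15, residue noise 0.5 (typical per-residue perturbation
    norm relative to the unit centroid), and a 10% chance of a second EC.
    The scales are chosen so raw mean-pooled 1-NN is good but imperfect,
    leaving measurable headroom for the trained projection.
    """

    n_top_classes: int = 4
    branching: tuple[int, int, int] = (3, 3, 3)
    train_per_class: int = 30
    test_per_class: int = 5
    length_range: tuple[int, int] = (20, 60)
    dim: int = 64
    level_scales: tuple[float, float, float, float] = (0.6, 0.4, 0.25, 0.15)
    residue_noise: float = 0.5
    multi_label_rate: float = 0.1
    holdout_classes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_top_classes < 1 or any(b < 1 for b in self.branching):
            raise ValueError("class counts must be >= 1")
        if self.train_per_class < 1 or self.test_per_class < 0:
            raise ValueError("sequence counts must be >= 1 train, >= 0 test")
        if not all(a > b for a, b in zip(self.level_scales,
                                        self.level_scales[1:])):
            raise ValueError("level_scales must be strictly decreasing")
        if not 0.0 <= self.multi_label_rate <= 1.0:
            raise ValueError("multi_label_rate must lie in [0, 1]")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("length_range must satisfy 1 <= lo <= hi")

    @property
    def n_classes(self) -> int:
        return self.n_top_classes * int(np.prod(self.branching))


def sample_ec_tree(config: FixtureConfig) -> list[str]:
    """All depth-4 codes ``a.b.c.d`` under the configured branching."""
    b2, b3, b4 = config.branching
    return [
        f"{a}.{b}.{c}.{d}"
        for a in range(1, config.n_top_classes + 1)
        for b in range(1, b2 + 1)
        for c in range(1, b3 + 1)
        for d in range(1, b4 + 1)
    ]


def _unit(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def make_centroids(
    tree: Sequence[str], config: FixtureConfig
) -> dict[str, np.ndarray]:
    """One unit centroid per depth-4 code, hierarchically constructed.

    The level-1 centroid of each top class is a random unit vector (its
    level scale is absorbed by the renormalisation); each deeper node
    adds a perturbation of its level's scale to its parent's centroid and
    renormalises.  Consequently the expected cosine similarity between
    two class centroids increases with the depth of their shared prefix.
    """
    rng = np.random.default_rng([config.seed, 17])
    node: dict[str, np.ndarray] = {}
    for code in tree:
        levels = code.split(".")
        for d in range(1, 5):
            prefix = ".".join(levels[:d])
            if prefix in node:
                continue
            if d == 1:
                node[prefix] = _unit(rng, config.dim)
            else:
                parent = node[".".join(levels[: d - 1])]
                v = parent + config.level_scales[d - 1] * _unit(rng, config.dim)
                node[prefix] = v / np.linalg.norm(v)
    return {code: node[code] for code in tree}


@dataclass
class FixtureBundle:
    """A generated benchmark: store + labels + split manifest + geometry."""

    config: FixtureConfig
    store: EmbeddingStore
    labels: dict[str, tuple[ECNumber, ...]]
    manifest: pd.DataFrame  # columns: sequence_id, split, ec_numbers
    centroids: dict[str, np.ndarray]
    holdout_codes: tuple[str, ...] = ()

    def _items(self, split: str) -> list[tuple[EmbeddingMatrix, ProteinLabelSet]]:
        ids = self.manifest.loc[self.manifest["split"] == split, "sequence_id"]
        return [
            (
                EmbeddingMatrix(sid, self.store[sid]),
                protein_label_set(list(self.labels[sid])),
            )
            for sid in ids
        ]

    def train_items(self):
        return self._items("train")

    def test_items(self):
        return self._items("test")

    def holdout_items(self):
        return self._items("holdout")

    def truth(self, split: str) -> dict[str, set[str]]:
        ids = self.manifest.loc[self.manifest["split"] == split, "sequence_id"]
        return {
            sid: {str(e) for e in self.labels[sid] if e.depth == 4}
            for sid in ids
        }


def generate_dataset(
    tree: Sequence[str],
    centroids: dict[str, np.ndarray],
    config: FixtureConfig,
) -> FixtureBundle:
    """Emit the embedding store, label table and split manifest.

    Per class, ``train_per_class`` + ``test_per_class`` sequences are
    drawn: the residue count L uniform in the length range, each row the
    class centroid plus a noise vector of typical norm ``residue_noise``.
    With probability ``multi_label_rate`` a sequence also carries a second
    EC from a different top class (its embedding stays at the primary
    centroid — label noise, like promiscuous enzymes).  ``holdout_classes``
    depth-4 codes contribute no training sequences; their would-be train
    and test members all land in the ``holdout`` split.
    """
    rng = np.random.default_rng([config.seed, 29])
    hold_rng = np.random.default_rng([config.seed, 43])
    holdout = (
        tuple(str(c) for c in sorted(
            hold_rng.choice(list(tree), size=config.holdout_classes,
                            replace=False)))
        if config.holdout_classes
        else ()
    )
    store = EmbeddingStore(config.dim, {"generator": "ecknn.synthetic",
                                        "seed": str(config.seed)})
    labels: dict[str, tuple[ECNumber, ...]] = {}
    rows = []
    lo, hi = config.length_range
    scale = config.residue_noise / np.sqrt(config.dim)
    for code in tree:
        c = centroids[code]
        base = code.replace(".", "-")
        held = code in holdout
        for role, count in (("train", config.train_per_class),
                            ("test", config.test_per_class)):
            for i in range(count):
                sid = f"{base}_{role}{i:03d}"
                L = int(rng.integers(lo, hi + 1))
                mat = c[None, :] + scale * rng.standard_normal((L, config.dim))
                store.put(sid, mat)
                ecs = [parse_ec(code)]
                if config.multi_label_rate and (
                    rng.random() < config.multi_label_rate
                ):
                    top = code.split(".")[0]
                    others = [t for t in tree if not t.startswith(top + ".")]
                    if others:
                        ecs.append(parse_ec(str(rng.choice(others))))
                labels[sid] = tuple(ecs)
                split = "holdout" if held else role
                rows.append(
                    {
                        "sequence_id": sid,
                        "split": split,
                        "ec_numbers": ";".join(sorted(str(e) for e in ecs)),
                    }
                )
    manifest = pd.DataFrame(rows, columns=["sequence_id", "split", "ec_numbers"])
    return FixtureBundle(config, store, labels, manifest, dict(centroids),
                         holdout)


def generate_fixture(config: FixtureConfig) -> FixtureBundle:
    """Tree + centroids + dataset in one deterministic call."""
    tree = sample_ec_tree(config)
    return generate_dataset(tree, make_centroids(tree, config), config)


def random_direction_queries(
    config: FixtureConfig, n: int, seed: int
) -> list[EmbeddingMatrix]:
    """Out-of-distribution queries: fresh random directions, same noise.

    Each query is built exactly like a fixture sequence but around a
    brand-new random unit direction unrelated to any class centroid —
    the synthetic analogue of sequences far outside the lookup set that
    a calibrated refusal threshold should decline to annotate.
    """
    rng = np.random.default_rng([seed, 71])
    lo, hi = config.length_range
    scale = config.residue_noise / np.sqrt(config.dim)
    out = []
    for i in range(n):
        c = _unit(rng, config.dim)
        L = int(rng.integers(lo, hi + 1))
        mat = c[None, :] + scale * rng.standard_normal((L, config.dim))
        out.append(EmbeddingMatrix(f"random{i:03d}", mat))
    return out
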