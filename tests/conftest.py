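"""Shared fixtures.

``benchmark`` is the expensive session-scoped pipeline run on the default
synthetic fixture (108 planted depth-4 classes, 4 held out, D=64):
contrastive training for 30 epochs, index construction from the training
split, and k=20 annotation of the test split.  Several integration and
property tests share it so the pipeline runs only once per session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from ecknn import (
    Annotation,
    FixtureBundle,
    FixtureConfig,
    LookupIndex,
    PredictionRecord,
    ProjectionModel,
    RetrievalConfig,
    TrainConfig,
    TrainResult,
    annotate_batch,
    build_index,
    generate_fixture,
    project_batch,
    small_config,
    train_model,
)


@dataclass
class BenchmarkRun:
    fixture: FixtureBundle
    result: TrainResult
    model: ProjectionModel
    index: LookupIndex
    train_items: list
    test_items: list
    test_vectors: list
    annotations: dict[str, list[Annotation]]
    records: list[PredictionRecord]


@pytest.fixture(scope="session")
def benchmark() -> BenchmarkRun:
    fix = generate_fixture(FixtureConfig(seed=1))
    train = fix.train_items()
    test = fix.test_items()
    rng = np.random.default_rng(123)
    order = rng.permutation(len(train))
    n_val = max(2, len(train) // 10)
    val = [train[i] for i in order[:n_val]]
    tr = [train[i] for i in order[n_val:]]
    result = train_model(tr, val, small_config(dim=64, seed=1),
                         TrainConfig(epochs=30, seed=1))
    vecs = project_batch(result.model, [e for e, _ in train])
    index = build_index(vecs, {e.sequence_id: ls for e, ls in train})
    test_vecs = project_batch(result.model, [e for e, _ in test])
    annotations = annotate_batch(index, test_vecs, RetrievalConfig(k=20))
    truth = fix.truth("test")
    records = [
        PredictionRecord(q, frozenset(str(a.ec) for a in annotations[q]),
                         frozenset(truth[q]))
        for q in truth
    ]
    return BenchmarkRun(fix, result, result.model, index, train, test,
                        test_vecs, annotations, records)


@pytest.fixture(scope="session")
def small_fixture() -> FixtureBundle:
    """A compact planted benchmark (16 classes, D=32) for fast tests."""
    return generate_fixture(
        FixtureConfig(n_top_classes=2, branching=(2, 2, 2),
                      train_per_class=10, test_per_class=3, dim=32,
                      holdout_classes=0, seed=3)
    )
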