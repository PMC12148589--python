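"""Calibrate the refusal distance cutoff and test it on outliers.

Holds a few depth-4 classes out of training, calibrates the cutoff as
the 75th percentile of their nearest-hit distances to the lookup set,
and shows that random out-of-distribution queries are refused while
in-distribution test sequences are annotated.
"""

import numpy as np

from ecknn import (
    FixtureConfig,
    RetrievalConfig,
    TrainConfig,
    annotate_batch,
    build_index,
    calibrate_distance_cutoff,
    generate_fixture,
    nearest_hit_distances,
    project_batch,
    random_direction_queries,
    small_config,
    train_model,
)

fix = generate_fixture(
    FixtureConfig(n_top_classes=2, branching=(2, 2, 2), train_per_class=15,
                  test_per_class=5, dim=32, holdout_classes=2, seed=11)
)
train = fix.train_items()
result = train_model(train[24:], train[:24], small_config(dim=32, seed=11),
                     TrainConfig(epochs=15, seed=11))
model = result.model

index = build_index(
    project_batch(model, [e for e, _ in train]),
    {e.sequence_id: ls for e, ls in train},
)

holdout_vecs = project_batch(model, [e for e, _ in fix.holdout_items()])
cutoff = calibrate_distance_cutoff(nearest_hit_distances(index, holdout_vecs))
print(f"held-out classes: {fix.holdout_codes}")
print(f"calibrated distance cutoff (75th percentile): {cutoff:.4f}")

cfg = RetrievalConfig(k=20, distance_cutoff=cutoff)
test_vecs = project_batch(model, [e for e, _ in fix.test_items()])
rand_vecs = project_batch(model, random_direction_queries(fix.config, 40, 11))
for name, queries in (("in-distribution test", test_vecs),
                      ("random outliers", rand_vecs)):
    ann = annotate_batch(index, queries, cfg)
    refused = sum(1 for a in ann.values() if not a)
    print(f"{name}: {refused}/{len(queries)} refused")
# Outlier queries sit farther from every lookup entry than the held-out
# relatives used for calibration, so nearly all are refused; genuine
# in-distribution queries land well inside the cutoff.
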