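"""Scoring protocol: one-hot depth-4 metrics, truncation, buckets."""

import numpy as np
import pytest

from ecknn.evaluation import (
    PredictionRecord,
    bucket_by_support,
    score,
    truncate_predictions,
    within_group_similarity,
    write_metrics_report,
)


def R(qid, pred, truth):
    return PredictionRecord(qid, frozenset(pred), frozenset(truth))


class TestScore:
    def test_perfect_predictions(self):
        recs = [R("a", {"1.1.1.1"}, {"1.1.1.1"}),
                R("b", {"2.3.2.27", "1.1.1.1"}, {"2.3.2.27", "1.1.1.1"})]
        for avg in ("weighted", "sample"):
            assert score(recs, avg).summary == (1.0, 1.0, 1.0)

    def test_fourth_level_sibling_is_simply_wrong(self):
        """Predicting 2.7.7.7 for truth 2.7.7.6 earns no partial credit."""
        rec = R("q", {"2.7.7.7"}, {"2.7.7.6"})
        rep = score([rec], "sample")
        assert rep.summary == (0.0, 0.0, 0.0)
        assert rep.per_class["2.7.7.7"].fp == 1
        assert rep.per_class["2.7.7.6"].fn == 1

    @pytest.mark.parametrize(
        "records, expected_sample",
        [
            # refusal: FN for every truth label
            ([R("a", set(), {"1.1.1.1"})], (0.0, 0.0, 0.0)),
            # one TP one FP: P=1/2, R=1, F1=2/3
            ([R("a", {"1.1.1.1", "2.2.2.2"}, {"1.1.1.1"})],
             (0.5, 1.0, 2 / 3)),
            # one TP one FN: P=1, R=1/2, F1=2/3
            ([R("a", {"1.1.1.1"}, {"1.1.1.1", "2.2.2.2"})],
             (1.0, 0.5, 2 / 3)),
            # mixed pair of records averaged
            ([R("a", {"1.1.1.1"}, {"1.1.1.1"}),
              R("b", {"2.2.2.2"}, {"3.3.3.3"})], (0.5, 0.5, 0.5)),
            # two TP + one FP + one FN across 3 truth labels
            ([R("a", {"1.1.1.1", "2.2.2.2", "4.4.4.4"},
                {"1.1.1.1", "2.2.2.2", "3.3.3.3"})],
             (2 / 3, 2 / 3, 2 / 3)),
        ],
    )
    def test_hand_counted_tables(self, records, expected_sample):
        got = score(records, "sample").summary
        assert got == pytest.approx(expected_sample, abs=1e-9)

    def test_weighted_average_hand_example(self):
        # class 1.1.1.1: support 2, TP=2 -> P=R=F1=1
        # class 2.2.2.2: support 1, FN=1 and FP elsewhere -> 0
        recs = [
            R("a", {"1.1.1.1"}, {"1.1.1.1"}),
            R("b", {"1.1.1.1"}, {"1.1.1.1"}),
            R("c", {"3.3.3.3"}, {"2.2.2.2"}),
        ]
        rep = score(recs, "weighted")
        assert rep.summary == pytest.approx((2 / 3, 2 / 3, 2 / 3), abs=1e-9)
        assert rep.support == {"1.1.1.1": 2, "2.2.2.2": 1}

    def test_matches_sklearn_on_random_records(self):
        """Independent oracle: scikit-learn's multilabel one-hot metrics."""
        from sklearn.metrics import precision_recall_fscore_support
        from sklearn.preprocessing import MultiLabelBinarizer

        rng = np.random.default_rng(2)
        codes = [f"{a}.1.1.{b}" for a in range(1, 4) for b in range(1, 4)]
        records = []
        for i in range(40):
            truth = rng.choice(codes, size=rng.integers(1, 3), replace=False)
            pred = rng.choice(codes, size=rng.integers(0, 3), replace=False)
            records.append(R(f"q{i}", set(pred), set(truth)))
        mlb = MultiLabelBinarizer(classes=sorted(codes))
        y_true = mlb.fit_transform([sorted(r.truth) for r in records])
        y_pred = mlb.transform([sorted(r.predicted) for r in records])
        for avg in ("weighted", "samples"):
            p, r, f1, _ = precision_recall_fscore_support(
                y_true, y_pred, average=avg, zero_division=0
            )
            ours = score(records,
                         "sample" if avg == "samples" else avg).summary
            assert ours == pytest.approx((p, r, f1), abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        recs = [R(f"q{i}", {f"{1 + i % 2}.1.1.1"}, {f"{1 + i % 3}.1.1.1"})
                for i in range(9)]
        shuffled = [recs[i] for i in rng.permutation(9)]
        for avg in ("weighted", "sample"):
            assert score(recs, avg).summary == score(shuffled, avg).summary

    def test_shallow_code_rejected(self):
        with pytest.raises(ValueError, match="truncate"):
            score([R("a", {"1.1.1"}, {"1.1.1.1"})])

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            score([])


class TestTruncate:
    def test_third_level(self):
        recs = truncate_predictions(
            [R("a", {"2.7.4.4"}, {"2.7.7.6"})], level=3
        )
        assert recs[0].predicted == {"2.7.4"}
        assert recs[0].truth == {"2.7.7"}

    def test_merging_deduplicates(self):
        recs = truncate_predictions(
            [R("a", {"2.3.2.27", "2.3.2.31"}, {"2.3.2.27"})], level=3
        )
        assert recs[0].predicted == {"2.3.2"}

    def test_level_four_is_identity(self):
        orig = [R("a", {"2.3.2.27"}, {"1.1.1.1"})]
        assert truncate_predictions(orig, 4) == orig

    def test_truncation_cannot_reduce_recall(self):
        """Coarser classes only merge misses into hits."""
        rng = np.random.default_rng(5)
        codes = [f"{a}.{b}.1.{c}" for a in (1, 2) for b in (1, 2)
                 for c in (1, 2)]
        records = []
        for i in range(60):
            truth = rng.choice(codes, size=rng.integers(1, 3), replace=False)
            pred = rng.choice(codes, size=rng.integers(0, 3), replace=False)
            records.append(R(f"q{i}", set(pred), set(truth)))
        rec4 = score(records, "sample").summary[1]
        rec3 = score(truncate_predictions(records, 3), "sample",
                     level=3).summary[1]
        assert rec3 >= rec4 - 1e-12


class TestBuckets:
    def test_single_bucket_equals_overall(self):
        recs = [R("a", {"1.1.1.1"}, {"1.1.1.1"}),
                R("b", set(), {"2.2.2.2"})]
        counts = {"1.1.1.1": 10, "2.2.2.2": 3}
        rows = bucket_by_support(recs, counts, [0, 100])
        overall = score(recs, "sample").summary[2]
        assert rows[0]["n_records"] == 2
        assert rows[0]["f1"] == pytest.approx(overall)

    def test_partition_recombines_to_overall(self):
        rng = np.random.default_rng(6)
        codes = [f"{a}.1.1.1" for a in range(1, 6)]
        counts = {c: int(rng.integers(0, 50)) for c in codes}
        recs = [R(f"q{i}", {str(rng.choice(codes))}, {str(rng.choice(codes))})
                for i in range(30)]
        rows = bucket_by_support(recs, counts, [0, 10, 25, 100])
        total_f1 = score(recs, "sample").summary[2]
        recombined = sum(
            r["f1"] * r["n_records"] for r in rows if r["n_records"]
        ) / len(recs)
        assert recombined == pytest.approx(total_f1, abs=1e-9)

    def test_zero_support_goes_to_lowest_bucket(self):
        recs = [R("a", {"1.1.1.1"}, {"1.1.1.1"})]
        rows = bucket_by_support(recs, {"1.1.1.1": 0}, [1, 5, 10])
        assert rows[0]["n_records"] == 1

    def test_empty_bucket_flagged_not_dropped(self):
        recs = [R("a", {"1.1.1.1"}, {"1.1.1.1"})]
        rows = bucket_by_support(recs, {"1.1.1.1": 1}, [0, 2, 10])
        assert rows[1]["n_records"] == 0 and rows[1]["f1"] is None


class TestWithinGroupSimilarity:
    def test_identical_pair(self):
        a = np.array([[1.0, 0.0], [1.0, 0.0]])
        b = np.array([[0.0, 1.0]])
        out = within_group_similarity(a, b)
        assert out[0][0] == pytest.approx(1.0)
        assert out[0][1] == pytest.approx(0.0)

    def test_singleton_within_is_missing(self):
        out = within_group_similarity(np.array([[1.0, 0.0]]),
                                      np.array([[0.0, 1.0]]))
        assert out[0][0] is None

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((6, 5))
        b = rng.standard_normal((4, 5))
        out = within_group_similarity(a, b)
        for i in range(6):
            within = max(float(a[i] @ a[j]) for j in range(6) if j != i)
            to_b = max(float(a[i] @ b[j]) for j in range(4))
            assert out[i][0] == pytest.approx(within, abs=1e-12)
            assert out[i][1] == pytest.approx(to_b, abs=1e-12)


def test_metrics_report_file(tmp_path):
    rep = score([R("a", {"1.1.1.1"}, {"1.1.1.1"})], "sample")
    path = tmp_path / "metrics.tsv"
    write_metrics_report(rep, path)
    text = path.read_text()
    assert "1.1.1.1" in text and "# f1\t1.000000" in text
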