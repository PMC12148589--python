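"""Scoring protocol for multi-label EC annotation.

Metrics are computed on depth-4 EC codes treated one-hot: predicting
``2.7.7.7`` for a protein whose truth is ``2.7.7.6`` is simply wrong, with
no partial credit for the shared prefix.  Per record,

    TP = |predicted ∩ truth|,  FP = |predicted \\ truth|,  FN = |truth \\ predicted|,

and precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN),
each defined as 0 when its denominator is 0 (so a refusal counts as a
missed recall for every truth label).  Two aggregations are reported:
the *sample* average (per-record metrics averaged over records) and the
*weighted* average (per-class metrics weighted by truth support, which
compensates class imbalance).

For hold-out-class studies predictions and truth can first be truncated
to a shallower level (``2.7.4.4`` at level 3 becomes ``2.7.4``) and scored
one-hot at that level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .ec_labels import parse_ec

__all__ = [
    "PredictionRecord",
    "ClassMetrics",
    "MetricsReport",
    "score",
    "truncate_predictions",
    "bucket_by_support",
    "within_group_similarity",
    "write_metrics_report",
]


@dataclass(frozen=True)
class PredictionRecord:
    """One query's predicted and true EC code sets (empty predicted = refusal)."""

    query_id: str
    predicted: frozenset[str]
    truth: frozenset[str]

    def __post_init__(self) -> None:
        if not self.truth:
            raise ValueError(f"record {self.query_id!r} has empty truth")


@dataclass(frozen=True)
class ClassMetrics:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0


@dataclass(frozen=True)
class MetricsReport:
    averaging: str
    per_class: dict[str, ClassMetrics]
    support: dict[str, int]
    summary: tuple[float, float, float]  # (precision, recall, F1)


def _check_depth(codes: Sequence[str], level: int, where: str) -> None:
    for c in codes:
        if parse_ec(c).depth != level:
            raise ValueError(
                f"{where} code {c!r} has depth {parse_ec(c).depth}, "
                f"expected {level}; truncate records first if intended"
            )


def score(
    records: Sequence[PredictionRecord],
    averaging: str = "weighted",
    level: int = 4,
) -> MetricsReport:
    """One-hot multi-label precision/recall/F1 over a record set.

    ``averaging`` is ``"weighted"`` (per-class metrics weighted by truth
    support) or ``"sample"`` (per-record metrics averaged over records).
    All codes must be at exactly ``level`` resolved levels.
    """
    if not records:
        raise ValueError("cannot score an empty record list")
    if averaging not in ("weighted", "sample"):
        raise ValueError(f"unknown averaging {averaging!r}")
    for r in records:
        _check_depth(sorted(r.predicted), level, f"predicted ({r.query_id})")
        _check_depth(sorted(r.truth), level, f"truth ({r.query_id})")

    counts: dict[str, list[int]] = {}
    support: dict[str, int] = {}
    for r in records:
        for c in r.predicted & r.truth:
            counts.setdefault(c, [0, 0, 0])[0] += 1
        for c in r.predicted - r.truth:
            counts.setdefault(c, [0, 0, 0])[1] += 1
        for c in r.truth - r.predicted:
            counts.setdefault(c, [0, 0, 0])[2] += 1
        for c in r.truth:
            support[c] = support.get(c, 0) + 1
    per_class = {c: ClassMetrics(*v) for c, v in counts.items()}

    if averaging == "weighted":
        total = sum(support.values())
        p = sum(
            per_class.get(c, ClassMetrics(0, 0, 0)).precision * n
            for c, n in support.items()
        ) / total
        rcl = sum(
            per_class.get(c, ClassMetrics(0, 0, 0)).recall * n
            for c, n in support.items()
        ) / total
        f1 = sum(
            per_class.get(c, ClassMetrics(0, 0, 0)).f1 * n
            for c, n in support.items()
        ) / total
        summary = (p, rcl, f1)
    else:
        per_record = []
        for r in records:
            m = ClassMetrics(
                len(r.predicted & r.truth),
                len(r.predicted - r.truth),
                len(r.truth - r.predicted),
            )
            per_record.append((m.precision, m.recall, m.f1))
        arr = np.asarray(per_record)
        summary = tuple(float(x) for x in arr.mean(axis=0))

    return MetricsReport(averaging, per_class, support, summary)


def truncate_predictions(
    records: Sequence[PredictionRecord], level: int
) -> list[PredictionRecord]:
    """Truncate every predicted and truth code to ``level`` leading fields.

    Codes that merge after truncation are deduplicated, so scoring then
    proceeds one-hot at the shallower level.
    """
    if not 1 <= level <= 4:
        raise ValueError("level must lie in 1..4")

    def cut(codes: frozenset[str]) -> frozenset[str]:
        return frozenset(str(parse_ec(c).truncate(level)) for c in codes)

    return [
        PredictionRecord(r.query_id, cut(r.predicted), cut(r.truth))
        for r in records
    ]


def bucket_by_support(
    records: Sequence[PredictionRecord],
    train_label_counts: Mapping[str, int],
    bucket_edges: Sequence[float],
) -> list[dict]:
    """Sample-average F1 of records bucketed by training-set support.

    A record's support is the minimum training-set count over its truth
    codes; bucket i spans [edges[i], edges[i+1]) and values below the
    first edge fall into the lowest bucket.  Empty buckets are reported
    with ``n_records`` 0 and F1 ``None`` rather than dropped.
    """
    edges = list(bucket_edges)
    if len(edges) < 2 or any(a >= b for a, b in zip(edges, edges[1:])):
        raise ValueError("bucket_edges must be strictly increasing, length >= 2")
    for r in records:
        for c in r.truth:
            if c not in train_label_counts:
                raise KeyError(f"no training count for truth code {c!r}")
    buckets: list[list[PredictionRecord]] = [[] for _ in edges[:-1]]
    for r in records:
        sup = min(train_label_counts[c] for c in r.truth)
        i = int(np.searchsorted(edges, sup, side="right")) - 1
        i = min(max(i, 0), len(buckets) - 1)
        buckets[i].append(r)
    rows = []
    for i, members in enumerate(buckets):
        f1 = (
            score(members, averaging="sample").summary[2] if members else None
        )
        rows.append(
            {
                "bucket_low": edges[i],
                "bucket_high": edges[i + 1],
                "n_records": len(members),
                "f1": f1,
            }
        )
    return rows


def within_group_similarity(
    vectors_a: np.ndarray, vectors_b: np.ndarray
) -> list[tuple[float | None, float]]:
    """Per vector of group a: (max cosine to other a members, max cosine to b).

    Used to ask whether held-out sequences embed closer to each other than
    to anything in the lookup set.  For a singleton group a the within-a
    value is undefined and reported as ``None``.
    """
    a = np.asarray(vectors_a, dtype=np.float64)
    b = np.asarray(vectors_b, dtype=np.float64)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both vector sets must be non-empty 2-D arrays")
    aa = a @ a.T
    ab = a @ b.T
    out: list[tuple[float | None, float]] = []
    for i in range(a.shape[0]):
        row = np.delete(aa[i], i)
        within = float(row.max()) if row.size else None
        out.append((within, float(ab[i].max())))
    return out


def write_metrics_report(report: MetricsReport, path) -> None:
    """TSV report: per-class block then a summary block."""
    with open(path, "w") as fh:
        fh.write("ec_number\tsupport\ttp\tfp\tfn\tprecision\trecall\tf1\n")
        for c in sorted(set(report.per_class) | set(report.support)):
            m = report.per_class.get(c, ClassMetrics(0, 0, 0))
            fh.write(
                f"{c}\t{report.support.get(c, 0)}\t{m.tp}\t{m.fp}\t{m.fn}"
                f"\t{m.precision:.6f}\t{m.recall:.6f}\t{m.f1:.6f}\n"
            )
        p, r, f1 = report.summary
        fh.write(f"# averaging\t{report.averaging}\n")
        fh.write(f"# precision\t{p:.6f}\n")
        fh.write(f"# recall\t{r:.6f}\n")
        fh.write(f"# f1\t{f1:.6f}\n")
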