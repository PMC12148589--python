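"""Readers, writers and dataset-construction filters.

File formats: FASTA for sequences; TSV label tables (``sequence_id``,
``ec_numbers`` semicolon-separated, optional ``first_seen_date``);
two-column TSV cluster tables (representative, member) as produced by an
external sequence-clustering tool; HDF5 embedding stores keyed by
sequence id with random access.  All writers are deterministic (sorted
keys) so re-running a pipeline reproduces byte-identical split files.

Split construction mirrors standard leakage-safe practice for homology-
aware evaluation: whole clusters are removed from training with only
their representatives kept as test queries (clusters of fewer than
``min_cluster_size`` members are ineligible, screening out fragments),
and a label-consistency filter drops any test/validation sequence with a
depth-4 EC that no training sequence carries — a class no retrieval
method could possibly annotate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .ec_labels import ECNumber

__all__ = [
    "EmbeddingStore",
    "ClusterTable",
    "SplitBundle",
    "read_fasta",
    "read_embedding_store",
    "write_embedding_store",
    "read_cluster_table",
    "select_test_clusters",
    "filter_label_consistency",
    "time_based_split",
    "consensus_filter",
]


class MissingIdError(KeyError):
    """Lookup of a sequence id absent from a store."""


class EmbeddingStore:
    """Keyed collection sequence_id -> (L × D) per-residue embedding matrix.

    In-memory by default; ``open`` returns a lazily HDF5-backed store with
    random access by id (matrices are read on demand, never all at once).
    """

    def __init__(self, dim: int, metadata: Mapping[str, str] | None = None):
        if dim < 1:
            raise ValueError("embedding dimension must be >= 1")
        self.dim = int(dim)
        self.metadata = dict(metadata or {})
        self._data: dict[str, np.ndarray] = {}
        self._h5 = None

    # -- in-memory path ----------------------------------------------------

    def put(self, seq_id: str, matrix: np.ndarray) -> None:
        m = np.asarray(matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] < 1:
            raise ValueError(f"matrix for {seq_id!r} must be (L>=1, D)")
        if m.shape[1] != self.dim:
            raise ValueError(
                f"matrix for {seq_id!r} has D={m.shape[1]}, store has D={self.dim}"
            )
        if seq_id in self:
            raise ValueError(f"duplicate id {seq_id!r} in embedding store")
        self._data[seq_id] = m

    # -- shared interface --------------------------------------------------

    def ids(self) -> list[str]:
        if self._h5 is not None:
            return sorted(self._h5["embeddings"].keys())
        return sorted(self._data)

    def __contains__(self, seq_id: str) -> bool:
        if self._h5 is not None:
            return seq_id in self._h5["embeddings"]
        return seq_id in self._data

    def __getitem__(self, seq_id: str) -> np.ndarray:
        if self._h5 is not None:
            grp = self._h5["embeddings"]
            if seq_id not in grp:
                raise MissingIdError(seq_id)
            return np.asarray(grp[seq_id])
        if seq_id not in self._data:
            raise MissingIdError(seq_id)
        return self._data[seq_id]

    def __len__(self) -> int:
        if self._h5 is not None:
            return len(self._h5["embeddings"])
        return len(self._data)

    def close(self) -> None:
        if self._h5 is not None:
            self._h5.close()
            self._h5 = None

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        write_embedding_store(path, self)

    @classmethod
    def open(cls, path) -> "EmbeddingStore":
        import h5py

        fh = h5py.File(path, "r")
        store = cls(int(fh.attrs["dim"]),
                    {k: str(v) for k, v in fh.attrs.items() if k != "dim"})
        store._h5 = fh
        return store


def write_embedding_store(path, store: EmbeddingStore) -> None:
    """Write a store to HDF5; write-then-read round-trips bitwise."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["dim"] = store.dim
        for k, v in store.metadata.items():
            fh.attrs[k] = v
        grp = fh.create_group("embeddings")
        for sid in store.ids():
            grp.create_dataset(sid, data=store[sid])


def read_embedding_store(path) -> EmbeddingStore:
    """Open an HDF5 embedding store with lazy random access by id."""
    return EmbeddingStore.open(path)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercased sequence), order preserved.

    The id is the first whitespace-delimited header token.  Duplicate ids
    and empty sequences are errors.
    """
    from Bio import SeqIO

    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        seen.add(rec.id)
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"{path} contains no FASTA records")
    return records


# -- cluster tables and split construction ---------------------------------

@dataclass(frozen=True)
class ClusterTable:
    """Clusters as produced by an external tool: representative -> members."""

    clusters: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rep, members in self.clusters.items():
            if rep not in members:
                raise ValueError(
                    f"representative {rep!r} is not a member of its own cluster"
                )
            for m in members:
                if m in seen:
                    raise ValueError(f"member {m!r} appears in two clusters")
                seen.add(m)


def read_cluster_table(path) -> ClusterTable:
    """Two-column TSV (representative, member), no header."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None,
                     names=["representative", "member"], dtype=str)
    clusters: dict[str, list[str]] = {}
    for rep, mem in zip(df["representative"], df["member"]):
        clusters.setdefault(rep, []).append(mem)
    return ClusterTable({r: tuple(ms) for r, ms in clusters.items()})


def select_test_clusters(
    clusters: ClusterTable,
    n_clusters: int,
    min_cluster_size: int = 5,
    seed: int = 0,
) -> tuple[list[str], set[str]]:
    """Sample whole clusters out of training; their representatives are test.

    Uniform sampling without replacement over clusters of at least
    ``min_cluster_size`` members.  Returns (test representative ids,
    all member ids to remove from training).
    """
    eligible = sorted(
        r for r, ms in clusters.clusters.items() if len(ms) >= min_cluster_size
    )
    if n_clusters > len(eligible):
        raise ValueError(
            f"requested {n_clusters} clusters but only {len(eligible)} have "
            f">= {min_cluster_size} members"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(eligible, size=n_clusters, replace=False))
    removed = {m for r in chosen for m in clusters.clusters[r]}
    return list(chosen), removed


@dataclass(frozen=True)
class SplitBundle:
    """Disjoint train/test/validation id sets with their label tables."""

    train: dict[str, tuple[ECNumber, ...]]
    test: dict[str, tuple[ECNumber, ...]]
    validation: dict[str, tuple[ECNumber, ...]] = field(default_factory=dict)
    dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t, s, v = set(self.train), set(self.test), set(self.validation)
        if t & s or t & v or s & v:
            raise ValueError("split id sets must be pairwise disjoint")


def _depth4(labels: Mapping[str, tuple[ECNumber, ...]]) -> set[str]:
    return {str(e) for ecs in labels.values() for e in ecs if e.depth == 4}


def filter_label_consistency(
    bundle: SplitBundle, require_all: bool = True
) -> SplitBundle:
    """Drop test/validation sequences whose labels have no training carrier.

    With ``require_all`` (default) a sequence is dropped if *any* of its
    depth-4 ECs is unrepresented in training — the strict reading, fair to
    all its labels; with ``require_all=False`` only sequences with *no*
    represented EC are dropped.  Training is untouched; the returned
    bundle records how many ids each split lost.  Idempotent.
    """
    train_codes = _depth4(bundle.train)

    def keep(ecs: tuple[ECNumber, ...]) -> bool:
        codes = [str(e) for e in ecs if e.depth == 4]
        if not codes:
            return True
        present = [c in train_codes for c in codes]
        return all(present) if require_all else any(present)

    test = {i: e for i, e in bundle.test.items() if keep(e)}
    val = {i: e for i, e in bundle.validation.items() if keep(e)}
    return SplitBundle(
        dict(bundle.train),
        test,
        val,
        {
            "test": len(bundle.test) - len(test),
            "validation": len(bundle.validation) - len(val),
        },
    )


def time_based_split(
    labels: Mapping[str, tuple[ECNumber, ...]],
    dates: Mapping[str, str],
    cutoff_date: str,
) -> SplitBundle:
    """Train = ids first seen on/before the cutoff, test = later arrivals.

    Dates are ISO-8601 strings; the label-consistency filter is applied to
    the resulting test set.
    """
    import pandas as pd

    missing = sorted(set(labels) - set(dates))
    if missing:
        raise ValueError(f"no first-seen date for ids: {missing[:5]}")
    cutoff = pd.Timestamp(cutoff_date)
    parsed = {i: pd.Timestamp(dates[i]) for i in labels}
    for i, ts in parsed.items():
        if pd.isna(ts):
            raise ValueError(f"unparseable date for id {i!r}: {dates[i]!r}")
    train = {i: e for i, e in labels.items() if parsed[i] <= cutoff}
    test = {i: e for i, e in labels.items() if parsed[i] > cutoff}
    return filter_label_consistency(SplitBundle(train, test))


def consensus_filter(
    labels_a: Mapping[str, tuple[ECNumber, ...]],
    labels_b: Mapping[str, tuple[ECNumber, ...]],
) -> dict[str, tuple[ECNumber, ...]]:
    """Keep only (id, EC) pairs on which two annotation methods agree.

    Ids with no agreeing EC are dropped entirely.  Used to curate
    high-confidence labels for lookup-set supplementation from an
    ensemble of annotators.
    """
    out: dict[str, tuple[ECNumber, ...]] = {}
    for sid in labels_a:
        if sid not in labels_b:
            continue
        a = {str(e): e for e in labels_a[sid]}
        b = {str(e) for e in labels_b[sid]}
        agreed = tuple(a[c] for c in sorted(set(a) & b))
        if agreed:
            out[sid] = agreed
    return out
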