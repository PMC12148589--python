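"""Enzyme Commission (EC) numbers as hierarchical label sets.

An EC number is a four-level code such as ``2.3.2.27`` (a RING-type E3
ubiquitin transferase): level 1 is one of seven broad reaction classes and
each further level refines the reaction.  For metric learning we represent
an EC number by the set of its dot-joined prefixes at every resolved depth,
e.g. ``{"2", "2.3", "2.3.2", "2.3.2.27"}``.  The similarity between two
proteins' label sets is the overlap coefficient

    y(A, B) = |A ∩ B| / min(|A|, |B|),

which for two complete single EC numbers equals (shared leading levels)/4 —
0.75 for ``2.3.2.27`` vs ``2.3.2.31``, whose first three levels agree.

Swiss-Prot also contains partially resolved codes (``3.4.-.-``) and
preliminary serial numbers (``2.7.1.n1``).  Partial codes are truncated at
the last resolved level; preliminary tokens are kept literally and match
only on exact equality.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ECNumber",
    "ECParseError",
    "ProteinLabelSet",
    "parse_ec",
    "hierarchical_set",
    "protein_label_set",
    "overlap_coefficient",
    "read_label_table",
    "write_label_table",
]

_RESOLVED_RE = re.compile(r"^(?:[1-9][0-9]*|n[1-9][0-9]*)$")


class ECParseError(ValueError):
    """Raised when an EC code string cannot be parsed."""


@dataclass(frozen=True)
class ECNumber:
    """A parsed EC code of 1-4 resolved levels.

    ``levels`` holds the resolved level tokens in order; ``depth`` is the
    number of resolved levels.  Unresolved trailing ``-`` fields in the
    source text truncate the depth and are not stored.
    """

    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.levels) <= 4:
            raise ECParseError(f"EC number must have 1-4 levels, got {self.levels!r}")
        for tok in self.levels:
            if not _RESOLVED_RE.match(tok):
                raise ECParseError(f"invalid EC level token {tok!r}")

    @property
    def depth(self) -> int:
        return len(self.levels)

    def prefix(self, level: int) -> str:
        """Dot-joined prefix of the first ``level`` resolved levels."""
        if not 1 <= level <= self.depth:
            raise ValueError(f"level {level} outside 1..{self.depth}")
        return ".".join(self.levels[:level])

    def truncate(self, level: int) -> "ECNumber":
        """The EC number restricted to at most ``level`` leading levels."""
        return ECNumber(self.levels[: min(level, self.depth)])

    def __str__(self) -> str:
        return ".".join(self.levels)


def parse_ec(text: str) -> ECNumber:
    """Parse an EC code string such as ``"2.3.2.27"`` or ``"3.4.-.-"``.

    Trailing ``-`` placeholders truncate the resolved depth; a resolved
    field after a ``-`` is an error, as is an empty field or more than
    four fields.
    """
    if not isinstance(text, str) or not text.strip():
        raise ECParseError("empty EC code")
    fields = [f.strip() for f in text.strip().split(".")]
    if len(fields) > 4:
        raise ECParseError(f"EC code {text!r} has {len(fields)} fields (max 4)")
    levels: list[str] = []
    seen_unresolved = False
    for f in fields:
        if f == "":
            raise ECParseError(f"EC code {text!r} contains an empty field")
        if f == "-":
            seen_unresolved = True
            continue
        if seen_unresolved:
            raise ECParseError(
                f"EC code {text!r}: resolved field {f!r} follows an unresolved '-'"
            )
        if not _RESOLVED_RE.match(f):
            raise ECParseError(f"EC code {text!r}: malformed field {f!r}")
        levels.append(f)
    if not levels:
        raise ECParseError(f"EC code {text!r} has no resolved levels")
    return ECNumber(tuple(levels))


def hierarchical_set(ec: ECNumber) -> frozenset[str]:
    """The set of dot-joined prefixes of ``ec`` at depths 1..depth."""
    return frozenset(ec.prefix(d) for d in range(1, ec.depth + 1))


@dataclass(frozen=True)
class ProteinLabelSet:
    """Union of hierarchical prefix sets over all EC numbers of one protein.

    This is the per-protein object whose pairwise overlap coefficient is the
    training target of the contrastive loss.  It is closed under prefix: if
    ``2.3.2`` is present so are ``2`` and ``2.3``.
    """

    prefixes: frozenset[str]
    source_ecs: tuple[ECNumber, ...] = field(compare=False)

    def __len__(self) -> int:
        return len(self.prefixes)

    def depth4_codes(self) -> tuple[str, ...]:
        """Sorted depth-4 EC codes of this protein (the annotatable labels)."""
        return tuple(sorted(str(ec) for ec in self.source_ecs if ec.depth == 4))


def protein_label_set(ecs: Sequence[ECNumber]) -> ProteinLabelSet:
    """Build a protein's label set from its (one or more) EC numbers."""
    if not ecs:
        raise ValueError("protein has no EC numbers: label set would be empty")
    prefixes: set[str] = set()
    for ec in ecs:
        prefixes |= hierarchical_set(ec)
    return ProteinLabelSet(frozenset(prefixes), tuple(ecs))


def overlap_coefficient(a: ProteinLabelSet, b: ProteinLabelSet) -> float:
    """Overlap coefficient |A∩B| / min(|A|,|B|) between two label sets."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("overlap coefficient undefined for an empty label set")
    inter = len(a.prefixes & b.prefixes)
    return inter / min(len(a), len(b))


# ---------------------------------------------------------------------------
# Label tables: TSV with columns sequence_id, ec_numbers (';'-separated),
# optionally first_seen_date.  Writers are deterministic (sorted ids and
# codes) so re-running a pipeline reproduces byte-identical files.

def parse_ec_field(field_text: str) -> tuple[ECNumber, ...]:
    """Parse a semicolon-separated EC list from a label-table cell."""
    codes = [c for c in (p.strip() for p in field_text.split(";")) if c]
    if not codes:
        raise ECParseError(f"label field {field_text!r} contains no EC codes")
    return tuple(parse_ec(c) for c in codes)


def read_label_table(path) -> dict[str, tuple[ECNumber, ...]]:
    """Read a TSV label table into a mapping sequence_id -> EC numbers."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sequence_id", "ec_numbers"):
        if col not in df.columns:
            raise ValueError(f"label table {path} lacks required column {col!r}")
    out: dict[str, tuple[ECNumber, ...]] = {}
    for sid, ecs in zip(df["sequence_id"], df["ec_numbers"]):
        if sid in out:
            raise ValueError(f"duplicate sequence_id {sid!r} in label table {path}")
        out[sid] = parse_ec_field(ecs)
    return out


def write_label_table(
    path,
    labels: Mapping[str, Iterable[ECNumber]],
    dates: Mapping[str, str] | None = None,
) -> None:
    """Write a label table TSV, sorted by id with sorted EC codes per id."""
    import pandas as pd

    ids = sorted(labels)
    rows = {
        "sequence_id": ids,
        "ec_numbers": [";".join(sorted(str(e) for e in labels[i])) for i in ids],
    }
    if dates is not None:
        rows["first_seen_date"] = [dates[i] for i in ids]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
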