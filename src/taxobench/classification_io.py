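"""Ground-truth and classifier-output tables.

Truth tables are plain TSV (``read_id``, ``expected_taxid``) where the
literal ``SHUFFLED`` marks a base-permuted true-negative sequence.

Classifier outputs are wildly heterogeneous — taxids vs. name strings vs.
semicolon lineages, confidence scores vs. E-values, ambiguity markers — so
each table is read under a declared *dialect* that maps columns and
conventions onto a normalized :class:`Assignment`.  Ambiguous multi-taxon
calls are collapsed to their lowest common ancestor; the read keeps its own
reported score.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import yaml

from .taxonomy import TaxonomyDB, lca, resolve_name

SHUFFLED_LABEL = "SHUFFLED"


class DialectError(ValueError):
    """Bad dialect configuration or a table violating its declared dialect."""


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    expected_taxid: Optional[int]
    is_shuffled: bool


@dataclass
class TruthSet:
    records: dict[str, TruthRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __getitem__(self, read_id: str) -> TruthRecord:
        return self.records[read_id]

    @property
    def n_shuffled(self) -> int:
        return sum(r.is_shuffled for r in self.records.values())


@dataclass
class Assignment:
    """One normalized classifier call.

    ``assigned_taxid`` is None when the read is unclassified *or* its label
    could not be resolved to any taxid; the latter case sets ``unresolved``
    and keeps ``raw_label`` so downstream policy can count it as a false
    positive.  When the call was ambiguous, ``ambiguous_members`` holds the
    reported taxa and ``assigned_taxid`` their LCA.
    """

    read_id: str
    assigned_taxid: Optional[int]
    raw_label: str = ""
    score: Optional[float] = None
    ambiguous_members: Optional[list[int]] = None
    unresolved: bool = False


@dataclass
class AssignmentSet:
    assignments: list[Assignment]
    score_direction: str = "higher_better"  # or "lower_better"
    method_name: str = "unknown"
    unresolved_policy: str = "fp"  # or "unclassified"
    unresolved_count: int = 0

    def __post_init__(self) -> None:
        if self.score_direction not in ("higher_better", "lower_better"):
            raise DialectError(f"bad score_direction {self.score_direction!r}")
        self.by_read: dict[str, Assignment] = {}
        for a in self.assignments:
            if a.read_id in self.by_read:
                raise DialectError(f"duplicate assignment for read {a.read_id!r}")
            self.by_read[a.read_id] = a

    def __len__(self) -> int:
        return len(self.assignments)

    def get(self, read_id: str) -> Optional[Assignment]:
        return self.by_read.get(read_id)


@dataclass(frozen=True)
class DialectSpec:
    """Column mapping + conventions for one classifier's output table.

    ``label_kind`` is one of ``taxid`` (integer id), ``name`` (taxon name
    resolved against the taxonomy), ``lineage`` (separator-joined names,
    deepest resolvable one wins).  ``ambiguity_marker`` introduces a
    multi-taxon call, e.g. ``AMBIGUOUS(a;b)``.
    """

    name: str = "native"
    read_id_col: int = 0
    label_col: int = 1
    score_col: Optional[int] = 2
    label_kind: str = "taxid"
    score_direction: str = "higher_better"
    ambiguity_marker: Optional[str] = "AMBIGUOUS"
    ambiguity_separator: str = ";"
    lineage_separator: str = ";"
    unresolved: str = "fp"
    has_header: bool = True
    unclassified_labels: tuple[str, ...] = ("", "unclassified", "NA")

    def __post_init__(self) -> None:
        if self.label_kind not in ("taxid", "name", "lineage"):
            raise DialectError(f"bad label_kind {self.label_kind!r}")
        if self.score_direction not in ("higher_better", "lower_better"):
            raise DialectError(f"bad score_direction {self.score_direction!r}")
        if self.unresolved not in ("fp", "unclassified"):
            raise DialectError(f"bad unresolved policy {self.unresolved!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "DialectSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise DialectError(f"{path}: dialect file must be a key-value mapping")
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DialectError(f"{path}: unknown dialect keys {sorted(unknown)}")
        if "unclassified_labels" in raw:
            raw["unclassified_labels"] = tuple(raw["unclassified_labels"])
        return cls(**raw)


#: The dialect used by :func:`write_assignments`.
NATIVE_DIALECT = DialectSpec(name="native")


def read_truth(path: str | Path) -> TruthSet:
    """Read a truth TSV: header ``read_id\\texpected_taxid``, one row per read;
    ``SHUFFLED`` in the taxid column flags a true-negative sequence."""
    records: dict[str, TruthRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise DialectError(f"{path}: empty truth file (header required)")
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            if len(row) < 2:
                raise DialectError(f"{path}:{lineno}: expected 2 columns")
            read_id, label = row[0], row[1].strip()
            if read_id in records:
                raise DialectError(f"{path}:{lineno}: duplicate read_id {read_id!r}")
            if label == SHUFFLED_LABEL:
                records[read_id] = TruthRecord(read_id, None, True)
            else:
                try:
                    taxid = int(label)
                except ValueError:
                    raise DialectError(
                        f"{path}:{lineno}: malformed expected_taxid {label!r}"
                    ) from None
                records[read_id] = TruthRecord(read_id, taxid, False)
    return TruthSet(records)


def write_truth(truth: TruthSet, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("read_id\texpected_taxid\n")
        for rec in truth:
            label = SHUFFLED_LABEL if rec.is_shuffled else str(rec.expected_taxid)
            out.write(f"{rec.read_id}\t{label}\n")


def collapse_ambiguous(db: TaxonomyDB, members: list[int]) -> int:
    """LCA of an ambiguous call's reported taxa."""
    return lca(db, members)


def _resolve_label(
    label: str, dialect: DialectSpec, db: TaxonomyDB
) -> tuple[Optional[int], bool]:
    """Resolve one (non-ambiguous) label to a taxid.

    Returns ``(taxid, unresolved)``; a resolvable homonym set collapses to
    its LCA.
    """
    if dialect.label_kind == "taxid":
        try:
            taxid = int(label)
        except ValueError:
            return None, True
        return (taxid, False) if taxid in db else (None, True)
    if dialect.label_kind == "name":
        hits = resolve_name(db, label)
        if not hits:
            return None, True
        return (hits[0] if len(hits) == 1 else lca(db, hits)), False
    # lineage: deepest resolvable name wins
    for part in reversed(label.split(dialect.lineage_separator)):
        hits = resolve_name(db, part)
        if hits:
            return (hits[0] if len(hits) == 1 else lca(db, hits)), False
    return None, True


def _parse_ambiguous(
    label: str, dialect: DialectSpec, db: TaxonomyDB
) -> Optional[tuple[Optional[int], list[int], bool]]:
    """If ``label`` matches the ambiguity convention, collapse it.

    Returns ``(lca_taxid, members, unresolved)`` or None when the label is
    not an ambiguous call.
    """
    marker = dialect.ambiguity_marker
    if marker is None or not label.startswith(marker):
        return None
    inner = label[len(marker):].strip()
    if inner.startswith("(") and inner.endswith(")"):
        inner = inner[1:-1]
    members: list[int] = []
    any_unresolved = False
    for part in inner.split(dialect.ambiguity_separator):
        part = part.strip()
        if not part:
            continue
        taxid, unres = _resolve_label(part, dialect, db)
        if unres:
            any_unresolved = True
        else:
            members.append(taxid)
    if not members:
        return None, [], True
    return collapse_ambiguous(db, members), members, any_unresolved


def read_assignments(
    path: str | Path,
    dialect: DialectSpec,
    db: TaxonomyDB,
    *,
    method_name: Optional[str] = None,
) -> AssignmentSet:
    """Read a classifier output table under ``dialect``.

    Every row becomes exactly one :class:`Assignment`; reads present in the
    truth but absent here stay absent — the evaluation joins on the truth
    set, so missing rows mean "unclassified" there.
    """
    assignments: list[Assignment] = []
    unresolved_count = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        if dialect.has_header:
            next(reader, None)
        needed = max(
            dialect.read_id_col,
            dialect.label_col,
            dialect.score_col if dialect.score_col is not None else 0,
        )
        for lineno, row in enumerate(reader, start=2 if dialect.has_header else 1):
            if not row or not "".join(row).strip():
                continue
            if len(row) <= needed:
                raise DialectError(
                    f"{path}:{lineno}: expected >= {needed + 1} columns, got {len(row)}"
                )
            read_id = row[dialect.read_id_col]
            label = row[dialect.label_col].strip()
            score: Optional[float] = None
            if dialect.score_col is not None:
                raw_score = row[dialect.score_col].strip()
                if raw_score not in ("", "NA", "nan"):
                    try:
                        score = float(raw_score)
                    except ValueError:
                        raise DialectError(
                            f"{path}:{lineno}: malformed score {raw_score!r}"
                        ) from None
                    if math.isnan(score):
                        score = None

            if label in dialect.unclassified_labels:
                assignments.append(Assignment(read_id, None, label, score))
                continue

            amb = _parse_ambiguous(label, dialect, db)
            if amb is not None:
                taxid, members, unres = amb
                if unres and taxid is None:
                    unresolved_count += 1
                    assignments.append(
                        Assignment(read_id, None, label, score, unresolved=True)
                    )
                else:
                    assignments.append(
                        Assignment(read_id, taxid, label, score, ambiguous_members=members)
                    )
                continue

            taxid, unres = _resolve_label(label, dialect, db)
            if unres:
                unresolved_count += 1
            assignments.append(Assignment(read_id, taxid, label, score, unresolved=unres))

    return AssignmentSet(
        assignments=assignments,
        score_direction=dialect.score_direction,
        method_name=method_name or dialect.name,
        unresolved_policy=dialect.unresolved,
        unresolved_count=unresolved_count,
    )


def write_assignments(aset: AssignmentSet, path: str | Path) -> None:
    """Write in the native dialect (read_id, taxid-or-AMBIGUOUS(...), score).

    Round-trips through :func:`read_assignments` with :data:`NATIVE_DIALECT`.
    """
    with open(path, "w") as out:
        out.write("read_id\ttaxid\tscore\n")
        for a in aset.assignments:
            if a.ambiguous_members:
                label = "AMBIGUOUS(" + ";".join(str(m) for m in a.ambiguous_members) + ")"
            elif a.assigned_taxid is not None:
                label = str(a.assigned_taxid)
            elif a.unresolved:
                label = a.raw_label
            else:
                label = "unclassified"
            score = "" if a.score is None else repr(a.score)
            out.write(f"{a.read_id}\t{label}\t{score}\n")
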