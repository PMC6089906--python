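"""Per-read, per-rank confusion labeling and classification metrics.

Every read is scored at each of the eight canonical ranks by comparing the
taxid of its expected lineage against the taxid of its assigned lineage:

* expected taxon present, assignment agrees           -> TP
* expected taxon present, assignment absent           -> FN
* expected taxon present, assignment disagrees        -> FP, and every
  deeper evaluated rank is FP too (a wrong branch cannot recover)
* expected lineage has no taxon at the rank           -> NA (excluded)
* shuffled (unclassifiable) read, assignment absent   -> TN
* shuffled read, assignment present                   -> FP

so a read correctly annotated to family but unclassified below yields
``TP TP TP TP TP FN FN FN``, while a wrong genus under a correct family
yields ``TP TP TP TP TP FP FP FP`` — non-classification and
misclassification stay distinguishable at every rank.

From the per-rank confusion counts the module computes error per query
(EPQ = FP / total queries), coverage (TP / reads with an expected taxon at
the rank), sensitivity, specificity, accuracy and the Matthews correlation
coefficient.  MCC = 0 means no better than random; MCC < 0 worse than
random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .classification_io import AssignmentSet, TruthSet
from .taxonomy import RANKS, Lineage, TaxonomyDB, homogenize

TP, FP, FN, TN, NA = "TP", "FP", "FN", "TN", "NA"


@dataclass(frozen=True)
class RankLabels:
    """The eight-rank confusion labels of one read.

    ``expected_filled[i]`` records whether the expected lineage carries a
    taxon at rank ``i`` (needed for per-rank coverage denominators).
    """

    read_id: str
    labels: tuple[str, ...]
    is_shuffled: bool
    expected_filled: tuple[bool, ...]


@dataclass
class RankConfusion:
    rank: str
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    na: int = 0
    total_queries: int = 0
    total_expected: int = 0


@dataclass
class MetricsRecord:
    """The six per-rank metrics; zero-denominator metrics are flagged in
    ``undefined`` instead of being coerced to a number (an MCC whose product
    of marginals is zero is reported as 0 and flagged ``degenerate``)."""

    rank: str
    tp: int
    fp: int
    fn: int
    tn: int
    na: int
    total_queries: int
    total_expected: int
    epq: Optional[float] = None
    coverage: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    accuracy: Optional[float] = None
    mcc: Optional[float] = None
    undefined: set = field(default_factory=set)


METRIC_NAMES = ("epq", "coverage", "sensitivity", "specificity", "accuracy", "mcc")


def label_read(
    expected: Optional[Lineage],
    assigned: Optional[Lineage],
    is_shuffled: bool,
    *,
    unresolved: bool = False,
    unresolved_policy: str = "fp",
    na_as_tn: bool = False,
) -> tuple[str, ...]:
    """Label one read at all eight ranks.

    ``assigned`` is None for an unclassified read.  ``unresolved`` marks a
    call whose label could not be mapped to any taxid; under the default
    ``fp`` policy such a call counts as a (wrong) classification at every
    evaluated rank, under ``unclassified`` it is treated as no call at all.

    ``na_as_tn`` converts structural gaps in the expected lineage (rank
    absent from the taxonomy) from NA into TN when the assignment is also
    empty there; default keeps them NA so specificity stays anchored to the
    shuffled true negatives.
    """
    unresolved_as_fp = unresolved and unresolved_policy == "fp"

    labels: list[str] = []
    if is_shuffled:
        # only FP (classified) and TN (not classified) exist for shuffled reads
        for i in range(len(RANKS)):
            slot = assigned.slots[i] if assigned is not None else None
            if slot is not None or unresolved_as_fp:
                labels.append(FP)
            else:
                labels.append(TN)
        return tuple(labels)

    if expected is None:
        raise ValueError("non-shuffled read requires an expected lineage")

    poisoned = False  # a wrong call at some rank poisons all deeper ranks
    for i in range(len(RANKS)):
        exp = expected.slots[i]
        if exp is None:
            got = assigned.slots[i] if assigned is not None else None
            if na_as_tn and got is None and not unresolved_as_fp:
                labels.append(TN)
            else:
                labels.append(NA)
            continue
        if poisoned:
            labels.append(FP)
            continue
        got = assigned.slots[i] if assigned is not None else None
        if unresolved_as_fp:
            labels.append(FP)
            poisoned = True
        elif got is None:
            labels.append(FN)
        elif got == exp:
            labels.append(TP)
        else:
            labels.append(FP)
            poisoned = True
    return tuple(labels)


def label_set(
    truth: TruthSet,
    assignments: AssignmentSet,
    db: TaxonomyDB,
    *,
    strain_as_subspecies: bool = False,
    na_as_tn: bool = False,
) -> list[RankLabels]:
    """Label every truth read.  Reads absent from the assignment table are
    treated as unclassified; assignment rows for unknown reads are an error
    in the evaluation join, not here."""
    lineage_cache: dict[int, Lineage] = {}

    def _lin(taxid: int) -> Lineage:
        if taxid not in lineage_cache:
            lineage_cache[taxid] = homogenize(
                db, taxid, strain_as_subspecies=strain_as_subspecies
            )
        return lineage_cache[taxid]

    out: list[RankLabels] = []
    for rec in truth:
        a = assignments.get(rec.read_id)
        assigned_lin = None
        unresolved = False
        if a is not None:
            unresolved = a.unresolved
            if a.assigned_taxid is not None:
                assigned_lin = _lin(a.assigned_taxid)
        expected_lin = None if rec.is_shuffled else _lin(rec.expected_taxid)
        labels = label_read(
            expected_lin,
            assigned_lin,
            rec.is_shuffled,
            unresolved=unresolved,
            unresolved_policy=assignments.unresolved_policy,
            na_as_tn=na_as_tn,
        )
        filled = (
            (False,) * len(RANKS)
            if expected_lin is None
            else tuple(s is not None for s in expected_lin.slots)
        )
        out.append(RankLabels(rec.read_id, labels, rec.is_shuffled, filled))
    return out


def aggregate(all_labels: Sequence[RankLabels], truth: TruthSet) -> list[RankConfusion]:
    """Per-rank confusion counts over a labeled read set."""
    known = truth.records
    confusions = [RankConfusion(rank=r) for r in RANKS]
    seen: set[str] = set()
    for rl in all_labels:
        if rl.read_id not in known:
            raise KeyError(f"labels for read {rl.read_id!r} not present in truth set")
        if rl.read_id in seen:
            raise KeyError(f"duplicate labels for read {rl.read_id!r}")
        seen.add(rl.read_id)
        for i, lab in enumerate(rl.labels):
            c = confusions[i]
            c.total_queries += 1
            if rl.expected_filled[i]:
                c.total_expected += 1
            if lab == TP:
                c.tp += 1
            elif lab == FP:
                c.fp += 1
            elif lab == FN:
                c.fn += 1
            elif lab == TN:
                c.tn += 1
            else:
                c.na += 1
    return confusions


def metrics(conf: RankConfusion) -> MetricsRecord:
    """The six metrics from one rank's confusion counts.

    NA (unevaluated) reads never enter tp/fp/fn/tn; EPQ keeps the full query
    count as its denominator because it measures error accumulation per
    submitted query, not per evaluated one.
    """
    tp, fp, fn, tn = conf.tp, conf.fp, conf.fn, conf.tn
    rec = MetricsRecord(
        rank=conf.rank,
        tp=tp, fp=fp, fn=fn, tn=tn, na=conf.na,
        total_queries=conf.total_queries,
        total_expected=conf.total_expected,
    )

    def ratio(num: float, den: float, name: str) -> Optional[float]:
        if den == 0:
            rec.undefined.add(name)
            return None
        return num / den

    rec.epq = ratio(fp, conf.total_queries, "epq")
    rec.coverage = ratio(tp, conf.total_expected, "coverage")
    rec.sensitivity = ratio(tp, tp + fn, "sensitivity")
    rec.specificity = ratio(tn, tn + fp, "specificity")
    rec.accuracy = ratio(tp + tn, tp + fp + fn + tn, "accuracy")

    prod = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if tp + fp + fn + tn == 0:
        rec.undefined.add("mcc")
        rec.mcc = None
    elif prod == 0:
        rec.undefined.add("degenerate")
        rec.mcc = 0.0
    else:
        rec.mcc = (tp * tn - fp * fn) / math.sqrt(prod)
    return rec


def metrics_table(
    confusions: Sequence[RankConfusion],
    *,
    method: str = "unknown",
    replicate: str | int = 1,
) -> pd.DataFrame:
    """Tidy per-rank metrics: one row per rank, undefined metrics as NaN."""
    rows = []
    for conf in confusions:
        m = metrics(conf)
        rows.append(
            {
                "method": method,
                "replicate": replicate,
                "rank": m.rank,
                "tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn, "na": m.na,
                "total_queries": m.total_queries,
                "total_expected": m.total_expected,
                **{
                    name: (np.nan if getattr(m, name) is None else getattr(m, name))
                    for name in METRIC_NAMES
                },
            }
        )
    return pd.DataFrame(rows)


def evaluate(
    truth: TruthSet,
    assignments: AssignmentSet,
    db: TaxonomyDB,
    *,
    replicate: str | int = 1,
    strain_as_subspecies: bool = False,
    na_as_tn: bool = False,
) -> tuple[list[RankLabels], list[RankConfusion], pd.DataFrame]:
    """Label, aggregate and compute metrics in one call."""
    labels = label_set(
        truth, assignments, db,
        strain_as_subspecies=strain_as_subspecies, na_as_tn=na_as_tn,
    )
    confusions = aggregate(labels, truth)
    table = metrics_table(
        confusions, method=assignments.method_name, replicate=replicate
    )
    return labels, confusions, table


def summarize_replicates(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-rank mean and sample (n-1) standard deviation across replicates.

    Undefined (NaN) metrics are excluded pairwise.  All replicates must
    cover the same rank set.
    """
    if len(tables) < 2:
        raise ValueError(">=2 replicates required to summarize")
    rank_sets = [tuple(t["rank"]) for t in tables]
    if len(set(rank_sets)) != 1:
        raise ValueError("replicates cover mismatched rank sets")
    stacked = pd.concat(tables, ignore_index=True)
    agg = stacked.groupby("rank", sort=False)[list(METRIC_NAMES)].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()


def abundance_profile(
    assignments: AssignmentSet,
    truth: TruthSet,
    db: TaxonomyDB,
    rank: str,
) -> pd.DataFrame:
    """Observed vs. expected relative abundance at one rank.

    Observed abundances are fractions of *classified* reads whose
    homogenized assigned lineage carries each taxon at the rank; expected
    abundances are computed identically from the truth taxids (shuffled
    reads excluded from the expected side, included in the observed side
    whenever a classifier assigned them).  Taxa observed but absent from the
    expected set are marked ``is_other`` — per-taxon detail is retained so
    spurious calls stay attributable.  ``bias = observed - expected``.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    idx = RANKS.index(rank)
    cache: dict[int, Optional[int]] = {}

    def slot_of(taxid: int) -> Optional[int]:
        if taxid not in cache:
            cache[taxid] = homogenize(db, taxid).slots[idx]
        return cache[taxid]

    observed: dict[int, int] = {}
    n_classified = 0
    for rec in truth:
        a = assignments.get(rec.read_id)
        if a is None or a.assigned_taxid is None:
            continue
        n_classified += 1
        slot = slot_of(a.assigned_taxid)
        if slot is not None:
            observed[slot] = observed.get(slot, 0) + 1

    expected: dict[int, int] = {}
    n_real = 0
    for rec in truth:
        if rec.is_shuffled:
            continue
        n_real += 1
        slot = slot_of(rec.expected_taxid)
        if slot is not None:
            expected[slot] = expected.get(slot, 0) + 1

    rows = []
    for taxid in sorted(set(observed) | set(expected)):
        obs = observed.get(taxid, 0) / n_classified if n_classified else 0.0
        exp = expected.get(taxid, 0) / n_real if n_real else 0.0
        rows.append(
            {
                "rank": rank,
                "taxid": taxid,
                "taxon": db.name(taxid),
                "observed": obs,
                "expected": exp,
                "bias": obs - exp,
                "is_other": taxid not in expected,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["rank", "taxid", "taxon", "observed", "expected", "bias", "is_other"],
    )
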