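"""Coverage-vs-error-per-query (CVE) curves and score cut-off extraction.

Assignments at one rank are ordered from best to worst reported score;
walking down the ranking, cumulative EPQ (false positives over *all*
queries) is plotted against cumulative coverage (true positives over reads
with an expected taxon at the rank).  A flatter curve means more coverage
bought per unit of error.  The cut-off at a target error rate (1%, 5%, 10%
by convention) is the worst score admitted before cumulative EPQ exceeds
the target, which makes heterogeneous scores (confidence, E-value,
reliability...) comparable across classifiers.

Ties on score are processed as one block, so curves and cut-offs are
invariant to the input order of equally-scored reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .classification_io import AssignmentSet
from .evaluation import FP, TP, RankLabels
from .taxonomy import RANKS

DEFAULT_TARGETS = (0.01, 0.05, 0.10)


@dataclass(frozen=True)
class CVEPoint:
    score: float
    cum_epq: float
    cum_coverage: float


@dataclass
class CVECurve:
    rank: str
    points: list[CVEPoint]
    total_queries: int
    total_expected: int
    score_direction: str
    method_name: str = "unknown"

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class CutoffResult:
    rank: str
    target_error: float
    score_cutoff: Optional[float]
    coverage_at_cutoff: float
    reached: bool


def build_cve(
    labels: Sequence[RankLabels],
    assignments: AssignmentSet,
    rank: str,
) -> CVECurve:
    """Build the score-ranked curve for one rank.

    Only reads carrying a score *and* labeled TP or FP at the rank enter the
    ranking; FN/TN/NA reads (and unscored calls) contribute to the fixed
    denominators only.  One point is appended per tie block, reflecting the
    whole block.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    idx = RANKS.index(rank)

    total_queries = len(labels)
    total_expected = sum(rl.expected_filled[idx] for rl in labels)

    scored: list[tuple[float, bool]] = []  # (score, is_tp)
    for rl in labels:
        lab = rl.labels[idx]
        if lab not in (TP, FP):
            continue
        a = assignments.get(rl.read_id)
        if a is None or a.score is None:
            continue
        scored.append((a.score, lab == TP))

    if not scored:
        import logging

        logging.getLogger(__name__).warning(
            "no scored TP/FP reads at rank %s for %s: empty curve",
            rank, assignments.method_name,
        )

    reverse = assignments.score_direction == "higher_better"
    scored.sort(key=lambda t: t[0], reverse=reverse)

    points: list[CVEPoint] = []
    cum_tp = cum_fp = 0
    i = 0
    while i < len(scored):
        j = i
        while j < len(scored) and scored[j][0] == scored[i][0]:
            j += 1
        for k in range(i, j):
            if scored[k][1]:
                cum_tp += 1
            else:
                cum_fp += 1
        points.append(
            CVEPoint(
                score=scored[i][0],
                cum_epq=cum_fp / total_queries if total_queries else 0.0,
                cum_coverage=cum_tp / total_expected if total_expected else 0.0,
            )
        )
        i = j

    return CVECurve(
        rank=rank,
        points=points,
        total_queries=total_queries,
        total_expected=total_expected,
        score_direction=assignments.score_direction,
        method_name=assignments.method_name,
    )


def cutoff_at_error(curve: CVECurve, target_error: float) -> CutoffResult:
    """Longest block-aligned prefix of the curve with cum_epq <= target.

    The cut-off score is the worst score in that prefix.  When even the
    best-scored block exceeds the target, ``reached`` is False and coverage
    is 0.
    """
    if not 0 < target_error < 1:
        raise ValueError(f"target_error must be in (0,1), got {target_error}")
    best: Optional[CVEPoint] = None
    for pt in curve.points:  # cum_epq is non-decreasing; keep the last admissible
        if pt.cum_epq <= target_error:
            best = pt
        else:
            break
    if best is None:
        return CutoffResult(curve.rank, target_error, None, 0.0, False)
    return CutoffResult(curve.rank, target_error, best.score, best.cum_coverage, True)


def cutoff_table(
    curves: Sequence[CVECurve],
    targets: Sequence[float] = DEFAULT_TARGETS,
    *,
    replicate: str | int = 1,
) -> pd.DataFrame:
    """Machine-readable cut-off table: one row per curve x target error."""
    rows = []
    for curve in curves:
        for t in targets:
            c = cutoff_at_error(curve, t)
            rows.append(
                {
                    "method": curve.method_name,
                    "replicate": replicate,
                    "rank": curve.rank,
                    "target_error": t,
                    "score_cutoff": c.score_cutoff,
                    "coverage": c.coverage_at_cutoff,
                    "reached": c.reached,
                }
            )
    return pd.DataFrame(rows)


def export_cve_plot(
    curves: Sequence[CVECurve],
    path: str | Path,
    annotations: Sequence[float] = DEFAULT_TARGETS,
) -> None:
    """Plot EPQ (x) against coverage (y), one series per curve, with vertical
    guides at the annotation error rates.  Format follows the extension
    (.svg / .png)."""
    if not curves:
        raise ValueError("at least one curve required")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for curve in curves:
        xs = [p.cum_epq for p in curve.points]
        ys = [p.cum_coverage for p in curve.points]
        ax.plot(xs, ys, marker=".", markersize=3, linewidth=1.2,
                label=curve.method_name)
    for t in annotations:
        ax.axvline(t, color="grey", linestyle=":", linewidth=0.8)
        ax.text(t, ax.get_ylim()[1], f"{t:.0%}", fontsize=7,
                ha="center", va="bottom", color="grey")
    ax.set_xlabel("Error per query (EPQ)")
    ax.set_ylabel("Coverage")
    ax.set_title(f"CVE at {curves[0].rank} level")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
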