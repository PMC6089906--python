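"""Self-contained benchmark dataset construction.

Builds everything a closed-loop benchmark needs without any download:

* a mock taxonomy with exactly the eight canonical ranks,
* one 16S-like template per leaf taxon with embedded primer sites,
* in-silico PCR with degenerate (IUPAC) primers,
* replicate amplicon libraries — merged amplicons plus fixed-quality paired
  reads — under a linear rank-abundance model with a shared reference pool
  across replicates,
* base-shuffled unclassifiable sequences as designed true negatives,
* a configurable mock annotator whose error rates are known by
  construction, closing the loop with the evaluation module.

Library defaults mirror a realistic V3-V4 amplicon benchmark: 750,000 read
pairs of 300 bp per replicate at a fixed Phred 30, three replicates sharing
90% of their reference sequences, and 37,500 shuffled sequences spiked into
each library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

from .classification_io import Assignment, AssignmentSet, TruthRecord, TruthSet
from .taxonomy import RANKS, TaxonomyDB, homogenize

# ---------------------------------------------------------------------------
# mock taxonomy

_RANK_CODES = ("d", "p", "c", "o", "f", "g", "s", "t")


def make_mock_taxonomy(
    branching: Sequence[int] = (1, 4, 2, 2, 2, 3, 3, 1),
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
) -> TaxonomyDB:
    """Balanced mock taxonomy with one level per canonical rank.

    ``branching[i]`` children of rank ``RANKS[i]`` hang under every node of
    the previous level; the default yields 288 leaf taxa.  Names encode the
    path (``d1_p2_c1...``) so they are unique and human-readable.  The
    structure is fully deterministic; ``seed`` is accepted for interface
    symmetry with the other generators.  With ``out_dir``, ``nodes.tsv`` and
    ``names.tsv`` are written in the simplified dialect.
    """
    if len(branching) != len(RANKS):
        raise ValueError(f"need {len(RANKS)} branching counts")
    if any(b < 1 for b in branching):
        raise ValueError("branching counts must be >= 1")

    nodes: dict[int, tuple[int, str]] = {1: (1, "no rank")}
    names: dict[int, str] = {1: "root"}
    next_id = 2
    level = [1]
    for depth, count in enumerate(branching):
        new_level = []
        for parent in level:
            for i in range(1, count + 1):
                taxid = next_id
                next_id += 1
                nodes[taxid] = (parent, RANKS[depth])
                prefix = "" if parent == 1 else names[parent] + "_"
                names[taxid] = f"{prefix}{_RANK_CODES[depth]}{i}"
                new_level.append(taxid)
        level = new_level

    name_index = {name.lower(): [taxid] for taxid, name in names.items()}
    db = TaxonomyDB(nodes=nodes, names=names, name_index=name_index, root_id=1)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "nodes.tsv", "w") as out:
            for taxid in sorted(nodes):
                parent, rank = nodes[taxid]
                out.write(f"{taxid}\t{parent}\t{rank}\n")
        with open(out_dir / "names.tsv", "w") as out:
            for taxid in sorted(names):
                out.write(f"{taxid}\t{names[taxid]}\n")
    return db


# ---------------------------------------------------------------------------
# primers and in-silico PCR

_IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}


@dataclass(frozen=True)
class PrimerPair:
    """A degenerate primer pair; ``reverse`` is given 5'->3' on the reverse
    strand, as primers are conventionally written."""

    forward: str
    reverse: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        for seq in (self.forward, self.reverse):
            if len(seq) < 10:
                raise ValueError(f"primer {seq!r} shorter than 10 nt")
            bad = set(seq.upper()) - set(_IUPAC_SETS)
            if bad:
                raise ValueError(f"non-IUPAC characters {sorted(bad)} in {seq!r}")


#: 341F / 805R, the standard bacterial V3-V4 pair (S-D-Bact-0341-b-S-17 /
#: S-D-Bact-0785-a-A-21 in the standard rRNA primer nomenclature).
DEFAULT_PRIMERS = PrimerPair("CCTACGGGNGGCWGCAG", "GACTACHVGGGTATCTAATCC")


@dataclass(frozen=True)
class AmpliconRecord:
    template_id: str
    source_taxid: Optional[int]
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive
    sequence: str


def _mismatches(window: str, primer: str, limit: int) -> int:
    """IUPAC-aware mismatch count, early-exiting past ``limit``."""
    mm = 0
    for t, p in zip(window, primer):
        pset = _IUPAC_SETS.get(p)
        tset = _IUPAC_SETS.get(t)
        if pset is None or tset is None or not (pset & tset):
            mm += 1
            if mm > limit:
                return mm
    return mm


def _find_sites(template: str, primer: str, max_mismatch: int) -> list[int]:
    n, m = len(template), len(primer)
    return [
        p
        for p in range(n - m + 1)
        if _mismatches(template[p : p + m], primer, max_mismatch) <= max_mismatch
    ]


def insilico_pcr(
    template: str,
    primers: PrimerPair,
    *,
    template_id: str = "",
    source_taxid: Optional[int] = None,
    product_range: Optional[tuple[int, int]] = None,
) -> list[AmpliconRecord]:
    """All properly oriented amplicons of ``template``.

    The forward primer is matched on the plus strand and the reverse primer
    via its reverse complement downstream; a product is emitted for every
    forward/reverse pairing whose length falls in ``product_range`` (no
    limit when None).  Amplicons include both primer footprints; coordinates
    are 0-based half-open on the template.
    """
    template = template.upper()
    fwd = primers.forward.upper()
    rev_site = reverse_complement(primers.reverse.upper())
    fwd_hits = _find_sites(template, fwd, primers.max_mismatch)
    rev_hits = _find_sites(template, rev_site, primers.max_mismatch)

    out: list[AmpliconRecord] = []
    for f in fwd_hits:
        for r in rev_hits:
            start, end = f, r + len(rev_site)
            if r < f + len(fwd):
                continue
            if product_range is not None and not (
                product_range[0] <= end - start <= product_range[1]
            ):
                continue
            out.append(
                AmpliconRecord(template_id, source_taxid, start, end,
                               template[start:end])
            )
    return out


# ---------------------------------------------------------------------------
# templates

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _instantiate(primer: str, rng: np.random.Generator) -> str:
    """Replace degenerate codes with a concrete base drawn from each code's
    expansion set."""
    return "".join(
        b if len(_IUPAC_SETS[b]) == 1 else rng.choice(sorted(_IUPAC_SETS[b]))
        for b in primer.upper()
    )


@dataclass(frozen=True)
class TemplateRecord:
    template_id: str
    source_taxid: int
    sequence: str


def make_templates(
    db: TaxonomyDB,
    primers: PrimerPair = DEFAULT_PRIMERS,
    insert_range: tuple[int, int] = (400, 440),
    flank_range: tuple[int, int] = (30, 80),
    seed: int = 0,
    taxids: Optional[Sequence[int]] = None,
) -> list[TemplateRecord]:
    """One amplifiable template per leaf taxon (or per given taxid).

    Each template is random flank + concrete forward-primer site + random
    insert (length uniform in ``insert_range``) + reverse complement of a
    concrete reverse-primer site + random flank, emulating a marker gene
    flanked by conserved primer-binding regions.
    """
    if taxids is None:
        taxids = db.leaves()
    rng = np.random.default_rng(seed)
    templates = []
    for taxid in taxids:
        fwd_site = _instantiate(primers.forward, rng)
        rev_site = reverse_complement(_instantiate(primers.reverse, rng))
        insert = _random_dna(rng, int(rng.integers(insert_range[0], insert_range[1] + 1)))
        left = _random_dna(rng, int(rng.integers(flank_range[0], flank_range[1] + 1)))
        right = _random_dna(rng, int(rng.integers(flank_range[0], flank_range[1] + 1)))
        seq = left + fwd_site + insert + rev_site + right
        templates.append(TemplateRecord(f"tmpl_{db.name(taxid)}", taxid, seq))
    return templates


def write_templates(
    templates: Sequence[TemplateRecord],
    fasta_path: str | Path,
    mapping_path: Optional[str | Path] = None,
) -> None:
    with open(fasta_path, "w") as out:
        for t in templates:
            out.write(f">{t.template_id}\n{t.sequence}\n")
    if mapping_path is not None:
        with open(mapping_path, "w") as out:
            out.write("template_id\tsource_taxid\n")
            for t in templates:
                out.write(f"{t.template_id}\t{t.source_taxid}\n")


# ---------------------------------------------------------------------------
# libraries

@dataclass(frozen=True)
class LibrarySpec:
    """Construction parameters of one benchmark library set.

    Defaults are the framework's reference conditions: 750,000 merged pairs
    of 300 bp per replicate at fixed Phred 30, 37,500 shuffled true
    negatives, a linear rank-abundance model, and three replicates sharing
    90% of their references.
    """

    n_read_pairs: int = 750_000
    read_length: int = 300
    phred: int = 30
    n_shuffled: int = 37_500
    abundance_model: str = "linear"
    shared_fraction: float = 0.9
    n_replicates: int = 3
    n_references: Optional[int] = None
    seed: int = 1

    def __post_init__(self) -> None:
        if min(self.n_read_pairs, self.n_shuffled, self.read_length) < 0:
            raise ValueError("counts must be >= 0")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError(f"shared_fraction must be in [0,1], got {self.shared_fraction}")
        if self.abundance_model not in ("linear", "uniform"):
            raise ValueError(f"unknown abundance model {self.abundance_model!r}")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")
        if not 0 <= self.phred <= 60:
            raise ValueError("phred must be in [0, 60]")


@dataclass
class ReplicateLibrary:
    name: str
    fasta: Path
    fastq_r1: Path
    fastq_r2: Path
    truth: Path
    reference_ids: list[str]
    n_read_pairs: int
    n_shuffled: int


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights`` that
    conserves the total exactly (ties broken toward lower index)."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("weights must have positive sum")
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    remainder = total - int(base.sum())
    frac = quota - base
    order = np.lexsort((np.arange(len(weights)), -frac))
    base[order[:remainder]] += 1
    return base


def shuffle_sequences(
    sources: Sequence[str], n: int, rng: np.random.Generator | int
) -> list[str]:
    """``n`` base-permuted sequences, each a Fisher-Yates shuffle of a
    randomly chosen source; per-sequence mononucleotide composition is
    preserved exactly, which destroys taxonomic signal without changing
    base frequencies."""
    if not sources:
        raise ValueError("no source sequences to shuffle")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out = []
    arrays = [np.frombuffer(s.encode(), dtype=np.uint8) for s in sources]
    for _ in range(n):
        arr = arrays[int(rng.integers(len(arrays)))]
        out.append(rng.permutation(arr).tobytes().decode())
    return out


def _partition_references(
    n_available: int, spec: LibrarySpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Split reference indices into a common pool shared by all replicates
    plus disjoint private pools, honoring ``shared_fraction`` per library."""
    k = spec.n_references
    if k is None:
        # largest per-replicate size feasible with disjoint private pools
        k = 0
        for cand in range(n_available, 0, -1):
            c = math.ceil(spec.shared_fraction * cand)
            if c + spec.n_replicates * (cand - c) <= n_available:
                k = cand
                break
    c = math.ceil(spec.shared_fraction * k)
    n_private = k - c
    needed = c + spec.n_replicates * n_private
    if k < 1 or needed > n_available:
        raise ValueError(
            f"reference pool too small: need {needed} references for "
            f"{spec.n_replicates} replicates of {k} "
            f"(shared fraction {spec.shared_fraction}), have {n_available}"
        )
    order = rng.permutation(n_available)
    common = np.sort(order[:c])
    privates = [
        np.sort(order[c + r * n_private : c + (r + 1) * n_private])
        for r in range(spec.n_replicates)
    ]
    return common, privates


def build_libraries(
    templates: Sequence[TemplateRecord],
    spec: LibrarySpec,
    primers: PrimerPair = DEFAULT_PRIMERS,
    out_dir: str | Path = ".",
) -> list[ReplicateLibrary]:
    """Construct the replicate libraries on disk.

    Per replicate: a merged-amplicon FASTA (real reads followed by shuffled
    true negatives), paired FASTQ (R1 = first ``read_length`` bases of the
    amplicon, R2 = reverse complement of the last, every quality character
    encoding the fixed Phred), and a truth TSV with one row per FASTA
    record.  Read counts per reference follow the abundance model through
    largest-remainder rounding, so totals are exact by construction.
    """
    out_dir = Path(out_dir)

    references: list[tuple[str, int, str]] = []
    for t in templates:
        amps = insilico_pcr(
            t.sequence, primers, template_id=t.template_id, source_taxid=t.source_taxid
        )
        if amps:
            references.append((t.template_id, t.source_taxid, amps[0].sequence))
    if not references:
        raise ValueError("no template yielded an amplicon")

    ss = np.random.SeedSequence(spec.seed)
    seeds = ss.spawn(spec.n_replicates + 1)
    common, privates = _partition_references(
        len(references), spec, np.random.default_rng(seeds[0])
    )

    qual_full = chr(spec.phred + 33) * spec.read_length
    libraries = []
    for r in range(spec.n_replicates):
        rng = np.random.default_rng(seeds[r + 1])
        idx = np.concatenate([common, privates[r]]).astype(int)
        refs = [references[i] for i in idx]
        k = len(refs)

        if spec.abundance_model == "linear":
            # rank-abundance decreasing linearly from k to 1; which reference
            # gets which rank is drawn per replicate
            ranks = rng.permutation(k)
            weights = (k - ranks).astype(float)
        else:
            weights = np.ones(k)
        counts = largest_remainder(weights, spec.n_read_pairs)

        rep_name = f"replicate_{r + 1}"
        rep_dir = out_dir / rep_name
        rep_dir.mkdir(parents=True, exist_ok=True)
        fasta_path = rep_dir / "amplicons.fasta"
        r1_path = rep_dir / "reads_R1.fastq"
        r2_path = rep_dir / "reads_R2.fastq"
        truth_path = rep_dir / "truth.tsv"

        # bulk emission: plain sequential FASTA/FASTQ records, written
        # directly for throughput at the 10^6-record scale
        serial = 0
        with open(fasta_path, "w") as fa, open(r1_path, "w") as f1, open(
            r2_path, "w"
        ) as f2, open(truth_path, "w") as tr:
            tr.write("read_id\texpected_taxid\n")
            for (ref_id, taxid, amp), count in zip(refs, counts):
                r1 = amp[: spec.read_length]
                r2 = reverse_complement(amp)[: spec.read_length]
                q1 = qual_full[: len(r1)]
                q2 = qual_full[: len(r2)]
                for _ in range(int(count)):
                    serial += 1
                    rid = f"rep{r + 1}_read{serial}"
                    fa.write(f">{rid}\n{amp}\n")
                    f1.write(f"@{rid}/1\n{r1}\n+\n{q1}\n")
                    f2.write(f"@{rid}/2\n{r2}\n+\n{q2}\n")
                    tr.write(f"{rid}\t{taxid}\n")
            shuffled = shuffle_sequences(
                [seq for _, _, seq in refs], spec.n_shuffled, rng
            )
            for j, seq in enumerate(shuffled, start=1):
                rid = f"rep{r + 1}_shuffled{j}"
                fa.write(f">{rid}\n{seq}\n")
                tr.write(f"{rid}\tSHUFFLED\n")

        libraries.append(
            ReplicateLibrary(
                name=rep_name,
                fasta=fasta_path,
                fastq_r1=r1_path,
                fastq_r2=r2_path,
                truth=truth_path,
                reference_ids=[ref_id for ref_id, _, _ in refs],
                n_read_pairs=spec.n_read_pairs,
                n_shuffled=spec.n_shuffled,
            )
        )
    return libraries


# ---------------------------------------------------------------------------
# mock annotator

@dataclass
class ErrorProfile:
    """Known-by-construction behavior of the mock annotator.

    ``p_correct[rank]`` is the probability that a real read's call is the
    expected lineage correctly truncated at that rank; ``p_misclassify[rank]``
    the probability of swapping the expected taxon at that rank for a random
    sibling (which poisons all deeper ranks).  Remaining probability mass
    leaves the read unclassified.  ``p_classify_shuffled`` is the chance a
    shuffled read gets (wrongly) classified to a random leaf.  Scores are
    drawn uniformly from ``correct_score`` / ``error_score`` ranges,
    higher-better.
    """

    p_correct: dict[str, float] = field(default_factory=dict)
    p_misclassify: dict[str, float] = field(default_factory=dict)
    p_classify_shuffled: float = 0.0
    correct_score: tuple[float, float] = (0.7, 1.0)
    error_score: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        for d in (self.p_correct, self.p_misclassify):
            for rank, p in d.items():
                if rank not in RANKS:
                    raise ValueError(f"unknown rank {rank!r} in error profile")
                if not 0 <= p <= 1:
                    raise ValueError(f"probability {p} for {rank!r} outside [0,1]")
        total = sum(self.p_correct.values()) + sum(self.p_misclassify.values())
        if total > 1 + 1e-9:
            raise ValueError(f"outcome probabilities sum to {total} > 1")
        if not 0 <= self.p_classify_shuffled <= 1:
            raise ValueError("p_classify_shuffled outside [0,1]")

    @classmethod
    def perfect(cls) -> "ErrorProfile":
        return cls(p_correct={"subspecies": 1.0})

    @classmethod
    def from_file(cls, path: str | Path) -> "ErrorProfile":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: profile must be a mapping")
        known = {
            "p_correct", "p_misclassify", "p_classify_shuffled",
            "correct_score", "error_score",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown profile keys {sorted(unknown)}")
        for key in ("correct_score", "error_score"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _truncate(lineage_slots: tuple, rank_idx: int) -> Optional[int]:
    """Deepest filled slot at or above ``rank_idx`` (the correctly truncated
    call), or None when nothing that shallow exists."""
    for i in range(rank_idx, -1, -1):
        if lineage_slots[i] is not None:
            return lineage_slots[i]
    return None


def mock_annotator(
    truth: TruthSet,
    db: TaxonomyDB,
    profile: ErrorProfile,
    seed: int = 0,
    method_name: str = "mock",
) -> AssignmentSet:
    """Sample one assignment per truth read according to ``profile``.

    Deterministic for a given seed and truth ordering.  Unclassified reads
    are emitted with no taxid and no score, matching how real classifiers
    leave reads out of their output.
    """
    rng = np.random.default_rng(seed)

    outcomes: list[tuple[str, int]] = []
    probs: list[float] = []
    for rank, p in profile.p_correct.items():
        outcomes.append(("correct", RANKS.index(rank)))
        probs.append(p)
    for rank, p in profile.p_misclassify.items():
        outcomes.append(("mis", RANKS.index(rank)))
        probs.append(p)
    outcomes.append(("unclassified", -1))
    probs.append(max(0.0, 1.0 - sum(probs)))
    p_arr = np.array(probs) / sum(probs)

    # per-taxid lookup tables: truncations and rank-level "wrong" candidates
    trunc_cache: dict[int, list[Optional[int]]] = {}
    wrong_cache: dict[tuple[int, int], list[int]] = {}
    rank_pool: dict[int, list[int]] = {}

    def truncations(taxid: int) -> list[Optional[int]]:
        if taxid not in trunc_cache:
            slots = homogenize(db, taxid).slots
            trunc_cache[taxid] = [_truncate(slots, i) for i in range(len(RANKS))]
        return trunc_cache[taxid]

    def wrong_candidates(taxid: int, rank_idx: int) -> list[int]:
        key = (taxid, rank_idx)
        if key not in wrong_cache:
            slots = homogenize(db, taxid).slots
            target = slots[rank_idx]
            cands: list[int] = []
            if target is not None:
                parent = db.parent(target)
                cands = [
                    c for c in db.children(parent)
                    if c != target and db.rank(c) == db.rank(target)
                ]
            if not cands:
                if rank_idx not in rank_pool:
                    rank_pool[rank_idx] = db.nodes_at_rank(RANKS[rank_idx])
                cands = [c for c in rank_pool[rank_idx] if c != target]
            wrong_cache[key] = cands
        return wrong_cache[key]

    leaves = db.leaves()
    records = list(truth)
    n = len(records)
    outcome_idx = rng.choice(len(outcomes), size=n, p=p_arr)
    u_shuffled = rng.random(n)
    u_pick = rng.random(n)
    correct_scores = rng.uniform(*profile.correct_score, size=n)
    error_scores = rng.uniform(*profile.error_score, size=n)

    assignments: list[Assignment] = []
    for i, rec in enumerate(records):
        if rec.is_shuffled:
            if u_shuffled[i] < profile.p_classify_shuffled:
                taxid = leaves[int(u_pick[i] * len(leaves))]
                assignments.append(
                    Assignment(rec.read_id, taxid, str(taxid), float(error_scores[i]))
                )
            else:
                assignments.append(Assignment(rec.read_id, None, "", None))
            continue

        kind, rank_idx = outcomes[outcome_idx[i]]
        if kind == "unclassified":
            assignments.append(Assignment(rec.read_id, None, "", None))
        elif kind == "correct":
            taxid = truncations(rec.expected_taxid)[rank_idx]
            if taxid is None:
                assignments.append(Assignment(rec.read_id, None, "", None))
            else:
                assignments.append(
                    Assignment(rec.read_id, taxid, str(taxid), float(correct_scores[i]))
                )
        else:  # misclassify at rank_idx
            cands = wrong_candidates(rec.expected_taxid, rank_idx)
            if not cands:
                assignments.append(Assignment(rec.read_id, None, "", None))
            else:
                taxid = cands[int(u_pick[i] * len(cands))]
                assignments.append(
                    Assignment(rec.read_id, taxid, str(taxid), float(error_scores[i]))
                )

    return AssignmentSet(
        assignments=assignments,
        score_direction="higher_better",
        method_name=method_name,
    )


def truth_from_taxids(read_ids: Sequence[str], taxids: Sequence[Optional[int]]) -> TruthSet:
    """Assemble a TruthSet in memory (None taxid = shuffled read)."""
    records = {}
    for rid, taxid in zip(read_ids, taxids):
        records[rid] = TruthRecord(rid, taxid, taxid is None)
    return TruthSet(records)
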