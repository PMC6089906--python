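# Methods

## Rank homogenization

All comparisons happen on eight fixed ranks: domain, phylum, class, order,
family, genus, species, subspecies. A taxid's lineage is obtained by
walking parent links to the root and filling each canonical slot with the
ancestor bearing that rank label; `superkingdom` is folded into `domain`
(the two terms are used interchangeably for prokaryotes). All other rank
labels are ignored, so lineages may have interior gaps (a species hanging
directly under an order has empty family and genus slots). Slots are never
overwritten: on a pathological lineage carrying a rank twice, the node
nearest the root wins and a warning is logged. An opt-in flag
(`strain_as_subspecies`) lets `strain`/`no rank` nodes whose parent is a
species fill the subspecies slot, because public taxonomies encode
below-species structure inconsistently; it is off by default so that the
default behaviour never guesses.

Unknown taxids are a hard lookup error everywhere — there is deliberately
no handling of merged/deleted-node files; keeping inputs current is the
caller's responsibility.

## Labeling rules and their edge cases

Per rank, for a real read: expected slot empty → NA; both filled and equal
→ TP; assignment empty → FN; mismatch → FP, with FP propagated to every
deeper evaluated rank even when the assigned lineage is empty there — a
read on the wrong branch stays wrong. For a shuffled read only FP
(classified) and TN (not classified) exist. Consequently, ignoring NA
slots, every label vector matches `TP* FN* FP*`: matches, then silence,
then (propagated) misclassification. The FN-before-FP tail can only occur
with gapped lineages (assignment silent at a rank the truth has, then
wrong deeper), which is faithful to the per-rank definitions.

NA policy: ranks absent from the expected lineage are excluded rather than
counted as TN. The true-negative class is anchored solely to shuffled
sequences; counting structural taxonomy gaps as TN would inflate
specificity with events the classifier never faced. `na_as_tn=True`
restores the alternative for comparison with benchmarks that count them.

Reads present in the truth but absent from a classifier's output are
unclassified (FN at expected ranks, TN for shuffled). Labels that cannot
be resolved to any taxid (e.g. placeholder names absent from the taxonomy)
are counted as classifications — FP at every evaluated rank — under the
default `unresolved=fp` policy, because a wrong made-up call is an error,
not an abstention; `unresolved=unclassified` flips this per dialect.

## Metrics

EPQ = FP / total queries; coverage = TP / reads with an expected taxon at
the rank; sensitivity, specificity, accuracy and MCC follow their standard
confusion-matrix definitions. NA reads never enter TP/FP/FN/TN, but EPQ
deliberately keeps the full submitted-query count as denominator: it
measures error accumulation per query, so `EPQ · total_queries` always
recovers the integer FP count. Any metric with a zero denominator is
reported as undefined (NaN in tables), never coerced; an MCC whose product
of marginals is zero is reported as 0 with a `degenerate` flag, the common
convention. Replicate summaries use the sample (n−1) standard deviation,
since replicates are draws from a stochastic generator; undefined metrics
are excluded pairwise.

For shotgun-style data the universe of classifiable sequences can depend
on the annotator itself; `RankConfusion.total_queries`/`total_expected`
are therefore plain fields that callers may override before computing
metrics, but every default is derived from the truth set.

## CVE curves and cut-offs

Only reads carrying a score and a TP-or-FP label at the rank enter the
ranking; FN/TN/NA reads and unscored calls contribute to the fixed
denominators only (a curve point needs a rankable score, but EPQ's
denominator is the full query count). Score direction is declared per
dialect and scores are never rescaled on input. Ties are processed as one
block — the point after a block reflects the whole block — so curves and
cut-offs are invariant to input order; cut-offs are likewise block-aligned:
the reported cut-off is the worst score of the longest admissible prefix.
The target error is interpreted against EPQ (FP over all queries), exactly
as the curve is built; an FDR-style alternative (FP over classified) was
considered and rejected as the default because it changes the denominator
mid-framework, but the per-rank counts needed to compute it are all in the
metrics tables.

Ambiguous multi-taxon calls are collapsed to the members' lowest common
ancestor before labeling; the read keeps its own reported score rather
than inheriting anything from the LCA, since the score describes the
read's evidence, not the consensus taxon.

## Synthetic data

The generator emulates a V3–V4 amplicon benchmark. A balanced mock
taxonomy (default branching 1,4,2,2,2,3,3,1 → 288 leaf taxa, a scale
comparable to a few hundred reference organisms) provides one template per
leaf: random flank + concrete forward-primer site + random insert of
400–440 nt + reverse-complemented reverse-primer site + random flank. The
default primers are the standard 341F/805R pair
(`CCTACGGGNGGCWGCAG` / `GACTACHVGGGTATCTAATCC`); degenerate positions are
instantiated per template, and in-silico PCR matches IUPAC codes with a
configurable mismatch budget (default 0).

Each replicate library draws its references as one common pool — present
in *all* replicates, sized ⌈0.9·k⌉ of the per-replicate count k — plus a
disjoint private sample; with the default 288 templates the derived k is
240, making the shared fraction exactly 90%. The linear abundance model
assigns rank-abundances proportional to k, k−1, …, 1, with the rank-to-
reference mapping drawn per replicate; read counts per reference are the
largest-remainder rounding of these weights, so per-replicate totals are
exact by construction, not in expectation. Reads are R1 = first 300 bases
of the amplicon and R2 = reverse complement of the last 300, every quality
character encoding Phred 30. There is no base-error model and no
overlap-merging step: the merged amplicon itself is emitted as the
evaluable unit (a FASTA alongside the paired FASTQ), because the
framework's subject is annotation, not base calling or read merging.

Shuffled true negatives are per-sequence Fisher–Yates permutations of
randomly chosen library amplicons: mononucleotide composition is preserved
exactly while word structure (and hence taxonomic signal) is destroyed.
Dinucleotide-preserving shuffling was left unimplemented.

What this generator does *not* emulate: sequencing error, chimeras,
length/quality variation, real 16S conservation structure (templates are
random DNA between primer sites, so real classifiers would not recognise
them — the generator feeds the *evaluation* machinery, and real-data
claims require real classifier outputs), and shotgun-style reads.

## Mock annotator

The closed-loop annotator samples, per real read: "correct, truncated at
rank r" with probability `p_correct[r]`, "swapped to a random sibling at
rank r" with `p_misclassify[r]` (which poisons deeper ranks, as in real
misclassification), remainder unclassified; shuffled reads are classified
to a random leaf with `p_classify_shuffled`. Scores come from two uniform
distributions (defaults: correct 0.7–1.0, erroneous 0.1–0.9,
higher-better), overlapping deliberately so CVE curves have a non-trivial
shape. Because every error rate is configured, measured EPQ converges to
the configured rate (binomially) and a perfect profile must yield MCC = 1,
EPQ = 0, coverage = 1 — the parameter-recovery tests assert exactly this.

## Numerical and interface choices

* Largest-remainder apportionment breaks ties toward lower index;
  determinism everywhere comes from `numpy.random.default_rng` seeded per
  component (library seeds are spawned from the spec seed, so replicates
  are independent but reproducible byte-for-byte).
* Name resolution is case-insensitive and whitespace-collapsed; homonyms
  return all bearers and, when a single call must be produced, collapse to
  their LCA.
* The acceptance script runs the library builder at full reference scale
  (3 × 787,500 records, ~30 s); the test suite exercises the identical
  code path at 1/100 scale, where every count scales linearly by
  construction.

## Known limitations

Homonym collapsing to the LCA can be generous to classifiers that emit
bare ambiguous names. Sub-species comparison is by taxid equality only —
no name heuristics. The evaluation assumes expected and assigned lineages
come from the same taxonomy load; nothing cross-checks database versions.
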