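"""Mock taxonomy, in-silico PCR, library construction, mock annotator."""

import math
import re
from collections import Counter

import numpy as np
import pytest
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

from taxobench import (
    DEFAULT_PRIMERS,
    ErrorProfile,
    LibrarySpec,
    PrimerPair,
    aggregate,
    build_libraries,
    evaluate,
    insilico_pcr,
    label_set,
    largest_remainder,
    make_mock_taxonomy,
    make_templates,
    mock_annotator,
    read_truth,
    shuffle_sequences,
)
from taxobench.simdata import truth_from_taxids, write_templates

SMOKE = LibrarySpec(n_read_pairs=2000, n_shuffled=100, n_replicates=3,
                    shared_fraction=0.9, seed=7)
SMOKE_BRANCHING = (1, 2, 1, 2, 2, 2, 3, 1)  # 48 leaf taxa


@pytest.fixture(scope="module")
def mock_db():
    return make_mock_taxonomy(SMOKE_BRANCHING, seed=7)


@pytest.fixture(scope="module")
def templates(mock_db):
    return make_templates(mock_db, seed=7)


@pytest.fixture(scope="module")
def smoke_libs(templates, tmp_path_factory):
    out = tmp_path_factory.mktemp("libs")
    return build_libraries(templates, SMOKE, out_dir=out), out


class TestMockTaxonomy:
    def test_leaf_count_is_branching_product(self):
        branching = (1, 2, 1, 1, 1, 2, 2, 1)
        db = make_mock_taxonomy(branching)
        assert len(db.leaves()) == math.prod(branching)

    def test_all_ones_is_a_chain(self):
        db = make_mock_taxonomy((1,) * 8)
        assert len(db) == 9  # root + one node per rank
        assert len(db.leaves()) == 1

    def test_same_seed_same_files(self, tmp_path):
        for d in ("a", "b"):
            make_mock_taxonomy(SMOKE_BRANCHING, seed=3, out_dir=tmp_path / d)
        for f in ("nodes.tsv", "names.tsv"):
            assert (tmp_path / "a" / f).read_bytes() == \
                (tmp_path / "b" / f).read_bytes()

    def test_round_trips_through_loader(self, tmp_path):
        from taxobench import load_taxdump

        db = make_mock_taxonomy(SMOKE_BRANCHING, out_dir=tmp_path)
        db2 = load_taxdump(tmp_path / "nodes.tsv", tmp_path / "names.tsv")
        assert db2.nodes == db.nodes and db2.names == db.names

    def test_bad_branching_rejected(self):
        with pytest.raises(ValueError):
            make_mock_taxonomy((1, 2, 0, 1, 1, 1, 1, 1))


class TestInsilicoPCR:
    def test_template_without_sites_is_empty(self):
        assert insilico_pcr("ACGT" * 100, DEFAULT_PRIMERS) == []

    def test_constructed_coordinates(self):
        """One forward site at 50, one reverse site ending at 500: the brute
        scan must find exactly that product with both footprints included."""
        rng = np.random.default_rng(0)
        fwd = "CCTACGGGAGGCAGCAG"  # concrete 341F instance
        rev_site = reverse_complement("GACTACAAGGGTATCTAATCC")
        bases = list("ACGT")
        body = "".join(rng.choice(bases, size=600))
        middle = body[50 : 500 - 50 - len(fwd) - len(rev_site) + 50]  # 412 nt
        tmpl = body[:50] + fwd + middle + rev_site + body[500:]
        amps = insilico_pcr(tmpl, DEFAULT_PRIMERS)
        assert len(amps) == 1
        amp = amps[0]
        assert (amp.start, amp.end) == (50, 500)
        assert amp.sequence == tmpl[50:500]
        assert amp.sequence.startswith(fwd)
        assert amp.sequence.endswith(rev_site)

    def test_iupac_n_matches_any_base(self):
        primers = PrimerPair("CCNACGTACG", "GGGGTACGTA")
        for base in "ACGT":
            tmpl = f"CC{base}ACGTACG" + "A" * 30 + reverse_complement("GGGGTACGTA")
            assert len(insilico_pcr(tmpl, primers)) == 1

    def test_mismatch_tolerance(self):
        primers0 = PrimerPair("CCTACGTACG", "GGGGTACGTA", max_mismatch=0)
        primers1 = PrimerPair("CCTACGTACG", "GGGGTACGTA", max_mismatch=1)
        tmpl = "CGTACGTACG" + "A" * 30 + reverse_complement("GGGGTACGTA")
        assert insilico_pcr(tmpl, primers0) == []
        assert len(insilico_pcr(tmpl, primers1)) == 1

    def test_agrees_with_regex_expansion(self, templates):
        """Cross-check the scanner against an independent IUPAC regex."""
        def iupac_regex(p):
            return re.compile("".join(
                c if len(ambiguous_dna_values[c]) == 1
                else f"[{ambiguous_dna_values[c]}]" for c in p))

        fwd_re = iupac_regex(DEFAULT_PRIMERS.forward)
        rev_re = iupac_regex(reverse_complement(DEFAULT_PRIMERS.reverse))
        for t in templates[:20]:
            amps = insilico_pcr(t.sequence, DEFAULT_PRIMERS)
            f_hits = [m.start() for m in fwd_re.finditer(t.sequence)]
            r_hits = [m.end() for m in rev_re.finditer(t.sequence)]
            expected = [(f, r) for f in f_hits for r in r_hits
                        if r - len(DEFAULT_PRIMERS.reverse) >= f + len(DEFAULT_PRIMERS.forward)]
            assert [(a.start, a.end) for a in amps] == expected

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            PrimerPair("ACGTACG", "GACTACAAGGGTATCTAATCC")


class TestTemplates:
    def test_every_template_amplifies(self, templates):
        for t in templates:
            assert len(insilico_pcr(t.sequence, DEFAULT_PRIMERS)) >= 1

    def test_amplicon_lengths_within_configured_bounds(self, mock_db):
        templates = make_templates(mock_db, insert_range=(400, 460), seed=3)
        footprints = len(DEFAULT_PRIMERS.forward) + len(DEFAULT_PRIMERS.reverse)
        for t in templates:
            amp = insilico_pcr(t.sequence, DEFAULT_PRIMERS)[0]
            assert 400 + footprints <= len(amp.sequence) <= 460 + footprints

    def test_same_seed_identical_fasta(self, mock_db, tmp_path):
        for name in ("a.fasta", "b.fasta"):
            write_templates(make_templates(mock_db, seed=5), tmp_path / name)
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()

    def test_one_template_per_leaf(self, mock_db, templates):
        assert len(templates) == len(mock_db.leaves())
        assert len({t.source_taxid for t in templates}) == len(templates)


class TestLargestRemainder:
    def test_conserves_total(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            w = rng.uniform(0.1, 10, size=rng.integers(1, 30))
            total = int(rng.integers(1, 10000))
            assert largest_remainder(w, total).sum() == total

    def test_uniform_weights_differ_by_at_most_one(self):
        counts = largest_remainder(np.ones(7), 100)
        assert counts.max() - counts.min() <= 1
        assert counts.sum() == 100


class TestLibraries:
    def test_truth_row_counts_exact(self, smoke_libs):
        libs, _ = smoke_libs
        for lib in libs:
            truth = read_truth(lib.truth)
            assert len(truth) == SMOKE.n_read_pairs + SMOKE.n_shuffled
            assert truth.n_shuffled == SMOKE.n_shuffled

    def test_fasta_and_fastq_record_counts(self, smoke_libs):
        libs, _ = smoke_libs
        lib = libs[0]
        n_fasta = sum(1 for _ in SeqIO.parse(str(lib.fasta), "fasta"))
        assert n_fasta == SMOKE.n_read_pairs + SMOKE.n_shuffled
        n_r1 = sum(1 for _ in SeqIO.parse(str(lib.fastq_r1), "fastq"))
        n_r2 = sum(1 for _ in SeqIO.parse(str(lib.fastq_r2), "fastq"))
        assert n_r1 == n_r2 == SMOKE.n_read_pairs

    def test_fixed_phred_and_read_length(self, smoke_libs):
        libs, _ = smoke_libs
        records = SeqIO.parse(str(libs[0].fastq_r1), "fastq")
        for rec in (next(records) for _ in range(50)):
            quals = rec.letter_annotations["phred_quality"]
            assert set(quals) == {SMOKE.phred}
            assert len(rec.seq) == SMOKE.read_length

    def test_r2_is_reverse_complement_of_amplicon_tail(self, smoke_libs):
        libs, _ = smoke_libs
        lib = libs[0]
        amps = {r.id: str(r.seq) for i, r in
                zip(range(20), SeqIO.parse(str(lib.fasta), "fasta"))}
        for rec in (r for _, r in zip(range(20), SeqIO.parse(str(lib.fastq_r2), "fastq"))):
            rid = rec.id.rsplit("/", 1)[0]
            amp = amps[rid]
            assert str(rec.seq) == reverse_complement(amp)[:SMOKE.read_length]

    def test_replicates_share_common_pool(self, smoke_libs):
        libs, _ = smoke_libs
        sets = [set(lib.reference_ids) for lib in libs]
        common = sets[0] & sets[1] & sets[2]
        k = len(sets[0])
        assert all(len(s) == k for s in sets)
        assert len(common) == math.ceil(SMOKE.shared_fraction * k)
        # private parts are pairwise disjoint
        for i in range(3):
            for j in range(i + 1, 3):
                assert (sets[i] - common) & (sets[j] - common) == set()

    def test_shared_fraction_one_means_identical_sets(self, templates, tmp_path):
        spec = LibrarySpec(n_read_pairs=100, n_shuffled=10, n_replicates=3,
                           shared_fraction=1.0, seed=1)
        libs = build_libraries(templates, spec, out_dir=tmp_path)
        assert len({frozenset(l.reference_ids) for l in libs}) == 1

    def test_uniform_model_counts_differ_by_one(self, templates, tmp_path):
        spec = LibrarySpec(n_read_pairs=500, n_shuffled=0, n_replicates=1,
                           abundance_model="uniform", seed=1)
        libs = build_libraries(templates, spec, out_dir=tmp_path)
        truth = read_truth(libs[0].truth)
        counts = Counter(r.expected_taxid for r in truth)
        assert max(counts.values()) - min(counts.values()) <= 1

    def test_linear_model_is_linear_in_rank(self, templates, tmp_path):
        spec = LibrarySpec(n_read_pairs=48000, n_shuffled=0, n_replicates=1,
                           abundance_model="linear", seed=1)
        libs = build_libraries(templates, spec, out_dir=tmp_path)
        truth = read_truth(libs[0].truth)
        counts = sorted(Counter(r.expected_taxid for r in truth).values())
        k = len(libs[0].reference_ids)
        # ranked abundances should be ~ proportional to 1..k
        total = spec.n_read_pairs
        expected = [total * (i + 1) / (k * (k + 1) / 2) for i in range(k)]
        assert counts == pytest.approx(expected, abs=1.0)

    def test_infeasible_sharing_split_errors(self, templates, tmp_path):
        spec = LibrarySpec(n_read_pairs=10, n_shuffled=0, n_replicates=3,
                           shared_fraction=0.5,
                           n_references=len(templates), seed=1)
        with pytest.raises(ValueError, match="reference pool too small"):
            build_libraries(templates, spec, out_dir=tmp_path)

    def test_byte_identical_for_same_seed(self, templates, tmp_path):
        spec = LibrarySpec(n_read_pairs=300, n_shuffled=30, n_replicates=2, seed=11)
        for d in ("x", "y"):
            build_libraries(templates, spec, out_dir=tmp_path / d)
        for rep in ("replicate_1", "replicate_2"):
            for f in ("amplicons.fasta", "reads_R1.fastq", "reads_R2.fastq",
                      "truth.tsv"):
                assert (tmp_path / "x" / rep / f).read_bytes() == \
                    (tmp_path / "y" / rep / f).read_bytes()

    def test_amplicons_round_trip_through_pcr(self, smoke_libs):
        """Every non-shuffled merged amplicon re-amplifies to itself."""
        libs, _ = smoke_libs
        seen = set()
        truth = read_truth(libs[0].truth)
        for rec in SeqIO.parse(str(libs[0].fasta), "fasta"):
            if truth[rec.id].is_shuffled or str(rec.seq) in seen:
                continue
            seen.add(str(rec.seq))
            amps = insilico_pcr(str(rec.seq), DEFAULT_PRIMERS)
            assert any(a.sequence == str(rec.seq) and a.start == 0 for a in amps)


class TestShuffleSequences:
    def test_base_histogram_preserved(self):
        src = ["ACGTACGGTT", "AAAACCCGGT"]
        out = shuffle_sequences(src, 20, rng=3)
        for s in out:
            assert Counter(s) in (Counter(src[0]), Counter(src[1]))

    def test_n_zero_is_empty(self):
        assert shuffle_sequences(["ACGT"], 0, rng=1) == []

    def test_same_seed_identical(self):
        src = ["ACGTACGGTTAACC"]
        assert shuffle_sequences(src, 5, rng=9) == shuffle_sequences(src, 5, rng=9)

    def test_empty_source_rejected(self):
        with pytest.raises(ValueError):
            shuffle_sequences([], 5, rng=1)


class TestMockAnnotator:
    def _truth(self, db, n, shuffled=0, seed=0):
        rng = np.random.default_rng(seed)
        leaves = db.leaves()
        taxids = [leaves[i] for i in rng.integers(0, len(leaves), size=n)]
        taxids += [None] * shuffled
        return truth_from_taxids([f"r{i}" for i in range(n + shuffled)], taxids)

    def test_perfect_profile_scores_perfectly(self, mock_db):
        truth = self._truth(mock_db, 400, shuffled=40)
        aset = mock_annotator(truth, mock_db, ErrorProfile.perfect(), seed=1)
        _, _, table = evaluate(truth, aset, mock_db)
        defined = table.dropna(subset=["mcc"])
        assert (defined["mcc"] == 1.0).all()
        assert (table["epq"] == 0.0).all()
        assert (table.dropna(subset=["coverage"])["coverage"] == 1.0).all()

    def test_genus_misclassification_rate_recovered(self, mock_db):
        p = 0.05
        n = 20_000
        truth = self._truth(mock_db, n)
        profile = ErrorProfile(p_correct={"subspecies": 0.9},
                               p_misclassify={"genus": p})
        aset = mock_annotator(truth, mock_db, profile, seed=2)
        labels = label_set(truth, aset, mock_db)
        conf = aggregate(labels, truth)[5]
        epq = conf.fp / conf.total_queries
        se = math.sqrt(p * (1 - p) / n)
        assert abs(epq - p) < 3 * se

    def test_unclassified_shuffled_are_all_tn(self, mock_db):
        truth = self._truth(mock_db, 50, shuffled=50)
        profile = ErrorProfile(p_correct={"species": 1.0}, p_classify_shuffled=0.0)
        aset = mock_annotator(truth, mock_db, profile, seed=3)
        labels = {rl.read_id: rl for rl in label_set(truth, aset, mock_db)}
        for rec in truth:
            if rec.is_shuffled:
                assert labels[rec.read_id].labels == ("TN",) * 8

    def test_classify_shuffled_rate(self, mock_db):
        truth = self._truth(mock_db, 0, shuffled=5000)
        profile = ErrorProfile(p_classify_shuffled=0.2)
        aset = mock_annotator(truth, mock_db, profile, seed=4)
        classified = sum(a.assigned_taxid is not None for a in aset.assignments)
        se = math.sqrt(0.2 * 0.8 / 5000)
        assert abs(classified / 5000 - 0.2) < 3 * se

    def test_deterministic_for_seed(self, mock_db):
        truth = self._truth(mock_db, 200, shuffled=20)
        profile = ErrorProfile(p_correct={"subspecies": 0.8},
                               p_misclassify={"species": 0.1})
        a = mock_annotator(truth, mock_db, profile, seed=5)
        b = mock_annotator(truth, mock_db, profile, seed=5)
        assert [(x.read_id, x.assigned_taxid, x.score) for x in a.assignments] \
            == [(y.read_id, y.assigned_taxid, y.score) for y in b.assignments]

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            ErrorProfile(p_correct={"genus": 0.8}, p_misclassify={"genus": 0.3})
        with pytest.raises(ValueError):
            ErrorProfile(p_correct={"tribe": 0.5})
        with pytest.raises(ValueError):
            ErrorProfile(p_classify_shuffled=1.5)

    def test_shipped_profiles_load(self):
        from importlib.resources import files

        perfect = ErrorProfile.from_file(files("taxobench") / "profiles" / "perfect.yaml")
        assert perfect.p_correct == {"subspecies": 1.0}
        genus = ErrorProfile.from_file(files("taxobench") / "profiles" / "genus_error.yaml")
        assert genus.p_misclassify == {"genus": 0.05}
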