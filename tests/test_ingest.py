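import gzip
import random

import pytest
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqFeature import BeforePosition, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from conftest import random_dna
from phyloslice.ingest import import_fasta, import_genbank
from phyloslice.records import SequenceRecord
from phyloslice.similarity import (SimilarityScorer, assign_by_similarity,
                                   compute_locus_cutoffs,
                                   six_frame_translations)


def gb_record(acc, taxid, genes, description="cDNA clone", partial=False,
              strand=1, seq=None):
    """One GenBank record with a CDS per gene name."""
    length = max(90, 90 * len(genes))
    dna = seq or random_dna(random.Random(hash(acc) % 2**31), length)
    rec = SeqRecord(Seq(dna), id=acc, name=acc, description=description)
    rec.annotations["molecule_type"] = "DNA"
    rec.features.append(SeqFeature(
        FeatureLocation(0, len(dna)), type="source",
        qualifiers={"db_xref": [f"taxon:{taxid}"]} if taxid else {}))
    for i, gene in enumerate(genes):
        start = i * 90
        loc = FeatureLocation(
            BeforePosition(start) if partial else start, start + 90,
            strand=strand)
        rec.features.append(SeqFeature(
            loc, type="CDS", qualifiers={"gene": [gene]}))
    return rec


def write_gb(tmp_path, records, name="in.gb"):
    path = tmp_path / name
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")
    return path


class TestImportGenbank:
    def test_annotated_cds_yields_one_assigned_record(
            self, tmp_path, toy_registry, toy_tree):
        path = write_gb(tmp_path, [gb_record("A1", 111, ["L8"])])
        report = import_genbank(path, toy_registry, toy_tree, {10})
        assert len(report.records) == 1
        rec = report.records[0]
        assert rec.locus == "rpL8" and rec.taxid == 111
        assert rec.provenance == "annotated" and rec.full_length

    def test_taxon_screen_rejects_disallowed_species(
            self, tmp_path, toy_registry, toy_tree):
        path = write_gb(tmp_path, [gb_record("A1", 111, ["L8"])])
        report = import_genbank(path, toy_registry, toy_tree, {20})
        assert not report.records
        assert [r.reason for r in report.rejections] == ["taxon screen"]

    def test_mixed_features_split_into_distinct_rejection_reasons(
            self, tmp_path, toy_registry, toy_tree):
        records = [
            gb_record("A1", 111, ["L8"]),        # accepted
            gb_record("A2", 111, ["mystery"]),   # unknown gene name
            gb_record("A3", 211, ["L9"]),        # disallowed taxon
        ]
        path = write_gb(tmp_path, records)
        report = import_genbank(path, toy_registry, toy_tree, {10})
        assert len(report.records) == 1
        reasons = sorted(r.reason for r in report.rejections)
        assert reasons == ["taxon screen", "unresolved gene name"]
        # conservation: every feature is either accepted or rejected
        assert len(report.records) + len(report.rejections) == 3

    def test_genome_description_sets_genome_provenance(
            self, tmp_path, toy_registry, toy_tree):
        path = write_gb(tmp_path, [gb_record(
            "G1", 111, ["L8"], description="Species one chromosome II")])
        report = import_genbank(path, toy_registry, toy_tree, None)
        assert report.records[0].provenance == "genome"

    def test_partial_cds_is_not_full_length(
            self, tmp_path, toy_registry, toy_tree):
        path = write_gb(tmp_path, [gb_record("P1", 111, ["L8"], partial=True)])
        report = import_genbank(path, toy_registry, toy_tree, None)
        assert report.records[0].full_length is False

    def test_minus_strand_feature_equals_plus_strand_equivalent(
            self, tmp_path, toy_registry, toy_tree):
        gene = random_dna(random.Random(5), 90)
        plus = gb_record("S1", 111, ["L8"], seq=gene)
        minus = gb_record("S2", 111, ["L8"], strand=-1,
                          seq=str(Seq(gene).reverse_complement()))
        path = write_gb(tmp_path, [plus, minus])
        report = import_genbank(path, toy_registry, toy_tree, None)
        assert len(report.records) == 2
        assert report.records[0].dna == report.records[1].dna == gene

    def test_gzipped_release_files_are_supported(
            self, tmp_path, toy_registry, toy_tree):
        plain = write_gb(tmp_path, [gb_record("A1", 111, ["L8"])])
        gz = tmp_path / "in.gb.gz"
        gz.write_bytes(gzip.compress(plain.read_bytes()))
        report = import_genbank(gz, toy_registry, toy_tree, None)
        assert len(report.records) == 1

    def test_record_without_taxid_rejected_not_fatal(
            self, tmp_path, toy_registry, toy_tree):
        path = write_gb(tmp_path, [gb_record("A1", None, ["L8"]),
                                   gb_record("A2", 111, ["L9"])])
        report = import_genbank(path, toy_registry, toy_tree, None)
        assert len(report.records) == 1
        assert report.rejections[0].reason == "no taxid"


class TestImportFasta:
    def test_tagged_header_builds_assigned_record(
            self, tmp_path, toy_registry, toy_tree):
        p = tmp_path / "in.fsa"
        p.write_text(">e1 locus=L8 taxid=111\nACGTACGTACGT\n")
        report = import_fasta(p, toy_registry, toy_tree, None)
        rec = report.records[0]
        assert (rec.locus, rec.taxid) == ("rpL8", 111)
        assert rec.provenance == "annotated" and not rec.full_length

    def test_header_without_taxid_rejected_with_position(
            self, tmp_path, toy_registry, toy_tree):
        p = tmp_path / "in.fsa"
        p.write_text(">e1 locus=L8\nACGT\n")
        report = import_fasta(p, toy_registry, toy_tree, None)
        assert not report.records
        assert report.rejections[0].reason == "no taxid"

    def test_untagged_records_queue_for_similarity(
            self, tmp_path, toy_registry, toy_tree):
        p = tmp_path / "in.fsa"
        p.write_text(">e1 taxid=111\nACGTACGT\n")
        report = import_fasta(p, toy_registry, toy_tree, None)
        assert not report.records
        assert len(report.unassigned) == 1
        assert report.unassigned[0].locus is None

    def test_bulk_est_import_counts_malformed_headers(
            self, tmp_path, toy_registry, toy_tree):
        rng = random.Random(11)
        lines = []
        for i in range(100):
            if i % 10 == 0:  # 10 malformed: taxid tag missing
                lines.append(f">est{i}\n{random_dna(rng, 60)}")
            else:
                lines.append(f">est{i} locus=L8 taxid=111\n{random_dna(rng, 60)}")
        p = tmp_path / "ests.fsa"
        p.write_text("\n".join(lines) + "\n")
        report = import_fasta(p, toy_registry, toy_tree, None)
        assert len(report.records) == 90
        assert len(report.rejections) == 10


def smith_waterman_affine(a, b, matrix, gap_open=-11, gap_ext=-1):
    """Quadratic local-alignment oracle (protein), plain DP."""
    la, lb = len(a), len(b)
    NEG = float("-inf")
    best = 0.0
    M = [[0.0] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = matrix[a[i - 1]][b[j - 1]]
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_ext)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_ext)
            M[i][j] = max(0.0,
                          max(M[i - 1][j - 1], X[i - 1][j - 1],
                              Y[i - 1][j - 1]) + s)
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


def make_cds(rng, n_codons):
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice("ACGT") for _ in range(3))
        if c not in ("TAA", "TAG", "TGA"):
            codons.append(c)
    return "".join(codons)


def mutate_dna(rng, dna, frac):
    chars = list(dna)
    for _ in range(int(len(dna) * frac)):
        pos = rng.randrange(len(chars))
        chars[pos] = rng.choice([b for b in "ACGT" if b != chars[pos]])
    return "".join(chars)


@pytest.fixture
def ref_records(toy_registry):
    """Two reference species with annotated full-length genes per locus."""
    rng = random.Random(42)
    records = []
    truth = {}
    for locus, gene in (("rpL8", "L8"), ("rpL9", "L9"), ("rpL14", "L14")):
        seq_a = make_cds(rng, 100)
        seq_b = mutate_dna(rng, seq_a, 0.35)  # deeply diverged outgroup ref
        truth[locus] = (seq_a, seq_b)
        records.append(SequenceRecord(f"ra_{locus}", 111, seq_a, locus,
                                      "annotated", True, frame_known=True))
        records.append(SequenceRecord(f"rb_{locus}", 211, seq_b, locus,
                                      "annotated", True, frame_known=True))
    return records, truth


class TestCutoffs:
    def test_identical_references_give_self_alignment_score(
            self, toy_registry):
        rng = random.Random(1)
        seq = make_cds(rng, 60)
        recs = [
            SequenceRecord("a", 111, seq, "rpL8", "annotated", True,
                           frame_known=True),
            SequenceRecord("b", 211, seq, "rpL8", "annotated", True,
                           frame_known=True),
        ]
        scorer = SimilarityScorer()
        table = compute_locus_cutoffs(recs, 111, 211, toy_registry,
                                      scorer=scorer)
        expected = scorer.score_protein(seq, seq, query_frame_known=True)
        assert table.thresholds["rpL8"] == expected

    def test_missing_reference_falls_back_to_default_with_warning(
            self, toy_registry):
        recs = [SequenceRecord("a", 111, make_cds(random.Random(2), 60),
                               "rpL8", "annotated", True, frame_known=True)]
        with pytest.warns(UserWarning, match="default threshold"):
            table = compute_locus_cutoffs(recs, 111, 211, toy_registry,
                                          default_threshold=77.0)
        assert table.threshold("rpL9") == 77.0
        assert "rpL8" not in table.thresholds

    def test_no_references_at_all_is_an_error(self, toy_registry):
        recs = [SequenceRecord("a", 121, "ATGAAA", "rpL8", "annotated")]
        with pytest.raises(ValueError, match="no references"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                compute_locus_cutoffs(recs, 111, 211, toy_registry)

    def test_threshold_matches_brute_force_local_alignment(
            self, toy_registry, ref_records):
        records, truth = ref_records
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = compute_locus_cutoffs(records, 111, 211, toy_registry)
        blosum = substitution_matrices.load("BLOSUM62")
        seq_a, seq_b = truth["rpL8"]
        prot_a = six_frame_translations(seq_a)[0]
        prot_b = six_frame_translations(seq_b)[0]
        oracle = smith_waterman_affine(prot_a, prot_b, blosum)
        assert table.thresholds["rpL8"] == pytest.approx(oracle)


class TestAssignBySimilarity:
    def test_exact_substring_est_assigned_to_its_locus(
            self, toy_registry, ref_records):
        records, truth = ref_records
        est = SequenceRecord("est1", 121, truth["rpL8"][0][30:270])
        table = compute_locus_cutoffs(records, 111, 211, toy_registry)
        assigned, leftovers = assign_by_similarity(
            [est], records, table, toy_registry)
        assert not leftovers
        assert assigned[0].locus == "rpL8"
        assert assigned[0].provenance == "similarity"

    def test_unrelated_sequence_is_a_leftover(self, toy_registry,
                                              ref_records):
        records, table_in = ref_records
        rng = random.Random(9)
        junk = SequenceRecord("junk", 121, random_dna(rng, 120))
        table = compute_locus_cutoffs(records, 111, 211, toy_registry)
        assigned, leftovers = assign_by_similarity(
            [junk], records, table, toy_registry)
        assert not assigned and leftovers == [junk]

    def test_mutated_ests_mostly_recover_their_true_locus(
            self, toy_registry, ref_records):
        records, truth = ref_records
        rng = random.Random(17)
        ests, labels = [], []
        loci = list(truth)
        for i in range(20):
            locus = loci[i % 3]
            window = truth[locus][0][rng.randrange(0, 60):][:240]
            ests.append(SequenceRecord(f"e{i}", 121,
                                       mutate_dna(rng, window, 0.05)))
            labels.append(locus)
        table = compute_locus_cutoffs(records, 111, 211, toy_registry)
        assigned, leftovers = assign_by_similarity(
            ests, records, table, toy_registry)
        correct = sum(1 for rec, want in zip(ests, labels)
                      if rec.locus == want)
        assert correct >= 19

    def test_no_assignment_below_locus_threshold(self, toy_registry,
                                                 ref_records):
        records, truth = ref_records
        scorer = SimilarityScorer()
        est = SequenceRecord("est1", 121, truth["rpL9"][0][:150])
        table = compute_locus_cutoffs(records, 111, 211, toy_registry)
        # force every threshold above anything attainable: nothing assigned
        for locus in table.thresholds:
            table.thresholds[locus] = 1e9
        assigned, leftovers = assign_by_similarity(
            [est], records, table, toy_registry, scorer=scorer)
        assert not assigned and leftovers
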