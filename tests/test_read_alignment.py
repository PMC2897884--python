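"""Aligner correctness against a brute-force oracle; sets, coverage, RPK."""

import random

import numpy as np
import pytest

from rnamend.io_formats import GeneModel, SequenceRecord, reverse_complement
from rnamend.read_alignment import (
    TranscriptMap,
    align_ungapped,
    compute_expression,
    coverage_profile,
    partition_alignment_sets,
)


def brute_force_alignments(reads, refs, max_mismatch):
    """Sliding-window Hamming scan over both orientations (oracle)."""
    out = set()
    for read in reads:
        for orient, seq in (("+", read.seq), ("-", reverse_complement(read.seq))):
            for ref in refs:
                for off in range(len(ref.seq) - len(seq) + 1):
                    d = sum(a != b for a, b in zip(seq, ref.seq[off : off + len(seq)]))
                    if d <= max_mismatch:
                        out.add((read.id, ref.id, off, orient, d))
    return out


def random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestAlignUngapped:
    @pytest.mark.parametrize("max_mismatch", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, max_mismatch):
        rng = random.Random(42 + max_mismatch)
        refs = [SequenceRecord(f"ref{i}", random_seq(rng, 400)) for i in range(2)]
        reads = []
        for k in range(30):
            src = rng.choice(refs).seq
            off = rng.randrange(len(src) - 30)
            seq = list(src[off : off + 30])
            for _ in range(rng.randrange(0, 4)):  # 0-3 injected mismatches
                p = rng.randrange(30)
                seq[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
            s = "".join(seq)
            if rng.random() < 0.5:
                s = reverse_complement(s)
            reads.append(SequenceRecord(f"r{k}", s))
        got = {
            (a.read_id, a.ref_id, a.offset, a.orientation, a.mismatches)
            for a in align_ungapped(reads, refs, max_mismatch)
        }
        assert got == brute_force_alignments(reads, refs, max_mismatch)

    def test_exact_substring_found(self):
        rng = random.Random(11)
        ref = SequenceRecord("ref", random_seq(rng, 80))
        read = SequenceRecord("r", ref.seq[10:56])
        alns = align_ungapped([read], [ref], 0)
        assert [(a.offset, a.orientation, a.mismatches) for a in alns if a.orientation == "+"] == [(10, "+", 0)]

    def test_too_many_mismatches_rejected(self):
        ref = SequenceRecord("ref", "A" * 60)
        read = SequenceRecord("r", "A" * 27 + "CCC")
        assert align_ungapped([read], [ref], 2) == []

    def test_reverse_complement_found(self):
        rng = random.Random(7)
        ref = SequenceRecord("ref", random_seq(rng, 80))
        read = SequenceRecord("r", reverse_complement(ref.seq[0:46]))
        alns = align_ungapped([read], [ref], 0)
        assert any(a.offset == 0 and a.orientation == "-" for a in alns)

    def test_read_longer_than_reference_is_no_alignment(self):
        assert (
            align_ungapped(
                [SequenceRecord("r", "ACGTACGT")], [SequenceRecord("s", "ACG")], 0
            )
            == []
        )

    def test_empty_read_set(self):
        assert align_ungapped([], [SequenceRecord("s", "ACGT")], 2) == []


def tiled_reads(tx, read_len, prefix="t"):
    return [
        SequenceRecord(f"{prefix}{o}", tx[o : o + read_len])
        for o in range(len(tx) - read_len + 1)
    ]


@pytest.fixture(scope="module")
def two_exon_world():
    """One plus-strand gene, exons 120 bp apart; error-free tiled reads."""
    rng = random.Random(3)
    seq = list(random_seq(rng, 600))
    # force the intron's terminal bases to differ from the adjacent exon
    # bases so no junction-crossing read can align to the genome by chance
    seq[199], seq[200], seq[319], seq[320] = "G", "A", "T", "C"
    scaffold = SequenceRecord("sc", "".join(seq))
    model = GeneModel("g", "sc", "+", [(50, 200), (320, 470)])
    tx = model.transcript(scaffold)
    reads = tiled_reads(tx, 46)
    genome_alns = align_ungapped(reads, [scaffold], 0)
    model_alns = align_ungapped(reads, [SequenceRecord("g", tx)], 0)
    sets = partition_alignment_sets(genome_alns, model_alns)
    return scaffold, model, tx, reads, sets


class TestAlignmentSets:
    def test_junction_spanning_reads_are_set2(self, two_exon_world):
        _sc, model, tx, reads, sets = two_exon_world
        set2_ids = {a.read_id for a in sets.set2}
        # oracle: enumerate tiled windows crossing the junction (mm=0, so any
        # overlap with the second exon breaks the genome alignment)
        junction = 150
        expected = {
            f"t{o}" for o in range(len(tx) - 45)
            if o < junction and o + 46 > junction
        }
        assert set2_ids == expected

    def test_genome_only_read_not_in_set2(self, two_exon_world):
        scaffold, *_ = two_exon_world
        read = SequenceRecord("gx", scaffold.seq[500:546])
        sets = partition_alignment_sets(
            align_ungapped([read], [scaffold], 0), []
        )
        assert sets.set1 and not sets.set2 and not sets.set3

    def test_set2_within_set3(self, two_exon_world):
        *_, sets = two_exon_world
        set3_ids = {a.read_id for a in sets.set3}
        assert {a.read_id for a in sets.set2} <= set3_ids


class TestCoverageProfile:
    def test_single_read_covers_read_len_bases(self):
        rng = random.Random(5)
        scaffold = SequenceRecord("sc", random_seq(rng, 200))
        model = GeneModel("g", "sc", "+", [(20, 180)])
        read = SequenceRecord("r", scaffold.seq[30:76])
        sets = partition_alignment_sets(align_ungapped([read], [scaffold], 0), [])
        prof = coverage_profile(model, sets, TranscriptMap(model), 46)
        assert prof.genome_align.sum() == 46
        assert (prof.genome_align[10:56] == 1).all()

    def test_no_reads_all_zero(self):
        scaffold = SequenceRecord("sc", "ACGT" * 50)
        model = GeneModel("g", "sc", "+", [(20, 180)])
        sets = partition_alignment_sets([], [])
        prof = coverage_profile(model, sets, TranscriptMap(model), 46)
        assert prof.genome_align.sum() == 0 and prof.border_align.sum() == 0

    def test_coverage_conservation(self, two_exon_world):
        scaffold, _model, _tx, reads, sets = two_exon_world
        # every Set-1 alignment lies inside this whole-scaffold "gene"
        whole = GeneModel("whole", "sc", "+", [(0, len(scaffold.seq))])
        prof = coverage_profile(whole, sets, TranscriptMap(whole), 46)
        assert prof.genome_align.sum() == len(sets.set1) * 46

    @pytest.mark.parametrize("min_overhang", [3, 6])
    def test_junction_support_tiling_formula(self, two_exon_world, min_overhang):
        _sc, model, _tx, _reads, sets = two_exon_world
        prof = coverage_profile(
            model, sets, TranscriptMap(model), 46, min_overhang
        )
        assert prof.junction_support == [46 - 2 * min_overhang + 1]

    def test_border_align_only_on_exonic_positions(self, two_exon_world):
        _sc, model, _tx, _reads, sets = two_exon_world
        prof = coverage_profile(model, sets, TranscriptMap(model), 46)
        exonic = np.zeros(model.span, dtype=bool)
        for s, e in model.exons:
            exonic[s - model.start : e - model.start] = True
        assert prof.border_align[~exonic].sum() == 0
        assert prof.border_align[exonic].sum() > 0


class TestTranscriptMap:
    def test_minus_strand_projection_runs_right_to_left(self):
        model = GeneModel("g", "sc", "-", [(10, 14), (20, 24)])
        tmap = TranscriptMap(model)
        assert [tmap.to_scaffold(t) for t in range(8)] == [23, 22, 21, 20, 13, 12, 11, 10]
        assert tmap.junctions == [4]


class TestComputeExpression:
    @staticmethod
    def _sets_with_model_hits(gene_id, n):
        from rnamend.read_alignment import AlignmentSets, ReadAlignment

        hits = [ReadAlignment(f"r{k}", gene_id, 0, "+", 0) for k in range(n)]
        return AlignmentSets(set1=[], set2=[], set3=hits)

    def test_rpk_500_means_depth_23(self):
        model = GeneModel("g", "sc", "+", [(0, 1000)])
        expr = compute_expression(model, self._sets_with_model_hits("g", 500), 46)
        assert expr.rpk == 500.0 and expr.mean_depth == 23.0

    def test_rpk_60_means_depth_about_3(self):
        model = GeneModel("g", "sc", "+", [(0, 2000)])
        expr = compute_expression(model, self._sets_with_model_hits("g", 120), 46)
        assert expr.rpk == 60.0
        assert expr.mean_depth == pytest.approx(2.76)

    def test_zero_reads(self):
        model = GeneModel("g", "sc", "+", [(0, 1000)])
        expr = compute_expression(model, self._sets_with_model_hits("g", 0), 46)
        assert expr.rpk == 0.0 and expr.mean_depth == 0.0


class TestSamImport:
    SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:sc\tLN:1000\n"

    def test_ungapped_records_imported(self, tmp_path):
        from rnamend.read_alignment import read_sam_alignments

        p = tmp_path / "a.sam"
        p.write_text(
            self.SAM_HEADER
            + "r1\t0\tsc\t11\t60\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\tNM:i:1\n"
            + "r2\t16\tsc\t21\t60\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\n"
            + "r3\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n"
        )
        alns = read_sam_alignments(str(p))
        assert [(a.read_id, a.offset, a.orientation, a.mismatches) for a in alns] == [
            ("r1", 10, "+", 1),
            ("r2", 20, "-", 0),
        ]

    def test_gapped_record_rejected(self, tmp_path):
        from rnamend.read_alignment import read_sam_alignments

        p = tmp_path / "b.sam"
        p.write_text(
            self.SAM_HEADER
            + "r1\t0\tsc\t11\t60\t5M2D5M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\n"
        )
        with pytest.raises(ValueError, match="ungapped"):
            read_sam_alignments(str(p))
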