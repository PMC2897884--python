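"""Spliced realignment: DP oracle equivalence, structure recovery, outcomes."""

import random
from functools import lru_cache

import pytest

from rnamend.bridge import BES, ResolvedFlag
from rnamend.io_formats import GeneModel, SequenceRecord, reverse_complement
from rnamend.realign import (
    ScoringScheme,
    classify_outcome,
    prepare_bes,
    recover_structure,
    spliced_align,
)


def random_seq(seed, n, alphabet="ACGT"):
    rng = random.Random(seed)
    return "".join(rng.choice(alphabet) for _ in range(n))


def oracle_score(bes, win, scheme=ScoringScheme()):
    """Independent top-down search over all constrained alignments.

    Explores every operation sequence (memoized on position and open-run
    length); a diagonal run may only end, and the alignment may only
    finish, once the run has at least min_bes_block columns.
    """
    m, n = len(bes), len(win)
    NEG = float("-inf")

    def sub(a, b):
        if "N" in (a, b):
            return scheme.n_match
        return scheme.match if a == b else scheme.mismatch

    @lru_cache(maxsize=None)
    def best(i, j, run):
        candidates = []
        if i == m and j == n:
            if run == 0 or run >= scheme.min_bes_block:
                candidates.append(0)
        if i < m and j < n:  # align column
            candidates.append(
                sub(bes[i], win[j]) + best(i + 1, j + 1, min(run + 1, 4))
            )
        if run == 0 or run >= scheme.min_bes_block:
            if j < n:  # window base unaligned (gap in BES / overhang)
                cost = scheme.bes_end_gap if i in (0, m) else scheme.gap_in_bes
                candidates.append(-cost + best(i, j + 1, 0))
            if i < m:  # BES base unaligned (gap in scaffold)
                candidates.append(-scheme.gap_in_scaffold + best(i + 1, j, 0))
        return max(candidates, default=NEG)

    return best(0, 0, 0)


class TestSplicedAlignOracle:
    def test_identical_10bp_scores_80_one_block(self):
        seq = random_seq(1, 10)
        aln = spliced_align(seq, seq)
        assert aln.score == 80
        assert aln.blocks == [((0, 10), (0, 10))]
        assert aln.identity == 1.0

    def test_intron_example_scores_710(self):
        e1, e2 = random_seq(2, 50), random_seq(3, 50)
        intron = random_seq(4, 90)
        aln = spliced_align(e1 + e2, e1 + intron + e2)
        assert aln.score == 100 * 8 - 90 * 1 == 710
        assert len(aln.window_exons) == 2

    @pytest.mark.parametrize("seed", range(12))
    def test_random_pairs_match_oracle(self, seed):
        rng = random.Random(seed)
        m = rng.randrange(4, 14)
        n = rng.randrange(4, 18)
        bes = random_seq(seed * 3 + 1, m, "ACGN")
        win = random_seq(seed * 3 + 2, n, "ACGN")
        assert spliced_align(bes, win).score == oracle_score(bes, win)

    @pytest.mark.parametrize("seed", range(8))
    def test_exonlike_pairs_match_oracle(self, seed):
        rng = random.Random(100 + seed)
        e1 = random_seq(200 + seed, rng.randrange(5, 10))
        e2 = random_seq(300 + seed, rng.randrange(5, 10))
        intron = random_seq(400 + seed, rng.randrange(3, 15))
        bes, win = e1 + e2, e1 + intron + e2
        assert len(bes) <= 40 and len(win) <= 40
        assert spliced_align(bes, win).score == oracle_score(bes, win)

    def test_short_island_is_not_emitted_as_block(self):
        # a 3-nt island matching only in isolation cannot form a block
        e1 = random_seq(11, 20)
        island = "TGA"
        win = e1 + random_seq(12, 30) + island + random_seq(13, 30)
        bes = e1 + island
        aln = spliced_align(bes, win)
        assert all(b[0][1] - b[0][0] >= 4 for b in aln.blocks)
        assert aln.score == oracle_score(bes, win)

    def test_added_mismatch_never_raises_score(self):
        rng = random.Random(21)
        e1, e2 = random_seq(22, 30), random_seq(23, 30)
        intron = random_seq(24, 40)
        bes, win = e1 + e2, e1 + intron + e2
        base_score = spliced_align(bes, win).score
        for _ in range(5):
            p = rng.randrange(len(bes))
            mutated = bes[:p] + ("G" if bes[p] != "G" else "T") + bes[p + 1 :]
            assert spliced_align(mutated, win).score <= base_score

    def test_deterministic(self):
        bes = random_seq(31, 60)
        win = random_seq(32, 100)
        a1, a2 = spliced_align(bes, win), spliced_align(bes, win)
        assert a1.score == a2.score and a1.ops == a2.ops


def make_bes(seq, up=0, down=0, bridged=0, unresolved=0):
    return BES(
        gene_id="g",
        sequence=seq,
        bridged_flags=[ResolvedFlag(1, 6, "")] * bridged,
        unresolved_flags=[1] * unresolved,
        upstream_extension_len=up,
        downstream_extension_len=down,
    )


class TestPrepareBES:
    def test_five_percent_trim_and_3x_window(self):
        scaffold = SequenceRecord("sc", random_seq(41, 2000))
        model = GeneModel("g", "sc", "+", [(500, 700)])
        bes = make_bes("A" * (100 + 200 + 50), up=100, down=50)
        trimmed, win_lo, window = prepare_bes(bes, model, scaffold)
        assert len(bes.sequence) - len(trimmed) == 5 + 2  # floor(5), floor(2.5)
        assert win_lo == 500 - 300
        assert len(window) == (700 + 150) - (500 - 300)

    def test_zero_extension_window_is_model_span(self):
        scaffold = SequenceRecord("sc", random_seq(42, 1000))
        model = GeneModel("g", "sc", "+", [(100, 300)])
        bes = make_bes("A" * 200)
        trimmed, win_lo, window = prepare_bes(bes, model, scaffold)
        assert trimmed == bes.sequence
        assert (win_lo, len(window)) == (100, 200)

    def test_window_clipped_at_scaffold_start(self):
        scaffold = SequenceRecord("sc", random_seq(43, 1000))
        model = GeneModel("g", "sc", "+", [(10, 200)])
        bes = make_bes("A" * 240, up=50)
        _trimmed, win_lo, _window = prepare_bes(bes, model, scaffold)
        assert win_lo == 0

    def test_minus_strand_upstream_extension_widens_scaffold_right(self):
        scaffold = SequenceRecord("sc", random_seq(44, 2000))
        model = GeneModel("g", "sc", "-", [(500, 700)])
        bes = make_bes("A" * 260, up=60)
        _trimmed, win_lo, window = prepare_bes(bes, model, scaffold)
        assert win_lo == 500
        assert win_lo + len(window) == 700 + 180


@pytest.fixture(scope="module")
def gene_world():
    rng = random.Random(51)
    seq = list(random_seq(52, 3000))
    exons = [(300, 500), (580, 760), (900, 1100)]
    # unambiguous splice boundaries (no score-tied one-base slides)
    for i in range(len(exons) - 1):
        s, e = exons[i][1], exons[i + 1][0]
        if seq[s] == seq[e]:
            seq[s] = "A" if seq[e] != "A" else "C"
        if seq[e - 1] == seq[s - 1]:
            seq[e - 1] = "A" if seq[s - 1] != "A" else "C"
    scaffold = SequenceRecord("sc", "".join(seq))
    return scaffold, exons


class TestRecoverStructure:
    def test_plus_strand_round_trip(self, gene_world):
        scaffold, exons = gene_world
        model = GeneModel("g", "sc", "+", exons)
        bes = make_bes(model.transcript(scaffold))
        cm = recover_structure(bes, model, scaffold)
        assert cm.exons == exons and cm.strand == "+"
        assert cm.outcome == "validated"

    def test_minus_strand_recovered_via_revcomp_retry(self, gene_world):
        scaffold, exons = gene_world
        model = GeneModel("g", "sc", "-", exons)
        bes = make_bes(model.transcript(scaffold))
        cm = recover_structure(bes, model, scaffold)
        assert cm.exons == exons and cm.strand == "-"

    def test_strand_symmetry(self, gene_world):
        scaffold, exons = gene_world
        plus = GeneModel("g", "sc", "+", exons)
        tx = plus.transcript(scaffold)
        cm_fwd = recover_structure(make_bes(tx), plus, scaffold)
        cm_rev = recover_structure(make_bes(reverse_complement(tx)), plus, scaffold)
        assert cm_fwd.exons == cm_rev.exons
        assert {cm_fwd.strand, cm_rev.strand} == {"+", "-"}

    def test_unresolved_flags_fail_without_alignment(self, gene_world):
        scaffold, exons = gene_world
        model = GeneModel("g", "sc", "+", exons)
        bes = make_bes("ACGT" * 50 + "X" + "ACGT" * 50, unresolved=1)
        cm = recover_structure(bes, model, scaffold)
        assert cm.outcome == "failed" and cm.reason == "unresolved_flags"

    def test_garbage_bes_fails_both_orientations(self, gene_world):
        scaffold, exons = gene_world
        model = GeneModel("g", "sc", "+", exons)
        bes = make_bes(random_seq(999, 500))
        cm = recover_structure(bes, model, scaffold)
        assert cm.outcome == "failed" and cm.reason == "no_alignment"


class TestClassifyOutcome:
    @pytest.fixture
    def model(self):
        return GeneModel("g", "sc", "+", [(0, 100), (200, 300)])

    def test_identical_structure_validates(self, model):
        outcome, rec = classify_outcome(model, model.exons, make_bes("A"))
        assert outcome == "validated"
        assert rec == rec.__class__(0, 0, 0.0)

    def test_bridged_flag_alone_means_corrected(self, model):
        outcome, _ = classify_outcome(model, model.exons, make_bes("A", bridged=1))
        assert outcome == "corrected"

    def test_exon_count_change_means_corrected(self, model):
        outcome, rec = classify_outcome(
            model, [(0, 100), (150, 160), (200, 290)], make_bes("A")
        )
        assert outcome == "corrected" and rec.exon_count_delta == 1

    def test_size_change_over_ten_percent_means_corrected(self, model):
        outcome, rec = classify_outcome(model, [(0, 130), (200, 300)], make_bes("A"))
        assert outcome == "corrected"
        assert rec.size_change_fraction == pytest.approx(0.15)

    def test_size_change_under_ten_percent_validates(self, model):
        outcome, _ = classify_outcome(model, [(0, 105), (200, 300)], make_bes("A"))
        assert outcome == "validated"
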