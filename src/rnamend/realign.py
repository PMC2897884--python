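"""Spliced realignment of a BES to its scaffold window.

The aligner is a Smith-Waterman variant shaped for cDNA-to-genome
alignment with asymmetric gap costs: gaps in the BES (introns) cost 1
per base, gaps in the scaffold (insertions relative to the assembly)
cost 24 per base, and gaps flanking the BES (scaffold overhang) are
free, making the alignment semi-global in the BES.  Matches score +8,
mismatches -12, and any column containing an 'N' scores +4, which keeps
assembly gaps from attracting spurious genome gaps without rewarding
runs of unknowns.  Isolated islands of fewer than 4 contiguous aligned
BES nucleotides are excluded inside the optimization itself via a
run-length DP state, so the returned score is optimal under the
constraint.  No splice-site dinucleotide signal is used: junction
placement comes from the alignment alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import GeneModel, SequenceRecord, reverse_complement

NEG = -(2**28)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 8
    mismatch: int = -12
    n_match: int = 4
    gap_in_scaffold: int = 24   # penalty per base, applied as negative
    gap_in_bes: int = 1         # penalty per base (introns)
    bes_end_gap: int = 0        # scaffold overhang beyond the BES
    min_bes_block: int = 4

    def substitution_matrix(self) -> np.ndarray:
        m = np.full((5, 5), self.mismatch, dtype=np.int32)
        np.fill_diagonal(m, self.match)
        m[4, :] = self.n_match
        m[:, 4] = self.n_match
        return m


@dataclass
class SplicedAlignment:
    score: int
    blocks: list[tuple[tuple[int, int], tuple[int, int]]]  # (bes, window) intervals
    orientation: str
    identity: float
    aligned_fraction: float     # fraction of non-N BES bases in aligned columns
    ops: list[str] = field(default_factory=list)  # 'D' diag, 'V' bes-insert, 'H' intron/overhang

    @property
    def window_exons(self) -> list[tuple[int, int]]:
        """Maximal aligned window intervals (exons in window coordinates)."""
        exons: list[list[int]] = []
        for (_b, (ws, we)) in self.blocks:
            if exons and exons[-1][1] == ws:
                exons[-1][1] = we
            else:
                exons.append([ws, we])
        return [(s, e) for s, e in exons]


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_CODE[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from exc


def spliced_align(
    bes_seq: str, window_seq: str, scheme: ScoringScheme = ScoringScheme()
) -> SplicedAlignment:
    """Optimal constrained alignment of the full BES into the window.

    States track the length of the open diagonal run (0, 1, 2, 3, >=4
    capped); a run may only be interrupted or ended once it has reached
    ``min_bes_block`` columns.  Ties are broken deterministically in the
    traceback by preferring to extend diagonal runs leftward, which
    yields the leftmost placement of score-equivalent introns and the
    fewest gap openings among optima.
    """
    if not bes_seq or not window_seq:
        raise ValueError("sequences must be non-empty")
    if scheme.min_bes_block != 4:
        # the run-length state machine below caps runs at 4
        raise NotImplementedError("min_bes_block other than 4 is not supported")

    bes = _encode(bes_seq)
    win = _encode(window_seq)
    m, n = len(bes), len(win)
    sub = scheme.substitution_matrix()
    gap_sc = scheme.gap_in_scaffold
    gap_bes = scheme.gap_in_bes

    S = np.full((m + 1, n + 1, 5), NEG, dtype=np.int32)
    S[0, :, 0] = 0  # free leading window overhang
    idx = np.arange(n + 1, dtype=np.int64)

    for i in range(1, m + 1):
        subrow = sub[bes[i - 1], win]          # length n, for j=1..n
        P = S[i - 1]
        C = S[i]
        C[1:, 1] = P[:-1, 0] + subrow
        C[1:, 2] = P[:-1, 1] + subrow
        C[1:, 3] = P[:-1, 2] + subrow
        C[1:, 4] = np.maximum(P[:-1, 3], P[:-1, 4]) + subrow
        V = np.maximum(P[:, 0], P[:, 4]) - gap_sc
        c = scheme.bes_end_gap if i == m else gap_bes
        A = V.astype(np.int64) + c * idx
        B = C[:, 4].astype(np.int64) + c * idx
        cmA = np.maximum.accumulate(A)
        cmB = np.maximum.accumulate(B)
        h = cmA.copy()
        h[1:] = np.maximum(h[1:], cmB[:-1])
        C[:, 0] = (h - c * idx).astype(np.int32)

    score = int(max(S[m, n, 0], S[m, n, 4]))

    # traceback
    ops_rev: list[str] = []
    i, j = m, n
    r = 4 if S[m, n, 4] >= S[m, n, 0] else 0
    while i > 0 or (r != 0):
        cur = S[i, j, r]
        if r >= 1:
            # diagonal step
            prev_r4 = None
            if r == 4:
                d = sub[bes[i - 1], win[j - 1]]
                prev_r4 = 4 if S[i - 1, j - 1, 4] + d == cur else 3
                prev = prev_r4
            else:
                prev = r - 1
            ops_rev.append("D")
            i, j, r = i - 1, j - 1, prev
            continue
        # r == 0: prefer continuing an open gap (predecessor state 0) over
        # closing a diagonal run (state 4), which yields the fewest introns
        # among equal-score alignments
        c = scheme.bes_end_gap if (i == m or i == 0) else gap_bes
        if j > 0 and S[i, j - 1, 0] - c == cur:
            ops_rev.append("H")
            j = j - 1
        elif i > 0 and S[i - 1, j, 0] - gap_sc == cur:
            ops_rev.append("V")
            i = i - 1
        elif j > 0 and S[i, j - 1, 4] - c == cur:
            ops_rev.append("H")
            j, r = j - 1, 4
        elif i > 0 and S[i - 1, j, 4] - gap_sc == cur:
            ops_rev.append("V")
            i, r = i - 1, 4
        elif i == 0:
            break
        else:  # pragma: no cover - would indicate a DP bookkeeping bug
            raise AssertionError("traceback failed")
    ops = ops_rev[::-1]
    j_start = j  # leading window overhang consumed for free

    # blocks, identity, aligned fraction
    blocks: list[tuple[tuple[int, int], tuple[int, int]]] = []
    bi, wi = 0, j_start
    run_b = run_w = None
    matches = informative = 0
    aligned_informative_bes = 0
    for op in ops:
        if op == "D":
            if run_b is None:
                run_b, run_w = bi, wi
            b_code, w_code = bes[bi], win[wi]
            if b_code != 4 and w_code != 4:
                informative += 1
                if b_code == w_code:
                    matches += 1
            if b_code != 4:
                aligned_informative_bes += 1
            bi += 1
            wi += 1
        else:
            if run_b is not None:
                blocks.append(((run_b, bi), (run_w, wi)))
                run_b = run_w = None
            if op == "V":
                bi += 1
            else:
                wi += 1
    if run_b is not None:
        blocks.append(((run_b, bi), (run_w, wi)))

    non_n_bes = int(np.sum(bes != 4))
    identity = matches / informative if informative else 0.0
    aligned_fraction = (
        aligned_informative_bes / non_n_bes if non_n_bes else 0.0
    )
    return SplicedAlignment(
        score=score,
        blocks=blocks,
        orientation="+",
        identity=identity,
        aligned_fraction=aligned_fraction,
        ops=ops,
    )


@dataclass(frozen=True)
class ChangeRecord:
    bridged_flag_count: int
    exon_count_delta: int
    size_change_fraction: float


@dataclass
class CorrectedModel:
    gene_id: str
    scaffold_id: str
    strand: str
    exons: list[tuple[int, int]]
    outcome: str                 # validated | corrected | failed
    change_record: ChangeRecord | None = None
    reason: str = ""

    def to_gene_model(self) -> GeneModel:
        return GeneModel(self.gene_id, self.scaffold_id, self.strand, list(self.exons))


def prepare_bes(
    bes, model: GeneModel, scaffold: SequenceRecord
) -> tuple[str, int, str]:
    """Trim extension ends and pick the scaffold window for realignment.

    5% (floor) of each terminus extension is trimmed from its outer end;
    the window is the original model span widened by three times the
    length of the sequence added on each scaffold side, clipped to the
    scaffold.  Returns (trimmed BES, window start, window sequence).
    """
    up, down = bes.upstream_extension_len, bes.downstream_extension_len
    trim_up = int(0.05 * up)
    trim_down = int(0.05 * down)
    seq = bes.sequence
    trimmed = seq[trim_up : len(seq) - trim_down if trim_down else len(seq)]

    # transcript-upstream is scaffold-left for '+' genes, scaffold-right for '-'
    if model.strand == "+":
        left_ext, right_ext = 3 * up, 3 * down
    else:
        left_ext, right_ext = 3 * down, 3 * up
    win_lo = max(0, model.start - left_ext)
    win_hi = min(len(scaffold.seq), model.end + right_ext)
    if win_lo >= win_hi:
        raise ValueError(f"empty scaffold window for gene {model.gene_id!r}")
    return trimmed, win_lo, scaffold.seq[win_lo:win_hi]


def classify_outcome(
    old: GeneModel, new_exons: list[tuple[int, int]], bes
) -> tuple[str, ChangeRecord]:
    """validated / corrected decision from the change record.

    A model counts as corrected when at least one flag was bridged, the
    exon count changed, or the expressed length moved by more than 10%.
    """
    new_len = sum(e - s for s, e in new_exons)
    old_len = old.transcript_length
    record = ChangeRecord(
        bridged_flag_count=len(bes.bridged_flags),
        exon_count_delta=len(new_exons) - len(old.exons),
        size_change_fraction=(new_len - old_len) / old_len,
    )
    corrected = (
        record.bridged_flag_count >= 1
        or record.exon_count_delta != 0
        or abs(record.size_change_fraction) > 0.10
    )
    return ("corrected" if corrected else "validated"), record


def recover_structure(
    bes,
    model: GeneModel,
    scaffold: SequenceRecord,
    scheme: ScoringScheme = ScoringScheme(),
    min_aligned_fraction: float = 0.9,
    min_identity: float = 0.95,
) -> CorrectedModel:
    """Realign a BES and emit the corrected exon structure and outcome.

    The first attempt aligns the BES as assembled; if it fails the
    acceptance test (>= *min_aligned_fraction* of non-N BES bases aligned
    and >= *min_identity* over informative columns), the reverse
    complement is tried.  A BES with unresolved flags fails immediately.
    """
    if bes.has_unresolved:
        return CorrectedModel(
            gene_id=model.gene_id,
            scaffold_id=model.scaffold_id,
            strand=model.strand,
            exons=list(model.exons),
            outcome="failed",
            reason="unresolved_flags",
        )
    trimmed, win_lo, window = prepare_bes(bes, model, scaffold)

    def acceptable(aln: SplicedAlignment) -> bool:
        return (
            aln.aligned_fraction >= min_aligned_fraction
            and aln.identity >= min_identity
        )

    aln = spliced_align(trimmed, window, scheme)
    strand = "+"
    if not acceptable(aln):
        aln_rc = spliced_align(reverse_complement(trimmed), window, scheme)
        aln_rc.orientation = "-"
        if acceptable(aln_rc):
            aln, strand = aln_rc, "-"
        else:
            return CorrectedModel(
                gene_id=model.gene_id,
                scaffold_id=model.scaffold_id,
                strand=model.strand,
                exons=list(model.exons),
                outcome="failed",
                reason="no_alignment",
            )
    exons = [(win_lo + s, win_lo + e) for s, e in aln.window_exons]
    outcome, record = classify_outcome(model, exons, bes)
    return CorrectedModel(
        gene_id=model.gene_id,
        scaffold_id=model.scaffold_id,
        strand=strand,
        exons=exons,
        outcome=outcome,
        change_record=record,
    )
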