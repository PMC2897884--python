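"""Ungapped read alignment, alignment-set partition, coverage and RPK.

This module stands in for the role a short-read mapper plays in the
correction pipeline.  Alignment is whole-read Hamming distance with a
configurable mismatch budget (default 2), deterministic and quality-blind:
everything downstream consumes only per-position counts, so the mapper's
seed/quality heuristics are deliberately not modelled.

Reads are mapped both to the genome (Set 1) and to the spliced model
transcripts (Set 3); the reads that hit a transcript but nowhere on the
genome (Set 2) are the junction-spanning evidence the per-junction and
border counts are built from.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .io_formats import GeneModel, SequenceRecord, reverse_complement

DEFAULT_MAX_MISMATCH = 2
# A read only counts as junction-spanning evidence with at least this many
# bases on each side of the junction.  With a 4-letter alphabet and a
# 2-mismatch budget, an overhang of o bases of the WRONG sequence still
# aligns with probability P[Binom(o, 3/4) <= 2] (~58% at o=3, <4% at o=6),
# so overhangs shorter than 6 bp cannot be told apart from chance matches
# and would let unexpressed junctions accumulate spurious support.
DEFAULT_MIN_OVERHANG = 6


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    ref_id: str
    offset: int          # 0-based start on the reference
    orientation: str     # '+' read as given; '-' reverse complement matches
    mismatches: int


@dataclass
class AlignmentSets:
    """The three alignment sets the method is defined over.

    set1: alignments to genomic sequence.
    set2: alignments to model transcripts from reads with no genome
          alignment at all (splice-junction evidence).
    set3: all alignments to model transcripts.
    """

    set1: list[ReadAlignment]
    set2: list[ReadAlignment]
    set3: list[ReadAlignment]

    def __post_init__(self) -> None:
        genome_reads = {a.read_id for a in self.set1}
        assert all(a.read_id not in genome_reads for a in self.set2), (
            "set2 must not contain reads with a genome alignment"
        )


def _hamming_at_most(a: str, b: str, limit: int) -> int:
    """Hamming distance of equal-length strings, or limit+1 if exceeded."""
    if a == b:
        return 0
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def align_ungapped(
    reads: list[SequenceRecord],
    refs: list[SequenceRecord],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> list[ReadAlignment]:
    """Report every placement of every read with <= max_mismatch mismatches.

    Both orientations are searched and all placements are kept
    (multi-mapping reads contribute at every site).  Exactness follows
    from pigeonhole seeding: a read split into ``max_mismatch + 1``
    disjoint seeds must place at least one seed without error, so looking
    up each seed in an exact k-mer index of the references enumerates
    every candidate diagonal.
    """
    if not reads:
        return []
    read_len = len(reads[0].seq)
    if any(len(r.seq) != read_len for r in reads):
        raise ValueError("all reads must have the same length")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")

    k = read_len // (max_mismatch + 1)
    if k < 1:
        raise ValueError("read length too short for this mismatch budget")

    index: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for ri, ref in enumerate(refs):
        seq = ref.seq
        for pos in range(len(seq) - k + 1):
            index[seq[pos : pos + k]].append((ri, pos))

    out: list[ReadAlignment] = []
    n_seeds = max_mismatch + 1
    for read in reads:
        seen: set[tuple[int, int, str]] = set()
        for orient, seq in (("+", read.seq), ("-", reverse_complement(read.seq))):
            for t in range(n_seeds):
                seed = seq[t * k : (t + 1) * k]
                for ri, pos in index.get(seed, ()):
                    off = pos - t * k
                    if off < 0:
                        continue
                    ref_seq = refs[ri].seq
                    if off + read_len > len(ref_seq):
                        continue
                    key = (ri, off, orient)
                    if key in seen:
                        continue
                    seen.add(key)
                    d = _hamming_at_most(seq, ref_seq[off : off + read_len], max_mismatch)
                    if d <= max_mismatch:
                        out.append(
                            ReadAlignment(read.id, refs[ri].id, off, orient, d)
                        )
    return out


def partition_alignment_sets(
    genome_alns: list[ReadAlignment], model_alns: list[ReadAlignment]
) -> AlignmentSets:
    """Split alignments into the genome / junction-evidence / model sets."""
    genome_reads = {a.read_id for a in genome_alns}
    set2 = [a for a in model_alns if a.read_id not in genome_reads]
    return AlignmentSets(set1=list(genome_alns), set2=set2, set3=list(model_alns))


class TranscriptMap:
    """Projection between transcript coordinates and scaffold coordinates.

    Transcript coordinate 0 is the 5' end of the spliced transcript; for
    minus-strand genes that is the rightmost exon base on the scaffold and
    the projection runs right-to-left.
    """

    def __init__(self, model: GeneModel):
        self.model = model
        lengths = [e - s for s, e in model.exons]
        self.cum = np.concatenate([[0], np.cumsum(lengths)])  # len = n_exons+1
        self.length = int(self.cum[-1])

    @property
    def junctions(self) -> list[int]:
        """Transcript coordinates of the internal exon/exon boundaries."""
        inner = self.cum[1:-1]
        if self.model.strand == "+":
            return [int(c) for c in inner]
        return [self.length - int(c) for c in reversed(inner)]

    def to_scaffold(self, t: int) -> int:
        """Map a transcript position to its scaffold position."""
        if not 0 <= t < self.length:
            raise IndexError(f"transcript position {t} outside model")
        if self.model.strand == "-":
            t = self.length - 1 - t
        i = bisect.bisect_right(self.cum, t) - 1
        start, _end = self.model.exons[i]
        return start + (t - int(self.cum[i]))


@dataclass
class CoverageProfile:
    """Per-base and per-junction read support for one gene model.

    Arrays cover the model's scaffold span ``[start, start + len)`` in
    scaffold orientation.  ``junction_support`` is indexed by intron in
    transcript order.
    """

    gene_id: str
    start: int
    genome_align: np.ndarray
    border_align: np.ndarray
    junction_support: list[int]
    min_overhang: int = DEFAULT_MIN_OVERHANG


def coverage_profile(
    model: GeneModel,
    sets: AlignmentSets,
    transcript_map: TranscriptMap,
    read_len: int,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> CoverageProfile:
    """Build GenomeAlign/BorderAlign counts and junction support for a gene.

    GenomeAlign counts Set-1 alignment bases per scaffold position inside
    the model span.  Each Set-2 alignment to this model is projected
    through the exon blocks and increments BorderAlign at every projected
    scaffold position.  Junction support counts Set-2 alignments crossing
    a predicted intron's transcript-coordinate junction with at least
    ``min_overhang`` bases on each side.
    """
    span = model.span
    start = model.start
    delta = np.zeros(span + 1, dtype=np.int64)
    for a in sets.set1:
        if a.ref_id != model.scaffold_id:
            continue
        lo = max(a.offset, start)
        hi = min(a.offset + read_len, model.end)
        if lo < hi:
            delta[lo - start] += 1
            delta[hi - start] -= 1
    genome_align = np.cumsum(delta[:-1])

    border_align = np.zeros(span, dtype=np.int64)
    # transcript coordinates of internal junctions, sorted ascending
    junctions = sorted(transcript_map.junctions)
    junction_hits = [0] * len(junctions)
    for a in sets.set2:
        if a.ref_id != model.gene_id:
            continue
        if a.offset < 0 or a.offset + read_len > transcript_map.length:
            raise ValueError(
                f"set-2 alignment of {a.read_id!r} projects outside model "
                f"{model.gene_id!r}"
            )
        for t in range(a.offset, a.offset + read_len):
            border_align[transcript_map.to_scaffold(t) - start] += 1
        for j, c in enumerate(junctions):
            if a.offset <= c - min_overhang and a.offset + read_len >= c + min_overhang:
                junction_hits[j] += 1

    # ascending transcript coordinate == transcript order for both strands
    support = junction_hits
    return CoverageProfile(
        gene_id=model.gene_id,
        start=start,
        genome_align=genome_align,
        border_align=border_align,
        junction_support=support,
        min_overhang=min_overhang,
    )


@dataclass(frozen=True)
class ExpressionSummary:
    gene_id: str
    aligned_read_count: int
    rpk: float
    mean_depth: float


def compute_expression(
    model: GeneModel, sets: AlignmentSets, read_len: int
) -> ExpressionSummary:
    """Reads-per-kilobase of transcript and the implied mean depth.

    With fixed-length reads, mean depth = RPK x read_len / 1000, e.g.
    500 RPK with 46-nt reads is a mean depth of 23.
    """
    if read_len <= 0:
        raise ValueError("read_len must be positive")
    tlen = model.transcript_length
    if tlen <= 0:
        raise ValueError(f"gene {model.gene_id!r}: zero-length transcript")
    count = sum(1 for a in sets.set3 if a.ref_id == model.gene_id)
    rpk = count / (tlen / 1000.0)
    return ExpressionSummary(
        gene_id=model.gene_id,
        aligned_read_count=count,
        rpk=rpk,
        mean_depth=rpk * read_len / 1000.0,
    )


def read_sam_alignments(path: str) -> list[ReadAlignment]:
    """Import mapped, ungapped records from SAM as an alternative front end.

    Lets a production mapper substitute for :func:`align_ungapped` at
    scale.  Records with indels or clipping in their CIGAR are rejected.
    """
    import pysam

    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if any(op != 0 for op, _n in (rec.cigartuples or [])):
                raise ValueError(
                    f"{path}: read {rec.query_name!r} has a gapped/clipped "
                    "CIGAR; only ungapped records can be imported"
                )
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            out.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    ref_id=rec.reference_name,
                    offset=rec.reference_start,
                    orientation="-" if rec.is_reverse else "+",
                    mismatches=int(nm),
                )
            )
    return out
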