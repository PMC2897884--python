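"""Flagged-Deviations-from-Model (FDM) sequences.

An FDM is the gene model's transcript as it is actually expressed: the
model is walked in transcript order and every position whose combined
per-base support (GenomeAlign + BorderAlign) falls below the expression
threshold is replaced by an 'X' error flag, and every predicted intron
without enough junction-spanning reads gets an 'X' inserted at the
junction.  Post-processing merges adjacent flags, absorbs expressed
islands too short to host probes (< 36 bp, i.e. two 18-mers), and strips
terminal flags into 'E' markers that later drive terminus extension.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, replace

from .io_formats import FormatError, GeneModel, SequenceRecord
from .read_alignment import CoverageProfile, TranscriptMap

DEFAULT_THRESHOLD = 2
DEFAULT_MIN_SEGMENT = 36  # two 18-mer probes

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Segment:
    """One FDM segment: expressed sequence or an internal error flag.

    ``scaffold_start``/``scaffold_end`` anchor the segment on the scaffold
    (0-based half-open envelope; zero-width for a junction flag).
    """

    kind: str  # 'seq' or 'X'
    text: str  # expressed bases for 'seq', '' for 'X'
    scaffold_start: int
    scaffold_end: int

    def __len__(self) -> int:
        return len(self.text) if self.kind == "seq" else 1


@dataclass
class FDMSequence:
    gene_id: str
    segments: list[Segment] = field(default_factory=list)
    e_start: bool = False
    e_end: bool = False
    threshold_used: int = DEFAULT_THRESHOLD

    def working_sequence(self) -> str:
        """The FDM string in transcript orientation, one 'X' per flag."""
        return "".join(s.text if s.kind == "seq" else "X" for s in self.segments)

    @property
    def internal_flag_count(self) -> int:
        return sum(1 for s in self.segments if s.kind == "X")

    @property
    def expressed_length(self) -> int:
        return sum(len(s.text) for s in self.segments if s.kind == "seq")


def build_fdm(
    model: GeneModel,
    profile: CoverageProfile,
    scaffold: SequenceRecord,
    threshold: int = DEFAULT_THRESHOLD,
    transcript_map: TranscriptMap | None = None,
) -> FDMSequence:
    """Walk the model in transcript order and flag unsupported positions.

    A position is expressed when GenomeAlign + BorderAlign at its scaffold
    coordinate reaches *threshold*; a predicted intron is supported when
    at least *threshold* junction-spanning reads cross it.  For
    minus-strand genes the emitted bases are complemented so the FDM reads
    5'->3' in transcript orientation.
    """
    if model.scaffold_id != scaffold.id:
        raise FormatError(
            f"gene {model.gene_id!r} is on scaffold {model.scaffold_id!r}, "
            f"got {scaffold.id!r}"
        )
    if model.end > len(scaffold.seq):
        raise FormatError(f"gene {model.gene_id!r} extends past scaffold end")
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if profile.gene_id != model.gene_id:
        raise FormatError("coverage profile belongs to a different gene")

    tmap = transcript_map or TranscriptMap(model)
    combined = profile.genome_align + profile.border_align
    junctions = tmap.junctions  # ascending transcript coords, transcript order
    junction_at = {c: j for j, c in enumerate(junctions)}
    minus = model.strand == "-"

    segments: list[Segment] = []
    run_text: list[str] = []
    run_lo = run_hi = None

    def close_run() -> None:
        nonlocal run_text, run_lo, run_hi
        if run_text:
            segments.append(
                Segment("seq", "".join(run_text), run_lo, run_hi + 1)
            )
            run_text, run_lo, run_hi = [], None, None

    def add_flag(lo: int, hi: int) -> None:
        close_run()
        if segments and segments[-1].kind == "X":
            prev = segments.pop()
            lo, hi = min(prev.scaffold_start, lo), max(prev.scaffold_end, hi)
        segments.append(Segment("X", "", lo, hi))

    for t in range(tmap.length):
        j = junction_at.get(t)
        if j is not None and profile.junction_support[j] < threshold:
            # anchor the junction flag at the intron boundary on the scaffold
            p_here = tmap.to_scaffold(t)
            boundary = p_here + 1 if minus else p_here
            add_flag(boundary, boundary)
        p = tmap.to_scaffold(t)
        if combined[p - profile.start] >= threshold:
            base = scaffold.seq[p]
            run_text.append(base.translate(_COMPLEMENT) if minus else base)
            if run_lo is None:
                run_lo = run_hi = p
            else:
                run_lo, run_hi = min(run_lo, p), max(run_hi, p)
        else:
            add_flag(p, p + 1)
    close_run()

    return FDMSequence(
        gene_id=model.gene_id, segments=segments, threshold_used=threshold
    )


def merge_and_trim_flags(
    fdm: FDMSequence, min_segment: int = DEFAULT_MIN_SEGMENT
) -> FDMSequence:
    """Merge adjacent flags, absorb short islands, strip terminal flags.

    Expressed segments shorter than *min_segment* that sit between two
    flags cannot host an 18-mer probe on both sides and are absorbed into
    a single flag.  Flags left at either end are recorded as 'E' markers
    (the terminus is unsupported) and removed from the working sequence.
    """
    segs = list(fdm.segments)

    def merge_adjacent(segs: list[Segment]) -> list[Segment]:
        out: list[Segment] = []
        for s in segs:
            if s.kind == "X" and out and out[-1].kind == "X":
                prev = out.pop()
                out.append(
                    Segment(
                        "X",
                        "",
                        min(prev.scaffold_start, s.scaffold_start),
                        max(prev.scaffold_end, s.scaffold_end),
                    )
                )
            else:
                out.append(s)
        return out

    segs = merge_adjacent(segs)
    changed = True
    while changed:
        changed = False
        for i, s in enumerate(segs):
            if (
                s.kind == "seq"
                and len(s.text) < min_segment
                and 0 < i < len(segs) - 1
                and segs[i - 1].kind == "X"
                and segs[i + 1].kind == "X"
            ):
                segs[i] = Segment("X", "", s.scaffold_start, s.scaffold_end)
                segs = merge_adjacent(segs)
                changed = True
                break

    e_start = fdm.e_start
    e_end = fdm.e_end
    if segs and segs[0].kind == "X":
        e_start = True
        segs = segs[1:]
    if segs and segs[-1].kind == "X":
        e_end = True
        segs = segs[:-1]

    return replace(
        fdm, segments=segs, e_start=e_start, e_end=e_end
    )


def write_fdms(
    fdms: list[FDMSequence], fasta_path: str | os.PathLike, anchors_path: str | os.PathLike
) -> None:
    """Serialize FDMs as FASTA-with-X plus a sidecar anchor table."""
    from .io_formats import write_sequences

    write_sequences(
        [(f.gene_id, f.working_sequence() or "X") for f in fdms], fasta_path
    )
    with open(anchors_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "gene_id", "segment_index", "kind", "scaffold_start",
                "scaffold_end", "e_start", "e_end", "threshold",
            ]
        )
        for f in fdms:
            if not f.segments:
                w.writerow(
                    [f.gene_id, 0, "EMPTY", 0, 0, int(f.e_start),
                     int(f.e_end), f.threshold_used]
                )
            for i, s in enumerate(f.segments):
                w.writerow(
                    [
                        f.gene_id, i, s.kind, s.scaffold_start, s.scaffold_end,
                        int(f.e_start), int(f.e_end), f.threshold_used,
                    ]
                )


def read_fdms(
    fasta_path: str | os.PathLike, anchors_path: str | os.PathLike
) -> list[FDMSequence]:
    """Rebuild FDMs from the FASTA/anchor-table pair written by write_fdms."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    rows_by_gene: dict[str, list[dict]] = {}
    with open(anchors_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows_by_gene.setdefault(row["gene_id"], []).append(row)

    fdms: list[FDMSequence] = []
    for gene_id, rows in rows_by_gene.items():
        rows.sort(key=lambda r: int(r["segment_index"]))
        seq = seqs.get(gene_id, "")
        pos = 0
        segments: list[Segment] = []
        for row in rows:
            lo, hi = int(row["scaffold_start"]), int(row["scaffold_end"])
            if row["kind"] == "EMPTY":
                continue
            if row["kind"] == "X":
                if pos >= len(seq) or seq[pos] != "X":
                    raise FormatError(
                        f"{fasta_path}: FDM for {gene_id!r} does not match "
                        "its anchor table"
                    )
                segments.append(Segment("X", "", lo, hi))
                pos += 1
            else:
                nxt = seq.find("X", pos)
                end = nxt if nxt != -1 else len(seq)
                segments.append(Segment("seq", seq[pos:end], lo, hi))
                pos = end
        fdms.append(
            FDMSequence(
                gene_id=gene_id,
                segments=segments,
                e_start=bool(int(rows[0]["e_start"])),
                e_end=bool(int(rows[0]["e_end"])),
                threshold_used=int(rows[0]["threshold"]),
            )
        )
    return fdms
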