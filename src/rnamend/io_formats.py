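"""Sequence and annotation I/O under one fixed coordinate convention.

All coordinates handled in memory are 0-based half-open intervals on the
forward strand of a scaffold.  GFF3 on disk is 1-based inclusive; the shift
is applied exactly once, here, on read and on write.

Sequences are restricted to the alphabet {A, C, G, T, N}; soft-masked
(lowercase) input is uppercased on read and masking is not otherwise used.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """A predicted gene: ordered exon blocks on one scaffold strand.

    ``exons`` are 0-based half-open ``(start, end)`` intervals in scaffold
    coordinates, sorted ascending and non-overlapping regardless of strand.
    For minus-strand genes the transcript runs right-to-left across the
    blocks and is the reverse complement of their concatenation.
    """

    gene_id: str
    scaffold_id: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"gene {self.gene_id!r}: unknown strand {self.strand!r}"
            )
        if not self.exons:
            raise FormatError(f"gene {self.gene_id!r}: no exons")
        prev_end = None
        for start, end in self.exons:
            if start < 0 or start >= end:
                raise FormatError(
                    f"gene {self.gene_id!r}: bad exon interval ({start}, {end})"
                )
            if prev_end is not None and start <= prev_end:
                raise FormatError(
                    f"gene {self.gene_id!r}: exons overlap or touch at {start}"
                )
            prev_end = end
        self.exons = [(int(s), int(e)) for s, e in self.exons]

    @property
    def start(self) -> int:
        """Leftmost scaffold coordinate of the model (startBP)."""
        return self.exons[0][0]

    @property
    def end(self) -> int:
        """One past the rightmost scaffold coordinate (stopBP, half-open)."""
        return self.exons[-1][1]

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exon blocks, scaffold coordinates."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def transcript(self, scaffold: SequenceRecord) -> str:
        """Spliced transcript sequence in 5'->3' transcript orientation."""
        if self.end > len(scaffold.seq):
            raise FormatError(
                f"gene {self.gene_id!r}: exon beyond end of scaffold "
                f"{scaffold.id!r} ({self.end} > {len(scaffold.seq)})"
            )
        joined = "".join(scaffold.seq[s:e] for s, e in self.exons)
        return joined if self.strand == "+" else reverse_complement(joined)


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A, C, G, T, N}; an involution."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise FormatError(f"cannot reverse-complement characters {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def read_sequences(path: str | os.PathLike, format: str = "fasta") -> list[SequenceRecord]:
    """Read FASTA or FASTQ into :class:`SequenceRecord` objects.

    FASTQ qualities are discarded: every step downstream of alignment is
    quality-blind, and the stand-in aligner counts mismatches only.
    Lowercase (soft-masked) bases are uppercased.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), format))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for rec in parsed:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    return records


def write_sequences(
    records: Iterable[SequenceRecord], path: str | os.PathLike, *, width: int = 70
) -> None:
    """Write records as FASTA (wrapped).

    Accepts :class:`SequenceRecord` objects or plain ``(id, seq)`` pairs, so
    working sequences containing flag characters (X) can be serialized too.
    """
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, tuple):
                rec_id, seq = rec
            else:
                rec_id, seq = rec.id, rec.seq
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gene_models(
    path: str | os.PathLike,
    scaffold_lengths: dict[str, int] | None = None,
) -> list[GeneModel]:
    """Read gene/exon features from a GFF3 file.

    Exon features must carry ``Parent`` attributes resolving to a gene (or
    mRNA whose parent is a gene).  If *scaffold_lengths* is given, exons
    falling outside their scaffold raise :class:`FormatError`.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise FormatError(f"{path}: failed to parse GFF3 ({exc})") from exc

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = []
        for exon in db.children(gene, featuretype="exon", order_by="start"):
            if exon.end < exon.start:
                raise FormatError(
                    f"{path}: exon end < start for gene {gene.id!r}"
                )
            exons.append((exon.start - 1, exon.end))  # 1-based incl -> 0-based half-open
        if gene.strand not in ("+", "-"):
            raise FormatError(f"{path}: unknown strand {gene.strand!r} for {gene.id!r}")
        model = GeneModel(gene.id, gene.seqid, gene.strand, exons)
        if scaffold_lengths is not None:
            limit = scaffold_lengths.get(model.scaffold_id)
            if limit is None:
                raise FormatError(
                    f"{path}: gene {model.gene_id!r} on unknown scaffold "
                    f"{model.scaffold_id!r}"
                )
            if model.end > limit:
                raise FormatError(
                    f"{path}: gene {model.gene_id!r} extends past end of "
                    f"scaffold {model.scaffold_id!r}"
                )
        models.append(model)
    return models


def write_gene_models(models: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write models as GFF3 with gene and exon features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                "\t".join(
                    [
                        m.scaffold_id,
                        "rnamend",
                        "gene",
                        str(m.start + 1),
                        str(m.end),
                        ".",
                        m.strand,
                        ".",
                        f"ID={m.gene_id}",
                    ]
                )
                + "\n"
            )
            for k, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    "\t".join(
                        [
                            m.scaffold_id,
                            "rnamend",
                            "exon",
                            str(s + 1),
                            str(e),
                            ".",
                            m.strand,
                            ".",
                            f"ID={m.gene_id}.exon{k};Parent={m.gene_id}",
                        ]
                    )
                    + "\n"
                )


def gene_models_roundtrip(models: Sequence[GeneModel]) -> list[GeneModel]:
    """write + read through a temporary file (testing helper)."""
    with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as fh:
        tmp = fh.name
    try:
        write_gene_models(models, tmp)
        return read_gene_models(tmp)
    finally:
        os.unlink(tmp)
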