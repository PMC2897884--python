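"""End-to-end orchestration: align -> FDM -> bridge -> realign -> classify.

The stages communicate through plain on-disk artifacts (TSV/FASTA/GFF3)
so each can be run, inspected and resumed separately; ``run_pipeline``
composes the same code paths in memory and the two routes produce
byte-identical outputs.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

from .bridge import BES, ReadIndex, ResolvedFlag, assemble_bes
from . import fdm as fdm_mod
from .io_formats import (
    GeneModel,
    SequenceRecord,
    write_gene_models,
    write_sequences,
)
from .read_alignment import (
    AlignmentSets,
    ReadAlignment,
    TranscriptMap,
    align_ungapped,
    compute_expression,
    coverage_profile,
    partition_alignment_sets,
)
from .realign import CorrectedModel, ScoringScheme, recover_structure


@dataclass
class PipelineConfig:
    """All knobs of the method; defaults are the published operating point."""

    threshold: int = 2
    min_rpk: float = 500.0
    read_len: int = 46
    probe_len: int = 18
    max_mismatch: int = 2
    min_overhang: int = 6
    max_look: int = 27
    max_n: int = 6
    extension_max_n: int = 1
    min_segment: int = 36
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    min_aligned_fraction: float = 0.9
    min_identity: float = 0.95
    seed: int = 0


@dataclass
class GeneRow:
    gene_id: str
    rpk: float
    flags_found: int
    flags_bridged: int
    outcome: str
    exon_delta: int
    size_change: float
    reason: str = ""


@dataclass
class RunReport:
    rows: list[GeneRow]
    summary: dict[str, int]
    fdms: list
    bes_list: list
    corrected: list[CorrectedModel]

    def __post_init__(self) -> None:
        tally = {
            "expressed": len(self.rows),
            "validated": sum(1 for r in self.rows if r.outcome == "validated"),
            "corrected": sum(1 for r in self.rows if r.outcome == "corrected"),
            "failed": sum(1 for r in self.rows if r.outcome == "failed"),
        }
        assert tally == self.summary, "summary counts must equal column tallies"


def make_transcripts(
    models: list[GeneModel], scaffolds: dict[str, SequenceRecord]
) -> list[SequenceRecord]:
    return [
        SequenceRecord(m.gene_id, m.transcript(scaffolds[m.scaffold_id]))
        for m in models
    ]


def build_fdms(
    models: list[GeneModel],
    scaffolds: dict[str, SequenceRecord],
    sets: AlignmentSets,
    cfg: PipelineConfig,
) -> tuple[list[GeneModel], dict[str, float], list]:
    """Expression filter plus FDM construction for the expressed genes.

    Returns (expressed models, gene_id -> RPK, post-processed FDMs), all
    in gene-id order.
    """
    expressed: list[GeneModel] = []
    rpk: dict[str, float] = {}
    fdms = []
    for model in sorted(models, key=lambda m: m.gene_id):
        expr = compute_expression(model, sets, cfg.read_len)
        if expr.rpk < cfg.min_rpk:
            continue
        expressed.append(model)
        rpk[model.gene_id] = expr.rpk
        scaffold = scaffolds[model.scaffold_id]
        tmap = TranscriptMap(model)
        profile = coverage_profile(model, sets, tmap, cfg.read_len, cfg.min_overhang)
        raw = fdm_mod.build_fdm(model, profile, scaffold, cfg.threshold, tmap)
        fdms.append(fdm_mod.merge_and_trim_flags(raw, cfg.min_segment))
    return expressed, rpk, fdms


def assemble_all(fdms: list, index, cfg: PipelineConfig) -> list:
    """Bridge and extend every FDM; fully flagged genes get an empty BES."""
    out = []
    for f in fdms:
        if not f.segments:
            out.append(
                BES(gene_id=f.gene_id, sequence="", unresolved_flags=[-1])
            )
            continue
        out.append(
            assemble_bes(
                f, index, max_look=cfg.max_look, max_n=cfg.max_n,
                extension_max_n=cfg.extension_max_n,
            )
        )
    return out


def classify_genes(
    models: list[GeneModel],
    scaffolds: dict[str, SequenceRecord],
    fdms: list,
    bes_list: list,
    rpk: dict[str, float],
    cfg: PipelineConfig,
) -> RunReport:
    """Realign every BES and build the per-gene report (shared by the
    in-memory run and the staged CLI, so both emit identical artifacts)."""
    by_id = {m.gene_id: m for m in models}
    rows: list[GeneRow] = []
    corrected: list[CorrectedModel] = []
    for f, bes in zip(fdms, bes_list):
        model = by_id[f.gene_id]
        if not bes.sequence:
            cm = CorrectedModel(
                model.gene_id, model.scaffold_id, model.strand,
                list(model.exons), "failed", reason="no_expressed_sequence",
            )
        else:
            cm = recover_structure(
                bes, model, scaffolds[model.scaffold_id], cfg.scheme,
                cfg.min_aligned_fraction, cfg.min_identity,
            )
        corrected.append(cm)
        rec = cm.change_record
        rows.append(
            GeneRow(
                gene_id=model.gene_id,
                rpk=rpk[model.gene_id],
                flags_found=f.internal_flag_count,
                flags_bridged=len(bes.bridged_flags),
                outcome=cm.outcome,
                exon_delta=rec.exon_count_delta if rec else 0,
                size_change=rec.size_change_fraction if rec else 0.0,
                reason=cm.reason,
            )
        )
    summary = {
        "expressed": len(rows),
        "validated": sum(1 for r in rows if r.outcome == "validated"),
        "corrected": sum(1 for r in rows if r.outcome == "corrected"),
        "failed": sum(1 for r in rows if r.outcome == "failed"),
    }
    return RunReport(rows, summary, fdms, bes_list, corrected)


def run_pipeline(
    genome: list[SequenceRecord],
    models: list[GeneModel],
    reads: list[SequenceRecord],
    config: PipelineConfig | None = None,
) -> RunReport:
    """Run the five-stage method over every expressed gene model."""
    cfg = config or PipelineConfig()
    if not models:
        raise ValueError("need at least one gene model")
    scaffolds = {s.id: s for s in genome}
    models = sorted(models, key=lambda m: m.gene_id)
    transcripts = make_transcripts(models, scaffolds)
    genome_alns = align_ungapped(reads, genome, cfg.max_mismatch) if reads else []
    model_alns = align_ungapped(reads, transcripts, cfg.max_mismatch) if reads else []
    sets = partition_alignment_sets(genome_alns, model_alns)
    expressed, rpk, fdms = build_fdms(models, scaffolds, sets, cfg)
    index = ReadIndex(reads, cfg.probe_len) if reads else None
    bes_list = assemble_all(fdms, index, cfg)
    return classify_genes(expressed, scaffolds, fdms, bes_list, rpk, cfg)


# ---------------------------------------------------------------------------
# on-disk artifacts

def write_alignments(alns: list[ReadAlignment], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["read_id", "ref_id", "offset", "orientation", "mismatches"])
        for a in alns:
            w.writerow([a.read_id, a.ref_id, a.offset, a.orientation, a.mismatches])


def read_alignments(path) -> list[ReadAlignment]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                ReadAlignment(row["read_id"], row["ref_id"], int(row["offset"]),
                              row["orientation"], int(row["mismatches"]))
            )
    return out


def write_expression(rpk: dict[str, float], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "rpk"])
        for gene_id in sorted(rpk):
            w.writerow([gene_id, f"{rpk[gene_id]:.4f}"])


def read_expression(path) -> dict[str, float]:
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["gene_id"]] = float(row["rpk"])
    return out


def write_bes(bes_list, fasta_path, report_path) -> None:
    write_sequences(
        [(b.gene_id, b.sequence or "N") for b in bes_list], fasta_path
    )
    with open(report_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["gene_id", "n_bridged", "n_unresolved", "offsets_used",
             "upstream_extension", "downstream_extension"]
        )
        for b in bes_list:
            w.writerow(
                [
                    b.gene_id,
                    len(b.bridged_flags),
                    len(b.unresolved_flags),
                    ",".join(str(r.offset_used) for r in b.bridged_flags) or "-",
                    b.upstream_extension_len,
                    b.downstream_extension_len,
                ]
            )


def read_bes(fasta_path, report_path) -> list:
    from Bio import SeqIO

    seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    out = []
    with open(report_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            n_bridged = int(row["n_bridged"])
            offsets = (
                [int(x) for x in row["offsets_used"].split(",")]
                if row["offsets_used"] != "-"
                else []
            )
            seq = seqs[row["gene_id"]]
            out.append(
                BES(
                    gene_id=row["gene_id"],
                    sequence="" if seq == "N" else seq,
                    bridged_flags=[
                        ResolvedFlag(
                            -1, offsets[k] if k < len(offsets) else 0, ""
                        )
                        for k in range(n_bridged)
                    ],
                    unresolved_flags=[-1] * int(row["n_unresolved"]),
                    upstream_extension_len=int(row["upstream_extension"]),
                    downstream_extension_len=int(row["downstream_extension"]),
                )
            )
    return out


def write_report(report: RunReport, path) -> None:
    with open(path, "w", newline="") as fh:
        for key in ("expressed", "validated", "corrected", "failed"):
            fh.write(f"# {key}\t{report.summary[key]}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["gene_id", "rpk", "flags_found", "flags_bridged", "outcome",
             "exon_delta", "size_change", "reason"]
        )
        for r in report.rows:
            w.writerow(
                [r.gene_id, f"{r.rpk:.4f}", r.flags_found, r.flags_bridged,
                 r.outcome, r.exon_delta, f"{r.size_change:.6f}", r.reason or "-"]
            )


def write_outputs(report: RunReport, outdir) -> None:
    """corrected.gff3, bes.fa, fdm.fa(+anchors), report.tsv under *outdir*."""
    os.makedirs(outdir, exist_ok=True)
    ok = [c.to_gene_model() for c in report.corrected if c.outcome != "failed"]
    write_gene_models(ok, os.path.join(outdir, "corrected.gff3"))
    write_bes(
        report.bes_list,
        os.path.join(outdir, "bes.fa"),
        os.path.join(outdir, "bes_report.tsv"),
    )
    fdm_mod.write_fdms(
        report.fdms,
        os.path.join(outdir, "fdm.fa"),
        os.path.join(outdir, "fdm_anchors.tsv"),
    )
    write_report(report, os.path.join(outdir, "report.tsv"))
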