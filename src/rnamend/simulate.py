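"""Ground-truth fixture generation: genomes, gene models, corruption, reads.

The generator produces a fully known world: random scaffolds carrying
non-overlapping multi-exon genes, a *true* model per gene, a *predicted*
(possibly deliberately corrupted) model per gene, and reads simulated
from the TRUE spliced transcripts.  The pipeline then sees the corrupted
predictions plus the reads, and its output can be compared with the
truth exon-by-exon.

Two properties of real data are intentionally absent and documented in
the methods note: coverage bias (tiling is uniform) and splice-placement
ambiguity (intron boundary bases are generated so that no score-tied
one-base shift of a junction exists, making exact recovery well-posed).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GeneModel, SequenceRecord, reverse_complement

BASES = "ACGT"

DEFAULT_CORRUPTION_RATES = {
    "splice_shift": 0.25,
    "spurious_intron": 0.25,
    "missing_exon": 0.25,
    "truncated_terminus": 0.05,
    "extended_terminus": 0.20,
}


@dataclass
class FixtureConfig:
    """Study conditions for the synthetic fixture.

    Defaults mirror the real-data regime the method was built for:
    46-nt reads, a mean depth of 23 (the 500-RPK operating point), genes
    averaging 5.4 exons of ~210 bp, introns 50-200 bp.
    """

    seed: int = 0
    n_scaffolds: int = 2
    scaffold_len: int = 25000
    n_genes: int = 20
    exon_count_mean: float = 5.4
    exon_len_range: tuple[int, int] = (60, 360)
    intron_len_range: tuple[int, int] = (50, 200)
    corruption_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CORRUPTION_RATES)
    )
    read_len: int = 46
    depth: float = 23.0
    read_error_rate: float = 0.0
    tiling: str = "step1"  # or "random"
    gene_spacing: int = 300

    def __post_init__(self) -> None:
        for k, v in self.corruption_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"corruption rate {k}={v} outside [0, 1]")
        if sum(self.corruption_rates.values()) > 1.0 + 1e-9:
            raise ValueError("corruption rates must sum to <= 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.read_len < 36:
            raise ValueError("read_len must be >= twice the probe length")
        if self.tiling not in ("step1", "random"):
            raise ValueError(f"unknown tiling mode {self.tiling!r}")


@dataclass(frozen=True)
class CorruptionRecord:
    gene_id: str
    kind: str
    details: str  # JSON blob describing exactly what was changed


@dataclass
class TruthSet:
    genome: list[SequenceRecord]
    true_models: list[GeneModel]
    corrupted_models: list[GeneModel]
    ledger: list[CorruptionRecord]
    config: FixtureConfig

    def scaffold(self, scaffold_id: str) -> SequenceRecord:
        for s in self.genome:
            if s.id == scaffold_id:
                return s
        raise KeyError(scaffold_id)


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return [BASES[b] for b in rng.integers(0, 4, size=n)]


def _other_base(rng: np.random.Generator, *exclude: str) -> str:
    choices = [b for b in BASES if b not in exclude]
    return choices[rng.integers(0, len(choices))]


def _disambiguate_junctions(
    seq: list[str], exons: list[tuple[int, int]], rng: np.random.Generator
) -> None:
    """Remove one-base splice-slide ambiguity at every intron.

    An intron [s, e) admits a score-tied right shift iff seq[s] == seq[e]
    and a left shift iff seq[s-1] == seq[e-1].  Mutating the intron's
    terminal bases (never exon bases) breaks both.
    """
    for i in range(len(exons) - 1):
        s, e = exons[i][1], exons[i + 1][0]  # intron, half-open
        if seq[s] == seq[e]:
            seq[s] = _other_base(rng, seq[e])
        if seq[e - 1] == seq[s - 1]:
            # keep the first-base fix intact for 1-bp introns
            seq[e - 1] = (
                _other_base(rng, seq[s - 1])
                if e - 1 != s
                else _other_base(rng, seq[s - 1], seq[e])
            )


def _sample_structure(
    cfg: FixtureConfig, rng: np.random.Generator
) -> list[int]:
    """Exon and intron lengths for one gene: [e0, i0, e1, i1, ..., ek]."""
    n_exons = 2 + int(rng.poisson(max(cfg.exon_count_mean - 2.0, 0.0)))
    lens: list[int] = []
    for k in range(n_exons):
        lens.append(int(rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1)))
        if k < n_exons - 1:
            lens.append(
                int(rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1))
            )
    return lens


def generate_truth_set(config: FixtureConfig) -> TruthSet:
    """Deterministically generate genome, true models and corrupted models."""
    rng = np.random.default_rng(config.seed)
    scaffolds = [
        _random_seq(rng, config.scaffold_len) for _ in range(config.n_scaffolds)
    ]

    # place genes round-robin across scaffolds, left to right
    cursors = [config.gene_spacing] * config.n_scaffolds
    true_models: list[GeneModel] = []
    for g in range(config.n_genes):
        placed = False
        for attempt in range(config.n_scaffolds):
            sc = (g + attempt) % config.n_scaffolds
            lens = _sample_structure(config, rng)
            span = sum(lens)
            if cursors[sc] + span + config.gene_spacing > config.scaffold_len:
                continue
            start = cursors[sc]
            exons = []
            pos = start
            for k, L in enumerate(lens):
                if k % 2 == 0:
                    exons.append((pos, pos + L))
                pos += L
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            _disambiguate_junctions(scaffolds[sc], exons, rng)
            true_models.append(
                GeneModel(f"gene{g:03d}", f"scaffold{sc}", strand, exons)
            )
            cursors[sc] = pos + config.gene_spacing
            placed = True
            break
        if not placed:
            raise ValueError(
                "genes cannot fit on the configured scaffolds; increase "
                "scaffold_len or reduce n_genes"
            )

    genome = [
        SequenceRecord(f"scaffold{i}", "".join(s)) for i, s in enumerate(scaffolds)
    ]

    # exact corruption counts by construction: round(rate * n) genes per type
    counts = {
        kind: int(round(rate * config.n_genes))
        for kind, rate in config.corruption_rates.items()
        if rate > 0
    }
    order = rng.permutation(config.n_genes)
    assignment: dict[int, str] = {}
    cursor = 0
    for kind in sorted(counts):
        for _ in range(counts[kind]):
            if cursor < config.n_genes:
                assignment[int(order[cursor])] = kind
                cursor += 1

    corrupted: list[GeneModel] = []
    ledger: list[CorruptionRecord] = []
    for gi, model in enumerate(true_models):
        kind = assignment.get(gi)
        if kind is None:
            corrupted.append(
                GeneModel(model.gene_id, model.scaffold_id, model.strand,
                          list(model.exons))
            )
            continue
        new_exons, applied_kind, details = _corrupt(model, kind, config, rng)
        corrupted.append(
            GeneModel(model.gene_id, model.scaffold_id, model.strand, new_exons)
        )
        ledger.append(
            CorruptionRecord(model.gene_id, applied_kind, json.dumps(details))
        )

    return TruthSet(genome, true_models, corrupted, ledger, config)


def _corrupt(
    model: GeneModel, kind: str, cfg: FixtureConfig, rng: np.random.Generator
) -> tuple[list[tuple[int, int]], str, dict]:
    """Returns (new exons, kind actually applied, detail record); genes whose
    structure cannot host the requested corruption fall back to a simpler one."""
    exons = [list(e) for e in model.exons]
    if kind == "splice_shift":
        # move one intron boundary 3-6 bp into the exon or the intron
        j = int(rng.integers(0, len(exons) - 1))  # intron index
        d = int(rng.integers(3, 7))
        into_intron = bool(rng.integers(0, 2))
        side = int(rng.integers(0, 2))  # 0: left boundary (exon j end)
        if side == 0:
            exons[j][1] += d if into_intron else -d
        else:
            exons[j + 1][0] += -d if into_intron else d
        detail = {"intron": j, "delta": d, "side": side, "into_intron": into_intron}
    elif kind == "spurious_intron":
        # split the longest exon with a fake intron
        k = max(range(len(exons)), key=lambda i: exons[i][1] - exons[i][0])
        s, e = exons[k]
        f_hi = min(80, (e - s) - 41)
        if f_hi < 10:
            return _corrupt(model, "splice_shift", cfg, rng)
        f = int(rng.integers(min(40, f_hi), f_hi + 1))
        cut = int(rng.integers(s + 20, e - 20 - f))
        exons[k : k + 1] = [[s, cut], [cut + f, e]]
        detail = {"exon": k, "intron_len": f, "at": cut}
    elif kind == "missing_exon":
        k = int(rng.integers(1, len(exons) - 1)) if len(exons) > 2 else None
        if k is None:
            # two-exon gene: fall back to dropping nothing structural is
            # impossible, so split-free genes get a spurious intron instead
            return _corrupt(model, "spurious_intron", cfg, rng)
        dropped = exons.pop(k)
        detail = {"exon": k, "interval": dropped}
    elif kind == "truncated_terminus":
        # clip a terminal exon: small boundary error, under half a read
        d = int(rng.integers(8, 19))
        if rng.integers(0, 2) == 0:
            exons[0][0] += d
            detail = {"end": "left", "clip": d}
        else:
            exons[-1][1] -= d
            detail = {"end": "right", "clip": d}
    elif kind == "extended_terminus":
        d = int(rng.integers(20, 61))
        if rng.integers(0, 2) == 0:
            exons[0][0] = max(0, exons[0][0] - d)
            detail = {"end": "left", "extend": d}
        else:
            exons[-1][1] += d
            detail = {"end": "right", "extend": d}
    else:
        raise ValueError(f"unknown corruption kind {kind!r}")
    return [tuple(e) for e in exons], kind, detail


def simulate_reads(
    truth: TruthSet, config: FixtureConfig | None = None
) -> list[SequenceRecord]:
    """Simulate fixed-length reads from the TRUE spliced transcripts.

    step1 tiling emits every transcript window at step 1; one pass gives
    exact uniform interior coverage equal to the read length, so the
    number of passes is the smallest whole number whose coverage reaches
    the requested depth.  Random mode draws depth x L / read_len start
    positions per transcript in both orientations.
    """
    cfg = config or truth.config
    rng = np.random.default_rng(cfg.seed + 1)
    L = cfg.read_len
    reads: list[SequenceRecord] = []
    for model in truth.true_models:
        scaffold = truth.scaffold(model.scaffold_id)
        tx = model.transcript(scaffold)
        if len(tx) < L:
            warnings.warn(
                f"transcript of {model.gene_id!r} shorter than read length; skipped"
            )
            continue
        if cfg.tiling == "step1":
            passes = max(1, math.ceil(cfg.depth / L))
            for p in range(passes):
                for off in range(len(tx) - L + 1):
                    seq = tx[off : off + L]
                    reads.append(
                        SequenceRecord(f"{model.gene_id}:p{p}:o{off}", seq)
                    )
        else:
            n = int(round(cfg.depth * len(tx) / L))
            offsets = rng.integers(0, len(tx) - L + 1, size=n)
            flips = rng.integers(0, 2, size=n)
            for k, (off, flip) in enumerate(zip(offsets, flips)):
                seq = tx[off : off + L]
                if flip:
                    seq = reverse_complement(seq)
                reads.append(SequenceRecord(f"{model.gene_id}:r{k}", seq))
    if cfg.read_error_rate > 0:
        reads = [_add_errors(r, cfg.read_error_rate, rng) for r in reads]
    return reads


def _add_errors(
    read: SequenceRecord, rate: float, rng: np.random.Generator
) -> SequenceRecord:
    seq = list(read.seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        if seq[i] in BASES:
            seq[i] = _other_base(rng, seq[i])
    return SequenceRecord(read.id, "".join(seq))


def middle_exon_series_truth(
    middle_lengths: list[int],
    flank_exon: int = 200,
    intron_len: int = 80,
    spacing: int = 400,
    seed: int = 0,
    read_len: int = 46,
    depth: float = 23.0,
) -> TruthSet:
    """Three-exon genes whose middle exon is omitted from the prediction.

    One gene per requested middle-exon length, all on one scaffold: true
    structure flank / intron / middle / intron / flank; the predicted
    model merges the two introns over the middle exon.  Used to measure
    the shortest internal exon the bridge-and-realign procedure can
    restore.
    """
    rng = np.random.default_rng(seed)
    total = spacing
    for L in middle_lengths:
        total += 2 * flank_exon + 2 * intron_len + L + spacing
    seq = _random_seq(rng, total)

    true_models: list[GeneModel] = []
    corrupted: list[GeneModel] = []
    ledger: list[CorruptionRecord] = []
    pos = spacing
    for gi, L in enumerate(middle_lengths):
        e1 = (pos, pos + flank_exon)
        m = (e1[1] + intron_len, e1[1] + intron_len + L)
        e3 = (m[1] + intron_len, m[1] + intron_len + flank_exon)
        exons = [e1, m, e3]
        _disambiguate_junctions(seq, exons, rng)
        gene_id = f"series{gi:02d}_L{L}"
        true_models.append(GeneModel(gene_id, "scaffold0", "+", exons))
        corrupted.append(GeneModel(gene_id, "scaffold0", "+", [e1, e3]))
        ledger.append(
            CorruptionRecord(gene_id, "missing_exon", json.dumps({"len": L}))
        )
        pos = e3[1] + spacing

    cfg = FixtureConfig(
        seed=seed,
        n_scaffolds=1,
        scaffold_len=total,
        n_genes=len(middle_lengths),
        corruption_rates={},
        read_len=read_len,
        depth=depth,
    )
    genome = [SequenceRecord("scaffold0", "".join(seq))]
    return TruthSet(genome, true_models, corrupted, ledger, cfg)


def write_fastq(reads: list[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_truth_set(truth: TruthSet, outdir) -> None:
    """Write genome.fa, true.gff3, predicted.gff3 and ledger.tsv."""
    import os

    from .io_formats import write_gene_models, write_sequences

    os.makedirs(outdir, exist_ok=True)
    write_sequences(truth.genome, os.path.join(outdir, "genome.fa"))
    write_gene_models(truth.true_models, os.path.join(outdir, "true.gff3"))
    write_gene_models(truth.corrupted_models, os.path.join(outdir, "predicted.gff3"))
    with open(os.path.join(outdir, "ledger.tsv"), "w") as fh:
        fh.write("gene_id\tkind\tdetails\n")
        for rec in truth.ledger:
            fh.write(f"{rec.gene_id}\t{rec.kind}\t{rec.details}\n")
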