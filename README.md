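# rnamend

Validation and correction of predicted gene models against RNA-seq
evidence.

Structural annotation of gene-dense eukaryotic genomes — fungi
especially, with their high intron density and exons sometimes shorter
than 10 codons — is error-prone: predicted exon/intron boundaries
frequently disagree with what is actually transcribed. `rnamend`
implements a transcript-evidence pipeline that takes a genome (FASTA),
predicted gene models (GFF3) and short fixed-length RNA-seq reads, and
for every sufficiently expressed model decides whether the prediction is
**validated** by the reads, can be **corrected** from them, or **fails**.
It is aimed at annotation engineers and comparative genomicists who need
per-gene, inspectable corrections rather than a full reannotation run.

## Method

Five stages, each exposed as a library function and a CLI subcommand:

1. **Align** (`align`). Reads are aligned ungapped, in both orientations,
   with at most 2 mismatches, to the genome (Set 1) and to the spliced
   model transcripts (Set 3). Reads hitting a transcript but nowhere on
   the genome (Set 2) are junction-spanning evidence. Expression is
   summarised as RPK (reads per kilobase of transcript); with 46-nt
   reads, mean depth = RPK × 46/1000, so the default filter RPK ≥ 500
   corresponds to depth ≈ 23.
2. **Flag deviations** (`fdm`). Each model is walked in transcript order;
   a position with combined per-base support `GenomeAlign[i] +
   BorderAlign[i] < 2` is replaced by an `X` flag, and a predicted intron
   with fewer than 2 junction-spanning reads gets an `X` at the junction.
   Adjacent flags merge, expressed islands under 36 bp between flags are
   absorbed, and flags at the termini become `E` markers. The result is
   the FDM (flagged deviations from the model) sequence.
3. **Bridge** (`bridge`). For each internal flag, exact 18-mer probes are
   taken 6 bp up- and downstream of the flag (retrying at 15 and 21 bp).
   A consensus contig is grown probe-by-probe through the read set —
   strict per-position majority, `N` on ties — until the downstream probe
   appears (≤ 27 iterations, ≤ 6 `N`s). Termini are extended the same way
   with no end probe and an `N` budget of 1. The output is the BES
   (bridged and extended sequence).
4. **Realign** (`realign`). The BES is aligned back to its scaffold
   window (model span plus 3× each extension, after trimming 5% off each
   extension's outer end) with a modified Smith–Waterman: match +8,
   mismatch −12, anything against `N` +4, gaps in the scaffold −24/base,
   gaps in the BES (introns) −1/base, gaps flanking the BES free, and no
   aligned BES block shorter than 4 nt. If the alignment is rejected
   (< 90% of non-N BES bases aligned or identity < 95%) the reverse
   complement is tried. Exon blocks are read off the traceback and
   written as GFF3. No splice-site dinucleotide signal is used.
5. **Classify**. A model is *corrected* when at least one flag was
   bridged, the exon count changed, or the expressed length moved by more
   than 10%; otherwise *validated*; *failed* if flags could not be
   bridged or nothing aligned.

A cumulative-binomial annotation-enrichment statistic
(p = 1 − B(x; n, p), reported for annotations with p < 0.001 and ≥ 10
carriers) is included for characterising a selected gene set (`enrich`).

Because real annotation truth is unknowable at test time, the package
ships a first-class synthetic-fixture generator (`rnamend.simulate`): a
random genome with multi-exon genes, predictions corrupted in five
controlled ways (shifted splice sites, spurious introns, missing exons,
truncated and extended termini), and error-free or noisy 46-nt reads
tiled from the *true* transcripts. The pipeline sees only the corrupted
predictions; its output is compared exon-by-exon with the hidden truth.

## Worked example

```sh
python examples/correct_gene_models.py
```

simulates 10 genes (8 corrupted), 8 552 reads, and prints:

```
gene      corruption          outcome    flags bridged exact
gene000   missing_exon        corrected      1       1   yes
gene001   -                   validated      0       0   yes
gene002   splice_shift        corrected      1       1   yes
...
summary: {'expressed': 10, 'validated': 4, 'corrected': 6, 'failed': 0}

gene000 (missing_exon):
  predicted: [(300, 482), (665, 760), (1118, 1364)]
  corrected: [(300, 482), (665, 760), (897, 1061), (1118, 1364)]
  truth:     [(300, 482), (665, 760), (897, 1061), (1118, 1364)]
```

Each row is one expressed gene: how many deviation flags were found, how
many were bridged from the reads, the outcome class, and whether the
corrected exon blocks equal the hidden truth. For `gene000` the exon at
897–1061, absent from the prediction, was reassembled from reads and
placed back on the scaffold exactly. `examples/short_exon_recovery.py`
runs a middle-exon length series (restored exactly down to 5 bp with
seed 1), and `examples/annotation_enrichment.py` shows the enrichment
statistic.

The same run from the shell:

```sh
rnamend simulate --out fix --seed 42 --n-genes 10
rnamend run --genome fix/genome.fa --models fix/predicted.gff3 \
            --reads fix/reads.fastq --out results/
```

writes `corrected.gff3`, `bes.fa`, `fdm.fa` and `report.tsv`. Stages can
also be run separately (`align`, `fdm`, `bridge`, `realign`) through a
shared working directory and produce byte-identical artifacts.

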