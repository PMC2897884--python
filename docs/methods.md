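# Methods

This note documents the model behind `rnamend`, the parameters that
matter, the numerical choices, what the synthetic fixtures do and do not
emulate, and the known limitations. Everything quantitative stated here
is computed by the test suite or `scripts/acceptance.py`.

## The evidence model

The pipeline treats RNA-seq reads as votes on a predicted gene model.
Three alignment sets carry all the evidence:

* **Set 1** — reads aligned ungapped to the genome. They support exonic
  bases (`GenomeAlign[i]`, a per-scaffold-position count).
* **Set 3** — reads aligned ungapped to the spliced model transcripts.
  Their count per model, normalised to reads per kilobase of transcript
  (RPK), is the expression filter. With fixed-length reads, mean depth
  = RPK × read_len/1000; at the defaults (46 nt, RPK ≥ 500) a gene
  enters the pipeline at mean depth ≥ 23.
* **Set 2** — reads in Set 3 with *no* genome alignment at all. Only a
  read spanning a splice junction behaves this way, so Set 2 is the
  junction evidence: projected through the exon map it yields
  `BorderAlign[i]`, and counted per predicted intron it yields junction
  support.

The aligner itself is whole-read Hamming matching (both orientations,
all placements kept, default ≤ 2 mismatches), implemented exactly via
pigeonhole seeding and verified in the tests against a sliding-window
scan. It is deliberately quality-blind: every downstream decision
consumes counts, not alignment details, so a production mapper can be
substituted through the SAM import without changing semantics.

## Flagging (FDM)

A model position is *expressed* when `GenomeAlign + BorderAlign >=
threshold` (default 2) at its scaffold coordinate; a predicted intron is
*supported* when at least `threshold` Set-2 reads cross its junction
with at least `min_overhang` bases on each side. Unexpressed positions
become `X` flags; unsupported junctions get an `X` inserted between the
flanking exonic positions, so a spurious intron whose flanks are well
covered is still caught. Adjacent flags merge; expressed islands
shorter than 36 bp (= two probe lengths, so an island can host one
upstream and one downstream probe) between flags are absorbed; terminal
flags are recorded as `E` markers and removed.

**min_overhang = 6, not a smaller value.** Junction support must be
discriminative against reads that cross the *wrong* junction. Under
ungapped alignment with a mismatch budget of 2 over a 4-letter alphabet,
a read whose overhang of o bases is the wrong sequence still aligns with
probability P[Binom(o, 3/4) ≤ 2] — about 0.58 at o = 3, 0.26 at o = 4,
under 0.04 at o = 6. Summed over all crossing offsets this puts ~2
expected chance "supporters" per wrong junction per tiling pass at an
overhang floor of 3 — exactly the expression threshold — whereas a floor
of 6 drops the expectation to ~0.1. Six is therefore the smallest
overhang at which junction support measures splicing rather than the
mismatch budget.

## Bridging and extension

Flags are repaired without ever aligning reads: an exact 18-mer probe
upstream of the flag seeds a consensus walk. All reads containing the
probe (either orientation) vote on the following bases; a base is called
only on a strict majority (> 50% of votes), `N` otherwise — ties and
coverage holes degrade to `N` rather than to an arbitrary call, which is
also what makes a 60/40 mixture of transcript variants resolve to the
majority variant. The walk appends 18-base chunks until the downstream
probe appears as an exact substring (success), or the iteration cap
(27) or the `N` budget (6) is exhausted. Probe pairs are tried 6, 15,
then 21 bp away from the flag, so a read error corrupting one probe site
does not kill the repair; a failure at all three offsets leaves the flag
unresolved and the gene is later classified failed. The bridge spans
from the start probe through the end probe, so the probe margins are
replaced by bridge-derived consensus; where two bridges overlap on a
short (≥ 36 bp) island the overlap is emitted once. Termini are
extended with the same walk, seeded by the FDM's terminal 18-mers, with
no end probe and an `N` budget of 1; the trailing `N` run is stripped.
The longest bridgeable flag region is therefore 26 × 18 = 468 bp
(27 chunks minus the one that must contain the end probe).

## Realignment

The repaired transcript (BES) is aligned to a scaffold window — the
model span widened by three times each terminus extension, after
trimming floor(0.05 × extension) bases from each extension's outer end —
under an asymmetric scheme: match +8, mismatch −12, any column with `N`
+4, gap in the scaffold −24/base, gap in the BES −1/base (introns are
expected; scaffold deletions are not), gaps flanking the BES free
(semi-global in the BES). Aligned BES islands shorter than 4 nt are
excluded *inside* the optimisation by a run-length DP state (runs
counted 0, 1, 2, 3, ≥4; a run may end only at ≥4), so the returned
score is optimal under the constraint rather than repaired post hoc.
The implementation is a vectorised row sweep with the linear-gap prefix
trick; the tests pin it to an independent memoized search on small
pairs.

Tie-breaking: among equal-score tracebacks the aligner prefers
continuing an open gap over closing a diagonal run. This yields the
fewest introns among optima — preferring to close runs instead provably
re-opens extra introns whenever an exon suffix happens to recur inside
an intron — and, where a junction can slide at equal score, lands on the
rightmost placement. One canonical choice had to be made; fewest
introns was judged the structurally meaningful criterion, and the
choice is deterministic, which the byte-identity tests rely on.

Acceptance of an alignment requires ≥ 90% of non-N BES bases aligned
and ≥ 95% identity over informative columns (both configurable); a
rejected alignment triggers one retry with the reverse complement, which
is how minus-strand genes are recovered. Splice-site dinucleotides are
never consulted; junction placement comes from the alignment alone.

## Enrichment statistic

For an annotation carried by background fraction p, observing x carriers
among n selected genes is scored as 1 − B(x; n, p) with B the cumulative
binomial — the probability of *more* than x carriers, which excludes the
observed count and is one notch more conservative than the conventional
upper tail (`inclusive=True` gives P(X ≥ x)). Annotations are reported
below p = 0.001 with at least 10 carriers; no multiple-testing
correction is applied. The CDF is delegated to scipy; the tests check
it against direct summation for n ≤ 25 and the closed forms B(n;n,p)=1,
B(0;n,p)=(1−p)^n.

## Synthetic fixtures: what they emulate, and what they do not

The generator produces scaffolds of i.i.d. random sequence carrying
non-overlapping genes on both strands: exon count 2 + Poisson(3.4)
(mean 5.4), exon lengths uniform 60–360 bp (mean 210), introns uniform
50–200 bp — the gene-architecture regime of an intron-dense fungal
genome. Reads are 46 nt, drawn from the *true* spliced transcripts;
step-1 tiling emits every window, so one pass already gives interior
coverage 46, and the number of passes is the smallest whole number whose
coverage reaches the requested depth (depth 23 → one pass). Random mode
draws depth × L/46 starts in both orientations, optionally with
substitution errors.

Five corruption modes turn true models into predictions: a splice
boundary shifted 3–6 bp, a 40–80 bp spurious intron splitting an exon, a
dropped internal exon, a terminal exon clipped by 8–18 bp (small
boundary errors, under half a read — larger terminal losses are
exercised separately by the missing-exon mode and the short-exon
series), and a terminus extended 20–60 bp into unexpressed sequence.
Default rates (0.25/0.25/0.25/0.05/0.20) are applied as exact gene
counts, at most one corruption per gene, with a per-gene ledger.

Two properties of real data are deliberately absent, and bound what
passing tests show:

* **No coverage bias.** Tiling is uniform; real libraries have GC and
  positional bias, so real coverage dips will produce flags the
  threshold rule cannot distinguish from annotation errors. The method
  inherits this limitation by design (it is a hard threshold, not a
  coverage model).
* **No splice-slide ambiguity.** Intron terminal bases are generated so
  that no one-base shift of a junction is score-tied (first intron base
  ≠ first base of the next exon; last intron base ≠ last base of the
  previous exon). In real genomes roughly 7/16 of introns admit a tied
  ±1 shift that *no* splice-signal-blind aligner can resolve; exact
  recovery there is a coin flip by construction. The fixtures remove
  the coin flip so that "restored exactly" measures the method, not the
  tie; on real data the corresponding boundary calls carry a ±1–2 bp
  ambiguity.

## Problem sizes

The default study fixture is 20 genes on two 25-kb scaffolds at depth
23 (~25 000 reads); the short-exon series is 28 three-exon genes on one
scaffold. These sizes keep the full suite and the acceptance script in
the tens of seconds while exercising every code path at the published
operating point; all sizes are configuration, not constants.

## Known limitations

* One transcript per locus: mixed splice variants at a site are resolved
  to the majority variant when one exceeds 50%, and otherwise degrade to
  `N`/unresolved; variant discovery is out of scope.
* Paired-end information, base qualities and gapped read alignment are
  not modelled; the stand-in aligner is ungapped by design.
* Exons shorter than the 4-nt block floor cannot be placed, and short
  exons whose sequence recurs in the surrounding intron window may tie
  and resolve to the wrong placement (observed for 3–4 bp exons in the
  recovery series).
* The expression filter is per-model RPK; partially expressed genes
  below the filter are simply not examined.
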