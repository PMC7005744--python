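# Methods

## Read classification and counting

Mapped reads are partitioned into three classes around annotated splice
sites, with precedence exon–exon junction > exon–intron bridging >
fully intronic:

1. **exon–exon junction** — the alignment contains at least one CIGAR
   `N` gap. Each gap yields one junction (donor = 0-based reference
   coordinate where the gap opens, acceptor = where it closes);
   `M/D/=/X` consume reference, `I/S/H/P` do not. Junctions matching an
   annotated intron inherit its strand; others are retained as novel
   with undetermined strand.
2. **exon–intron bridging** — an unspliced alignment crossing an
   annotated intron boundary with at least the minimum overhang
   (default 6 nt) on both sides.
3. **fully intronic** — an unspliced alignment contained in one
   annotated intron. These feed per-intron coverage summaries:
   covered fraction (positions with depth ≥ 1) and mean per-position
   depth.

Read filters (all configurable): primary alignments only, duplicates
excluded, MAPQ ≥ 20, junction anchors ≥ 6 nt on each side of every
counted gap. Counting is **fragment-level**: a junction supported by
both mates of a pair counts once (dedup on query name per junction).
The QC partition `reads_seen = passed + filtered` and
`passed = Σ class tallies` is asserted by tests.

STAR `SJ.out.tab` tables are accepted as a drop-in counting source
(unique-mapper column by default; multimappers behind a flag; strand
code 0 resolved from annotation, else the junction is dropped).

## Event enumeration

Candidate events come from the annotation, per gene and across
isoforms:

* **cassette exon** — every internal exon with two flanking annotated
  introns; inclusion junctions are the two flanks, the skipping
  junction joins the outer splice sites, and the event is marked
  `annotated` when some isoform witnesses that skip.
* **intron retention** — one candidate per annotated intron; the
  spliced junction is the skipping evidence, bridging reads the
  inclusion evidence.
* **alternative 5′/3′ splice site** — each adjacent pair of junctions
  sharing one splice site; which side varies decides the type,
  strand-aware. The longer-exon (shorter-intron) junction defines
  inclusion.

Event identifiers are pure functions of coordinates, so enumeration is
deterministic and the event list round-trips byte-identically through
its TSV interchange format. Internal coordinates are 0-based half-open
everywhere; GTF and SJ readers convert at the boundary.

## Splicing index

`SI = inclusion_reads / (inclusion_reads + skipping_reads)`, undefined
when the total is zero. Per type:

* cassette — inclusion = rounded mean of the two flanking junction
  counts (combiner configurable: mean | sum | min; mean keeps inclusion
  and skipping on the same per-junction scale), skipping = skip
  junction count. Rounding is half-to-even so Fisher tables stay
  integral.
* alt-5′/3′ss — inclusion = longer-exon junction count, skipping = the
  alternative.
* intron retention — inclusion = rounded mean of the two boundary
  bridging counts, skipping = spliced junction count; intronic
  covered fraction and mean depth ride along, and differential calls
  additionally require covered fraction ≥ 0.9 (configurable) so a
  retention call needs body coverage, not just boundary reads.

## Differential screen

Replicates within an arm are pooled by count summation (a per-replicate
mode with sign agreement is available). Each event's pooled 2×2 table
is tested with a **two-sided Fisher exact test computed in exact
integer arithmetic**: all tables with the observed margins are
enumerated, and those whose (integer) hypergeometric weight does not
exceed the observed weight contribute to p. This minimum-likelihood
two-sided convention matches mainstream exact-test implementations, but
ties are decided exactly rather than to floating-point tolerance; a
table costs ~15 µs, so exhaustive oracle sweeps are cheap. The
reported total junction reads is the **minimum over the two arms**
(each arm must carry the support; `sum` is available), and events with
an undefined SI in either pooled arm are excluded from testing and
flagged.

FDR is Benjamini–Hochberg, pooled across all tested events of a
contrast (all event types together). The screen's inequalities are
exactly as printed: total ≥ 15, |ΔSI| ≥ 0.10, FDR < 0.2, with a 1e-12
grace on the ΔSI comparison only to absorb binary-float representation
of decimal thresholds.

The bidirectional join has two modes. `strict`: every supplied KD and
OE contrast passes the screen and all KD ΔSI share one sign opposite to
all OE ΔSI. `relaxed`: at least one (KD, OE) pair is opposite-signed
with both members passing. ΔSI = 0 satisfies neither. Each call
records the satisfying pairs.

## Motif context

The positive set is the called cassette exons (relaxed mode, matching
how the motif input set is defined); the control set is a seeded,
size-matched random sample of cassette exons with |ΔSI| < 0.10 in every
overexpression contrast. Sequences are exon ± 250 nt flanks on the
sense strand (minus-strand genes reverse-complemented), written as
MEME-ready FASTA; de-novo motif discovery itself is deliberately
external.

The built-in GA-rich scanner looks for windows of width 6–9 containing
only purines with ≥ 2 G and ≥ 2 A — wide enough to capture the
GAAGGAGA / GAAAAG class of elements, narrow enough to exclude
homopolymer runs — reported as maximal windows, greedily
non-overlapping from the left, with the region (upstream flank / exon /
downstream flank) assigned from the hit's start offset. All rule
parameters are configurable, and a PWM path is the intended extension
point for users who run MEME externally.

## AS-NMD rule

Skipping an internal exon concatenates the remaining exon sequences in
transcription order; the CDS offset carries over when the start-codon
exon survives. The skip is frameshifting iff the skipped exon lies in
the CDS and its length is not a multiple of 3. Translation proceeds
from the start codon until the first stop (TAA/TAG/TGA, no
readthrough); the distance from that stop to the last exon–exon
junction decides NMD sensitivity, with the canonical 50-nt threshold
(configurable, strict inequality). A stop in the last exon gives a
non-positive distance and is never NMD-sensitive. The test suite pins
this logic to an engineered six-exon transcript whose frameshifting
exon-3 skip plants a stop at the first base of exon 5, 368 nt upstream
of the last junction.

## Clinical rules

Tumor/normal pairs: regulator-high iff the tumor/NT expression fold is
≥ 1.5 (inclusive, either regulator for the combined group); inclusion
up/down iff the PSI shift strictly exceeds 5 percentage points
(absolute PSI points, strict inequality with a 1e-9 representation
guard). RIP enrichment: %Input = 2^−ΔCt × 100 with
ΔCt = Ct_RIP − (Ct_input − dilution factor), the dilution factor in Ct
units (log2 of the input dilution). Xenograft volume:
0.5 × length × width² (mm³), with swapped axes corrected.

## Synthetic-data generator

The generator emulates the perturbation design: two regulators, each
with a knockdown arm (two shRNA-like replicates) and an overexpression
arm (one replicate) against their own controls. Defaults: 3–8 exons
per gene (60–300 nt, introns 300–900 nt), one cassette exon per gene
with an included and a skipped isoform, base PSI uniform on
[0.2, 0.8], |ΔPSI| = 0.3 for the designated shifted subset with the KD
sign drawn at random and the OE sign opposite, depth 100 fragments per
event and sample, pure binomial counts (beta-binomial overdispersion
available, default 0 — the knob exists precisely to probe how the
pooled Fisher test degrades under replicate variability).

Count model per event and sample: total ~ Poisson(depth); inclusion
fragments ~ Binomial(total, PSI). Each inclusion fragment spans the
cassette exon and evidences **both** flanking junctions, so 2 ×
inclusion junction observations are split Binomial(·, ½) between the
flanks — the mean-combined estimate then recovers the fragment count
exactly and SI is an unbiased binomial estimate of PSI. Constitutive
junctions draw Poisson(depth) support; intron-boundary bridging reads
are emitted at 5 % of depth.

The genome sequence is synthetic in a deliberately structured way:
bases are drawn in purine/pyrimidine runs capped at five, so no GA-rich
window of width ≥ 6 arises by chance on either strand, and GA-rich
elements planted 100 nt into the transcription-upstream intron flank of
a labelled 66 % of shifted events are the only motif signal. Real
flanking sequence is not run-capped — real scans face a purine-rich
background — so motif tests here demonstrate scanner correctness and
set construction, not expected real-data enrichment contrast. Other
non-goals: sequencing error, positional bias, expression-level realism,
multi-cassette genes.

SAM emission realises the tabulated counts as valid single-end 100-nt
reads (half-and-half anchors across each junction gap, MAPQ 255, unique
names, sequences copied from the genome), plus bridging and intronic
reads; re-counting an emitted SAM reproduces the junction counts
exactly, which the tests assert. Everything is deterministic in the
seed; annotation, truth and count draws use independent RNG streams so
changing one stage's parameters does not perturb another's draws.

## Problem sizes and numerical checks

The acceptance script and end-to-end tests use: a 2,000-gene screen
with 100 shifted events at depth 100 per event and arm (strict-mode
recovery, null false calls, sign concordance); 200 replicates per
(PSI, depth) cell on PSI ∈ {0.1, 0.5, 0.9} × depth ∈ {20, 200, 2000}
for estimator calibration against the central 99 % binomial interval;
an exhaustive Fisher sweep over every 2×2 table with margins ≤ 40
against a hypergeometric enumeration oracle (the oracle's tie tolerance
of 1e-9 is safe: the smallest relative gap between distinct
hypergeometric weights at these margins is ~1.2e-4); and 1,000 random
p-vectors against a quadratic-time BH reference.

## Known limitations

* Replicate-aware models (GLMs, hierarchical tests) are out of scope by
  design: the screen is a plain Fisher exact test on pooled counts, and
  with overdispersed replicates it will be anticonservative — the
  generator's overdispersion knob exists to demonstrate this.
* Event enumeration from annotation yields correlated sibling
  candidates (alternative framings sharing junctions); a shifted exon
  therefore typically produces a small cluster of calls in its gene.
  Downstream consumers who need one call per locus should collapse by
  gene or by core interval.
* The GA-rich scanner is a rule, not a learned PWM; it stands in for
  motif-discovery output, it does not reproduce it.
* Junction counts are keyed purely by coordinates (strand as an
  annotation label, summed over at lookup). Overlapping genes on
  opposite strands therefore need no assignment step — each event reads
  the counts at its own junction coordinates — but a junction whose
  coordinates coincide across two genes would be credited to both.
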