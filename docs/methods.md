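# Methods

This note documents the models and procedures implemented in `srnacascade`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the design choices made where the original analysis left the
procedure open.

## Study design assumptions

The pipeline targets a specific, historically common design: one pooled
36-base Illumina sRNA library per condition (here: transgenic TaDREB3 barley
vs non-transgenic Golden Promise control), sequenced in the same flow cell,
with no biological replicates and no genome assembly. Everything downstream
follows from those constraints: classification is against ordered reference
libraries, differential expression is a pure fold-change rule (no variance
model or multiple-testing correction is possible or attempted), and novel
miRNA discovery is homology- and hairpin-based.

## Preprocessing

Artifact removal deletes reads containing any `N` and reads that are a
single-nucleotide homopolymer over their **entire** length. The narrower
full-length reading of the "poly-A/T/C/G" rule is deliberate: removing any
read merely containing a homopolymer run would discard legitimate sRNAs and
is incompatible with the populated length rows of the published size tables.

Adapter trimming scans candidate 1-based adapter start positions; a hit needs
at least `min_match = 10` aligned adapter bases (truncated at the read end,
mismatches counted only over aligned bases) with at most `max_mismatch = 1`
substitutions; the leftmost hit wins (at a fixed position the alignment is
unique, so no further tie-break is needed). The primary pass starts at base
`search_start = 18`; reads it leaves untrimmed get a permissive secondary
pass from base 1. The two passes are logged separately. This two-pass scheme
is an inference: a start-at-18 rule alone cannot produce the 0–16 nt insert
rows that the published size tables show, while a secondary scan reproduces
them naturally, with an adapter at position 1 read as an adapter-only
(length-0) insert. Untrimmed reads appear only in the diagnostic length-36
row and never enter classification. Read-count conservation
(`raw = artifacts + untrimmed + Σ inserts`) is asserted on every run.

Unique reads are identical inserts pooled per library, ordered by descending
count then lexicographically. Size tables report unique reads and read counts
per insert length at thresholds 1, 4 and 10 (threshold included), with a
totals row equal to the column sums.

## Classification cascade

Alignment is full-read, substitution-only (no indels), consistent with the
short-read aligners of the era and exactly checkable against a brute-force
Hamming scan, which the test suite does for budgets 0–2. Minus-strand hits
are reported in plus-strand coordinates (1-based, inclusive) with strand `−`.

Stage order and budgets: chloroplast (0 mismatches, both strands, all
lengths) → species mature miRNAs (reads ≥17 nt) → isomiRs → homolog miRNAs →
ncRNA families (≤2 mismatches) → repeats (0, reads ≥20 nt, both strands) →
antisense of genes (0) → transgene set (0, both strands). Reads mapped at a
stage are removed before the next, so labels are exclusive and per-library
counts partition the input; conservation is asserted per run. Reads shorter
than 17 nt are set aside after the chloroplast stage (`length_filtered`).

Two decisions where the source procedure is open:

* **Mature counting is by exact sequence identity.** Reads that are
  truncations/extensions of a mature sequence are routed to the isomiR
  stage instead. This keeps mature and isomiR accounting disjoint; a
  substring-tolerant mature stage would silently absorb most isomiRs.
* **The isomiR stage sits immediately after the mature stage**, although the
  narrative order lists it inside the miRNA profiling step: a read is an
  isomiR of miRNA M if it aligns within M's precursor with ≤1 substitution,
  overlapping M's locus, and is not the mature itself. Two substitutions
  disqualify. Ambiguous multi-precursor isomiRs are counted for every
  matching precursor and flagged.

**Mature\*** sequences are inferred from the precursor structure assuming a
perfect 2-nt 3′ overhang on each strand of the miRNA/miRNA\* duplex: with a
pair table `pt` and mature occupying `[i, j]`, the star spans the partners of
`j−2` and `i−2`; on imperfect pairing the outermost paired mature bases
anchor the duplex and unpaired ends are extrapolated along the stem. A mature
with no paired bases, or one spanning the loop, yields no star (reported,
not silently skipped). Stars join the mature stage's lookup so previously
un-annotated star reads are detected.

**natsiRNA clustering** groups antisense-of-gene reads by perfect inclusion:
reads sorted by descending length (then lexicographically, making the greedy
pass order-invariant); each read joins the first cluster whose representative
contains it exactly, else founds one. Representatives are re-mapped to the
forward strands of the other libraries to annotate a plausible origin.

**Transgene profiling** reports exact hits per strand per gene, flags
sense/antisense interval overlaps, and emits per-position coverage as the
fraction of unique reads covering each position (the denominator is stated in
the output because read counts are dominated by few reads).

## Normalization and differential expression

The factor `F = total_A / total_B` is computed once from the non-chloroplast
totals of reads ≥17 nt and applied to every transgenic count (the published
tables are consistent with one global factor, 3575645/2585109 ≈ 1.3832).
Counts are stored at full double precision; display layers round.

For each shared read/feature, `log2(F·count_B / count_A)`; |log2| ≥ 1 is the
differential-expression rule. A zero count on either side makes the ratio
undefined and the feature group-specific — no pseudocounts, matching the
`#NUM!` convention of the published tables. Group statistics per threshold
t ∈ {1, 4, 10}: the universe is every read with count ≥ t in at least one
group; sample-specific means count ≥ t in one group and 0 in the other;
everything else present in both groups is common and enters the DE
percentage. (At t = 1 this reduces to the simple partition; at higher
thresholds it reproduces the published accounting in which common reads need
not clear the threshold in both groups.)

## Novel miRNA discovery

Unassigned reads map to primary-species contigs with ≤1 substitution;
only reads without a primary hit try related-species contigs with ≤2.
Around each locus two windows are cut (default `flank = 150` nt, one biased
to leave room for a 3′ arm and one for a 5′ arm; the value is a package
default — the source analysis names no window size). Both windows are folded
and the one placing the read on a single well-paired arm at lower energy is
kept.

The default folding backend is a non-crossing minimum-energy dynamic program:
legal pairs {AU, GC, GU}; hairpin loops ≥3 nt with a logarithmic penalty;
exact stacked pairs scored by a small nearest-neighbor table; bulge/internal
loops up to 10 unpaired bases with a logarithmic penalty; multibranch
closures with a flat penalty; the empty structure at 0 kcal/mol bounds the
MFE from above. This is an approximation adequate for thresholding hairpins,
not a substitute thermodynamic model; the backend is pluggable and the
filter consumes externally computed MFE values (e.g. published ones)
directly. The test suite cross-checks it against ViennaRNA's RNAfold on
planted stems.

Filter verdicts, in order of precedence: `fail_repeat` if the read occurs in
the repeat set (either strand, 0 mismatches); `fail_mfe` if MFE ≥ −18
kcal/mol (**strictly** "lower than": a hairpin at exactly −18.0 fails — the
boundary reading of the published criterion); `fail_hairpin` if fewer than
60% of the read's bases are paired or the read does not lie on a single arm.
"Single arm" requires ≥90% of the read's paired bases to have partners on
one side of the read; the 10% allowance tolerates a stray pair contributed
by flanking sequence while still rejecting loop-spanning reads. The
hairpin-quality criteria of the prior work the source analysis cites are not
restated there; these concrete values (60% pairing, 90% arm purity) are this
package's documented stand-in. A crude protein-coding screen flags (does not
fail) candidates whose window holds an open reading frame of ≥80 codons.

## Degradome calling

A tag supports cleavage between miRNA positions p and p+1 (p ∈ 10..15,
canonical 10/11) when, after skipping at most one 5′ tag base, the next p
bases equal the reverse complement of miRNA positions p..1 — exact
complementarity, no G:U credit, minimum span 10. When several (offset, p)
alignments pass, the smallest offset wins first, then the smallest p; this
makes canonical offset-0 calls dominate and is the convention that
reproduces the published position labels (a smallest-p-first rule would
relabel the printed 11/12–14/15 rows, whose complementary block sits at
offset 0). The 1-base slack is flagged on the call, never silent: the
published table's first row needs it. Bulk scans gate tags to 20–21 nt (the
expected MmeI product); the calling function itself only requires the
minimum span, since several published tags are 22 nt. Tag-to-transcript
assignment is exact plus-strand substring search; antisense-only occurrences
are flagged separately, not counted as hits.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, with
known ground truth:

* **References:** a 20-kb chloroplast contig with an embedded 74-nt tRNA
  gene; 20 miRNA matures (20–24 nt) each planted on the 5′ arm of a perfect
  stem precursor; 10 homolog matures; 16 ncRNAs (10 tRNAs, rRNA/snoRNA/U6);
  5 transposons; 30 gene transcripts; a TaDREB3-like transgene plus 9
  CBF/DHN-like downstream genes; 20 novel miRNAs planted in hairpins inside
  EST-like contigs (2 of them only on related-species contigs); and a
  separate transcript set carrying a perfectly complementary target site per
  novel miRNA for degradome tags. Mature sequences are checked to occur in
  no other library, so cascade ground truth is unambiguous.
* **Composition** (defaults follow the observed class shares of the two real
  libraries): adapter-only 3.0%/3.6%, untrimmed 4.0%/5.9% (emitted as 27–30
  nt inserts that leave <10 adapter bases in the read), a dominant tRNA 5′
  fragment at 28.9%/42.2% of reads in two length variants, chloroplast
  background absorbing the remainder so that roughly half of each library is
  chloroplast-derived, two dominant miRNAs with opposite regulation, 7
  down-/1 up-regulated minor miRNAs and novel candidates shaped like the
  published spread, an expression-flat U6 fragment, ncRNA fragments
  including 1- and 2-substitution variants (exercising the Rfam budget),
  repeat/antisense/transgene classes, and perfect-inclusion chains for the
  clustering stage. The expected non-chloroplast totals are pinned so their
  ratio equals the published factor 1.3832.
* **Counts** are Poisson per feature (the simplest model consistent with
  sequencing count data; the source states none). The ground-truth table
  freezes, per feature, the expected counts and the designed log2
  — defined as `log2(E_B · F_exp / E_A)` with `F_exp` the expected-total
  ratio, i.e. exactly what the pipeline estimates — so recovery is measured
  against the realized design rather than round input knobs.
* **Reads** are insert + 3′ adapter prefix, random-filled/truncated to 36
  bases, Phred+33 constant quality; only the 3′ adapter appears (the 5′
  adapter is consumed upstream of sequencing in the real protocol). All
  sequences are stored in DNA alphabet; RNA input is U→T converted at
  ingest.

Not emulated: per-cycle sequencing error, quality-score realism, 5′-adapter
read-through, genome-scale reference sizes, and the long low-count tail of
real unique-read diversity (the catalog has ~150 designed inserts). Passing
tests therefore demonstrate correctness of the pipeline's logic and
accounting under the designed conditions, not performance on full-scale
noisy libraries.

Default problem sizes — 10⁵ reads per group for the end-to-end run and the
acceptance script, 10⁴ random cases for the oracle equivalence checks — were
chosen so the statistical tolerances below are meaningful while a full run
stays in seconds on one CPU.

## Numerical and verification notes

* Deterministic throughout under a fixed seed (numpy `default_rng`);
  re-running a pipeline reproduces byte-identical TSVs, checksummed in the
  run manifest.
* The matcher and trimmer are verified against brute-force
  enumeration oracles; collapsing against a hash-free sort-and-scan; folding
  against pair-table validity properties and RNAfold; designed fold changes
  are recovered within ±0.2 log2 at expectations ≥500; per-class counts
  within 3 Poisson SD at 10⁵ reads per group.
* The bundled published tables verify almost perfectly against their own
  printed raw integers: every size-table column sums to its printed total,
  all group-statistics fractions/percentages reproduce at printed precision,
  and all novel-candidate cells reproduce. Three known-miRNA rows — exactly
  the rows pooling a mature with its star — carry printed normalized/log2
  cells that do not follow from their own printed counts under any single
  factor; `verify_paper_tables` reports them as discrepancies rather than
  reproducing them. Likewise one printed degradome tag (miRX19) has its
  complementary block 5 bases into the tag and cannot fit its printed 10/11
  label under the 1-base slack convention; it is reported, not forced.
* Two published prose totals are not reconstructible from the printed
  tables (the unique-read remainder quoted per group, and the abstract's
  42% shared-DE figure vs ≈36.2–36.7% from the table); the package follows
  the tables.
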