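# Methods

## Conventions

Coordinates are 0-based half-open everywhere in the library; any 1-based
rendering happens only in printed text. All sequences are stored in the
DNA alphabet (RNA input is converted U→T on read); tail classes are
reported in RNA spelling (`mono_U`, `oligoU`). Reference transcripts are
stored sense-strand; "antisense" means a read matches the reverse
complement. The reference model is a small transcript set — a pre-rRNA
transcription unit annotated with ETS5–18S–ITS1–5.8S–ITS2–26S–ETS3, an
independently transcribed 5S, and decoy mRNAs standing in for the rest of
the transcriptome — which acts as both the mapping target and the
"genome" for normalization purposes.

## Small-RNA pipeline

**Trimming.** The 3′ adaptor (DNA form `TCGTATGCCGTCTTCTGCTTG`) is located
at its left-most occurrence within a Hamming budget (default 1); a ≥5 nt
adaptor prefix is accepted at the read end with the budget scaled to the
overlap. Reads without an adaptor are rejected — in this library design an
insert always precedes the adaptor, so an adaptorless read is unusable.
Clean inserts are kept when 18 ≤ length ≤ 30 (both bounds inclusive).

**Alignment.** A deterministic exact-seed + extension aligner reports
*all* placements on both strands with at most `max_mismatch` (default 0)
substitutions over the matched span and at most `allow_soft_tail`
(default 4) unmatched 3′ bases; at each position the soft tail is minimal,
i.e. the templated span is maximal. Seeds are disjoint k-mers spread over
the 5′ core of the read that must be part of any within-budget placement,
so by pigeonhole no placement can be missed for reads of ≥ 18 nt; the test
suite enforces set equality against an independent exhaustive
position-by-position scan for mismatch budgets 0–2. A SAM importer is
provided for placements produced by an external aligner. The soft tail
carries candidate untemplated additions; 4 nt covers the 1–3 nt U runs
typical of siRNA uridylation with one base of slack — reads with longer
untemplated tails are deliberately left unmapped rather than force-fit.

**Classification.** Priority risiRNA > sense_rRNA > other_mapped:

- any accepted antisense placement on a transcript carrying rRNA features
  makes the read a risiRNA (the priority preserves the antisense signal
  for reads that also map elsewhere);
- otherwise the best placement (fewest mismatches, then shortest soft
  tail, then transcript order, then position) decides: a sense placement
  whose span lies majority inside a mature rRNA (5S, 5.8S, 18S, 26S) is a
  sense rRNA fragment; sense reads mostly in spacers are `other_mapped`
  and tallied separately as `sense_spacer`.

Antisense-to-5S reads are counted in their own field (`risiRNA_5S`) and
are *not* merged into the default risiRNA numerator: 5S is transcribed
independently of the unit whose per-region profile the analysis reports.
Both merged and unmerged numbers are recoverable from the summary.

**Counting and normalization.** The normalization denominator is
`total_mapped − sense_rRNA`, excluding sense-rRNA degradation fragments
from the scale; risiRNA RPM is `risiRNA · 10⁶ / denominator`, and fold
enrichment is the RPM ratio of two samples. Adding pure sense-rRNA reads
to a library provably leaves RPM unchanged (they enter mapped count and
subtrahend equally); the test suite asserts this exactly, not
approximately. A zero denominator is flagged and per-million values
refuse to compute. Zero risiRNA in the baseline yields `inf` by default;
an optional pseudocount (added to both numerator counts) gives a finite
alternative. Multi-mapping reads contribute 1/k to each of their k
best-tier placements in per-transcript counts, avoiding double counting
without discarding signal. Per-region risiRNA counts assign each read to
the region containing the majority of its aligned span, ties to the
5′-most region.

**Uridylation of risiRNAs.** For each antisense read the 3′ soft tail is
first extended greedily against the template continuation (for an
antisense read this is the reverse complement of the reference walking
left from the alignment start); a read is uridylated iff the remaining
tail is non-empty and all U. A histogram over untemplated tail lengths is
reported alongside the count, so "exactly one terminal U" and "any
terminal U run" readings are both recoverable.

## Tail-seq pipeline

**Demultiplexing.** Reads are scanned for the best linker occurrence
(left-most offset, then fewest mismatches, budget 2 over the full 41–42 nt
linker; a ≥10 nt linker prefix is accepted at the read end with a scaled
budget). The linkers are matched as full sequences — their barcodes
differ at the 5′ end and identify the sample. Insert orientation is
auto-detected by retrying the reverse complement when linker or primer
matching fails in sequencing orientation.

**Primer verification.** The insert must begin with the 26S or 5.8S
forward primer (≤1 mismatch). In auto mode both primers are tested and an
insert matching both is rejected as ambiguous.

**Boundary rule.** One pure function, `split_templated_tail`, splits an
anchored insert into templated prefix and untemplated tail: the prefix is
*maximal* subject to (a) at most `max_mismatch` substitutions (default 2,
absorbing PCR plus sequencing errors over the ~100 nt amplicon) and (b) no
mismatch within the last 3 bases of the prefix. The protection window
keeps the bases that decide the boundary free of mismatch tolerance, so a
sequencing error at the boundary shortens or rejects the call instead of
silently reclassifying the tail. Anchorings leaving < 15 templated bases
or a tail > 8 nt are rejected (unassigned) rather than called. From the
split, `end_offset` (0 at the annotated mature 3′ end, −k if trimmed),
`templated_ext` (bases of genomic read-through past the end) and the tail
class follow directly. The call is flagged `ambiguous_boundary` when the
last templated base is a U, since an untemplated U run starting there
would have been absorbed.

Two consequences of maximal extension are intentional and quantified by
the simulator: (i) a drawn U-run whose leading bases equal the genomic
continuation is reported shorter, exactly as the rule dictates; (ii) a
long U-run over a template offering ≥3 consecutive matching bases after
one mismatching base can be absorbed entirely using the mismatch budget
(e.g. `TTTT` over genomic `ATTT`). Both are labelled `ambiguous` in the
truth tables; neither can be distinguished from read-through by any
caller that sees only the read.

**Aggregation.** Per replicate: tail-class counts and fractions over
assigned reads; across replicates: mean and sample SD (n−1); replicates
with zero assigned reads are excluded with a warning. The
uridine-run-length histogram pools mono-U (k = 1) with oligo-U (k ≥ 2)
into bins 1..5 and 6+. Condition comparisons use the two-tailed Student's
*t*-test on per-replicate fractions (equal-variance by default, Welch by
flag); with fewer than two replicates on either side the effect is
reported and the p-value is absent. Counts and fractions are both
emitted, since library depths differ.

## Synthetic data

The generator is the package's ground-truth oracle. One seeded PRNG
drives all draws in a fixed order, so identical configurations give
byte-identical FASTQ and truth files.

**Small-RNA libraries.** Per read: class ~ {sense_rRNA, risiRNA,
other_mapped, unmapped} (defaults 0.30/0.01/0.64/0.05 — rRNA fragments
prominent, risiRNA rare in an unperturbed background); length from a
distribution with mode 22 (the 22G-RNA length); risiRNA reads are
antisense substrings of the transcription unit with the 5′ base biased to
G (probability 0.85) by drawing template positions holding C, which
preserves exact mapping; sense-rRNA reads are substrings of mature rRNAs
weighted by length; an untemplated U run (lengths 1–3, mostly 1) is
appended to risiRNAs with configurable probability; the 3′ adaptor is
appended to every read; substitutions are injected at `seq_error_rate`
(default 0.001, Illumina-like). Truth records carry the drawn values
*and* the expected pipeline outcome: U bases coinciding with the genomic
continuation are absorbed (ambiguity flag), an effective tail longer than
the aligner's soft-tail allowance makes the read expectedly unmapped, and
trimmed inserts outside 18–30 nt are expectedly filtered.

**Tail-seq libraries.** Per read: an end trim from {0..−5} (mostly 0 — 
mature ends are well processed), a tail class from a configurable
distribution, the sense fragment from the embedded forward primer to the
trimmed end, the tail, and the linker. The 26S amplicon spans 60 nt
upstream of the mature end, the 5.8S amplicon 50 nt. The expected call in
the truth table is computed by the *caller's own* boundary function on
the clean insert, which makes zero-error agreement exact by construction
and turns boundary ambiguity into a labelled property instead of test
flakiness.

**Condition presets** (`risipipe.study`). Five paired small-RNA scenarios
with true enrichments 4.7, 17, 9.9, 1.6 and 164; pairs share sense/unmapped
fractions so the expected RPM ratio equals the risiRNA fraction ratio
exactly. Baselines carry 1% risiRNA except the enhanced-RNAi IP scenario
(0.35%), whose near-empty baseline is what makes a two-order-of-magnitude
enrichment arithmetically possible — the mutant library caps at
`(1 − sense − unmapped)` risiRNA. Mutants also lose most risiRNA
uridylation (U probability 0.30 → 0.02), mirroring loss of the writer.
Tail-seq conditions set (mono-U, oligo-U) loads per genotype: a
uridylation-writer mutant depleted for oligo-U, cold shock inducing it
(with mono-U also rising on 5.8S), and an exonuclease mutant accumulating
it; 26S oligo-U runs are drawn mostly at 3–6 U, 5.8S at 1–3.

**What the simulator does not emulate:** ligation sequence bias, PCR
duplicates and amplification bias across the 16 cycles, indels, quality
score variation (constant Q is emitted), 5′-phosphorylation state, and
genome-scale multi-mapping outside the toy transcript set. Passing
recovery tests therefore demonstrate correctness of the *computations*
under the stated read model, not robustness to every artefact of real
libraries.

## Problem sizes and test design

Acceptance-level checks run 100,000 reads per small-RNA library and
10,000 tail-seq reads; the analysis drivers use 20,000 and 3 × 2,000 for
fast iteration. At the extreme enrichment (164×) the baseline library can
carry at most ~410 risiRNA reads, so one library pair estimates the ratio
with ~5% binomial CV; the recovery check therefore averages three
independent pairs (CV of the mean ~3%, matching the single-pair precision
of the low-enrichment scenarios) rather than judging a single draw. The
estimator itself is unbiased — pipeline counts equal truth expectations
exactly on clean reads.

## Known limitations

- The aligner is designed for desk-scale references (kilobases); it is
  exact, not fast, at genome scale.
- Maximal templated extension is conservative: genuinely untemplated Us
  that duplicate genomic sequence are undercounted, with the bias
  quantified per read by the ambiguity flags.
- The tail caller assumes untemplated tails ≤ 8 nt; longer tails reject.
- Fractions of tail classes are slightly below configured generator
  values because absorbed tails reclassify — by design, and mirrored in
  the expected-truth tables.
- No multiple-testing correction is applied to condition comparisons; the
  comparison table records every test performed.
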