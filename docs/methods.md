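# Methods

This note records the models, conventions and deliberate design choices
behind each stage, the parameters that matter, and what the synthetic
data do and do not establish.

## Synthetic libraries

The generator emulates a normalized, full-length-enriched cDNA library
sequenced as long single-end pyrosequencing-style reads.

* **Transcriptome.** `n_genes` transcripts with log-normal lengths
  (moment-matched to a mean of 1,500 bp, sd 800 bp, truncated at
  ≥ 200 bp) over uniform random nucleotides. Expression is log-normal
  with log-space sd `abundance_sigma = 1.5` — the paper-gap here is that
  no abundance law is observable from a normalized library, and any
  heavy-tailed law produces the characteristic steep left-skewed
  coverage histogram, so the simplest standard choice is used.
* **Normalization.** Read counts per transcript are multinomial with
  probabilities ∝ abundance^`normalization_exponent` (default 0.25):
  0 models perfect normalization, 1 none. Smaller exponents provably
  flatten reads-per-transcript variance (property-tested over 20 seeds).
* **Reads.** Fragment lengths are normal (mean 372.6 bp, sd 96.36 bp,
  clamped to 78–624 bp — the observed statistics of cleaned GS-FLX
  Titanium libraries) and placed uniformly within the transcript;
  fragmentation by sonication has no positional bias. Decorations:
  residual 5'/3' adapters (15 % each), polyA or polyT tails (20 %,
  length ~N(18, 6) with a floor of 6 nt), substitutions at 5×10⁻³ per
  base, and the dominant 454 error mode — ±1 bp indels in homopolymer
  runs ≥ 3 bp at a per-run rate proportional to run length. A tail
  appended after a fragment that itself ends in the tail base would make
  the core/tail boundary unobservable, so the generator absorbs those
  core bases into the recorded tail and shrinks the truth interval
  accordingly; the truth table is exact by construction.
* **Contaminants.** `spike_contaminants` appends
  round(fraction × n_reads) reads from a foreign transcript library
  (default fraction 0.018, matching the observed non-plant best-hit
  rate), decorated identically and flagged.
* **Planted repeats.** For the end-to-end fixtures, 5 % of transcripts
  receive one perfect SSR (primitive 2–5 bp motif, 8–15 copies) and 3 %
  a 120–300 bp fragment of a labelled repeat-library element, each copy
  independently mutated at 10 % so copies stay far below the 94 %
  assembly threshold (no chimeric merges) while remaining detectable by
  the 75 %-identity repeat screen.

What the generator does **not** model: flowgram/quality-score realism,
positional coverage bias, chimeric cDNAs, alternative splice forms, and
sequence composition beyond uniform random DNA. Tests passing on these
data show algorithmic correctness against known truth, not performance
on real libraries, whose error and repeat structure is richer.

## Read cleaning

Order per read: adapter trimming, polyA/T trimming, then the length
filter (trimming can only shorten, so filtering last is the conservative
order). Adapter matches are scanned at every alignment of the adapter
against the read; terminal matches of ≥ 8 bp with mismatch fraction
≤ 0.15 are trimmed, and a full internal match truncates the read at the
match. PolyA/T trimming slides a 10 bp window inward from each end (both
bases, both ends): while consecutive windows hold ≥ 80 % of the target
base the chain extends, the cut reaching the innermost passing window's
inner edge, then giving back any inner-edge characters that are not the
tail base; terminal pure runs ≥ 5 bp are also removed, and the whole
procedure iterates to a fixpoint (making `clean_reads` idempotent).
This "aggressive" trimmer necessarily consumes junction-adjacent core
bases that match the tail base — an identifiability limit of any polyA
trimmer, documented in the tests rather than hidden. The minimum kept
length defaults to 78 bp, the smallest cleaned read observed in the
library the defaults mirror. The cleaning report reconciles exactly:
n_in = n_out + n_discarded, bp_removed = bp_in − bp_out.

## Two-step OLC assembly

**Overlap detection.** Candidate pairs share an exact k-mer (k = 16
primary, 12 secondary) in either relative orientation. The index stores
every stride-th k-mer of both strands of every read while queries use
every forward k-mer, so any overlap containing an exact stretch
≥ k + stride − 1 is seeded; stride is 1 below 5,000 sequences and 8
above (memory bound), k-mers occurring in more than 60 reads are treated
as repeats and skipped. Each candidate diagonal cluster (±12) is
verified by global alignment of the implied dovetail region (edlib),
with early abandonment beyond the edit-distance bound implied by the
identity threshold. Identity = matches / alignment columns, gap columns
included; the paper-gap is that published identity thresholds never
state their denominator, and this is the strictest common convention.

**Layout and consensus.** Per connected component, the most-connected
read seeds the layout (ties by read id); extension repeatedly applies
the best remaining overlap (identity, then length) from a placed to an
unplaced read, tracking offsets and strands through reverse-complement
frame flips. Consensus is per-column majority vote over placed reads,
ties resolved by the earliest-placed covering read; consensus is
reported on the seed read's strand. Each read is then re-anchored on the
consensus; a read whose polished identity falls below the pass threshold
is *released to singleton status, not discarded* — the original primary
assembler's internal discard criteria are unreproducible, so the default
discard count is 0 and the read-conservation identity
(assembled + discarded + singletons = input) is asserted everywhere.

**Secondary pass.** Unigene sequences are merged pairwise at ≥ 95 %
identity over ≥ 25 bp with the same machinery; merged products become
secondary contigs, member reads are unioned with coordinates mapped
through the merge (strand flips included), no reads are discarded, and
the unigene count can only decrease.

## Accumulation curve

Percentile confidence bands (2.5/97.5 across replicates per draw) were
chosen over a normal approximation; milestones use the mean curve; the
last-ten statistic is computed per replicate then averaged (the two
published phrasings are ambiguous between that and a mean-curve
definition; the per-replicate form has a variance and is declared here).
The estimator is validated against the closed-form hypergeometric
expectation; near saturation the integer-valued percentile band
collapses to [U, U] while the expectation sits below U by at most
−ln(0.975) ≈ 0.025 when the 2.5 % quantile has collapsed, so closed-form
agreement is asserted with a 0.05-unigene epsilon.

## Taxonomic screening

The bitscore floor (75) is strict (>), and "within 10 % of the top
bitscore" is read multiplicatively (≥ 0.9 × top) — both published
phrasings are ambiguous; these readings are declared and tested. Ties at
the top-n cutoff break by subject id for determinism. Unresolvable taxon
ids are dropped from LCA computation (and best-hit becomes None). The
plastid screen merges subject-side hit intervals per query (1-based
inclusive input converted to 0-based half-open) and flags genomic
contamination when a merged span strictly exceeds 3.5 kb or the merged
regions overlap more than five annotated genes.

## SSR and repeat screening

"Longer than 9, 8, 6, 5 repeats" is interpreted as minimum counts
10/9/7/6 (strictly greater); the alternative (≥) convention is a
one-line configuration change. Maximal perfect runs are reported; calls
overlapping across motif lengths resolve to the longest interval, ties
to the shorter motif; the canonical motif is the lexicographic minimum
over all rotations of the motif and of its reverse complement, which
also excludes homopolymers (non-primitive motifs are never emitted).
Primer design proper is replaced by a flank-length proxy (≥ 20 bp each
side, boundary inclusive). Repeat screening is plain local alignment
(match +1, mismatch −2, gap −3) of labelled consensus elements on both
strands with iterative masking of found copies; per-class summaries
merge masked intervals before measuring length.

## Annotation statistics

Longest-ORF length is measured in nucleotides **including the
terminating stop codon** when present, ties broken by frame order
(+1, +2, +3, −1, −2, −3) then position. This convention is forced by
consistency: a stop-terminated frame spanning the whole sequence must
outrank (or tie and win over) an unterminated reverse-frame segment of
equal nucleotide extent. Slim projection follows is_a and part_of by
default (an is_a-only mode exists); enrichment counts annotated
sequences, not term occurrences, per term, with two-tailed Fisher tests
and Benjamini–Hochberg FDR across all tested terms; direction compares
term frequency between the sets.

## Pipeline

Stages run in the order clean → assemble → curve → tax → ssr → repeats →
annotate from a single YAML config with one global seed; unknown config
keys are rejected. The manifest records parameters, SHA-256 input hashes
and outputs per stage; a rerun with unchanged inputs is a no-op per
stage. Reports are always TSV/JSON.

## Problem sizes

The end-to-end fixture ("paper-like-mini") uses 2,000 genes and 50,000
reads — large enough that overlap detection, normalization flattening,
contaminant statistics and curve saturation all behave asymptotically,
while a full run stays in the minutes range on one CPU. Unit and oracle
suites use hundreds of sequences. The original library's dataset-scale
counts depend on the actual reads, databases and assembler binaries and
are exercised here only as arithmetic identities through the reporting
operations.

## Known limitations

* The greedy layout has no multi-pass error correction; highly similar
  paralogs just below the identity threshold can fragment rather than
  separate cleanly.
* Placement coordinates assume substitution-dominated errors; dense
  indels shift placements, which the polishing step detects (release to
  singleton) rather than repairs.
* The repeat screen reports the best local alignment per masked
  iteration and is not a substitute for a curated repeat annotator's
  scoring model.
* Homology search itself is out of scope everywhere: the screens consume
  standard tabular hits from any engine.
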