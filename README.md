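# gametotk

A toolkit for *de novo* characterization of long-read (454-style) EST
transcriptomes, built around the analysis chain used for normalized cDNA
libraries from non-model plants such as fern gametophytes: read cleaning,
two-step overlap-layout-consensus (OLC) assembly into unigenes, saturation
and coverage statistics, taxonomic contamination screening, microsatellite
and transposable-element discovery, and GO-slim enrichment. Every stage is
also exercised end-to-end on a built-in synthetic-data generator with
known ground truth, so the whole pipeline is testable without downloading
reads or databases.

It is aimed at researchers analysing single-pass cDNA sequence collections
(ESTs/unigenes) for gene discovery and marker development, and at anyone
who needs a transparent, scriptable re-implementation of that classic
workflow.

## What it computes

**Two-step assembly.** Reads are assembled greedily from verified pairwise
overlaps (primary pass: identity ≥ 0.94, overlap ≥ 40 bp), retaining
unassembled reads as singletons; the resulting unigene sequences (contigs
plus singletons) are then merged in a redundancy-reducing secondary pass
whenever they overlap by ≥ 25 bp at ≥ 95 % identity. Identity is defined
as matches / alignment columns, counting gap columns. Mean read depth of a
unigene is Σ member placement lengths / consensus length.

**Unigene accumulation curve.** Given the empirical reads-per-unigene
counts *m₁…m_U* (Σmᵢ = T), each bootstrap replicate shuffles the labelled
read multiset and tracks distinct unigenes after every draw; the mean
curve is compared in tests against the exact without-replacement
expectation

&nbsp;&nbsp;&nbsp;&nbsp;E[detected at t] = Σᵢ ( 1 − C(T−mᵢ, t) / C(T, t) ).

Milestones report the first draw at which the mean curve reaches 90/95/99 %
of U; a last-ten statistic averages, per replicate, the reads needed for
each of the final ten detections.

**Taxonomic screening.** From 13-column tabular homology hits (the 12
standard columns plus a subject taxon id), each query gets a best-hit
taxon and a lowest-common-ancestor (LCA) taxon computed from hits with
bitscore > 75 that lie within 10 % of the query's top bitscore, requiring
at least three qualifying hits. A plastid screen flags putative genomic
contamination when merged hit spans exceed 3.5 kb or cover more than five
annotated genes.

**Repeats.** Perfect SSRs of motif length 2–5 are mined at minimum repeat
counts 10/9/7/6 with motifs canonicalized over rotations and reverse
complements, plus a flank-length check (≥ 20 bp both sides) for marker
amplifiability. A labelled repeat library is screened by local alignment
(match +1, mismatch −2, gap −3) on both strands at ≥ 75 % identity over
≥ 30 bp, summarized per repeat class.

**Annotation statistics.** Longest-ORF extraction over six frames (no
start codon required), GO → GO-slim projection under the true-path rule
(is_a and part_of), per-term two-tailed Fisher's exact tests with
Benjamini–Hochberg FDR across terms, conserved-gene detection rates, and
2–3-way set-overlap (Venn) counts.

## Worked example

Generate a small synthetic bundle and run the full pipeline:

```bash
gametotk fixture --preset tiny --seed 42 --out demo
gametotk run --config demo/config.yaml
```

`demo/out/` then contains, per stage, TSV/JSON reports. With seed 42 the
cleaning report shows 407 reads in, 407 surviving, 4,126 of 153,318 bp
(2.7 %) removed as adapter/polyA decoration; the assembly report reads

```
                              primary   secondary
reads_assembled_into_contigs      389         389
reads_retained_as_singletons       18          18
primary_contigs                    48          46
secondary_contigs                   0           1
total_unigenes                     66          65
mean_unigene_length                         780.8
mean_read_depth                              2.57
```

i.e. the 40 simulated genes assemble into 65 unigenes (some genes split
across non-overlapping contigs, as in any real EST assembly), with the
read-conservation identity 389 + 0 + 18 = 407 checked internally. The
accumulation milestones (`milestones.json`) report that on average 90 % of
unigenes were tagged after 277 of the 407 reads, and the taxonomic summary
recovers the spiked contaminant reads as non-plant best hits. SSR output
lists loci such as `(AG)×14` with canonical motif `AG` and an
amplifiability flag from the flank check.

Each stage is also available directly (`gametotk clean|assemble|curve|tax|
ssr|repeats|annotate|stats|simulate`), and the same functionality is
importable from `gametotk.*` modules.

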