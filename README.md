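# shatterscan

Detection and characterization of **chromoanagenesis** — the catastrophic
shattering and random reassembly of a chromosome segment — from short-read
sequencing of a single affected individual against diploid controls.

The package targets the situation seen in plant genetics when defective
meiosis (e.g. in an *Arabidopsis thaliana asy1* mutant) leaves a lagging
chromosome in a micronucleus, where it is pulverized and stitched back
together: the offspring carries two intact homologs plus a shattered,
reorganized extra copy of one chromosome arm. `shatterscan` provides the
full computational workflow to detect and describe such an event, and a
fully ground-truthed simulator so every stage can be validated without any
external data.

## What it computes

Given aligned reads (SAM) for a target sample, two control samples, a
reference genome (FASTA) and a parent-diagnostic SNP table:

1. **Dosage** (`shatterscan.coverage`) — reads are counted in consecutive
   non-overlapping bins and normalized to pooled diploid controls on the
   *relative coverage* scale where diploid ≈ 2, a heterozygous deletion ≈ 1
   and a single-copy gain ≈ 3. Dense clusters of copy-number-variant bins
   flag the shattered region.
2. **Novel DNA junctions** (`shatterscan.junctions`) — read pairs whose
   mates map > 2,000 bp apart (or to different chromosomes) are clustered;
   clusters present in either control or below a control-derived support
   threshold `max(3, ceil(mu + 3*sqrt(mu)))` are discarded; the survivors
   are assembled into junction-spanning contigs from chimeric reads,
   anchored to the reference by exact k-mer matching (one locus per flank),
   and classified by orientation (tail–head, head–head, tail–tail) and
   repair chemistry: **microhomology** (an identical 1–29 bp motif on both
   flanks, present once at the join), **perfect** (blunt) joining, or
   **insertion** of 1–80 untemplated bases.
3. **Fragment reconstruction** (`shatterscan.reconstruct`) — breakpoints
   partition the shattered region into segments; each junction joins two
   specific segment ends; maximal simple paths through this graph are the
   reconstructed rearranged fragments, ordered and oriented.
4. **Meiotic origin** (`shatterscan.haplotypes`) — the parent-B allele
   fraction per 10-kb bin reads out copy composition: 1/2 for a balanced
   {A,B} region, 1/3 for an {A,A,B} trisomy, 2/3 or 0 for sister-chromatid
   {B,B}/{A,A} trisomies. A trisomic region oscillating between 1/2 and
   1/3 carries two *different* maternal haplotypes — the signature of
   **meiosis-I** nondisjunction; uniform 2/3 (or 0 with trisomic dosage)
   indicates **meiosis II**. The low-recombination pericentromeric window
   is weighted decisively.
5. **Breakpoint enrichment** (`shatterscan.enrichment`) — for each
   annotation track (genes, transposable elements, chromatin states, ...),
   the fraction of breakpoints whose 1-kb or 10-kb centered window touches
   the track is compared against randomly placed pseudo-breakpoints;
   enrichment ratio = observed/expected with an empirical permutation
   p-value.

The simulator (`shatterscan.simulate`) generates the whole scenario with
known truth: random genome, two SNP-bearing haplotypes, a shattered region
reassembled in random order/orientation with a chosen microhomology /
perfect / insertion mix, offspring karyotypes for balanced transmission or
meiosis-I/II nondisjunction, and idealized paired-end alignments whose
per-copy dosage and junction-spanning pairs follow directly from the truth.

## Worked example

```bash
shatterscan run --outdir demo_run --seed 7
```

simulates a 2-Mb genome with a 12-fragment shattering of the 0.3–1.0 Mb
region transmitted through meiosis-I nondisjunction, then runs every stage.
The printed report (abridged) from that exact command:

```json
{
  "n_junctions": 10,
  "fraction_both_breakpoints_in_cluster": 0.9,
  "breakpoint_spacing_kb": 33.4,
  "n_chains": 1,
  "longest_chain_junctions": 10,
  "repair_class_percent": {"microhomology": 70.0, "insertion": 20.0, "perfect": 10.0},
  "inverted_percent": 30.0,
  "meiosis_verdict": "meiosis_I",
  "truth": {"stage": "meiosis_I", "junction_recall": 1.0, "junction_precision": 1.0}
}
```

Reading it: all 10 surviving truth junctions were recovered with no false
positives; 9 of the 10 junctions have both breakpoints inside the detected
CNV cluster (one sits at its very edge); one breakpoint every ~33 kb
across the cluster; the junctions chain into a single reconstructed
fragment; and the 1/2–1/3 allele-frequency oscillation correctly identifies
meiosis-I mis-segregation. `demo_run/` holds the per-stage TSV tables, the
dosage and allele-frequency plots, and an SVG of the longest reconstructed
chain.

Individual stages are available as `shatterscan simulate`, `shatterscan
coverage` and `shatterscan junctions`; the library API mirrors the CLI.

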