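# Methods

This note documents the models, algorithms, defaults and design choices
behind `shatterscan`, and what the simulation-based tests do and do not
demonstrate about real data.

## The biological scenario

A hybrid female carrying two distinguishable haplotypes (call them A, the
reference-like parent, and B) is crossed to a homozygous A male. Defective
meiosis can mis-segregate one chromosome; the laggard ends up in a
micronucleus, is pulverized, and its pieces are religated in random order
and orientation. The resulting offspring is diploid everywhere except the
shattered segment, which is present in three copies (two intact homologs
plus the reassembled fragments), minus whatever pieces were lost.

Three observables identify and time the event:

- **Dosage**: binned relative coverage ≈ 3 over retained fragments, ≈ 2
  elsewhere, ≈ 1 where something was deleted.
- **Novel junctions**: read pairs spanning two loci that are distant in
  the reference but adjacent in the sample.
- **Haplotype dosage**: the parent-B allele fraction per bin equals
  (#B copies)/(total copies). A trisomy that oscillates between 1/2 (extra
  copy absent) and 1/3 (extra A copy present) implies the two maternal
  copies carry *different* haplotypes, which only meiosis-I nondisjunction
  produces; sister-chromatid (meiosis-II) trisomies give 2/3 or 0. Because
  crossovers could re-assort distal haplotypes, the pericentromeric
  region, where recombination is rare, is the decisive readout.

## Simulator

`simulate.make_genome` draws i.i.d. bases at a target GC (default 0.36,
A+T-rich like the *A. thaliana* nuclear genome). `derive_haplotypes`
scatters diagnostic SNPs at a per-bp rate (default 1e-3); haplotype A *is*
the reference allele.

`simulate.shatter` cuts a region into `n_fragments` at uniform random
positions, drops each fragment with probability `loss_fraction` (default
0.1; fragment loss through micronucleus attrition is real but
unquantified), and reassembles the survivors under a uniform random
permutation and strand assignment. Junction repair chemistry is drawn per
junction from `repair_mix` (default 63.8% microhomology / 11.2% perfect /
25% insertion, the empirical mix in shattered plant chromosomes);
microhomology lengths are uniform on 1–29 bp and insertions uniform on
1–80 bp.

Two simulator subtleties deserve note:

- **Microhomology requires motif planting.** A microhomologous junction
  needs the same motif at both reference flanks, which essentially never
  happens between random cut sites. The simulator therefore copies the
  left fragment's terminal motif into the reference at the right
  fragment's boundary (inside the shattered region) before emitting the
  reference, then joins the fragments with a single copy of the motif.
- **Planted vs realized truth.** Chance sequence identity at a junction
  can extend a planted motif by a base or two, shorten an insertion whose
  terminal base happens to match a flank continuation, or give a nominally
  blunt join 1 bp of homology. Each `TruthJunction` therefore records both
  the construction (`planted_trim`, `planted_ins`), which drives exact
  sequence reconstruction, and the *realized* repair class / `mh_len` /
  `ins_seq` computed from the final sequences with the same
  flank-extension definition a detector must use. Tests compare detector
  output against realized truth; any mismatch is a detector defect, not
  rounding in the simulator.

`make_offspring` builds the karyotype: balanced (one maternal copy of
either haplotype + paternal A), meiosis-I (maternal A and B homologs +
paternal A; the shattered event rides the A copy, matching the inference
that the supernumerary chromosome was reference-like), or meiosis-II (two
maternal sister chromatids of one haplotype, B by default for the 2/3
dosage readout; configurable). A shattered copy consists of the
reassembled region only — the rest of that chromosome did not survive.

`simulate_reads` samples read pairs uniformly per copy so that a segment
in c copies has expected coverage `depth * c / 2`; insert sizes are
truncated normal (default 300 ± 50, min = read length; library geometry is
a stand-in, as are the 100-bp reads and 30x depth). Alignments are
idealized from known provenance: each mate is placed at the reference
locus of the block holding the majority of its bases with a full-match
CIGAR; a mate sitting mostly in untemplated inserted bases is reported at
the adjacent flank, as a real aligner would with soft-clipping. Reads are
error-free by default (`error_rate` adds uniform substitutions). Passing
tests on these alignments demonstrates the logic of the downstream stages,
*not* robustness to mapping artifacts, repeats, indel alignment noise or
base errors in real BWA output.

## Coverage

Reads are assigned to non-overlapping bins by leftmost mapped coordinate
(5-kb default; 100-kb for genome overviews). Two controls are summed
before normalization. Each bin's sample/control ratio is scaled so the
genome-wide *median* ratio maps to 2, with one refinement pass that
re-estimates the scale from bins classifying as diploid. A total-count
calibration was rejected: when a sizable segment is trisomic the inflated
sample total deflates the diploid baseline (a 500-kb gain on a 2-Mb genome
would read 1.78/2.67 instead of 2/3). The median calibration assumes the
majority of bins are diploid, which is the regime the method targets.
Bins with pooled control count < 10 are masked rather than divided.

CNV states use thresholds 1.5/2.5, midway between the integer dosage
anchors 1, 2, 3; both are configurable knobs, not inferred values. The
dense-CNV cluster finder slides a 500-kb window (100-kb in the small demo
configs) requiring ≥ 20% CNV bins, merges hot windows into maximal runs
and trims each run to its first/last CNV bin.

## Junction calling

Discovery: mate pairs > 2,000 bp apart or on different chromosomes.
Clustering: greedy single-linkage within a 500-bp radius on both sides
with strand agreement (radius ≈ insert + read length). Control
subtraction drops any cluster matched on both sides and strands in either
control; the support floor is `max(3, ceil(mu + 3*sqrt(mu)))` with `mu`
the mean support of control clusters — a declared surrogate for the
"coverage threshold" of the upstream literature, exposed in config.

Assembly replaces an external assembler with a greedy overlap-extension
loop over *chimeric* candidate reads — reads near either breakpoint whose
sequence disagrees with the reference at their mapped locus (≥ 4
mismatches; diagnostic-SNP mismatches essentially never reach that count
at the default SNP rate). Exact overlaps of ≥ 40 bp in either orientation
extend the seed; a branch whose second-best support is within 10% of the
best aborts the contig (irreconcilable mixture). Because two junctions
that share a fragment corner sit within a few bases of each other, the
resolver retries assembly from several seed reads until the anchored
contig agrees with the cluster's two sides — including the side labels
implied by the cluster's strands (forward flank reads approach a 3' tail,
reverse reads a 5' head).

Anchoring: exact 25-mer seeds at the contig's two ends, extended
maximally; a flank whose seed occurs at more than one reference locus
sets `unique_mapping = False` and the call is excluded ("no multiple
mapping allowed"). Ties break toward the longer match, then the leftmost
coordinate. Repair classification falls out of the anchor extents: anchor
overlap = microhomology (length = overlap), gap = insertion (the gap
bases), abutment = perfect. An insertion with incidental internal homology
is reported as insertion. Microhomology lengths > 29 bp are reported and
flagged out-of-range rather than truncated — the 1–29 bp range is an
observation, not a rule. Split-read (single-read chimera) evidence is not
used; mate-pair spanning only. Two clusters occasionally resolve to the
same junction (corner clouds overlap); identical calls are merged with
summed support.

A junction whose two breakpoints are closer than 2,000 bp in the
reference (fragments reassembled next to their original neighbours)
produces no distant pairs and is invisible to this method — simulation
truth is filtered accordingly when measuring recall
(`junctions.detectable_truth`).

## Reconstruction

Breakpoints inside the dense-CNV region partition it into segments; each
junction edge joins the two segment ends named by its orientation class.
Boundaries within 6 bp are snapped together (microhomology makes the
exact cut ambiguous by up to the motif length; in practice detected
boundaries jitter by 1–2 bp), and boundaries within the snap tolerance of
the region edge are clamped to it. Chains are maximal simple paths using
each segment end at most once; when two edges claim one end the
higher-support junction wins (logged); cycles are broken at their
lowest-support edge; breakpoints outside the region get ad-hoc nodes.
Output order is deterministic and each chain is normalized so its
leftmost reference segment reads '+'; comparisons accept whole-chain
reversal, since both directions describe the same molecule.

## Haplotype analysis

Allele counts at diagnostic SNPs are pooled *read-weighted* within 10-kb
bins (total B reads / total informative reads), not averaged per SNP:
depth varies several-fold with the CNV landscape, and per-SNP averaging
would overweight shallow sites. Bins with < 20 informative reads are
masked. Bins classify to the nearest of {0, 1/3, 1/2, 2/3} within a 0.06
tolerance (below half the minimal state gap of 1/12); beyond it, "other".

The verdict renormalizes state shares over recognized states (a few
noise-displaced bins must not veto a clear signal, but a region that is
mostly unrecognizable is inconclusive), then applies: 1/2 and 1/3
coexisting → meiosis I; dominant 2/3, or dominant 0 in a region whose
dosage says trisomic → meiosis II; uniform 1/2 — or uniform 0 with
disomic dosage, i.e. maternal transmission of an A chromosome → balanced.
Allele frequency alone cannot separate a disomic A,A region from an
A,A,A trisomy, so the coverage stage's dosage estimate is passed in when
available. When a pericentromeric window is supplied its verdict is
decisive whenever conclusive.

## Enrichment

The statistic is the per-breakpoint binary window-overlap fraction
(window sizes 1 kb and 10 kb, clipped at chromosome ends), robust to
window truncation; a bp-weighted alternative was considered and rejected
as the primary statistic. The null draws equal-sized pseudo-breakpoint
sets uniformly — within the CNV cluster when the observed breakpoints come
from one (otherwise genome-wide density differences dominate), or
genome-wide for whole-genome comparisons. p-values are empirical and
two-sided on the overlap fraction with the +1 finite-permutation
correction, so `1/(n_perm+1) <= p <= 1`; no asymptotic approximation is
claimed. Benjamini–Hochberg-adjusted values are emitted in a separate,
labeled column as an extension. Null calibration (500 replicate null
experiments) holds the false-positive rate at 5% ± 2% and the mean ratio
at 1 ± 0.05.

## Problem sizes and determinism

The test suite and the acceptance script run the full method on 0.4–2 Mb
genomes at 30x with 5–20 junctions — sizes at which every stage's
behaviour (dosage scale, recall/precision, exact repair classification,
chain recovery, stage inference, null calibration) is measurable in
minutes on one core; the algorithms are linear to near-linear in genome
size and junction count, and nothing in them is specific to these scales.
All randomness flows from named integer seeds (`numpy.random.default_rng`
/ `SeedSequence`); identical seeds give identical outputs, including the
pipeline report.

## Known limitations

- Idealized alignments carry no mapping ambiguity or error model beyond
  optional uniform substitutions; performance on real alignments will be
  bounded by the aligner, repeat content and library quality.
- The junction caller requires breakpoints > 2,000 bp apart; fragments
  religated near their original position are invisible by construction.
- The reconstruction reports linear chains; copy-number-consistent
  multiplicities and phasing onto specific homologs are out of scope.
- The enrichment null is uniform; GC- or distance-matched nulls are not
  implemented.
- The genome-wide parent-A allele floor of 50% holds for disomic
  karyotypes and for any trisomy whose supernumerary copy is parent-A
  (the configuration this package's default simulations model); a
  sister-chromatid B,B trisomy dips below it over the trisomic segment,
  exactly as the 2/3 parent-B readout implies.
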