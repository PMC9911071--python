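"""Synthetic chromoanagenesis generator.

Produces a random reference genome, a pair of parent-diagnostic SNP
haplotypes, a shattered-and-reassembled copy of a chromosome segment, an
offspring karyotype reflecting meiosis-I or meiosis-II nondisjunction, and
idealized paired-end alignments — all with complete ground truth, so the
detection modules can be validated against known answers.

The biological scenario emulated: a hybrid female (haplotypes A and B,
e.g. Col-0/Ler-1) crossed to a homozygous A male. Chromosome
mis-segregation during female meiosis leaves a laggard chromosome in a
micronucleus, where it is pulverized and reassembled in random order and
orientation, with junctions healed by microhomology-mediated joining,
blunt (perfect) joining, or joining with a short untemplated insertion.

Coordinates are 0-based half-open internally; 1-based inclusive in text
reports (SAM/GFF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

_COMP = str.maketrans("ACGTN", "TGCAN")

BASES = np.frombuffer(b"ACGT", dtype="S1")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class SyntheticGenome:
    """A reference genome: list of (name, length, sequence)."""

    chromosomes: list[tuple[str, int, str]]
    seed: int

    def seq(self, name: str) -> str:
        for n, _, s in self.chromosomes:
            if n == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [n for n, _, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return {n: ln for n, ln, _ in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(ln for _, ln, _ in self.chromosomes)

    def with_seq(self, name: str, seq: str) -> "SyntheticGenome":
        chroms = [
            (n, len(seq), seq) if n == name else (n, ln, s)
            for n, ln, s in self.chromosomes
        ]
        return SyntheticGenome(chroms, self.seed)

    def write_fasta(self, path: str, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, _, seq in self.chromosomes:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass
class HaplotypePair:
    """Diagnostic SNPs distinguishing the two parental haplotypes.

    alleleA is the reference base (haplotype A is reference-like);
    alleleB is the alternate carried by haplotype B.
    """

    parentA_label: str
    parentB_label: str
    snps: list[tuple[str, int, str, str]]  # chrom, pos0, alleleA, alleleB
    snp_rate: float

    def for_chrom(self, chrom: str) -> list[tuple[int, str, str]]:
        return [(p, a, b) for c, p, a, b in self.snps if c == chrom]

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\talleleA\talleleB\n")
            for c, p, a, b in self.snps:
                fh.write(f"{c}\t{p + 1}\t{a}\t{b}\n")


@dataclass
class TruthJunction:
    """One ground-truth novel junction between two reassembled fragments.

    repair_class / mh_len / ins_seq are the *realized* values — what a
    breakpoint detector anchoring reference flanks will see, including
    chance flank identity. planted_trim and planted_ins record the exact
    construction (bases trimmed from the right fragment's start for a
    microhomology join; bases inserted) and drive sequence reconstruction.
    """

    left_bp: tuple[str, int, str]  # chrom, pos 1-based, side in {head, tail}
    right_bp: tuple[str, int, str]
    orientation_class: str  # tail_head | head_head | tail_tail
    repair_class: str  # microhomology | perfect | insertion
    mh_len: int = 0
    ins_seq: str = ""
    planted_trim: int = 0
    planted_ins: str = ""


@dataclass
class ShatterEvent:
    """Ground truth of one simulated shattering event."""

    region: tuple[str, int, int]  # chrom, start, end (0-based half-open)
    fragments: list[tuple[int, int, str]]  # kept, in sample order: start, end, orient
    lost_fragments: list[tuple[int, int]]
    junctions_truth: list[TruthJunction]
    seed: int

    @property
    def n_junctions(self) -> int:
        return len(self.junctions_truth)

    def kept_intervals(self) -> list[tuple[int, int]]:
        return sorted((s, e) for s, e, _ in self.fragments)

    def apply(self, chrom_seq: str) -> str:
        """Rebuild the rearranged region sequence from the event (round-trip)."""
        pieces = []
        for i, (s, e, o) in enumerate(self.fragments):
            frag = chrom_seq[s:e]
            if o == "-":
                frag = revcomp(frag)
            if i > 0:
                j = self.junctions_truth[i - 1]
                if j.planted_trim:
                    frag = frag[j.planted_trim :]
                if j.planted_ins:
                    pieces.append(j.planted_ins)
            pieces.append(frag)
        return "".join(pieces)

    def coordinate_blocks(self) -> list[tuple[int, int, int, int, str]]:
        """Sample-to-reference map of the rearranged region.

        Returns (sample_start, sample_end, ref_start, ref_end, strand)
        blocks, sample coordinates relative to the region start. Inserted
        bases get ref_start = ref_end = -1.
        """
        blocks = []
        cur = 0
        for i, (s, e, o) in enumerate(self.fragments):
            s_eff, e_eff = s, e
            if i > 0:
                j = self.junctions_truth[i - 1]
                if j.planted_trim:
                    # trimmed sample bases merged into the previous
                    # fragment's copy of the microhomology motif
                    if o == "+":
                        s_eff = s + j.planted_trim
                    else:
                        e_eff = e - j.planted_trim
                if j.planted_ins:
                    blocks.append((cur, cur + len(j.planted_ins), -1, -1, "+"))
                    cur += len(j.planted_ins)
            ln = e_eff - s_eff
            blocks.append((cur, cur + ln, s_eff, e_eff, o))
            cur += ln
        return blocks


@dataclass
class ChromosomeCopy:
    chrom: str
    haplotype: str  # "A" | "B"
    shatter: ShatterEvent | None = None
    parent: str = "maternal"
    deletions: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class Karyotype:
    copies: list[ChromosomeCopy]
    meiosis_origin: str  # balanced | meiosis_I_nondisjunction | meiosis_II_...

    def copies_of(self, chrom: str) -> list[ChromosomeCopy]:
        return [c for c in self.copies if c.chrom == chrom]

    def haplotype_multiset(self, chrom: str, pos: int) -> list[str]:
        """Haplotype labels of all copies physically covering position pos.

        A shattered copy is the rearranged region only (the mis-segregated
        chromosome survives as reassembled fragments of the shattered
        segment), so it covers a position only where a kept fragment does.
        """
        labels = []
        for c in self.copies_of(chrom):
            if c.shatter is not None:
                n = sum(s <= pos < e for s, e, _ in c.shatter.fragments)
                labels.extend([c.haplotype] * n)
            elif not any(s <= pos < e for s, e in c.deletions):
                labels.append(c.haplotype)
        return labels

    def genome_wide_fraction_A(self, genome: SyntheticGenome) -> float:
        """Length-weighted parent-A allele fraction at the karyotype level."""
        bp_A = 0
        bp_tot = 0
        for c in self.copies:
            if c.shatter is not None:
                ln = sum(e - s for s, e, _ in c.shatter.fragments)
            else:
                ln = genome.lengths[c.chrom]
            bp_tot += ln
            if c.haplotype == "A":
                bp_A += ln
        return bp_A / bp_tot


@dataclass
class ReadPair:
    name: str
    copy_index: int
    sample_start: int  # fragment start on the copy's forward strand
    isize: int
    seq1: str
    seq2: str


@dataclass
class ReadSet:
    pairs: list[ReadPair]
    depth: float
    read_len: int
    insert_mean: float
    insert_sd: float
    seed: int


# ---------------------------------------------------------------------------
# operations


def make_genome(
    n_chroms: int = 1,
    lengths: int | list[int] = 1_000_000,
    gc: float = 0.36,
    seed: int = 0,
    name_prefix: str = "chr",
) -> SyntheticGenome:
    """Random reference genome with the given GC content.

    Default GC 0.36 matches the A+T richness typical of the A. thaliana
    nuclear genome.
    """
    if isinstance(lengths, int):
        lengths = [lengths] * n_chroms
    if len(lengths) != n_chroms:
        raise ValueError("lengths must match n_chroms")
    if any(ln < 10_000 for ln in lengths):
        raise ValueError("chromosome lengths must be >= 10 kb")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chroms = []
    for i, ln in enumerate(lengths):
        seq = rng.choice(BASES, size=ln, p=p).tobytes().decode()
        chroms.append((f"{name_prefix}{i + 1}", ln, seq))
    return SyntheticGenome(chroms, seed)


def derive_haplotypes(
    genome: SyntheticGenome,
    snp_rate: float = 0.001,
    seed: int = 0,
    parentA_label: str = "Col-0",
    parentB_label: str = "Ler-1",
) -> HaplotypePair:
    """Scatter diagnostic SNPs: haplotype A is the reference, B differs."""
    if not 0 <= snp_rate < 0.1:
        raise ValueError("snp_rate must be in [0, 0.1)")
    rng = np.random.default_rng(seed)
    snps: list[tuple[str, int, str, str]] = []
    for name, ln, seq in genome.chromosomes:
        mask = rng.random(ln) < snp_rate
        for pos in np.flatnonzero(mask):
            ref = seq[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            snps.append((name, int(pos), ref, alt))
    return HaplotypePair(parentA_label, parentB_label, snps, snp_rate)


def _orientation_class(side1: str, side2: str) -> tuple[str, bool]:
    """Class name plus whether the breakpoint pair was swapped to normalize."""
    if side1 == "tail" and side2 == "head":
        return "tail_head", False
    if side1 == "head" and side2 == "tail":
        return "tail_head", True
    if side1 == "head":
        return "head_head", False
    return "tail_tail", False


def _frag_end_bp(frag: tuple[int, int, str]) -> tuple[int, str]:
    """(1-based ref pos, side) of the sample-orientation END of a fragment."""
    s, e, o = frag
    return (e, "tail") if o == "+" else (s + 1, "head")


def _frag_start_bp(frag: tuple[int, int, str]) -> tuple[int, str]:
    """(1-based ref pos, side) of the sample-orientation START of a fragment."""
    s, e, o = frag
    return (s + 1, "head") if o == "+" else (e, "tail")


def _oriented(seq: str, s: int, e: int, o: str) -> str:
    frag = seq[s:e]
    return frag if o == "+" else revcomp(frag)


def _common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _realized_junction(
    chrom_seq: str,
    left: tuple[int, int, str],
    right: tuple[int, int, str],
    trim: int,
    ins: str,
    max_ext: int = 60,
) -> tuple[str, int, str]:
    """Classify the join as a flank-anchoring detector will see it.

    The sample around the junction is S_left + mid + S_right', where
    S_right' had its first `trim` bases removed (microhomology
    construction) and mid = `ins` (insertion construction). The left
    reference flank is extended maximally rightward past its nominal end
    and the right flank maximally leftward past its nominal start; anchor
    overlap = microhomology, gap = insertion, abutment = perfect.
    """
    ls, le, lo = left
    rs, re, ro = right
    # last 2*max_ext bases of the oriented left fragment: for a '-'
    # fragment the oriented tail comes from the reference *start*
    if lo == "+":
        S_left = chrom_seq[max(ls, le - 2 * max_ext) : le]
    else:
        S_left = revcomp(chrom_seq[ls : min(le, ls + 2 * max_ext)])
    # first bases of the oriented right fragment
    if ro == "+":
        S_right = chrom_seq[rs : min(re, rs + 2 * max_ext)]
    else:
        S_right = revcomp(chrom_seq[max(rs, re - 2 * max_ext) : re])
    # reference continuation past the left fragment end, sample orientation
    if lo == "+":
        lcont = chrom_seq[le : le + max_ext]
    else:
        lcont = revcomp(chrom_seq[max(0, ls - max_ext) : ls])
    # reference preceding the right fragment start, sample orientation
    if ro == "+":
        rprec = chrom_seq[max(0, rs - max_ext) : rs]
    else:
        rprec = revcomp(chrom_seq[re : re + max_ext])
    T = ins + S_right[trim:]  # sample content after the left fragment
    ext_r = _common_prefix(T, lcont)
    # leftward extension of the right reference flank: the first base of T
    # sits at refB offset `trim` (after ins), so refB's preceding sequence
    # in sample orientation is rprec + S_right[:trim]; for an insertion the
    # scan runs back through the inserted bases first
    left_context = S_left + ins
    ext_l = _common_prefix(left_context[::-1], (rprec + S_right[:trim])[::-1])
    j_left = len(S_left)  # junction point in local coordinates
    p1 = j_left + ext_r
    p2 = j_left + len(ins) - ext_l
    if p2 < p1:
        return "microhomology", p1 - p2, ""
    if p2 > p1:
        return "insertion", 0, (S_left + T)[p1:p2]
    return "perfect", 0, ""


def shatter(
    genome: SyntheticGenome,
    region: tuple[str, int, int],
    n_fragments: int,
    loss_fraction: float = 0.1,
    repair_mix: dict[str, float] | None = None,
    mh_len_range: tuple[int, int] = (1, 29),
    ins_len_range: tuple[int, int] = (1, 80),
    seed: int = 0,
    derange: bool = False,
) -> tuple[SyntheticGenome, ShatterEvent, str]:
    """Shatter a region into fragments and reassemble them at random.

    Fragment order and orientations are a uniform random permutation and
    flip assignment (pass derange=True to reject the identity outcome).
    Junction repair chemistry is drawn per junction from repair_mix
    (default 0.638 microhomology / 0.112 perfect / 0.25 insertion, the
    empirical mix seen in shattered chromosomes).

    Microhomology requires the motif to be present at both reference
    flanks, which almost never happens in random sequence, so the motif is
    planted into the returned genome at the right fragment's boundary
    (inside the shattered region; sequence outside the region is never
    touched). Returns (genome with planted motifs, event, rearranged
    region sequence). The recorded repair class / mh_len / ins_seq are the
    values realized in the final sequence, so chance flank identity at a
    nominally blunt join is accounted for.
    """
    chrom, start, end = region
    chrom_seq = genome.seq(chrom)
    if not (0 <= start < end <= len(chrom_seq)):
        raise ValueError("region out of chromosome bounds")
    if n_fragments < 2:
        raise ValueError("n_fragments must be >= 2")
    if n_fragments > end - start:
        raise ValueError("more fragments than base pairs in region")
    if repair_mix is None:
        repair_mix = {"microhomology": 0.638, "perfect": 0.112, "insertion": 0.25}
    if abs(sum(repair_mix.values()) - 1) > 1e-9:
        raise ValueError("repair_mix must sum to 1")
    rng = np.random.default_rng(seed)

    cuts = np.sort(
        rng.choice(np.arange(start + 1, end), size=n_fragments - 1, replace=False)
    )
    bounds = [start, *cuts.tolist(), end]
    frags = [(bounds[i], bounds[i + 1]) for i in range(n_fragments)]

    keep_mask = rng.random(n_fragments) >= loss_fraction
    if not keep_mask.any():
        keep_mask[rng.integers(n_fragments)] = True
    kept = [f for f, k in zip(frags, keep_mask) if k]
    lost = [f for f, k in zip(frags, keep_mask) if not k]

    for _ in range(1000):
        order = rng.permutation(len(kept))
        orients = rng.choice(["+", "-"], size=len(kept))
        identity = bool((order == np.arange(len(kept))).all() and (orients == "+").all())
        if not (derange and identity and len(kept) > 1):
            break
    ordered = [(kept[i][0], kept[i][1], str(o)) for i, o in zip(order, orients)]

    classes = list(repair_mix)
    probs = np.array([repair_mix[c] for c in classes])
    draw = rng.choice(classes, size=max(len(ordered) - 1, 0), p=probs)

    # plant microhomology motifs; build junction mid-sequences
    seq = list(chrom_seq)
    mids: list[tuple[str, int, str]] = []  # repair, mh_len, ins
    for i, cls in enumerate(draw):
        lfrag, rfrag = ordered[i], ordered[i + 1]
        if cls == "microhomology":
            lo, hi = mh_len_range
            L = int(rng.integers(lo, hi + 1))
            min_len = min(lfrag[1] - lfrag[0], rfrag[1] - rfrag[0])
            if min_len < 2 * L + 2:
                L = max(1, min_len // 2 - 1)
            motif = _oriented("".join(seq), *lfrag)[-L:]
            rs, re, ro = rfrag
            if ro == "+":
                seq[rs : rs + L] = list(motif)
            else:
                seq[re - L : re] = list(revcomp(motif))
            mids.append(("microhomology", L, ""))
        elif cls == "insertion":
            lo, hi = ins_len_range
            L = int(rng.integers(lo, hi + 1))
            ins = "".join(rng.choice(BASES, size=L).astype("U1"))
            mids.append(("insertion", 0, ins))
        else:
            mids.append(("perfect", 0, ""))
    new_seq = "".join(seq)

    junctions: list[TruthJunction] = []
    for i, (cls, mh, ins) in enumerate(mids):
        lfrag, rfrag = ordered[i], ordered[i + 1]
        rcls, rmh, rins = _realized_junction(new_seq, lfrag, rfrag, mh, ins)
        lpos, lside = _frag_end_bp(lfrag)
        rpos, rside = _frag_start_bp(rfrag)
        oclass, swapped = _orientation_class(lside, rside)
        bp1 = (chrom, lpos, lside)
        bp2 = (chrom, rpos, rside)
        if swapped:
            bp1, bp2 = bp2, bp1
        junctions.append(
            TruthJunction(bp1, bp2, oclass, rcls, rmh, rins,
                          planted_trim=mh, planted_ins=ins)
        )

    genome2 = genome.with_seq(chrom, new_seq)
    event = ShatterEvent((chrom, start, end), ordered, lost, junctions, seed)
    # rebuild from the event record: guarantees the round-trip invariant
    rearranged = event.apply(new_seq)
    return genome2, event, rearranged


def make_offspring(
    genome: SyntheticGenome,
    haplotypes: HaplotypePair,
    shatter_event: ShatterEvent | None,
    stage: str = "meiosis_I",
    seed: int = 0,
    crossover: int | None = None,
    meiosis_II_haplotype: str = "B",
) -> Karyotype:
    """Offspring karyotype of the (A/B hybrid female x A male) cross.

    balanced: one maternal copy (A or B at random) + one paternal A copy.
    meiosis_I: both maternal homologs (one A, one B) are retained, plus
    the paternal A copy; the shattered event lands on the maternal copy
    whose haplotype differs from the intact maternal copy (the A copy,
    so trisomic dosage reads as 1/3 parent-B alleles).
    meiosis_II: two maternal sister chromatids of the same haplotype
    (B by default) plus the paternal A copy (2/3 parent-B alleles).

    crossover is accepted for karyotype bookkeeping of a recombinant
    maternal chromatid; the shattered chromosome itself is modeled as
    non-recombinant, matching the pericentromeric readout logic.
    """
    if stage not in {"balanced", "meiosis_I", "meiosis_II"}:
        raise ValueError(f"unknown stage {stage!r}")
    rng = np.random.default_rng(seed)
    target_chrom = shatter_event.region[0] if shatter_event else genome.names[0]
    copies: list[ChromosomeCopy] = []
    origin = "balanced"
    for name in genome.names:
        if name != target_chrom:
            mat = str(rng.choice(["A", "B"]))
            copies.append(ChromosomeCopy(name, mat, None, "maternal"))
            copies.append(ChromosomeCopy(name, "A", None, "paternal"))
            continue
        if stage == "balanced":
            mat = str(rng.choice(["A", "B"]))
            copies.append(ChromosomeCopy(name, mat, None, "maternal"))
        elif stage == "meiosis_I":
            origin = "meiosis_I_nondisjunction"
            copies.append(ChromosomeCopy(name, "B", None, "maternal"))
            copies.append(ChromosomeCopy(name, "A", shatter_event, "maternal"))
        else:
            # sister chromatids: both maternal copies carry one haplotype
            # (B by default, for the 2/3 parent-B dosage readout)
            origin = "meiosis_II_nondisjunction"
            h = meiosis_II_haplotype
            copies.append(ChromosomeCopy(name, h, None, "maternal"))
            copies.append(ChromosomeCopy(name, h, shatter_event, "maternal"))
        copies.append(ChromosomeCopy(name, "A", None, "paternal"))
    return Karyotype(copies, origin)


def _copy_sequence(
    genome: SyntheticGenome, haplotypes: HaplotypePair, copy: ChromosomeCopy
) -> tuple[str, list[tuple[int, int, int, int, str]]]:
    """Physical sequence of one chromosome copy + sample->ref block map."""
    seq = genome.seq(copy.chrom)
    if copy.haplotype == "B":
        s = list(seq)
        for pos, _a, b in haplotypes.for_chrom(copy.chrom):
            s[pos] = b
        seq = "".join(s)
    if copy.shatter is None:
        if not copy.deletions:
            return seq, [(0, len(seq), 0, len(seq), "+")]
        # excise deleted intervals (heterozygous-deletion simulation)
        blocks = []
        pieces = []
        cur = 0
        prev = 0
        for ds, de in sorted(copy.deletions):
            if ds > prev:
                pieces.append(seq[prev:ds])
                blocks.append((cur, cur + ds - prev, prev, ds, "+"))
                cur += ds - prev
            prev = max(prev, de)
        if prev < len(seq):
            pieces.append(seq[prev:])
            blocks.append((cur, cur + len(seq) - prev, prev, len(seq), "+"))
        return "".join(pieces), blocks
    # a shattered copy is the reassembled region only: the rest of the
    # mis-segregated chromosome did not survive the micronucleus
    rearranged = copy.shatter.apply(seq)
    blocks = copy.shatter.coordinate_blocks()
    return rearranged, [b for b in blocks if b[1] > b[0]]


def _map_to_ref(
    blocks: list[tuple[int, int, int, int, str]], s: int, e: int
) -> tuple[int, str] | None:
    """Map sample interval [s, e) to (ref_pos, strand) via its majority block.

    Untemplated insertion blocks have no reference locus, so the majority
    is taken over reference-backed blocks only (a read sitting mostly in
    an inserted stretch still reports at the adjacent flank, as a real
    aligner would with soft-clipping); None if no reference block overlaps.
    """
    best, best_ov = None, 0
    for bs, be, fs, fe, o in blocks:
        if fs < 0:
            continue
        ov = min(e, be) - max(s, bs)
        if ov > best_ov:
            best, best_ov = (bs, be, fs, fe, o), ov
    if best is None:
        return None
    bs, be, fs, fe, o = best
    cs, ce = max(s, bs), min(e, be)
    if o == "+":
        pos = fs + (cs - bs)
    else:
        pos = fs + (be - ce)
    return pos, o


def simulate_reads(
    genome: SyntheticGenome,
    haplotypes: HaplotypePair,
    karyotype: Karyotype,
    depth: float = 30.0,
    read_len: int = 100,
    insert_mean: float = 300.0,
    insert_sd: float = 50.0,
    seed: int = 0,
    error_rate: float = 0.0,
    name_prefix: str = "rp",
) -> tuple[ReadSet, list[dict]]:
    """Uniform paired-end sampling over the karyotype's physical sequence.

    depth is the haploid-pair scale: a segment present in c copies gets
    expected per-base coverage depth * c / 2. Returns the read set plus
    idealized alignment records (dicts ready for SAM emission); each mate
    is placed at the reference locus of the block holding the majority of
    its bases, so a pair whose mates flank a novel junction is reported at
    the junction's two reference loci.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if read_len < 30:
        raise ValueError("read_len must be >= 30")
    rng = np.random.default_rng(seed)
    copies = []
    for idx, copy in enumerate(karyotype.copies):
        seq, blocks = _copy_sequence(genome, haplotypes, copy)
        copies.append((idx, copy, seq, blocks))
    if not copies or all(len(c[2]) == 0 for c in copies):
        raise ValueError("karyotype has no sequence")

    pairs: list[ReadPair] = []
    records: list[dict] = []
    counter = 0
    for idx, copy, seq, blocks in copies:
        ln = len(seq)
        n_pairs = rng.poisson(depth / 2 * ln / (2 * read_len))
        isizes = rng.normal(insert_mean, insert_sd, size=n_pairs)
        isizes = np.clip(np.rint(isizes), read_len, None).astype(int)
        starts = rng.integers(0, np.maximum(ln - isizes, 1))
        for s, isz in zip(starts, isizes):
            s = int(s)
            isz = int(min(isz, ln - s))
            e = s + isz
            seq1 = seq[s : s + read_len]
            seq2 = revcomp(seq[max(e - read_len, s) : e])
            if error_rate > 0:
                seq1 = _mutate(seq1, error_rate, rng)
                seq2 = _mutate(seq2, error_rate, rng)
            name = f"{name_prefix}{counter:07d}"
            counter += 1
            pairs.append(ReadPair(name, idx, s, isz, seq1, seq2))
            m1 = _map_to_ref(blocks, s, s + read_len)
            m2 = _map_to_ref(blocks, e - read_len, e)
            if m1 is None or m2 is None:
                continue
            p1, t1 = m1
            p2, t2 = m2
            # mate1 sequenced forward, mate2 reverse on the copy
            rec = {
                "name": name,
                "chrom": copy.chrom,
                "mate1": (p1, ("-" if t1 == "-" else "+"), seq1 if t1 == "+" else revcomp(seq1)),
                "mate2": (p2, ("+" if t2 == "-" else "-"), revcomp(seq2) if t2 == "+" else seq2),
            }
            records.append(rec)
    rs = ReadSet(pairs, depth, read_len, insert_mean, insert_sd, seed)
    return rs, records


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    s = list(seq)
    for i in np.flatnonzero(rng.random(len(s)) < rate):
        s[i] = str(rng.choice([b for b in "ACGT" if b != s[i]]))
    return "".join(s)


def write_sam(
    records: list[dict], genome: SyntheticGenome, path: str, read_len: int = 100
) -> None:
    """Emit idealized alignments as a text SAM with @SQ headers."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": ln} for n, ln, _ in genome.chromosomes],
    }
    tid = {n: i for i, (n, _, _) in enumerate(genome.chromosomes)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rec in records:
            for mate_i, key in enumerate(("mate1", "mate2")):
                pos, strand, seq = rec[key]
                opos, ostrand, _ = rec["mate2" if mate_i == 0 else "mate1"]
                a = pysam.AlignedSegment(out.header)
                a.query_name = rec["name"]
                a.query_sequence = seq
                a.reference_id = tid[rec["chrom"]]
                a.reference_start = pos
                a.cigarstring = f"{len(seq)}M"
                a.mapping_quality = 60
                flag = 0x1
                flag |= 0x40 if mate_i == 0 else 0x80
                if strand == "-":
                    flag |= 0x10
                if ostrand == "-":
                    flag |= 0x20
                a.flag = flag
                a.next_reference_id = tid[rec["chrom"]]
                a.next_reference_start = opos
                a.template_length = 0
                out.write(a)


def write_fastq(readset: ReadSet, path1: str, path2: str) -> None:
    q = "I"
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in readset.pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{q * len(p.seq1)}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{q * len(p.seq2)}\n")


# ---------------------------------------------------------------------------
# annotation tracks


def make_tracks(
    genome: SyntheticGenome,
    track_specs: dict[str, tuple[float, int]],
    seed: int = 0,
) -> dict[str, list[tuple[str, int, int]]]:
    """Random non-overlapping interval tracks.

    track_specs maps track name -> (target genome fraction, mean feature
    length in bp). Feature lengths are exponential around the mean;
    placement is rejection sampling until the realized fraction reaches
    the target (within 10% relative for fractions >= 0.05).
    """
    rng = np.random.default_rng(seed)
    tracks: dict[str, list[tuple[str, int, int]]] = {}
    for name, (fraction, mean_len) in track_specs.items():
        if not 0 <= fraction <= 1:
            raise ValueError("track fraction must be in [0, 1]")
        intervals: list[tuple[str, int, int]] = []
        for chrom, ln, _ in genome.chromosomes:
            target = fraction * ln
            placed: list[tuple[int, int]] = []
            covered = 0
            tries = 0
            max_tries = int(target / max(mean_len, 1) * 50) + 100
            while covered < target and tries < max_tries:
                tries += 1
                flen = max(1, int(rng.exponential(mean_len)))
                s = int(rng.integers(0, max(ln - flen, 1)))
                e = min(s + flen, ln)
                if any(s < pe and ps < e for ps, pe in placed):
                    continue
                placed.append((s, e))
                covered += e - s
            intervals.extend((chrom, s, e) for s, e in sorted(placed))
        tracks[name] = intervals
    return tracks


def make_partition_tracks(
    genome: SyntheticGenome,
    names: list[str],
    probs: list[float] | None = None,
    mean_len: int = 2000,
    seed: int = 0,
) -> dict[str, list[tuple[str, int, int]]]:
    """Disjoint tracks that jointly partition the genome (chromatin states)."""
    rng = np.random.default_rng(seed)
    if probs is None:
        probs = [1 / len(names)] * len(names)
    tracks: dict[str, list[tuple[str, int, int]]] = {n: [] for n in names}
    for chrom, ln, _ in genome.chromosomes:
        pos = 0
        while pos < ln:
            flen = max(1, int(rng.exponential(mean_len)))
            e = min(pos + flen, ln)
            state = names[int(rng.choice(len(names), p=probs))]
            tracks[state].append((chrom, pos, e))
            pos = e
    return tracks


def write_bed(intervals: list[tuple[str, int, int]], path: str, name: str = ".") -> None:
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")
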