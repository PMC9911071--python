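"""Novel DNA junction discovery, assembly, and classification.

A novel junction is an adjacency between two reference loci that are
distant in the reference (> min_distance apart, or on different
chromosomes) but contiguous in the sample. Evidence comes from read
pairs whose mates map to the two sides; clusters of such pairs that are
absent from control samples and exceed a support threshold are assembled
into junction-spanning contigs from chimeric reads, anchored back to the
reference by exact k-mer matching (one locus per flank — no multiple
mapping allowed), and classified by orientation (tail-head, head-head,
tail-tail) and repair chemistry (microhomology / perfect / insertion).
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .simulate import SyntheticGenome, _orientation_class, revcomp

DEFAULT_MIN_DISTANCE = 2000
DEFAULT_RADIUS = 500
DEFAULT_ANCHOR_K = 25
DEFAULT_MIN_OVERLAP = 40
MIN_FLANK = 30
CHIMERA_MIN_MISMATCH = 4


@dataclass
class DistantPair:
    name: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str


@dataclass
class JunctionEvidence:
    cluster_id: int
    side1: tuple[str, float, str]  # chrom, mean pos, strand
    side2: tuple[str, float, str]
    support: int
    members: list[str] = field(default_factory=list)


@dataclass
class SupportThresholdModel:
    """Support floor derived from the control distant-pair background."""

    mu: float
    min_support: int

    @classmethod
    def fit(cls, control_evidence: list[JunctionEvidence]) -> "SupportThresholdModel":
        mu = (
            float(np.mean([e.support for e in control_evidence]))
            if control_evidence
            else 0.0
        )
        return cls(mu, max(3, math.ceil(mu + 3 * math.sqrt(mu))))


@dataclass
class JunctionCall:
    breakpoint1: tuple[str, int, str]  # chrom, pos 1-based, side head|tail
    breakpoint2: tuple[str, int, str]
    orientation_class: str
    repair_class: str
    mh_len: int
    ins_seq: str
    contig: str
    support: int
    unique_mapping: bool

    @property
    def breakpoints(self) -> list[tuple[str, int]]:
        return [self.breakpoint1[:2], self.breakpoint2[:2]]


# ---------------------------------------------------------------------------
# discovery


def find_distant_pairs(
    sam_path: str, min_distance: int = DEFAULT_MIN_DISTANCE
) -> list[DistantPair]:
    """Read pairs whose mates map > min_distance apart or to different
    chromosomes. Sides are stored in canonical (chrom, pos) order."""
    pending: dict[str, tuple[str, int, str]] = {}
    out: list[DistantPair] = []
    n_mates = 0
    with pysam.AlignmentFile(sam_path, "r") as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if not rec.is_paired:
                raise ValueError("unpaired read in input stream")
            n_mates += 1
            here = (rec.reference_name, rec.reference_start, "-" if rec.is_reverse else "+")
            other = pending.pop(rec.query_name, None)
            if other is None:
                pending[rec.query_name] = here
                continue
            c1, p1, s1 = other
            c2, p2, s2 = here
            if c1 == c2 and abs(p1 - p2) <= min_distance:
                continue
            if (c2, p2) < (c1, p1):
                (c1, p1, s1), (c2, p2, s2) = (c2, p2, s2), (c1, p1, s1)
            out.append(DistantPair(rec.query_name, c1, p1, s1, c2, p2, s2))
    return out


def cluster_pairs(
    records: list[DistantPair], radius: int = DEFAULT_RADIUS
) -> list[JunctionEvidence]:
    """Greedy single-linkage clustering of distant pairs.

    Pairs merge when both sides fall within radius of the cluster's
    running means and both strands agree.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    groups: dict[tuple, list[list]] = {}
    for r in sorted(records, key=lambda r: (r.chrom1, r.pos1, r.chrom2, r.pos2)):
        key = (r.chrom1, r.chrom2, r.strand1, r.strand2)
        placed = False
        for cl in groups.setdefault(key, []):
            m1 = cl[0] / cl[2]
            m2 = cl[1] / cl[2]
            if abs(r.pos1 - m1) <= radius and abs(r.pos2 - m2) <= radius:
                cl[0] += r.pos1
                cl[1] += r.pos2
                cl[2] += 1
                cl[3].append(r.name)
                placed = True
                break
        if not placed:
            groups[key].append([r.pos1, r.pos2, 1, [r.name]])
    out = []
    cid = 0
    for (c1, c2, s1, s2), cls in groups.items():
        for p1, p2, n, names in cls:
            out.append(
                JunctionEvidence(cid, (c1, p1 / n, s1), (c2, p2 / n, s2), n, names)
            )
            cid += 1
    return out


def _match(a: JunctionEvidence, b: JunctionEvidence, radius: int) -> bool:
    for x, y in ((a.side1, b.side1), (a.side2, b.side2)):
        if x[0] != y[0] or x[2] != y[2] or abs(x[1] - y[1]) > radius:
            return False
    return True


def subtract_controls(
    evidence: list[JunctionEvidence],
    control_evidence_1: list[JunctionEvidence],
    control_evidence_2: list[JunctionEvidence] | None = None,
    radius: int = DEFAULT_RADIUS,
) -> list[JunctionEvidence]:
    """Keep clusters unique to the target: drop any cluster matched (both
    sides within radius, strands equal) in either control."""
    controls = list(control_evidence_1) + list(control_evidence_2 or [])
    return [
        e for e in evidence if not any(_match(e, c, radius) for c in controls)
    ]


def support_filter(
    evidence: list[JunctionEvidence], model: SupportThresholdModel
) -> list[JunctionEvidence]:
    return [e for e in evidence if e.support >= model.min_support]


# ---------------------------------------------------------------------------
# assembly


class AssemblyError(Exception):
    pass


def _extensions(contig: str, reads: list[str], min_overlap: int) -> list[str]:
    """Right extensions of contig by reads with exact suffix overlap."""
    exts = []
    for r in reads:
        for seq in (r, revcomp(r)):
            best = None
            for ov in range(min(len(contig), len(seq)) - 1, min_overlap - 1, -1):
                if contig.endswith(seq[:ov]):
                    best = ov
                    break
            if best is not None and len(seq) > best:
                exts.append(seq[best:])
    return exts


def assemble_contig(
    reads: list[str],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_rounds: int = 200,
    branch_ratio: float = 0.9,
    seed: str | None = None,
) -> str | None:
    """Greedy overlap-extension assembly with per-column majority consensus.

    Seeds on `seed` (default: the longest read), extends both directions
    by exact overlaps of at least min_overlap bases (either orientation).
    Returns None (unresolved) on irreconcilable branching — two consensus
    candidates whose support is within 10% of each other — or when fewer
    than two reads are given.
    """
    reads = [r for r in reads if r]
    if len(reads) < 2:
        return None
    contig = seed if seed is not None else max(reads, key=len)
    for direction in ("right", "left"):
        for _ in range(max_rounds):
            view = contig if direction == "right" else revcomp(contig)
            exts = _extensions(view, reads, min_overlap)
            if not exts:
                break
            by_base: dict[str, int] = {}
            for e in exts:
                by_base[e[0]] = by_base.get(e[0], 0) + 1
            ranked = sorted(by_base.items(), key=lambda kv: -kv[1])
            if len(ranked) > 1 and ranked[1][1] >= branch_ratio * ranked[0][0:2][1]:
                return None  # irreconcilable branch
            winner = ranked[0][0]
            cands = [e for e in exts if e[0] == winner]
            ext = max(cands, key=len)
            for c in cands:
                if not ext.startswith(c):
                    return None  # nested disagreement within the winning branch
            view = view + ext
            contig = view if direction == "right" else revcomp(view)
    return contig


# ---------------------------------------------------------------------------
# anchoring / classification


class ReferenceIndex:
    """Exact k-mer occurrence index over the reference (forward strand)."""

    def __init__(self, genome: SyntheticGenome, k: int = DEFAULT_ANCHOR_K):
        self.genome = genome
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, _, seq in genome.chromosomes:
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((name, i))

    def occurrences(self, kmer: str) -> list[tuple[str, int, str]]:
        occ = [(c, p, "+") for c, p in self.index.get(kmer, [])]
        occ += [(c, p, "-") for c, p in self.index.get(revcomp(kmer), [])]
        return occ


@dataclass
class Anchor:
    chrom: str
    bp: int  # 1-based breakpoint position
    side: str  # head | tail
    contig_extent: int  # contig coordinate where the anchor stops
    unique: bool


def _anchor_left(contig: str, index: ReferenceIndex) -> Anchor | None:
    """Anchor the left contig flank; extend the exact match rightward."""
    k = index.k
    if len(contig) < k:
        return None
    occ = index.occurrences(contig[:k])
    if not occ:
        return None
    results = []
    for chrom, p, strand in occ:
        ref = index.genome.seq(chrom)
        e = 0
        if strand == "+":
            while e < len(contig) and p + e < len(ref) and contig[e] == ref[p + e]:
                e += 1
            results.append((e, chrom, p + e, "tail", strand))
        else:
            start = p + k - 1
            while e < len(contig) and start - e >= 0 and contig[e] == revcomp(ref[start - e])[0]:
                e += 1
            results.append((e, chrom, start - e + 2, "head", strand))
    results.sort(key=lambda r: (-r[0], r[1], r[2]))
    e, chrom, bp, side, _ = results[0]
    return Anchor(chrom, bp, side, e, unique=len(occ) == 1)


def _anchor_right(contig: str, index: ReferenceIndex) -> Anchor | None:
    """Anchor the right contig flank; extend the exact match leftward."""
    k = index.k
    if len(contig) < k:
        return None
    occ = index.occurrences(contig[-k:])
    if not occ:
        return None
    n = len(contig)
    results = []
    for chrom, p, strand in occ:
        ref = index.genome.seq(chrom)
        e = 0
        if strand == "+":
            while e < n and p + k - 1 - e >= 0 and contig[n - 1 - e] == ref[p + k - 1 - e]:
                e += 1
            results.append((e, chrom, p + k - e + 1, "head", strand))
        else:
            while e < n and p + e < len(ref) and contig[n - 1 - e] == revcomp(ref[p + e])[0]:
                e += 1
            results.append((e, chrom, p + e, "tail", strand))
    results.sort(key=lambda r: (-r[0], r[1], r[2]))
    e, chrom, bp, side, _ = results[0]
    return Anchor(chrom, bp, side, n - e, unique=len(occ) == 1)


def locate_breakpoints(
    contig: str, index: ReferenceIndex
) -> tuple[Anchor, Anchor, str, bool] | None:
    """Anchor both contig flanks to the reference.

    Returns (left anchor, right anchor, orientation_class, unique_mapping)
    or None when a flank finds no seed match. tail = the junction uses the
    3' end of the reference segment in its reported orientation; head =
    the 5' end.
    """
    if len(contig) < 2 * MIN_FLANK:
        return None
    left = _anchor_left(contig, index)
    right = _anchor_right(contig, index)
    if left is None or right is None:
        return None
    oclass, _ = _orientation_class(left.side, right.side)
    return left, right, oclass, left.unique and right.unique


def classify_repair(
    contig: str, left: Anchor, right: Anchor
) -> tuple[str, int, str]:
    """Repair chemistry from the two anchors' maximal extents.

    Overlapping anchors mean an identical motif flanks both reference
    breakpoints but appears once in the sample: microhomology, length =
    the overlap. A gap between anchors is untemplated inserted sequence.
    Exact abutment is a perfect (blunt) join. An insertion showing
    incidental homology is still an insertion.
    """
    p1 = left.contig_extent
    p2 = right.contig_extent
    if p2 < p1:
        return "microhomology", p1 - p2, ""
    if p2 > p1:
        return "insertion", 0, contig[p1:p2]
    return "perfect", 0, ""


# ---------------------------------------------------------------------------
# read gathering + top-level calling


class _ReadStore:
    """All primary reads of a SAM, per-chromosome, sorted by position."""

    def __init__(self, sam_path: str):
        data: dict[str, list[tuple[int, str]]] = {}
        with pysam.AlignmentFile(sam_path, "r") as sam:
            for rec in sam:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                data.setdefault(rec.reference_name, []).append(
                    (rec.reference_start, rec.query_sequence)
                )
        self.pos: dict[str, list[int]] = {}
        self.seq: dict[str, list[str]] = {}
        for chrom, rows in data.items():
            rows.sort(key=lambda r: r[0])
            self.pos[chrom] = [r[0] for r in rows]
            self.seq[chrom] = [r[1] for r in rows]

    def window(self, chrom: str, lo: int, hi: int) -> list[tuple[int, str]]:
        if chrom not in self.pos:
            return []
        i = bisect_left(self.pos[chrom], lo)
        j = bisect_right(self.pos[chrom], hi)
        return list(zip(self.pos[chrom][i:j], self.seq[chrom][i:j]))


def _chimeric_reads(
    store: _ReadStore,
    genome: SyntheticGenome,
    chrom: str,
    center: int,
    window: int,
    min_mismatch: int = CHIMERA_MIN_MISMATCH,
) -> list[str]:
    """Reads near center whose sequence disagrees with the reference at
    their mapped locus — the signature of a junction-crossing read."""
    ref = genome.seq(chrom)
    out = []
    for pos, seq in store.window(chrom, center - window, center + window):
        refpart = ref[pos : pos + len(seq)]
        mm = sum(a != b for a, b in zip(seq, refpart))
        if mm >= min_mismatch or len(refpart) < len(seq):
            out.append(seq)
    return out


def resolve_junction(
    evidence: JunctionEvidence,
    store: _ReadStore,
    index: ReferenceIndex,
    read_window: int = 300,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    side_tol: int = 1200,
    max_seeds: int = 30,
) -> JunctionCall | None:
    """Assemble and classify one evidence cluster; None if unresolved.

    The chimeric-read pool near a cluster can contain reads from a second
    junction sharing a fragment boundary, so assembly is retried from
    several seed reads until the anchored contig's breakpoints agree with
    the cluster's two sides (within side_tol of the distant-pair means).
    """
    reads = []
    for chrom, pos, _ in (evidence.side1, evidence.side2):
        reads.extend(
            _chimeric_reads(store, index.genome, chrom, int(pos), read_window)
        )
    reads = list(dict.fromkeys(reads))

    # an evidence side's strand encodes which segment end the junction
    # uses: flank reads mapping forward approach a tail (3') end, reverse
    # reads a head (5') end — this separates the two junctions of a
    # shared fragment corner, whose coordinates nearly coincide
    expected = [
        (s[0], s[1], "tail" if s[2] == "+" else "head")
        for s in (evidence.side1, evidence.side2)
    ]

    def consistent(a: Anchor, b: Anchor) -> bool:
        for x, y in ((a, b), (b, a)):
            if all(
                anc.chrom == exp[0]
                and abs(anc.bp - exp[1]) <= side_tol
                and anc.side == exp[2]
                for anc, exp in ((x, expected[0]), (y, expected[1]))
            ):
                return True
        return False

    for seed in reads[:max_seeds]:
        contig = assemble_contig(reads, min_overlap=min_overlap, seed=seed)
        if contig is None:
            continue
        located = locate_breakpoints(contig, index)
        if located is None:
            continue
        left, right, oclass, unique = located
        if min(left.contig_extent, len(contig) - right.contig_extent) < MIN_FLANK:
            continue
        if not consistent(left, right):
            continue
        repair, mh_len, ins_seq = classify_repair(contig, left, right)
        bp1 = (left.chrom, left.bp, left.side)
        bp2 = (right.chrom, right.bp, right.side)
        _, swapped = _orientation_class(left.side, right.side)
        if swapped or (bp2[:2] < bp1[:2] and left.side == right.side):
            bp1, bp2 = bp2, bp1
        return JunctionCall(
            bp1, bp2, oclass, repair, mh_len, ins_seq, contig,
            evidence.support, unique,
        )
    return None


def call_junctions(
    sample_sam: str,
    control_sams: list[str],
    genome: SyntheticGenome,
    min_distance: int = DEFAULT_MIN_DISTANCE,
    radius: int = DEFAULT_RADIUS,
    index: ReferenceIndex | None = None,
) -> tuple[list[JunctionCall], dict]:
    """Full junction-calling pipeline on one sample vs >= 1 controls.

    Returns reported calls (unique-mapping, resolved, support-filtered)
    plus a log dict with kept/dropped counts at each stage.
    """
    log: dict = {}
    pairs = find_distant_pairs(sample_sam, min_distance)
    log["distant_pairs"] = len(pairs)
    evidence = cluster_pairs(pairs, radius)
    log["clusters"] = len(evidence)
    ctrl_evidence = []
    ctrl_clusters = []
    for path in control_sams:
        ce = cluster_pairs(find_distant_pairs(path, min_distance), radius)
        ctrl_clusters.append(ce)
        ctrl_evidence.extend(ce)
    evidence = subtract_controls(
        evidence,
        ctrl_clusters[0] if ctrl_clusters else [],
        ctrl_clusters[1] if len(ctrl_clusters) > 1 else [],
        radius,
    )
    log["after_control_subtraction"] = len(evidence)
    model = SupportThresholdModel.fit(ctrl_evidence)
    log["min_support"] = model.min_support
    evidence = support_filter(evidence, model)
    log["after_support_filter"] = len(evidence)
    if index is None:
        index = ReferenceIndex(genome)
    store = _ReadStore(sample_sam)
    calls = []
    unresolved = 0
    nonunique = 0
    for ev in evidence:
        call = resolve_junction(ev, store, index)
        if call is None:
            unresolved += 1
        elif not call.unique_mapping:
            nonunique += 1
        else:
            calls.append(call)
    log["unresolved"] = unresolved
    log["non_unique_mapping"] = nonunique
    # two evidence clusters can resolve to the same junction (e.g. the
    # distant-pair clouds of two junctions at a shared fragment corner
    # overlap); merge identical calls, summing support
    merged: dict[tuple, JunctionCall] = {}
    for c in calls:
        key = (c.breakpoint1, c.breakpoint2, c.orientation_class)
        if key in merged:
            merged[key].support += c.support
        else:
            merged[key] = c
    calls = list(merged.values())
    log["reported_calls"] = len(calls)
    return calls, log


# ---------------------------------------------------------------------------
# summaries / io


def breakpoint_density(
    breakpoints: list[tuple[str, int]], region: tuple[str, int, int]
) -> float:
    """Mean breakpoint spacing in kb over region (1-based inclusive bounds).

    Breakpoints are counted individually (a junction contributes two when
    both fall inside the region)."""
    chrom, start, end = region
    if end <= start:
        raise ValueError("region length must be positive")
    n = sum(1 for c, p in breakpoints if c == chrom and start <= p <= end)
    if n == 0:
        raise ValueError("no breakpoints in region; spacing undefined")
    return (end - start + 1) / n / 1000


def calls_to_table(calls: list[JunctionCall]) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(calls):
        rows.append(
            {
                "junction_id": i,
                "chrom1": c.breakpoint1[0],
                "pos1": c.breakpoint1[1],
                "side1": c.breakpoint1[2],
                "chrom2": c.breakpoint2[0],
                "pos2": c.breakpoint2[1],
                "side2": c.breakpoint2[2],
                "orientation_class": c.orientation_class,
                "repair_class": c.repair_class,
                "mh_len": c.mh_len,
                "ins_seq": c.ins_seq,
                "support": c.support,
                "unique_mapping": c.unique_mapping,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "junction_id", "chrom1", "pos1", "side1", "chrom2", "pos2", "side2",
            "orientation_class", "repair_class", "mh_len", "ins_seq",
            "support", "unique_mapping",
        ],
    )


def write_bedpe(calls: list[JunctionCall], path: str) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(calls):
            c1, p1, _ = c.breakpoint1
            c2, p2, _ = c.breakpoint2
            fh.write(
                f"{c1}\t{p1 - 1}\t{p1}\t{c2}\t{p2 - 1}\t{p2}\t"
                f"junction_{i}\t{c.support}\t.\t.\n"
            )


def detectable_truth(truth, min_distance: int = DEFAULT_MIN_DISTANCE):
    """Truth junctions visible to the distant-pair criterion.

    A junction whose two breakpoints are closer than min_distance on the
    same chromosome (fragments that ended up reference-adjacent) produces
    no distant read pairs and is outside the method's target class.
    """
    return [
        j for j in truth
        if j.left_bp[0] != j.right_bp[0]
        or abs(j.left_bp[1] - j.right_bp[1]) > min_distance
    ]


def match_calls_to_truth(
    calls: list[JunctionCall], truth, tol: int = 5
) -> tuple[int, int, int, list[tuple]]:
    """Match calls against simulator truth junctions by breakpoint pairs.

    A call matches a truth junction if both breakpoint positions agree
    within tol bp (in either pairing order) with matching orientation
    class. Returns (n_matched_truth, n_truth, n_calls, matched pairs).
    """
    def bp_match(cb, tb):
        return cb[0] == tb[0] and cb[2] == tb[2] and abs(cb[1] - tb[1]) <= tol

    used = set()
    matched = []
    for call in calls:
        for ti, tj in enumerate(truth):
            if ti in used:
                continue
            tb1, tb2 = tj.left_bp, tj.right_bp
            cb1, cb2 = call.breakpoint1, call.breakpoint2
            # side labels disambiguate the two junctions of a shared
            # fragment corner, whose coordinates differ by only 1 bp
            direct = bp_match(cb1, tb1) and bp_match(cb2, tb2)
            flipped = bp_match(cb1, tb2) and bp_match(cb2, tb1)
            if (direct or flipped) and call.orientation_class == tj.orientation_class:
                used.add(ti)
                matched.append((call, tj))
                break
    return len(used), len(truth), len(calls), matched


def classification_matches(call: JunctionCall, truth) -> bool:
    """Repair class, microhomology length and inserted bases agree.

    A junction represented from the opposite strand carries the reverse
    complement of the inserted sequence; both are the same junction.
    """
    from .simulate import revcomp as _rc

    if call.repair_class != truth.repair_class or call.mh_len != truth.mh_len:
        return False
    return call.ins_seq in (truth.ins_seq, _rc(truth.ins_seq))
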