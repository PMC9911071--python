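"""Chain junction calls into reconstructed rearranged fragments.

Breakpoints partition the shattered region into segments; each junction
joins two specific segment ends (tail = 3' end, head = 5' end, in
reference orientation). Maximal simple paths through this graph, using
each segment end at most once, are the reconstructed fragments: ordered,
oriented runs of reference segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .junctions import JunctionCall

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentNode:
    chrom: str
    start: int  # 0-based half-open
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class JunctionEdge:
    junction: JunctionCall
    seg1: int  # segment indices
    end1: str  # head | tail
    seg2: int
    end2: str


@dataclass
class SegmentGraph:
    segments: list[SegmentNode]
    edges: list[JunctionEdge]


@dataclass
class FragmentChain:
    """An ordered, oriented run of reference segments joined by junctions."""

    entries: list[tuple[SegmentNode, str]]  # (segment, orientation + | -)
    junctions: list[JunctionCall]

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    def reversed_(self) -> "FragmentChain":
        flip = {"+": "-", "-": "+"}
        return FragmentChain(
            [(s, flip[o]) for s, o in reversed(self.entries)],
            list(reversed(self.junctions)),
        )


def build_segment_graph(
    calls: list[JunctionCall], region: tuple[str, int, int], snap_tol: int = 6
) -> SegmentGraph:
    """Segments between adjacent breakpoints; one edge per junction.

    region is (chrom, start, end), 0-based half-open. The two junctions
    that share a fragment corner report boundaries that can differ by a
    few bases (microhomology makes the exact cut ambiguous), so boundaries
    within snap_tol of each other are merged to a single segment edge.
    Junctions with a breakpoint outside the region get ad-hoc segment
    nodes for that side rather than triggering whole-genome segmentation;
    junctions on other chromosomes are attached via ad-hoc nodes too.
    """
    chrom, rstart, rend = region
    # a tail breakpoint p (1-based last base) puts the half-open boundary at
    # p; a head breakpoint p (first base) puts it at p - 1
    def clamp(b: int) -> int:
        # a breakpoint within snap_tol of the region edge is the edge
        if abs(b - rstart) <= snap_tol:
            return rstart
        if abs(b - rend) <= snap_tol:
            return rend
        return b

    raw = sorted(
        {
            clamp(p if side == "tail" else p - 1)
            for c in calls
            for (ch, p, side) in (c.breakpoint1, c.breakpoint2)
            if ch == chrom
            and rstart < clamp(p if side == "tail" else p - 1) < rend
        }
    )
    snap: dict[int, int] = {}
    bps = []
    for b in raw:
        if bps and b - bps[-1] <= snap_tol:
            snap[b] = bps[-1]
        else:
            bps.append(b)
            snap[b] = b
    bounds = [rstart, *bps, rend]
    segments = [
        SegmentNode(chrom, bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)
    ]
    seg_index: dict[tuple[str, int, int], int] = {
        (s.chrom, s.start, s.end): i for i, s in enumerate(segments)
    }

    def locate(ch: str, pos1: int, side: str) -> int:
        """Segment index whose end at `side` sits at breakpoint pos1."""
        boundary = pos1 if side == "tail" else pos1 - 1
        if ch == chrom:
            boundary = clamp(boundary)
        if ch == chrom and rstart <= boundary <= rend:
            boundary = snap.get(boundary, boundary)
            if side == "tail":
                for i, s in enumerate(segments):
                    if s.end == min(boundary, rend):
                        return i
            else:
                for i, s in enumerate(segments):
                    if s.start == max(boundary, rstart):
                        return i
        # ad-hoc node outside the segmented region
        pos = pos1 - 1
        key = (ch, pos, pos + 1)
        if key not in seg_index:
            seg_index[key] = len(segments)
            segments.append(SegmentNode(ch, pos, pos + 1))
        return seg_index[key]

    edges = []
    for call in calls:
        c1, p1, side1 = call.breakpoint1
        c2, p2, side2 = call.breakpoint2
        i1 = locate(c1, p1, side1)
        i2 = locate(c2, p2, side2)
        edges.append(JunctionEdge(call, i1, side1, i2, side2))
    return SegmentGraph(segments, edges)


def chain(graph: SegmentGraph) -> list[FragmentChain]:
    """Maximal simple paths under the one-junction-per-segment-end rule.

    When two edges claim the same segment end (possible with imperfect
    calls), the higher-support junction wins and the loser is logged.
    Cycles are broken at their lowest-support edge. Output is
    deterministic: chains sorted by leftmost reference coordinate then
    length, and each chain is normalized so its leftmost reference
    segment appears in '+' orientation.
    """
    used_ends: set[tuple[int, str]] = set()
    kept: list[JunctionEdge] = []
    for e in sorted(graph.edges, key=lambda e: -e.junction.support):
        ends = {(e.seg1, e.end1), (e.seg2, e.end2)}
        if len(ends) < 2 or ends & used_ends:
            logger.info(
                "dropping conflicting junction edge (support %d) at segments %s/%s",
                e.junction.support, e.seg1, e.seg2,
            )
            continue
        used_ends |= ends
        kept.append(e)

    # adjacency: segment end -> edge
    by_end: dict[tuple[int, str], JunctionEdge] = {}
    for e in kept:
        by_end[(e.seg1, e.end1)] = e
        by_end[(e.seg2, e.end2)] = e

    visited_edges: set[int] = set()
    chains: list[FragmentChain] = []

    def other_side(e: JunctionEdge, seg: int, end: str) -> tuple[int, str]:
        if (e.seg1, e.end1) == (seg, end):
            return e.seg2, e.end2
        return e.seg1, e.end1

    def walk(start_seg: int, enter_end: str | None) -> FragmentChain:
        """Walk from a segment, entering through enter_end (None = free)."""
        entries: list[tuple[SegmentNode, str]] = []
        junctions: list[JunctionCall] = []
        seg, enter = start_seg, enter_end
        while True:
            # orientation: entering through head means '+' (reads 5'->3'),
            # through tail means '-'
            orient = "+" if enter in (None, "head") else "-"
            entries.append((graph.segments[seg], orient))
            exit_end = (
                "tail" if orient == "+" else "head"
            )
            e = by_end.get((seg, exit_end))
            if e is None or id(e) in visited_edges:
                break
            visited_edges.add(id(e))
            junctions.append(e.junction)
            seg, enter = other_side(e, seg, exit_end)
        return FragmentChain(entries, junctions)

    # degree per segment: ends used
    seg_count = len(graph.segments)
    for seg in range(seg_count):
        for free_end in ("head", "tail"):
            # start walks at segments whose free_end has no edge (path tips)
            if (seg, free_end) in by_end:
                continue
            other = "tail" if free_end == "head" else "head"
            e = by_end.get((seg, other))
            if e is None:
                continue
            if id(e) in visited_edges:
                continue
            ch = walk(seg, free_end)
            if ch.n_junctions > 0:
                chains.append(ch)
            break
    # remaining edges belong to cycles: break at lowest support
    remaining = [e for e in kept if id(e) not in visited_edges]
    while remaining:
        weakest = min(remaining, key=lambda e: e.junction.support)
        visited_edges.add(id(weakest))
        logger.info("breaking cycle at junction with support %d", weakest.junction.support)
        seg, enter = weakest.seg2, weakest.end2
        ch = walk(seg, enter)
        if ch.n_junctions > 0:
            chains.append(ch)
        remaining = [e for e in kept if id(e) not in visited_edges]

    # singleton segments with no junctions are not reported as chains
    normalized = []
    for ch in chains:
        leftmost = min(range(len(ch.entries)), key=lambda i: (ch.entries[i][0].chrom, ch.entries[i][0].start))
        if ch.entries[leftmost][1] == "-":
            ch = ch.reversed_()
        normalized.append(ch)
    normalized.sort(
        key=lambda ch: (
            min((s.chrom, s.start) for s, _ in ch.entries),
            -ch.n_junctions,
        )
    )
    return normalized


def chains_equal(a: FragmentChain, b: FragmentChain, tol: int = 0) -> bool:
    """Comparator accepting whole-chain reversal as the same reconstruction.

    tol allows segment boundaries to differ by a few bases (junction-level
    breakpoint ambiguity at microhomology motifs)."""

    def same(x: FragmentChain, y: FragmentChain) -> bool:
        if len(x.entries) != len(y.entries):
            return False
        return all(
            sx.chrom == sy.chrom
            and abs(sx.start - sy.start) <= tol
            and abs(sx.end - sy.end) <= tol
            and ox == oy
            for (sx, ox), (sy, oy) in zip(x.entries, y.entries)
        )

    return same(a, b) or same(a, b.reversed_())


def chains_to_table(chains: list[FragmentChain]):
    import pandas as pd

    rows = []
    for ci, ch in enumerate(chains):
        for oi, (seg, orient) in enumerate(ch.entries):
            rows.append(
                {
                    "chain_id": ci,
                    "order_index": oi,
                    "chrom": seg.chrom,
                    "start": seg.start + 1,
                    "end": seg.end,
                    "orientation": orient,
                    "n_junctions": ch.n_junctions,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chain_id", "order_index", "chrom", "start", "end",
                 "orientation", "n_junctions"],
    )


def chain_diagram_svg(ch: FragmentChain, path: str, width: int = 900) -> None:
    """Minimal arrow diagram of one reconstructed fragment chain."""
    n = len(ch.entries)
    h = 60
    seg_w = (width - 40) / max(n, 1)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{h}">'
    ]
    for i, (seg, orient) in enumerate(ch.entries):
        x = 20 + i * seg_w
        y = 25
        x2 = x + seg_w * 0.8
        if orient == "-":
            x, x2 = x2, x
        parts.append(
            f'<line x1="{x:.0f}" y1="{y}" x2="{x2:.0f}" y2="{y}" '
            'stroke="black" stroke-width="3" marker-end="url(#a)"/>'
        )
        parts.append(
            f'<text x="{min(x, x2):.0f}" y="{y + 20}" font-size="9">'
            f"{seg.chrom}:{seg.start + 1}-{seg.end}</text>"
        )
    parts.insert(
        1,
        '<defs><marker id="a" markerWidth="8" markerHeight="8" refX="6" refY="3" '
        'orient="auto"><path d="M0,0 L6,3 L0,6 z"/></marker></defs>',
    )
    parts.append("</svg>")
    with open(path, "w") as fh:
        fh.write("".join(parts))
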