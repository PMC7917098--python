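"""Interval block maps for lifting coordinates across simulated genome edits.

A block ``(s0, s1, chrom, d0, d1, strand)`` maps source interval [s0, s1) to
destination interval [d0, d1) on ``chrom``; lengths are equal.  Strand ``+``
pairs s0 with d0; strand ``-`` pairs s0 with d1-1 (the block is reversed).
"""

from __future__ import annotations

from typing import NamedTuple


class Block(NamedTuple):
    s0: int
    s1: int
    chrom: str
    d0: int
    d1: int
    strand: str


def map_interval(block: Block, m0: int, m1: int) -> tuple[int, int]:
    """Destination sub-interval for source sub-interval [m0, m1) of `block`."""
    if not (block.s0 <= m0 <= m1 <= block.s1):
        raise ValueError("interval outside block")
    if block.strand == "+":
        return block.d0 + (m0 - block.s0), block.d0 + (m1 - block.s0)
    return block.d0 + (block.s1 - m1), block.d0 + (block.s1 - m0)


def compose(a_blocks: list[Block], b_blocks_by_chrom: dict[str, list[Block]]) -> list[Block]:
    """Compose src->mid blocks with mid->dst blocks (keyed by mid chromosome)."""
    out: list[Block] = []
    for a in a_blocks:
        for b in b_blocks_by_chrom.get(a.chrom, ()):
            m0, m1 = max(a.d0, b.s0), min(a.d1, b.s1)
            if m0 >= m1:
                continue
            # source piece of `a` whose image is [m0, m1)
            if a.strand == "+":
                s0, s1 = a.s0 + (m0 - a.d0), a.s0 + (m1 - a.d0)
            else:
                s0, s1 = a.s0 + (a.d1 - m1), a.s0 + (a.d1 - m0)
            d0, d1 = map_interval(b, m0, m1)
            strand = "+" if a.strand == b.strand else "-"
            out.append(Block(s0, s1, b.chrom, d0, d1, strand))
    out.sort(key=lambda bl: (bl.s0, bl.s1))
    return out


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and merged (touching ends merge)."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def complement_intervals(intervals: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    """Complement of a merged interval union within [0, length)."""
    out = []
    pos = 0
    for s, e in merge_intervals(intervals):
        s, e = max(0, s), min(length, e)
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < length:
        out.append((pos, length))
    return out


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/|a|, overlap/|b|); 0 for disjoint or empty intervals."""
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    la, lb = a[1] - a[0], b[1] - b[0]
    if la <= 0 or lb <= 0:
        return 0.0
    return min(ov / la, ov / lb)
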