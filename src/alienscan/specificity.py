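"""Chromosome-specific sequence discovery and marker selection.

The two-step procedure: (1) take the unaligned complement of the donor
genome against its whole-genome alignment with the recipient — donor
sequence with no counterpart in the recipient; (2) realign each candidate to
the full donor genome and keep only candidates whose every non-self hit lies
on the candidate's own chromosome.  Markers are then picked evenly along
each chromosome from the candidates above a length floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import edlib
import numpy as np

from .coords import complement_intervals
from .genome import Genome, revcomp
from .wga import (
    DEFAULT_MIN_SCORE,
    AlignedSegment,
    KmerIndex,
    _parse_cigar,
    build_kmer_index,
    canonical_codes,
)
from .genome import encode

DEFAULT_MIN_CANDIDATE_LENGTH = 28  # smallest specific sequence retained
DEFAULT_MARKER_MIN_LENGTH = 400
DEFAULT_SCREEN_K = 15


@dataclass(frozen=True)
class SpecificInterval:
    """A donor interval absent from the recipient and unique to one chromosome."""

    chrom: str
    start: int
    end: int
    n_self_hits_same_chrom: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class Marker:
    """A selected chromosome-specific marker with its placement metadata."""

    interval: SpecificInterval
    rank_in_chromosome: int
    bin_center_distance: float

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def unaligned_complement(
    segments: list[AlignedSegment],
    chromosome_lengths: dict[str, int],
    min_length: int = DEFAULT_MIN_CANDIDATE_LENGTH,
) -> list[tuple[str, int, int]]:
    """Per-chromosome complement of the aligned intervals.

    Aligned intervals are collected from whichever side of each segment
    (target or query) names a chromosome in ``chromosome_lengths``, merged,
    and complemented; pieces shorter than ``min_length`` are dropped.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {name: [] for name in chromosome_lengths}
    for s in segments:
        for chrom, lo, hi in ((s.tchrom, s.tstart, s.tend), (s.qchrom, s.qstart, s.qend)):
            if chrom not in by_chrom:
                continue
            if lo < 0 or hi > chromosome_lengths[chrom]:
                raise ValueError(f"segment [{lo},{hi}) outside chromosome {chrom}")
            by_chrom[chrom].append((lo, hi))
    out: list[tuple[str, int, int]] = []
    for chrom, length in chromosome_lengths.items():
        for lo, hi in complement_intervals(by_chrom[chrom], length):
            if hi - lo >= min_length:
                out.append((chrom, lo, hi))
    return out


def _local_score(ops: list[tuple[int, str]]) -> int:
    """Best local score along a fixed alignment path (run-level Kadane).

    Match runs contribute +n, mismatch runs -n, gap runs -(n+2); maximal
    local alignments start and end inside match runs, so run granularity
    loses nothing.
    """
    best = cur = 0
    for n, op in ops:
        if op == "=":
            cur += n
        elif op == "X":
            cur -= n
        else:
            cur -= n + 2
        cur = max(cur, 0)
        best = max(best, cur)
    return best


def _cluster_hits(tpos: np.ndarray, qpos: np.ndarray, plus: np.ndarray, gap: int = 100):
    """Group seed hits of one (chromosome, strand) into diagonal clusters."""
    diag = np.where(plus, tpos - qpos, tpos + qpos)
    order = np.lexsort((tpos, diag))
    clusters = []
    start = 0
    d = diag[order]
    for i in range(1, order.size + 1):
        if i == order.size or d[i] - d[i - 1] > gap:
            idx = order[start:i]
            clusters.append((tpos[idx], qpos[idx]))
            start = i
    return clusters


def screen_chromosome_uniqueness(
    candidates: list[tuple[str, int, int]],
    donor_genome: Genome,
    k: int = DEFAULT_SCREEN_K,
    min_score: int = DEFAULT_MIN_SCORE,
    index: KmerIndex | None = None,
) -> list[SpecificInterval]:
    """Keep candidates whose every strong hit lies on their own chromosome.

    Each candidate sequence is realigned to the full donor genome by seeding
    (no repeat suppression) and local extension; hits overlapping the
    candidate's own locus are ignored, and the candidate is retained iff
    every remaining hit scoring at least ``min_score`` sits on the
    candidate's own chromosome.  Duplications elsewhere on the same
    chromosome are permitted and counted.
    """
    if index is None:
        index = build_kmer_index(donor_genome, k)
    out: list[SpecificInterval] = []
    for chrom, start, end in candidates:
        seq = donor_genome.fetch(chrom, start, end)
        if len(seq) < index.k:
            continue
        canon, fwd_flag, valid = canonical_codes(encode(seq), index.k)
        pos = np.flatnonzero(valid)
        if pos.size == 0:
            continue
        canon = canon[pos]
        lo = np.searchsorted(index.codes, canon, "left")
        hi = np.searchsorted(index.codes, canon, "right")
        cnt = hi - lo
        total = int(cnt.sum())
        if total == 0:
            out.append(SpecificInterval(chrom, start, end, 0))
            continue
        base = np.repeat(lo, cnt)
        within = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
        tidx = base + within
        qpos = np.repeat(pos, cnt)
        qflag = np.repeat(fwd_flag[pos], cnt)
        tchrom = index.chrom_ids[tidx]
        tpos = index.offsets[tidx]
        plus = index.fwd_flags[tidx] == qflag

        keep_candidate = True
        n_self_same_chrom = 0
        for ci in np.unique(tchrom):
            cname = index.chrom_names[ci]
            m = tchrom == ci
            for strand_plus in (True, False):
                mm = m & (plus == strand_plus)
                if not mm.any():
                    continue
                for c_tpos, c_qpos in _cluster_hits(tpos[mm], qpos[mm], plus[mm]):
                    h_lo, h_hi = int(c_tpos.min()), int(c_tpos.max()) + index.k
                    if cname == chrom and h_lo < end and h_hi > start:
                        continue  # own locus
                    q_lo, q_hi = int(c_qpos.min()), int(c_qpos.max()) + index.k
                    pad = 50
                    qseq = seq[max(0, q_lo - pad) : q_hi + pad]
                    tseq = donor_genome.fetch(cname, h_lo - pad, h_hi + pad)
                    if not strand_plus:
                        qseq = revcomp(qseq)
                    res = edlib.align(qseq, tseq, mode="HW", task="path")
                    score = _local_score(_parse_cigar(res["cigar"])) if res["cigar"] else 0
                    if score >= min_score:
                        if cname == chrom:
                            n_self_same_chrom += 1
                        else:
                            keep_candidate = False
                if not keep_candidate:
                    break
            if not keep_candidate:
                break
        if keep_candidate:
            out.append(SpecificInterval(chrom, start, end, n_self_same_chrom))
    return out


def select_markers(
    specific: list[SpecificInterval],
    chromosome_lengths: dict[str, int],
    per_chromosome: int = 3,
    min_length: int = DEFAULT_MARKER_MIN_LENGTH,
) -> list[Marker]:
    """Pick ``per_chromosome`` evenly spaced markers per chromosome.

    Candidates strictly longer than ``min_length`` are eligible.  Each
    chromosome is split into ``per_chromosome`` equal bins; for each bin
    center the not-yet-chosen candidate whose midpoint is nearest is taken
    (ties go to the longer interval).  Chromosomes with fewer eligible
    candidates than bins yield fewer markers, with a warning.
    """
    if per_chromosome < 1:
        raise ValueError("per_chromosome must be >= 1")
    eligible: dict[str, list[SpecificInterval]] = {c: [] for c in chromosome_lengths}
    for iv in specific:
        if iv.length > min_length and iv.chrom in eligible:
            eligible[iv.chrom].append(iv)
    if not any(eligible.values()):
        warnings.warn("no eligible specific intervals; no markers selected")
        return []
    markers: list[Marker] = []
    for chrom, length in chromosome_lengths.items():
        cands = eligible[chrom]
        if len(cands) < per_chromosome:
            warnings.warn(
                f"{chrom}: only {len(cands)} candidate(s) longer than {min_length} bp "
                f"for {per_chromosome} marker bins"
            )
        used: set[tuple[int, int]] = set()
        for b in range(per_chromosome):
            center = (b + 0.5) * length / per_chromosome
            pool = [iv for iv in cands if (iv.start, iv.end) not in used]
            if not pool:
                break
            chosen = min(pool, key=lambda iv: (abs(iv.midpoint - center), -iv.length, iv.start))
            used.add((chosen.start, chosen.end))
            markers.append(Marker(chosen, rank_in_chromosome=b, bin_center_distance=abs(chosen.midpoint - center)))
    return markers


def find_specific_sequences(
    donor: Genome,
    segments: list[AlignedSegment],
    min_length: int = DEFAULT_MIN_CANDIDATE_LENGTH,
    k: int = DEFAULT_SCREEN_K,
    min_score: int = DEFAULT_MIN_SCORE,
) -> list[SpecificInterval]:
    """Both steps in one call: unaligned complement, then uniqueness screen."""
    candidates = unaligned_complement(segments, donor.lengths(), min_length=min_length)
    return screen_chromosome_uniqueness(candidates, donor, k=k, min_score=min_score)
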