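"""Nucleotide-level alignment summaries.

Aligned totals and fractions per genome, identity distributions of
one-to-one segments (with length-weighted and unweighted medians),
per-identity-interval length statistics, and species-specific totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coords import merge_intervals
from .genome import Genome
from .wga import AlignedSegment


@dataclass
class IdentityIntervalStat:
    low: float
    high: float
    n_segments: int
    total_length: int
    average_length: float


@dataclass
class AlignmentSummary:
    """Per-genome aligned/one-to-one totals plus identity means."""

    per_genome: dict[str, dict[str, float]] = field(default_factory=dict)
    mean_identity_weighted: float = 0.0
    mean_identity_unweighted: float = 0.0


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, cum[-1] / 2.0)])


def identity_distribution(
    segments: list[AlignedSegment], bin_width: float = 1.0
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Identity histogram over [0, 100] plus unweighted/length-weighted medians."""
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    if edges[-1] < 100.0:
        edges = np.append(edges, 100.0)
    if not segments:
        hist = pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:], "count": 0})
        return hist, {"median": float("nan"), "weighted_median": float("nan")}
    ident = np.array([s.identity for s in segments])
    spans = np.array([s.alignment_columns for s in segments])
    counts, _ = np.histogram(ident, bins=edges)
    hist = pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts})
    medians = {
        "median": float(np.median(ident)),
        "weighted_median": _weighted_median(ident, spans),
    }
    return hist, medians


def interval_length_stats(
    segments: list[AlignedSegment],
    interval_edges: list[float] | None = None,
) -> list[IdentityIntervalStat]:
    """Count, total and average query-side span per identity interval.

    Intervals are half-open [low, high) except the last, which includes its
    upper edge so that 100% identity is representable.
    """
    edges = list(interval_edges) if interval_edges is not None else [70, 75, 80, 85, 90, 95, 100]
    if sorted(edges) != edges or len(edges) < 2:
        raise ValueError("interval_edges must be ascending with >= 2 entries")
    for s in segments:
        if not 0.0 <= s.identity <= 100.0:
            raise ValueError(f"segment identity {s.identity} outside [0, 100]")
    out = []
    for i in range(len(edges) - 1):
        low, high = float(edges[i]), float(edges[i + 1])
        last = i == len(edges) - 2
        sel = [
            s
            for s in segments
            if (low <= s.identity < high) or (last and s.identity == high)
        ]
        total = sum(s.q_span for s in sel)
        out.append(
            IdentityIntervalStat(
                low=low,
                high=high,
                n_segments=len(sel),
                total_length=total,
                average_length=total / len(sel) if sel else 0.0,
            )
        )
    return out


def _union_bp(segments: list[AlignedSegment], genome: Genome) -> int:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in segments:
        if s.tchrom in genome:
            by_chrom.setdefault(s.tchrom, []).append((s.tstart, s.tend))
        if s.qchrom in genome:
            by_chrom.setdefault(s.qchrom, []).append((s.qstart, s.qend))
    return sum(e - s for ivs in by_chrom.values() for s, e in merge_intervals(ivs))


def genome_alignment_summary(
    segments: list[AlignedSegment],
    one_to_one_segments: list[AlignedSegment],
    genomes: dict[str, Genome],
    complements: dict[str, list[tuple[str, int, int]]] | None = None,
) -> AlignmentSummary:
    """Aligned bp/fractions per genome, identity means, species-specific bp.

    ``genomes`` maps a label (e.g. 'donor', 'recipient') to the genome;
    chromosome names decide which side of each segment belongs to which
    genome, so the two genomes must not share chromosome names.
    ``complements`` optionally supplies per-label unaligned interval lists
    whose total is reported as species-specific bp.
    """
    names_seen: set[str] = set()
    for label, g in genomes.items():
        overlap = names_seen & set(g.names)
        if overlap:
            raise ValueError(f"genomes share chromosome names: {sorted(overlap)}")
        names_seen |= set(g.names)
    for s in segments + one_to_one_segments:
        if not any(s.tchrom in g for g in genomes.values()) or not any(
            s.qchrom in g for g in genomes.values()
        ):
            raise ValueError(f"segment references unknown chromosomes: {s.tchrom}/{s.qchrom}")

    summary = AlignmentSummary()
    cols = np.array([s.alignment_columns for s in one_to_one_segments], dtype=float)
    idents = np.array([s.identity for s in one_to_one_segments], dtype=float)
    if cols.size:
        summary.mean_identity_weighted = float((idents * cols).sum() / cols.sum())
        summary.mean_identity_unweighted = float(idents.mean())
    for label, g in genomes.items():
        total = g.total_length
        aligned = _union_bp(segments, g)
        o2o = _union_bp(one_to_one_segments, g)
        entry = {
            "genome_length": float(total),
            "aligned_bp": float(aligned),
            "aligned_fraction": aligned / total if total else 0.0,
            "one_to_one_bp": float(o2o),
            "one_to_one_fraction": o2o / total if total else 0.0,
        }
        if complements is not None and label in complements:
            entry["species_specific_bp"] = float(sum(e - s for _, s, e in complements[label]))
        summary.per_genome[label] = entry
    return summary
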