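"""Alien chromosome detection from low-depth resequencing reads.

Reads are subsampled to ~2x depth, best-hit aligned to the donor genome,
and labelled donor-origin when the best hit exceeds both classification
thresholds (alignment length strictly greater than 145 bp and identity
strictly above 99%).  Donor-origin read starts are counted in 1 Mb sliding
windows advanced by 10 kb, and a donor chromosome is called present when a
majority of its windows are supported by a sustained, contiguous signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome
from .synthetic import ReadSet
from .wga import DEFAULT_READ_K, KmerIndex, build_kmer_index, align_reads

DEFAULT_WINDOW = 1_000_000
DEFAULT_STEP = 10_000


@dataclass
class ClassificationParams:
    """Thresholds for donor-origin read classification (strict inequalities)."""

    min_aligned_length: int = 145
    min_identity: float = 99.0
    target_depth: float = 2.0
    read_length: int = 150

    def __post_init__(self) -> None:
        if not 0 < self.min_aligned_length <= self.read_length:
            raise ValueError("0 < min_aligned_length <= read_length required")
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")


@dataclass
class ChromosomeCall:
    present: bool
    fraction_supported_windows: float
    longest_supported_run: int
    n_windows: int
    mean_count: float
    expected_count: float


@dataclass
class CallReport:
    """Per-chromosome presence calls plus the audit statistics behind them."""

    per_chromosome: dict[str, ChromosomeCall] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def called(self) -> set[str]:
        return {c for c, r in self.per_chromosome.items() if r.present}

    def to_dict(self) -> dict:
        return {
            "called": sorted(self.called),
            "params": self.params,
            "chromosomes": {
                c: {
                    "present": r.present,
                    "fraction_supported_windows": r.fraction_supported_windows,
                    "longest_supported_run": r.longest_supported_run,
                    "n_windows": r.n_windows,
                    "mean_count": r.mean_count,
                    "expected_count": r.expected_count,
                }
                for c, r in self.per_chromosome.items()
            },
        }


def subsample_reads(
    reads: ReadSet,
    target_depth: float,
    genome_size: int,
    read_length: int,
    seed: int = 0,
) -> ReadSet:
    """Uniform sample without replacement to ~``target_depth`` coverage."""
    if target_depth <= 0:
        raise ValueError("target_depth must be > 0")
    if len(reads) == 0:
        warnings.warn("empty read set")
        return ReadSet()
    n = int(round(target_depth * genome_size / read_length))
    if n >= len(reads):
        if n > len(reads):
            warnings.warn(f"requested {n} reads but only {len(reads)} available; returning all")
        return ReadSet(list(reads.names), list(reads.sequences))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=n, replace=False))
    return ReadSet([reads.names[i] for i in idx], [reads.sequences[i] for i in idx])


def classify_reads(hits, params: ClassificationParams | None = None) -> pd.DataFrame:
    """Label best hits donor-origin by the >145 bp / >99% rule.

    ``hits`` is the best-hit table from `align_reads` (one row per read), or
    a list of ReadHit records.  Returns the table with a ``donor_origin``
    boolean column.
    """
    params = params or ClassificationParams()
    if not isinstance(hits, pd.DataFrame):
        hits = pd.DataFrame(
            {
                "read_id": [h.read_id for h in hits],
                "chrom": [h.chrom for h in hits],
                "start": [h.start for h in hits],
                "end": [h.end for h in hits],
                "strand": [h.strand for h in hits],
                "aligned_length": [h.aligned_length for h in hits],
                "matches": [h.matches for h in hits],
                "identity": [h.identity for h in hits],
                "score": [h.score for h in hits],
            }
        )
    out = hits.copy()
    out["donor_origin"] = (out["aligned_length"] > params.min_aligned_length) & (
        out["identity"] > params.min_identity
    )
    return out


def window_counts(
    classified: pd.DataFrame,
    chromosome_lengths: dict[str, int],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> pd.DataFrame:
    """Donor-origin read starts counted in sliding windows.

    One row per (chromosome, window start) for every start 0, step, 2*step,
    ... below the chromosome length, including final truncated windows
    (flagged, with their effective end recorded).
    """
    if not (window >= step > 0):
        raise ValueError("window >= step > 0 required")
    donor = classified[classified["donor_origin"]]
    rows = []
    for chrom, length in chromosome_lengths.items():
        starts = np.arange(0, length, step, dtype=np.int64)
        rstarts = np.sort(donor.loc[donor["chrom"] == chrom, "start"].to_numpy())
        counts = np.searchsorted(rstarts, starts + window, "left") - np.searchsorted(rstarts, starts, "left")
        ends = starts + window
        eff_ends = np.minimum(ends, length)
        for ws, we, ee, c in zip(starts, ends, eff_ends, counts):
            rows.append((chrom, int(ws), int(we), int(ee), bool(we > length), int(c)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "effective_end", "truncated", "count"])


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def call_alien_chromosomes(
    profiles: pd.DataFrame,
    params: ClassificationParams | None = None,
    depth: float | None = None,
    support_fraction: float = 0.25,
    window_fraction: float = 0.5,
    run_fraction: float = 0.5,
    chromosomes: list[str] | None = None,
) -> CallReport:
    """Presence calls from window profiles.

    A window is supported when its count reaches ``support_fraction`` of the
    expected donor-origin read count for that window; the expectation is
    depth * effective_window_span / read_length, so truncated windows are
    judged against their actual span.  A chromosome is called present when
    at least ``window_fraction`` of its windows are supported and the
    longest contiguous supported run covers at least ``run_fraction`` of
    them.
    """
    params = params or ClassificationParams()
    depth = params.target_depth if depth is None else depth
    if chromosomes is not None:
        missing = set(chromosomes) - set(profiles["chrom"])
        if missing:
            raise ValueError(f"profiles missing chromosomes: {sorted(missing)}")
    report = CallReport(
        params={
            "depth": depth,
            "read_length": params.read_length,
            "support_fraction": support_fraction,
            "window_fraction": window_fraction,
            "run_fraction": run_fraction,
        }
    )
    for chrom, grp in profiles.groupby("chrom", sort=True):
        counts = grp["count"].to_numpy()
        spans = (grp["effective_end"] - grp["start"]).to_numpy()
        expected = depth * spans / params.read_length
        supported = counts >= support_fraction * expected
        frac = float(supported.mean()) if supported.size else 0.0
        run = _longest_run(supported)
        present = frac >= window_fraction and run >= run_fraction * supported.size
        report.per_chromosome[str(chrom)] = ChromosomeCall(
            present=bool(present),
            fraction_supported_windows=frac,
            longest_supported_run=int(run),
            n_windows=int(supported.size),
            mean_count=float(counts.mean()) if counts.size else 0.0,
            expected_count=float(expected.mean()) if expected.size else 0.0,
        )
    return report


def detect_alien_chromosomes(
    donor: Genome,
    reads: ReadSet,
    params: ClassificationParams | None = None,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    sampled_genome_size: int | None = None,
    seed: int = 0,
    index: KmerIndex | None = None,
    seed_k: int = DEFAULT_READ_K,
) -> tuple[CallReport, pd.DataFrame, pd.DataFrame]:
    """Full detection pass: subsample, align, classify, window, call.

    ``sampled_genome_size`` is the size of the genome the reads were drawn
    from (recipient plus any alien chromosomes); when omitted the read set
    is used as-is without depth subsampling.  Returns the call report, the
    window profiles, and the classified best-hit table.
    """
    params = params or ClassificationParams()
    if sampled_genome_size is not None:
        reads = subsample_reads(
            reads, params.target_depth, sampled_genome_size, params.read_length, seed=seed
        )
    if index is None:
        index = build_kmer_index(donor, seed_k)
    hits = align_reads(index, donor, reads.names, reads.sequences, seed_k=index.k)
    classified = classify_reads(hits, params)
    profiles = window_counts(classified, donor.lengths(), window=window, step=step)
    report = call_alien_chromosomes(profiles, params, chromosomes=donor.names)
    return report, profiles, classified
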