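"""Pipeline configuration and the end-to-end driver.

One YAML-able config object carries every stage parameter; `run_pipeline`
executes simulate -> whole-genome alignment -> specific-sequence discovery
-> marker selection -> per-line detection -> summaries, writing standard
formats plus a manifest (config, seeds, version, config hash) sufficient to
reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .compstats import genome_alignment_summary, identity_distribution, interval_length_stats
from .genome import Genome
from .introgression import (
    ClassificationParams,
    call_alien_chromosomes,
    classify_reads,
    subsample_reads,
    window_counts,
)
from .io import (
    read_fasta,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_fastq,
    write_json,
    write_ortholog_map_tsv,
    write_paf,
    write_segments_tsv,
    write_tsv,
)
from .specificity import (
    DEFAULT_MARKER_MIN_LENGTH,
    DEFAULT_MIN_CANDIDATE_LENGTH,
    screen_chromosome_uniqueness,
    select_markers,
    unaligned_complement,
)
from .synthetic import (
    EvolutionParams,
    GenomeSpec,
    ReadSimParams,
    make_fusion_plan,
    make_species_pair,
    simulate_aal_reads,
)
from .wga import (
    DEFAULT_GENOME_K,
    DEFAULT_MAX_GAP,
    DEFAULT_MIN_ANCHORS,
    DEFAULT_MIN_SCORE,
    DEFAULT_READ_K,
    DEFAULT_SPLIT_GAP,
    align_genomes,
    align_reads,
    build_kmer_index,
    filter_one_to_one,
)

logger = logging.getLogger("alienscan")


@dataclass
class PipelineConfig:
    """All stage parameters; validated before any stage runs."""

    # inputs (paths) or simulation
    donor_fasta: str | None = None
    recipient_fasta: str | None = None
    simulate: bool = True
    seed: int = 0
    # simulated study dimensions
    n_chromosomes: int = 12
    chromosome_length: int = 500_000
    n_recipient_chromosomes: int = 7
    substitution_rate: float = 0.0845
    indel_rate: float = 0.001
    specific_insertions: int = 200
    insertion_length_range: tuple[int, int] = (400, 5000)
    # simulated AAL lines: mapping line name -> list of added donor chromosomes
    lines: dict[str, list[str]] = field(default_factory=lambda: {"AAL01": ["chrH06", "chrH09"]})
    # whole-genome alignment
    genome_k: int = DEFAULT_GENOME_K
    max_gap: int = DEFAULT_MAX_GAP
    min_anchors: int = DEFAULT_MIN_ANCHORS
    split_gap: int = DEFAULT_SPLIT_GAP
    # specific sequences and markers
    min_candidate_length: int = DEFAULT_MIN_CANDIDATE_LENGTH
    marker_min_length: int = DEFAULT_MARKER_MIN_LENGTH
    markers_per_chromosome: int = 3
    hit_score_threshold: int = DEFAULT_MIN_SCORE
    screen_k: int = 15
    # read classification / windowing
    read_k: int = DEFAULT_READ_K
    min_aligned_length: int = 145
    min_identity: float = 99.0
    depth: float = 2.0
    read_length: int = 150
    error_rate: float = 0.005
    window: int = 1_000_000
    step: int = 10_000
    support_fraction: float = 0.25
    window_fraction: float = 0.5
    run_fraction: float = 0.5

    def validate(self) -> None:
        if not self.simulate:
            for p, label in ((self.donor_fasta, "donor_fasta"), (self.recipient_fasta, "recipient_fasta")):
                if p is None:
                    raise ValueError(f"{label} required when simulate is false")
                if not Path(p).exists():
                    raise ValueError(f"{label} not found: {p}")
        if self.window < self.step or self.step <= 0:
            raise ValueError("window >= step > 0 required")
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")
        if self.depth <= 0 or self.read_length <= 0:
            raise ValueError("depth and read_length must be positive")
        if self.genome_k < 2 or self.read_k < 2 or self.screen_k < 2:
            raise ValueError("k sizes must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _stage(name: str):
    logger.info("stage %s", name)
    return time.time()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage and write all artifacts under ``outdir``.

    Returns the manifest (also written as manifest.json).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "version": __version__,
        "stages": {},
    }

    t = _stage("simulate")
    if config.simulate:
        spec = GenomeSpec(
            config.n_chromosomes,
            [config.chromosome_length] * config.n_chromosomes,
            seed=config.seed,
        )
        donor_names = [spec.name_template.format(i + 1) for i in range(config.n_chromosomes)]
        evo = EvolutionParams(
            substitution_rate=config.substitution_rate,
            indel_rate=config.indel_rate,
            specific_insertion_count=config.specific_insertions,
            specific_insertion_length_range=tuple(config.insertion_length_range),
            fusion_plan=make_fusion_plan(donor_names, config.n_recipient_chromosomes),
            seed=config.seed + 1,
        )
        pair = make_species_pair(spec, evo)
        donor, recipient, truth = pair.donor, pair.recipient, pair.truth
        write_fasta(donor, outdir / "donor.fa")
        write_fasta(recipient, outdir / "recipient.fa")
        write_bed(truth.specific_regions, outdir / "truth_specific.bed")
        write_ortholog_map_tsv(truth.ortholog_map, outdir / "truth_ortholog_map.tsv")
    else:
        donor = read_fasta(config.donor_fasta)
        recipient = read_fasta(config.recipient_fasta)
        truth = None
    manifest["stages"]["simulate"] = round(time.time() - t, 2)

    t = _stage("wga")
    segments = align_genomes(
        donor,
        recipient,
        k=config.genome_k,
        max_gap=config.max_gap,
        min_anchors=config.min_anchors,
        split_gap=config.split_gap,
    )
    one2one = filter_one_to_one(segments)
    write_paf(one2one, outdir / "alignment.one2one.paf", donor.lengths(), recipient.lengths())
    write_segments_tsv(segments, outdir / "alignment.tsv")
    manifest["stages"]["wga"] = round(time.time() - t, 2)

    t = _stage("specific")
    candidates = unaligned_complement(segments, donor.lengths(), min_length=config.min_candidate_length)
    specific = screen_chromosome_uniqueness(
        candidates, donor, k=config.screen_k, min_score=config.hit_score_threshold
    )
    write_bed(specific, outdir / "specific.bed")
    manifest["stages"]["specific"] = round(time.time() - t, 2)

    t = _stage("markers")
    markers = select_markers(
        specific,
        donor.lengths(),
        per_chromosome=config.markers_per_chromosome,
        min_length=config.marker_min_length,
    )
    write_bed(markers, outdir / "markers.bed")
    marker_seqs = Genome(
        {f"{m.chrom}:{m.start}-{m.end}": donor.fetch(m.chrom, m.start, m.end) for m in markers}
    )
    write_fasta(marker_seqs, outdir / "markers.fa")
    import pandas as pd

    rows = []
    for chrom in donor.names:
        rows.append(
            {
                "chrom": chrom,
                "n_candidates": sum(1 for c, _, _ in candidates if c == chrom),
                "n_specific": sum(1 for iv in specific if iv.chrom == chrom),
                "n_over_marker_length": sum(
                    1 for iv in specific if iv.chrom == chrom and iv.length > config.marker_min_length
                ),
                "n_markers": sum(1 for m in markers if m.chrom == chrom),
            }
        )
    write_tsv(pd.DataFrame(rows), outdir / "specific_summary.tsv")
    manifest["stages"]["markers"] = round(time.time() - t, 2)

    t = _stage("detect")
    cls_params = ClassificationParams(
        min_aligned_length=config.min_aligned_length,
        min_identity=config.min_identity,
        target_depth=config.depth,
        read_length=config.read_length,
    )
    read_index = build_kmer_index(donor, config.read_k)
    calls: dict[str, dict] = {}
    if config.simulate:
        for li, (line, added) in enumerate(sorted(config.lines.items())):
            rparams = ReadSimParams(
                read_length=config.read_length,
                depth=config.depth,
                error_rate=config.error_rate,
                seed=config.seed + 101 + li,
            )
            reads, rtruth = simulate_aal_reads(recipient, donor, set(added), rparams)
            write_fastq(reads, outdir / f"{line}.fq")
            genome_size = recipient.total_length + sum(len(donor[c]) for c in added)
            reads = subsample_reads(reads, config.depth, genome_size, config.read_length, seed=config.seed)
            hits = align_reads(read_index, donor, reads.names, reads.sequences)
            classified = classify_reads(hits, cls_params)
            profiles = window_counts(classified, donor.lengths(), window=config.window, step=config.step)
            report = call_alien_chromosomes(
                profiles,
                cls_params,
                support_fraction=config.support_fraction,
                window_fraction=config.window_fraction,
                run_fraction=config.run_fraction,
                chromosomes=donor.names,
            )
            write_bedgraph(profiles, outdir / f"{line}.windows.bedgraph")
            write_tsv(profiles, outdir / f"{line}.windows.tsv")
            calls[line] = {"truth": sorted(added), "report": report.to_dict()}
    write_json(calls, outdir / "call_reports.json")
    manifest["stages"]["detect"] = round(time.time() - t, 2)

    t = _stage("summarize")
    complements = {
        "donor": unaligned_complement(segments, donor.lengths(), min_length=0),
        "recipient": unaligned_complement(segments, recipient.lengths(), min_length=0),
    }
    summary = genome_alignment_summary(
        segments, one2one, {"donor": donor, "recipient": recipient}, complements
    )
    hist, medians = identity_distribution(one2one)
    write_tsv(hist, outdir / "identity_histogram.tsv")
    stats = interval_length_stats(one2one)
    write_tsv(
        pd.DataFrame(
            {
                "identity_low": [s.low for s in stats],
                "identity_high": [s.high for s in stats],
                "n_segments": [s.n_segments for s in stats],
                "total_length": [s.total_length for s in stats],
                "average_length": [round(s.average_length, 1) for s in stats],
            }
        ),
        outdir / "identity_interval_stats.tsv",
    )
    write_json(
        {"per_genome": summary.per_genome,
         "mean_identity_weighted": summary.mean_identity_weighted,
         "mean_identity_unweighted": summary.mean_identity_unweighted,
         "medians": medians},
        outdir / "alignment_summary.json",
    )
    manifest["stages"]["summarize"] = round(time.time() - t, 2)

    write_json(manifest, outdir / "manifest.json")
    return manifest
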