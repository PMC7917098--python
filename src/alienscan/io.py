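"""File formats: FASTA/FASTQ via Biopython, plus BED, PAF, bedGraph, TSV, JSON.

All coordinate-bearing outputs are 0-based half-open.  Numeric formatting is
locale-independent.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .genome import Genome
from .synthetic import ReadSet
from .wga import AlignedSegment


def read_fasta(path) -> Genome:
    """Load a FASTA file; headers cut at first whitespace, sequence uppercased."""
    path = Path(path)
    seqs: dict[str, str] = {}
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            name = header.split()[0] if header.split() else header
            if name in seqs:
                raise ValueError(f"duplicate sequence name {name!r} in {path}")
            seqs[name] = seq.upper()
    if not seqs:
        warnings.warn(f"{path}: no sequences found")
    return Genome(seqs)


def write_fasta(genome: Genome, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> ReadSet:
    reads = ReadSet()
    with open(path) as fh:
        for name, seq, qual in FastqGeneralIterator(fh):
            if len(seq) != len(qual):
                raise ValueError(f"{path}: sequence/quality length mismatch for {name}")
            reads.names.append(name.split()[0])
            reads.sequences.append(seq.upper())
    return reads


def write_fastq(reads: ReadSet, path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for name, seq in zip(reads.names, reads.sequences):
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_bed(intervals, path, names=None, scores=None) -> None:
    """BED6; intervals are (chrom, start, end) triples or objects with those fields.

    Default name is chrom:start-end and default score the interval length.
    """
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            chrom, start, end = (
                (iv.chrom, iv.start, iv.end) if hasattr(iv, "chrom") else (iv[0], iv[1], iv[2])
            )
            name = names[i] if names else f"{chrom}:{start}-{end}"
            score = scores[i] if scores else end - start
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t+\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith(("#", "track", "browser")):
                f = line.split("\t")
                out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_paf(
    segments: list[AlignedSegment],
    path,
    target_lengths: dict[str, int],
    query_lengths: dict[str, int],
) -> None:
    """Standard 12-column PAF (query first), mapq fixed at 255."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        s.qchrom,
                        query_lengths[s.qchrom],
                        s.qstart,
                        s.qend,
                        s.strand,
                        s.tchrom,
                        target_lengths[s.tchrom],
                        s.tstart,
                        s.tend,
                        s.matches,
                        s.alignment_columns,
                        255,
                    )
                )
                + "\n"
            )


def write_segments_tsv(segments: list[AlignedSegment], path) -> None:
    df = pd.DataFrame(
        {
            "target_chrom": [s.tchrom for s in segments],
            "target_start": [s.tstart for s in segments],
            "target_end": [s.tend for s in segments],
            "query_chrom": [s.qchrom for s in segments],
            "query_start": [s.qstart for s in segments],
            "query_end": [s.qend for s in segments],
            "strand": [s.strand for s in segments],
            "matches": [s.matches for s in segments],
            "alignment_columns": [s.alignment_columns for s in segments],
            "identity": [round(s.identity, 4) for s in segments],
            "score": [s.score for s in segments],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_bedgraph(profiles: pd.DataFrame, path) -> None:
    """Window counts as bedGraph rows (chrom, start, effective end, count)."""
    with open(path, "w") as fh:
        for row in profiles.itertuples():
            fh.write(f"{row.chrom}\t{row.start}\t{row.effective_end}\t{row.count}\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, set):
        return sorted(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_ortholog_map_tsv(ortholog_map, path) -> None:
    df = pd.DataFrame(
        ortholog_map,
        columns=["donor_chrom", "d_start", "d_end", "recip_chrom", "r_start", "r_end", "strand"],
    )
    df.to_csv(path, sep="\t", index=False)
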