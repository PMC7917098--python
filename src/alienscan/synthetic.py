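"""Synthetic genome-pair and resequencing-read simulator.

Emulates the data structure the downstream analysis assumes: a 12-chromosome
donor and a 7-chromosome recipient related by chromosome fusions, ~91.5%
nucleotide identity in alignable regions (all divergence placed on the
recipient branch), donor-only insertions that share no 21-mer with the
recipient, and 150 bp paired reads at ~2x depth drawn from recipient +
introgressed donor chromosomes with uniform per-base sequencing error.

Every operation is deterministic given its seed; truth tables record the
orthologous interval correspondence, the final coordinates of the planted
donor-specific insertions, and the true source of every simulated read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coords import Block, compose
from .genome import Genome, decode, encode, revcomp_codes

# -- parameter objects -------------------------------------------------------


@dataclass
class GenomeSpec:
    """Ancestor genome dimensions: chromosome count, lengths, base composition."""

    n_chromosomes: int
    chromosome_lengths: list[int]
    gc_fraction: float = 0.35
    seed: int = 0
    name_template: str = "chrH{:02d}"

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ValueError("chromosome_lengths must have n_chromosomes entries")
        if any(l <= 0 for l in self.chromosome_lengths):
            raise ValueError("all chromosome lengths must be > 0")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")


@dataclass
class EvolutionParams:
    """Divergence model between the simulated species pair.

    Substitutions are uniform over sites with a uniform alternative base;
    indels have geometric lengths with the stated mean and are applied after
    substitutions.  ``fusion_plan`` maps each recipient chromosome to the
    ordered, oriented donor chromosomes concatenated to form it and must
    cover every donor chromosome exactly once.
    """

    substitution_rate: float = 0.0845
    indel_rate: float = 0.001
    indel_length_mean: float = 3.0
    specific_insertion_count: int = 200
    specific_insertion_length_range: tuple[int, int] = (400, 5000)
    fusion_plan: dict[str, list[tuple[str, str]]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        lo, hi = self.specific_insertion_length_range
        if lo > hi or lo < 1:
            raise ValueError("insertion length range must satisfy 1 <= min <= max")
        if self.indel_length_mean < 1:
            raise ValueError("indel_length_mean must be >= 1")


@dataclass
class ReadSimParams:
    """Read simulation: 150 bp pairs at ~2x depth with uniform error."""

    read_length: int = 150
    depth: float = 2.0
    error_rate: float = 0.005
    paired: bool = True
    insert_size_mean: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.paired and self.insert_size_mean < self.read_length:
            raise ValueError("insert_size_mean must be >= read_length for pairs")


@dataclass
class TruthTables:
    """Ground truth recorded by the simulator for downstream validation.

    ortholog_map rows: (donor_chrom, d_start, d_end, recip_chrom, r_start,
    r_end, strand), 0-based half-open.  specific_regions rows:
    (donor_chrom, start, end).  read_sources rows: (read_id, chrom, start).
    """

    ortholog_map: list[tuple[str, int, int, str, int, int, str]] = field(default_factory=list)
    specific_regions: list[tuple[str, int, int]] = field(default_factory=list)
    introgressed_chromosomes: set[str] = field(default_factory=set)
    read_sources: list[tuple[str, str, int]] = field(default_factory=list)


@dataclass
class ReadSet:
    """In-memory read collection; names and sequences are parallel lists."""

    names: list[str] = field(default_factory=list)
    sequences: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.names)


def default_genome_spec(seed: int = 0) -> GenomeSpec:
    """Study-scale donor karyotype: 12 chromosomes of 500 kb."""
    return GenomeSpec(12, [500_000] * 12, gc_fraction=0.35, seed=seed)


def make_fusion_plan(
    donor_names: list[str],
    n_recipient: int,
    name_template: str = "chrC{:02d}",
) -> dict[str, list[tuple[str, str]]]:
    """Pairwise fusion plan reducing ``len(donor_names)`` chromosomes to
    ``n_recipient``: the first fusions merge consecutive pairs (the second
    member reverse-complemented in every other fusion), the rest stay
    singletons."""
    n = len(donor_names)
    n_fusions = n - n_recipient
    if not 0 <= n_fusions <= n // 2:
        raise ValueError("need n/2 <= n_recipient <= n")
    plan: dict[str, list[tuple[str, str]]] = {}
    di = 0
    for ri in range(n_recipient):
        out = name_template.format(ri + 1)
        if ri < n_fusions:
            orient = "-" if ri % 2 == 0 else "+"
            plan[out] = [(donor_names[di], "+"), (donor_names[di + 1], orient)]
            di += 2
        else:
            plan[out] = [(donor_names[di], "+")]
            di += 1
    return plan


# study karyotype: 12 donor chromosomes fused down to 7 recipient chromosomes
DEFAULT_FUSION_PLAN: dict[str, list[tuple[str, str]]] = make_fusion_plan(
    [f"chrH{i:02d}" for i in range(1, 13)], 7
)


def default_evolution_params(seed: int = 0) -> EvolutionParams:
    return EvolutionParams(fusion_plan=dict(DEFAULT_FUSION_PLAN), seed=seed)


# -- operations ---------------------------------------------------------------


def simulate_ancestor(spec: GenomeSpec) -> Genome:
    """Draw an i.i.d. ancestor genome at the requested GC fraction."""
    rng = np.random.default_rng(spec.seed)
    at, gc = (1.0 - spec.gc_fraction) / 2.0, spec.gc_fraction / 2.0
    probs = np.array([at, gc, gc, at])  # A C G T
    seqs: dict[str, str] = {}
    for i, length in enumerate(spec.chromosome_lengths):
        name = spec.name_template.format(i + 1)
        seqs[name] = decode(rng.choice(4, size=length, p=probs).astype(np.uint8))
    return Genome(seqs)


def _apply_substitutions(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return codes.copy()
    out = codes.copy()
    hit = (rng.random(codes.size) < rate) & (codes < 4)
    n = int(hit.sum())
    # uniform alternative base: shift by 1..3 mod 4 guarantees a change
    out[hit] = (out[hit] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return out


def evolve_genome(
    ancestor: Genome, params: EvolutionParams
) -> tuple[Genome, TruthTables, dict[str, list[Block]]]:
    """Derive a diverged genome by substitutions then indels.

    Returns the derived genome, truth tables whose ortholog_map relates
    ancestor coordinates to derived coordinates, and the raw block maps
    (per ancestor chromosome) used for coordinate lifting.
    """
    if len(ancestor) == 0:
        raise ValueError("ancestor genome is empty")
    rng = np.random.default_rng(params.seed)
    derived: dict[str, str] = {}
    block_maps: dict[str, list[Block]] = {}
    truth = TruthTables()
    for name, seq in ancestor.sequences.items():
        codes = _apply_substitutions(encode(seq), params.substitution_rate, rng)
        blocks: list[Block] = []
        if params.indel_rate <= 0:
            derived[name] = decode(codes)
            blocks.append(Block(0, len(seq), name, 0, len(seq), "+"))
        else:
            pos = np.flatnonzero(rng.random(len(seq)) < params.indel_rate)
            is_ins = rng.random(pos.size) < 0.5
            lens = rng.geometric(1.0 / params.indel_length_mean, size=pos.size)
            pieces: list[np.ndarray] = []
            src, dst = 0, 0
            for p, ins, ln in zip(pos.tolist(), is_ins.tolist(), lens.tolist()):
                if p < src:  # swallowed by an earlier deletion
                    continue
                if p > src:
                    pieces.append(codes[src:p])
                    blocks.append(Block(src, p, name, dst, dst + (p - src), "+"))
                    dst += p - src
                    src = p
                if ins:
                    pieces.append(rng.integers(0, 4, size=ln).astype(np.uint8))
                    dst += ln
                else:
                    src = min(p + ln, len(seq))
            if src < len(seq):
                pieces.append(codes[src:])
                blocks.append(Block(src, len(seq), name, dst, dst + (len(seq) - src), "+"))
            derived[name] = decode(np.concatenate(pieces) if pieces else np.empty(0, np.uint8))
        block_maps[name] = blocks
        for b in blocks:
            truth.ortholog_map.append((name, b.s0, b.s1, b.chrom, b.d0, b.d1, b.strand))
    return Genome(derived), truth, block_maps


def apply_karyotype_reduction(
    genome: Genome, fusion_plan: dict[str, list[tuple[str, str]]]
) -> tuple[Genome, TruthTables, dict[str, list[Block]]]:
    """Concatenate (optionally reverse-complemented) chromosomes per the plan.

    Returns the fused genome, truth relating input to output coordinates, and
    the per-input-chromosome block maps.
    """
    seen: list[str] = []
    for members in fusion_plan.values():
        for chrom, strand in members:
            if chrom not in genome:
                raise KeyError(f"fusion plan references unknown chromosome {chrom!r}")
            if strand not in "+-":
                raise ValueError(f"bad orientation {strand!r}")
            seen.append(chrom)
    if sorted(seen) != sorted(genome.names) or len(seen) != len(set(seen)):
        raise ValueError("fusion plan must cover every chromosome exactly once")

    fused: dict[str, str] = {}
    block_maps: dict[str, list[Block]] = {name: [] for name in genome.names}
    truth = TruthTables()
    for out_name, members in fusion_plan.items():
        parts: list[str] = []
        offset = 0
        for chrom, strand in members:
            seq = genome[chrom]
            if strand == "-":
                seq = decode(revcomp_codes(encode(genome[chrom])))
            parts.append(seq)
            b = Block(0, len(seq), out_name, offset, offset + len(seq), strand)
            block_maps[chrom].append(b)
            truth.ortholog_map.append((chrom, 0, len(seq), out_name, b.d0, b.d1, strand))
            offset += len(seq)
        fused[out_name] = "".join(parts)
    return Genome(fused), truth, block_maps


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Forward k-mer codes (uint64) at every valid position; invalid -> dropped."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    vals = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    c = codes.astype(np.uint64)
    for i in range(k):
        vals = (vals << np.uint64(2)) | c[i : i + n]
        bad |= codes[i : i + n] >= 4
    return vals[~bad]


def insert_specific_sequences(
    genome: Genome,
    params: EvolutionParams,
    recipient: Genome | None = None,
    screen_k: int = 21,
) -> tuple[Genome, TruthTables, dict[str, list[Block]]]:
    """Insert donor-only sequences at random non-overlapping positions.

    Each inserted sequence is rejection-sampled to share no exact ``screen_k``-mer
    (on either strand) with ``recipient``.  Truth specific_regions carry the
    final donor coordinates; block maps lift pre-insertion coordinates.
    """
    rng = np.random.default_rng(params.seed + 1)
    count = params.specific_insertion_count
    lo, hi = params.specific_insertion_length_range
    truth = TruthTables()
    block_maps: dict[str, list[Block]] = {}
    if count == 0:
        for name, seq in genome.sequences.items():
            block_maps[name] = [Block(0, len(seq), name, 0, len(seq), "+")]
        return Genome(dict(genome.sequences)), truth, block_maps

    forbidden: np.ndarray | None = None
    if recipient is not None:
        parts = []
        for seq in recipient.sequences.values():
            c = encode(seq)
            parts.append(_kmer_codes(c, screen_k))
            parts.append(_kmer_codes(revcomp_codes(c), screen_k))
        # sorted with duplicates; searchsorted membership tests don't need unique
        forbidden = np.sort(np.concatenate(parts)) if parts else None

    lengths = rng.integers(lo, hi + 1, size=count)
    total_ins = int(lengths.sum())
    if total_ins > 50 * genome.total_length:
        raise ValueError("requested insertions exceed genome capacity")

    def draw_insert(ln: int) -> np.ndarray:
        for _ in range(100):
            cand = rng.integers(0, 4, size=ln).astype(np.uint8)
            if forbidden is None:
                return cand
            kc = _kmer_codes(cand, screen_k)
            idx = np.searchsorted(forbidden, kc)
            idx[idx == forbidden.size] = 0
            if not np.any(forbidden[idx] == kc):
                return cand
        raise RuntimeError("could not sample a recipient-free insertion")

    # choose insertion points: chromosome ~ length-weighted, position uniform,
    # all points distinct so truth intervals stay disjoint
    names = genome.names
    lens = np.array([len(genome[n]) for n in names], dtype=float)
    chrom_idx = rng.choice(len(names), size=count, p=lens / lens.sum())
    points = np.array([rng.integers(1, len(genome[names[i]])) for i in chrom_idx])
    order = np.lexsort((points, chrom_idx))

    out: dict[str, str] = {}
    for ci, name in enumerate(names):
        seq_codes = encode(genome[name])
        mine = [j for j in order if chrom_idx[j] == ci]
        pieces: list[np.ndarray] = []
        blocks: list[Block] = []
        src, dst = 0, 0
        last_point = -1
        for j in mine:
            p = int(points[j])
            if p == last_point:  # keep points distinct
                p = min(p + 1, len(genome[name]))
            last_point = p
            ln = int(lengths[j])
            if p > src:
                pieces.append(seq_codes[src:p])
                blocks.append(Block(src, p, name, dst, dst + (p - src), "+"))
                dst += p - src
                src = p
            ins = draw_insert(ln)
            pieces.append(ins)
            truth.specific_regions.append((name, dst, dst + ln))
            dst += ln
        if src < seq_codes.size:
            pieces.append(seq_codes[src:])
            blocks.append(Block(src, seq_codes.size, name, dst, dst + (seq_codes.size - src), "+"))
        out[name] = decode(np.concatenate(pieces))
        block_maps[name] = blocks
    truth.specific_regions.sort()
    return Genome(out), truth, block_maps


def simulate_aal_reads(
    recipient: Genome,
    donor: Genome,
    added_chromosomes: set[str],
    params: ReadSimParams,
) -> tuple[ReadSet, TruthTables]:
    """Simulate resequencing reads of an alien addition line.

    Reads are drawn uniformly from the recipient plus the added donor
    chromosomes at ``params.depth``; per-base substitution errors are applied
    independently.  Both mates count as independent reads for the depth
    arithmetic.  Truth labels every read with its true source chromosome and
    0-based start on that chromosome.
    """
    for name in added_chromosomes:
        if name not in donor:
            raise KeyError(f"unknown donor chromosome {name!r}")
    pool: list[tuple[str, str]] = [(n, s) for n, s in recipient.sequences.items()]
    pool += [(n, donor[n]) for n in sorted(added_chromosomes)]
    rng = np.random.default_rng(params.seed)
    rl = params.read_length
    total = sum(len(s) for _, s in pool)
    n_reads = int(round(params.depth * total / rl))
    truth = TruthTables(introgressed_chromosomes=set(added_chromosomes))
    reads = ReadSet()
    if n_reads == 0:
        return reads, truth

    frag_len = params.insert_size_mean if params.paired else rl
    lens = np.array([len(s) for _, s in pool], dtype=float)
    eligible = np.array([max(0, len(s) - frag_len + 1) for _, s in pool], dtype=float)
    if eligible.sum() == 0:
        raise ValueError("no chromosome long enough for the requested fragment length")

    n_frags = (n_reads + 1) // 2 if params.paired else n_reads
    frag_chrom = rng.choice(len(pool), size=n_frags, p=eligible / eligible.sum())
    mats: list[np.ndarray] = []
    names: list[str] = []
    sources: list[tuple[str, int]] = []
    win = np.arange(rl)
    serial = 0
    for ci in range(len(pool)):
        chrom, seq = pool[ci]
        k = int((frag_chrom == ci).sum())
        if k == 0:
            continue
        codes = encode(seq)
        starts = rng.integers(0, len(seq) - frag_len + 1, size=k)
        r1 = codes[starts[:, None] + win]
        mats.append(r1)
        for s in starts.tolist():
            names.append(f"read{serial:07d}/1")
            sources.append((chrom, s))
            serial += 1
        if params.paired:
            ends = starts + frag_len
            r2 = codes[ends[:, None] - 1 - win]  # reversed
            ok = r2 < 4
            r2 = np.where(ok, 3 - r2, r2).astype(np.uint8)  # complemented
            mats.append(r2)
            for s in ends.tolist():
                names.append(f"read{serial:07d}/2")
                sources.append((chrom, s - rl))
                serial += 1
    mat = np.concatenate(mats, axis=0)
    if params.paired and mat.shape[0] > n_reads:
        keep = rng.permutation(mat.shape[0])[:n_reads]
        keep.sort()
        mat = mat[keep]
        names = [names[i] for i in keep.tolist()]
        sources = [sources[i] for i in keep.tolist()]
    if params.error_rate > 0:
        err = (rng.random(mat.shape) < params.error_rate) & (mat < 4)
        n_err = int(err.sum())
        mat[err] = (mat[err] + rng.integers(1, 4, size=n_err).astype(np.uint8)) % 4
    from .genome import _DECODE  # local import avoids polluting module surface

    raw = _DECODE[mat].tobytes()
    reads.names = names
    reads.sequences = [raw[i * rl : (i + 1) * rl].decode("ascii") for i in range(mat.shape[0])]
    truth.read_sources = [(names[i], sources[i][0], sources[i][1]) for i in range(len(names))]
    return reads, truth


# -- study assembly -----------------------------------------------------------


@dataclass
class SpeciesPair:
    donor: Genome
    recipient: Genome
    truth: TruthTables
    ancestor: Genome | None = None


def make_species_pair(
    spec: GenomeSpec | None = None,
    params: EvolutionParams | None = None,
    seed: int = 0,
) -> SpeciesPair:
    """Build the full donor/recipient pair with composed truth tables.

    The donor is the ancestor plus species-specific insertions (no divergence
    on the donor branch); the recipient is the ancestor after substitutions,
    indels, and karyotype-reducing fusions.  The returned ortholog map relates
    final donor coordinates to final recipient coordinates.
    """
    spec = spec or default_genome_spec(seed=seed)
    params = params or default_evolution_params(seed=seed + 1)
    fusion_plan = params.fusion_plan or DEFAULT_FUSION_PLAN
    ancestor = simulate_ancestor(spec)
    derived, _, evolve_maps = evolve_genome(ancestor, params)
    recipient, _, fusion_maps = apply_karyotype_reduction(derived, fusion_plan)
    donor, ins_truth, donor_maps = insert_specific_sequences(ancestor, params, recipient=recipient)

    truth = TruthTables(specific_regions=list(ins_truth.specific_regions))
    for name in ancestor.names:
        anc_to_recip = compose(evolve_maps[name], {name: fusion_maps[name]})
        # join donor-side and recipient-side maps over shared ancestor coords
        d_blocks = donor_maps[name]
        for r in anc_to_recip:
            for d in d_blocks:
                m0, m1 = max(r.s0, d.s0), min(r.s1, d.s1)
                if m0 >= m1:
                    continue
                dd0 = d.d0 + (m0 - d.s0)
                dd1 = d.d0 + (m1 - d.s0)
                if r.strand == "+":
                    rr0 = r.d0 + (m0 - r.s0)
                    rr1 = r.d0 + (m1 - r.s0)
                else:
                    rr0 = r.d0 + (r.s1 - m1)
                    rr1 = r.d0 + (r.s1 - m0)
                truth.ortholog_map.append((name, dd0, dd1, r.chrom, rr0, rr1, r.strand))
    truth.ortholog_map.sort()
    return SpeciesPair(donor=donor, recipient=recipient, truth=truth, ancestor=ancestor)
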