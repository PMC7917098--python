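"""Simulator unit tests: dimensions, determinism, mutation and read models."""

import numpy as np
import pytest

from alienscan.genome import revcomp
from alienscan.synthetic import (
    EvolutionParams,
    GenomeSpec,
    ReadSimParams,
    apply_karyotype_reduction,
    evolve_genome,
    insert_specific_sequences,
    make_fusion_plan,
    make_species_pair,
    simulate_aal_reads,
    simulate_ancestor,
)


class TestAncestor:
    def test_dimensions(self):
        g = simulate_ancestor(GenomeSpec(12, [5000] * 12, seed=1))
        assert len(g) == 12
        assert g.total_length == 60_000
        assert all(set(s) <= set("ACGT") for s in g.sequences.values())

    def test_gc_fraction_within_binomial_noise(self):
        g = simulate_ancestor(GenomeSpec(1, [1000], gc_fraction=0.5, seed=2))
        seq = g["chrH01"]
        gc = (seq.count("G") + seq.count("C")) / 1000
        # 4 sigma for p=0.5, n=1000 is ~0.063
        assert abs(gc - 0.5) < 0.065

    def test_deterministic(self):
        spec = GenomeSpec(2, [1000, 2000], seed=7)
        assert simulate_ancestor(spec).sequences == simulate_ancestor(spec).sequences

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_chromosomes=0, chromosome_lengths=[]),
            dict(n_chromosomes=1, chromosome_lengths=[0]),
            dict(n_chromosomes=1, chromosome_lengths=[10], gc_fraction=1.5),
            dict(n_chromosomes=2, chromosome_lengths=[10]),
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GenomeSpec(**kwargs)


class TestEvolve:
    def test_no_mutation_limit(self):
        anc = simulate_ancestor(GenomeSpec(2, [5000, 5000], seed=1))
        derived, truth, _ = evolve_genome(anc, EvolutionParams(0.0, 0.0, seed=2))
        assert derived.sequences == anc.sequences
        assert truth.ortholog_map == [
            ("chrH01", 0, 5000, "chrH01", 0, 5000, "+"),
            ("chrH02", 0, 5000, "chrH02", 0, 5000, "+"),
        ]

    def test_lengths_conserved_without_indels(self):
        anc = simulate_ancestor(GenomeSpec(3, [4000, 5000, 6000], seed=1))
        derived, _, _ = evolve_genome(anc, EvolutionParams(0.1, 0.0, seed=2))
        assert derived.lengths() == anc.lengths()

    def test_substitution_rate_sets_hamming_divergence(self):
        anc = simulate_ancestor(GenomeSpec(1, [200_000], seed=1))
        derived, _, _ = evolve_genome(anc, EvolutionParams(0.0845, 0.0, seed=2))
        a, d = anc["chrH01"], derived["chrH01"]
        diff = sum(1 for x, y in zip(a, d) if x != y) / len(a)
        assert abs(diff - 0.0845) < 0.003

    def test_divergence_monotonic_in_rate(self):
        anc = simulate_ancestor(GenomeSpec(1, [50_000], seed=1))
        for seed in range(5):
            low, _, _ = evolve_genome(anc, EvolutionParams(0.05, 0.0, seed=seed))
            high, _, _ = evolve_genome(anc, EvolutionParams(0.10, 0.0, seed=seed))
            d_low = sum(1 for x, y in zip(anc["chrH01"], low["chrH01"]) if x != y)
            d_high = sum(1 for x, y in zip(anc["chrH01"], high["chrH01"]) if x != y)
            assert d_low < d_high

    def test_indel_truth_blocks_lift_coordinates(self):
        anc = simulate_ancestor(GenomeSpec(1, [20_000], seed=5))
        derived, truth, _ = evolve_genome(anc, EvolutionParams(0.0, 0.01, indel_length_mean=3, seed=6))
        # every truth block must copy identical sequence (no substitutions here)
        for chrom, s0, s1, dchrom, d0, d1, strand in truth.ortholog_map:
            assert strand == "+"
            assert anc[chrom][s0:s1] == derived[dchrom][d0:d1]


class TestKaryotypeReduction:
    def test_twelve_to_seven(self):
        anc = simulate_ancestor(GenomeSpec(12, [2000] * 12, seed=1))
        plan = make_fusion_plan(anc.names, 7)
        fused, _, _ = apply_karyotype_reduction(anc, plan)
        assert len(fused) == 7
        assert fused.total_length == anc.total_length

    def test_identity_plan_is_noop(self):
        anc = simulate_ancestor(GenomeSpec(3, [1000] * 3, seed=1))
        plan = {n: [(n, "+")] for n in anc.names}
        fused, _, _ = apply_karyotype_reduction(anc, plan)
        assert list(fused.sequences.values()) == list(anc.sequences.values())

    def test_fused_sequence_and_orientation(self):
        anc = simulate_ancestor(GenomeSpec(2, [1000, 1500], seed=1))
        fused, truth, _ = apply_karyotype_reduction(anc, {"f": [("chrH01", "+"), ("chrH02", "-")]})
        assert fused["f"] == anc["chrH01"] + revcomp(anc["chrH02"])
        assert ("chrH02", 0, 1500, "f", 1000, 2500, "-") in truth.ortholog_map

    def test_incomplete_or_unknown_plan_rejected(self):
        anc = simulate_ancestor(GenomeSpec(2, [1000, 1000], seed=1))
        with pytest.raises(ValueError):
            apply_karyotype_reduction(anc, {"f": [("chrH01", "+")]})
        with pytest.raises(KeyError):
            apply_karyotype_reduction(anc, {"f": [("chrH01", "+"), ("nope", "+")]})


class TestSpecificInsertions:
    def test_zero_count_is_noop(self):
        anc = simulate_ancestor(GenomeSpec(1, [5000], seed=1))
        out, truth, _ = insert_specific_sequences(
            anc, EvolutionParams(specific_insertion_count=0, seed=2)
        )
        assert out.sequences == anc.sequences
        assert truth.specific_regions == []

    def test_insertion_bookkeeping(self):
        anc = simulate_ancestor(GenomeSpec(2, [50_000, 50_000], seed=1))
        params = EvolutionParams(
            specific_insertion_count=40, specific_insertion_length_range=(200, 5000), seed=2
        )
        out, truth, _ = insert_specific_sequences(anc, params)
        assert len(truth.specific_regions) == 40
        inserted = sum(e - s for _, s, e in truth.specific_regions)
        assert out.total_length == anc.total_length + inserted
        # intervals disjoint and in-bounds per chromosome
        by_chrom = {}
        for c, s, e in truth.specific_regions:
            assert 0 <= s < e <= len(out[c])
            by_chrom.setdefault(c, []).append((s, e))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_no_shared_21mer_with_recipient_brute_force(self):
        anc = simulate_ancestor(GenomeSpec(1, [30_000], seed=3))
        recipient, _, _ = evolve_genome(anc, EvolutionParams(0.0845, 0.0, seed=4))
        out, truth, _ = insert_specific_sequences(
            anc,
            EvolutionParams(specific_insertion_count=20, specific_insertion_length_range=(100, 500), seed=5),
            recipient=recipient,
        )
        k = 21
        rec_kmers = set()
        for seq in recipient.sequences.values():
            for i in range(len(seq) - k + 1):
                km = seq[i : i + k]
                rec_kmers.add(km)
                rec_kmers.add(revcomp(km))
        for c, s, e in truth.specific_regions:
            seq = out[c][s:e]
            assert all(seq[i : i + k] not in rec_kmers for i in range(len(seq) - k + 1))


class TestReadSimulation:
    def test_read_count_arithmetic_and_labels(self):
        anc = simulate_ancestor(GenomeSpec(1, [150_000], seed=1))
        reads, truth = simulate_aal_reads(anc, anc, set(), ReadSimParams(depth=2.0, seed=2))
        assert len(reads) == round(2 * 150_000 / 150)
        assert len(truth.read_sources) == len(reads)
        assert {c for _, c, _ in truth.read_sources} == {"chrH01"}
        assert truth.introgressed_chromosomes == set()

    def test_error_free_reads_are_exact_substrings(self):
        anc = simulate_ancestor(GenomeSpec(2, [30_000, 30_000], seed=1))
        donor = anc
        recipient = simulate_ancestor(GenomeSpec(1, [30_000], gc_fraction=0.4, seed=9))
        reads, truth = simulate_aal_reads(
            recipient, donor, {"chrH02"}, ReadSimParams(depth=1.0, error_rate=0.0, seed=3)
        )
        src = dict((n, (c, s)) for n, c, s in truth.read_sources)
        donor_reads = [(n, q) for n, q in zip(reads.names, reads.sequences) if src[n][0] == "chrH02"]
        assert donor_reads
        chrom = donor["chrH02"]
        for name, seq in donor_reads:
            assert seq in chrom or revcomp(seq) in chrom

    def test_truth_records_added_chromosomes(self):
        pair_donor = simulate_ancestor(GenomeSpec(9, [10_000] * 9, seed=1))
        recipient = simulate_ancestor(GenomeSpec(1, [20_000], seed=2))
        _, truth = simulate_aal_reads(
            recipient, pair_donor, {"chrH06", "chrH09"}, ReadSimParams(depth=1.0, seed=3)
        )
        assert truth.introgressed_chromosomes == {"chrH06", "chrH09"}

    def test_unknown_chromosome_rejected(self):
        g = simulate_ancestor(GenomeSpec(1, [10_000], seed=1))
        with pytest.raises(KeyError):
            simulate_aal_reads(g, g, {"chrX"}, ReadSimParams(seed=1))

    def test_deterministic_reads(self):
        g = simulate_ancestor(GenomeSpec(1, [50_000], seed=1))
        r1, _ = simulate_aal_reads(g, g, set(), ReadSimParams(seed=5))
        r2, _ = simulate_aal_reads(g, g, set(), ReadSimParams(seed=5))
        assert r1.sequences == r2.sequences and r1.names == r2.names


def test_species_pair_truth_blocks_match_sequences(tiny_pair):
    """Every ortholog-map block must relate identically long intervals and,
    at zero indel rate inside blocks, sequence content differing only by the
    substitution process (donor side equals the ancestor)."""
    donor, recipient = tiny_pair.donor, tiny_pair.recipient
    for d_chrom, d0, d1, r_chrom, r0, r1, strand in tiny_pair.truth.ortholog_map:
        assert d1 - d0 == r1 - r0
        dseq = donor[d_chrom][d0:d1]
        rseq = recipient[r_chrom][r0:r1]
        if strand == "-":
            rseq = revcomp(rseq)
        diff = sum(1 for a, b in zip(dseq, rseq) if a != b) / max(1, len(dseq))
        assert diff < 0.12  # ~8.45% substitutions plus noise

    # specific regions must be donor-only: not a single 21-mer in the recipient
    rec = "#".join(recipient.sequences.values())
    rec_rc = revcomp(rec)
    for c, s, e in tiny_pair.truth.specific_regions[:3]:
        probe = donor[c][s : s + 21]
        assert probe not in rec and probe not in rec_rc
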