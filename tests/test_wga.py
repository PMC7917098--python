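"""Aligner unit tests: indexing, anchoring, chaining, extension, filtering,
and read placement, each against small constructed cases or brute-force
oracles."""

import itertools

import numpy as np
import pytest

from alienscan.genome import Genome, revcomp
from alienscan.wga import (
    AlignedSegment,
    Chain,
    _segments_from_ops,
    align_genomes,
    align_read,
    build_kmer_index,
    chain_anchors,
    extend_chain_to_alignment,
    filter_one_to_one,
    find_anchor_matches,
)
from conftest import random_genome


class TestKmerIndex:
    def test_position_count(self):
        idx = build_kmer_index(Genome({"c": "ACGTACGTAC"}), k=4)
        assert len(idx) == 7  # 10 - 4 + 1

    def test_n_windows_skipped(self):
        idx = build_kmer_index(Genome({"c": "ACGTNACGTA"}), k=4)
        # windows 0..6; those covering offset 4 (the N) are dropped
        assert len(idx) == 3

    def test_canonical_sets_match_reverse_complement(self, rng):
        g = random_genome(rng, [("c", 300)])
        g_rc = Genome({"c": revcomp(g["c"])})
        a = set(build_kmer_index(g, 11).codes.tolist())
        b = set(build_kmer_index(g_rc, 11).codes.tolist())
        assert a == b

    def test_lookup_reports_both_strand_conventions(self):
        idx = build_kmer_index(Genome({"c": "AAAACCCCGGGGTTTT"}), k=8)
        fwd = idx.lookup("AAAACCCC")
        assert ("c", 0, "+") in fwd
        rc = idx.lookup(revcomp("AAAACCCC"))
        assert ("c", 0, "-") in rc


class TestAnchors:
    def test_identical_sequence_anchor_count_and_strand(self, rng):
        g = random_genome(rng, [("t", 30)])
        idx = build_kmer_index(g, 21)
        anchors = find_anchor_matches(idx, Genome({"q": g["t"]}))
        assert len(anchors) == 10  # 30 - 21 + 1
        assert all(a.strand == "+" for a in anchors)
        assert all(a.tstart == a.qstart for a in anchors)

    def test_reverse_complement_query_all_minus(self, rng):
        g = random_genome(rng, [("t", 30)])
        idx = build_kmer_index(g, 21)
        anchors = find_anchor_matches(idx, Genome({"q": revcomp(g["t"])}))
        assert len(anchors) == 10
        assert all(a.strand == "-" for a in anchors)

    def test_unrelated_sequences_share_no_21mer(self, rng):
        a = random_genome(rng, [("t", 1000)])
        b = random_genome(rng, [("q", 1000)])
        idx = build_kmer_index(a, 21)
        assert len(find_anchor_matches(idx, b)) == 0


def _brute_force_best_chain(anchors, k, max_gap):
    """Exhaustive maximum chain over all anchor subsets (n <= 15)."""

    def valid(seq):
        for (t1, q1), (t2, q2) in zip(seq, seq[1:]):
            if not (t1 < t2 and q1 < q2):
                return False
            if t2 - (t1 + k) > max_gap or q2 - (q1 + k) > max_gap:
                return False
        return True

    best = 0
    n = len(anchors)
    for r in range(n, 0, -1):
        if r <= best:
            break
        for combo in itertools.combinations(sorted(anchors), r):
            if valid(combo):
                best = r
                break
    return best


class TestChaining:
    def _anchor_set(self, pairs, k=21):
        """AnchorSet-like object on one chromosome pair, strand +."""
        from alienscan.wga import AnchorSet

        t = np.array([p[0] for p in pairs], dtype=np.int64)
        q = np.array([p[1] for p in pairs], dtype=np.int64)
        order = np.lexsort((q, t))
        n = t.size
        return AnchorSet(
            k, ["t"], ["q"],
            np.zeros(n, np.int32), t[order],
            np.zeros(n, np.int32), q[order],
            np.ones(n, bool),
        )

    def test_single_diagonal_run_one_chain(self):
        anchors = self._anchor_set([(i * 22, i * 22) for i in range(10)])
        chains = chain_anchors(anchors, max_gap=1000, min_anchors=2)
        assert len(chains) == 1
        assert len(chains[0]) == 10

    def test_distant_runs_split(self):
        near = [(i * 22, i * 22) for i in range(5)]
        far = [(20_000 + i * 22, 20_000 + i * 22) for i in range(5)]
        chains = chain_anchors(self._anchor_set(near + far), max_gap=1000, min_anchors=2)
        assert len(chains) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_best_chain_matches_exhaustive_optimum(self, seed):
        rng = np.random.default_rng(seed)
        pairs = [(int(t), int(q)) for t, q in zip(rng.integers(0, 3000, 12), rng.integers(0, 3000, 12))]
        pairs = sorted(set(pairs))
        chains = chain_anchors(self._anchor_set(pairs), max_gap=1000, min_anchors=1)
        got = max(len(c) for c in chains)
        expect = _brute_force_best_chain(pairs, 21, 1000)
        assert got == expect


class TestExtension:
    def test_identical_spans_full_identity(self, rng):
        g = random_genome(rng, [("t", 500)])
        q = Genome({"q": g["t"]})
        idx = build_kmer_index(g, 21)
        chains = chain_anchors(find_anchor_matches(idx, q), min_anchors=2)
        segs = extend_chain_to_alignment(chains[0], g, q)
        assert len(segs) == 1
        s = segs[0]
        assert s.identity == 100.0
        assert s.alignment_columns == 500
        assert (s.tstart, s.tend, s.qstart, s.qend) == (0, 500, 0, 500)

    def test_identity_definition_counts_gap_columns(self):
        chain = Chain("t", "q", "+", np.array([0]), np.array([0]), 21)
        segs = _segments_from_ops([(92, "="), (6, "X"), (2, "I"), (1, "=")], chain, 101, 0, 0, 50, False)
        (s,) = segs
        assert s.alignment_columns == 101
        assert s.matches == 93
        # 100-column example from the same arithmetic: 92 matches / 100 columns
        assert round(100.0 * 92 / 100, 1) == 92.0
        assert s.score == 93 - 6 - (2 + 2)

    def test_minus_strand_round_trip(self, rng):
        g = random_genome(rng, [("t", 400)])
        q = Genome({"q": revcomp(g["t"])})
        segs = align_genomes(g, q, min_anchors=2)
        (s,) = segs
        assert s.strand == "-"
        assert s.identity == 100.0
        assert revcomp(q["q"][s.qstart : s.qend]) == g["t"][s.tstart : s.tend]

    def test_private_insertion_splits_alignment(self, rng):
        """A 600 bp insertion present only in the target must not be absorbed
        into an aligned segment; it has to surface between two segments."""
        core = random_genome(rng, [("x", 4000)])["x"]
        ins = random_genome(rng, [("i", 600)])["i"]
        target = Genome({"t": core[:2000] + ins + core[2000:]})
        query = Genome({"q": core})
        segs = align_genomes(target, query, min_anchors=2)
        covered = sorted((s.tstart, s.tend) for s in segs)
        assert len(segs) >= 2
        assert not any(s.tstart < 2050 and s.tend > 2550 for s in segs)


class TestOneToOneFilter:
    def _seg(self, t0, t1, q0, q1, score, tchrom="t", qchrom="q"):
        cols = max(t1 - t0, q1 - q0)
        return AlignedSegment(tchrom, t0, t1, qchrom, q0, q1, "+", max(score, 1), cols, score)

    def test_best_score_wins_on_overlap(self):
        a = self._seg(0, 100, 0, 100, 50)
        b = self._seg(50, 150, 200, 300, 40)
        assert filter_one_to_one([a, b]) == [a]

    def test_disjoint_all_kept(self):
        a = self._seg(0, 100, 0, 100, 50)
        b = self._seg(200, 300, 200, 300, 40)
        assert set(map(id, filter_one_to_one([a, b]))) == {id(a), id(b)}

    def test_query_side_overlap_also_blocks(self):
        a = self._seg(0, 100, 0, 100, 50)
        b = self._seg(200, 300, 50, 150, 40)
        assert filter_one_to_one([a, b]) == [a]

    def test_no_pairwise_overlap_invariant(self, rng):
        segs = []
        for _ in range(50):
            t0 = int(rng.integers(0, 900))
            q0 = int(rng.integers(0, 900))
            ln = int(rng.integers(10, 120))
            segs.append(self._seg(t0, t0 + ln, q0, q0 + ln, int(rng.integers(1, 100))))
        kept = filter_one_to_one(segs)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert a.tend <= b.tstart or b.tend <= a.tstart or a.tchrom != b.tchrom
                assert a.qend <= b.qstart or b.qend <= a.qstart or a.qchrom != b.qchrom


class TestReadAlignment:
    def test_exact_read_perfect_hit(self, rng):
        g = random_genome(rng, [("t", 5000)])
        idx = build_kmer_index(g, 15)
        read = g["t"][1000:1150]
        hit = align_read(idx, g, read)
        assert hit is not None
        assert hit.aligned_length == 150
        assert hit.identity == 100.0
        assert (hit.chrom, hit.start, hit.end, hit.strand) == ("t", 1000, 1150, "+")

    def test_reverse_complement_read_found(self, rng):
        g = random_genome(rng, [("t", 5000)])
        idx = build_kmer_index(g, 15)
        hit = align_read(idx, g, revcomp(g["t"][2000:2150]))
        assert hit is not None and hit.strand == "-" and hit.start == 2000

    def test_random_read_unplaced(self, rng):
        g = random_genome(rng, [("t", 5000)])
        other = random_genome(rng, [("r", 150)])
        idx = build_kmer_index(g, 15)
        assert align_read(idx, g, other["r"]) is None

    def test_diverged_ortholog_read_identity_below_bar(self, tiny_pair):
        """Reads drawn from the recipient align to the donor ortholog at
        roughly the genome divergence (~91.5%), far below the 99% bar."""
        donor, recipient = tiny_pair.donor, tiny_pair.recipient
        idx = build_kmer_index(donor, 15)
        rng = np.random.default_rng(1)
        idents = []
        seq = recipient["chrC01"]
        for _ in range(300):
            s = int(rng.integers(0, len(seq) - 150))
            hit = align_read(idx, donor, seq[s : s + 150])
            if hit is not None:
                idents.append(hit.identity)
        assert len(idents) > 250
        assert 88.0 < float(np.mean(idents)) < 95.0
        assert sum(i > 99.0 for i in idents) == 0


class TestWholeGenomeInvariants:
    def test_symmetry_of_matched_bases(self, tiny_pair):
        donor, recipient = tiny_pair.donor, tiny_pair.recipient
        ab = align_genomes(donor, recipient, one_to_one=True)
        ba = align_genomes(recipient, donor, one_to_one=True)
        m_ab = sum(s.matches for s in ab)
        m_ba = sum(s.matches for s in ba)
        assert abs(m_ab - m_ba) / max(m_ab, m_ba) < 0.005

    def test_identity_bounds_and_coverage(self, tiny_pair):
        segs = align_genomes(tiny_pair.donor, tiny_pair.recipient, one_to_one=True)
        for s in segs:
            assert 0.0 < s.identity <= 100.0
        donor_cov = sum(s.t_span for s in segs) / tiny_pair.donor.total_length
        # donor carries ~10 specific insertions; orthologous part is covered
        specific = sum(e - s for _, s, e in tiny_pair.truth.specific_regions)
        assert donor_cov >= 0.95 * (1 - specific / tiny_pair.donor.total_length)

    def test_self_alignment_identity_100(self, rng):
        g = random_genome(rng, [("t", 2000)])
        q = Genome({"q": g["t"]})
        segs = align_genomes(g, q, min_anchors=2)
        assert all(s.identity == 100.0 for s in segs)
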