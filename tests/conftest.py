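"""Shared fixtures: simulated species pairs at study scale and desk scale.

Session-scoped fixtures cache the expensive artifacts (the full 12x500 kb
study pair and its whole-genome alignment) so the acceptance-style tests
share one simulation instead of re-running it.
"""

import numpy as np
import pytest

from alienscan.genome import Genome
from alienscan.synthetic import (
    EvolutionParams,
    GenomeSpec,
    default_evolution_params,
    default_genome_spec,
    make_fusion_plan,
    make_species_pair,
)
from alienscan.wga import align_genomes, build_kmer_index, filter_one_to_one

STUDY_SEED = 11


@pytest.fixture(scope="session")
def study_pair():
    """Full study-scale pair: 12x500 kb donor, 7-chromosome recipient,
    substitution rate 0.0845, 200 planted donor-specific insertions."""
    return make_species_pair(default_genome_spec(seed=STUDY_SEED),
                             default_evolution_params(seed=STUDY_SEED + 1))


@pytest.fixture(scope="session")
def study_segments(study_pair):
    return align_genomes(study_pair.donor, study_pair.recipient)


@pytest.fixture(scope="session")
def study_one2one(study_segments):
    return filter_one_to_one(study_segments)


@pytest.fixture(scope="session")
def study_specific(study_pair, study_segments):
    """Marker-grade specific intervals: complement at the 400 bp floor, then
    the cross-chromosome uniqueness screen."""
    from alienscan.specificity import screen_chromosome_uniqueness, unaligned_complement

    candidates = unaligned_complement(study_segments, study_pair.donor.lengths(), min_length=400)
    return screen_chromosome_uniqueness(candidates, study_pair.donor)


@pytest.fixture(scope="session")
def donor_read_index(study_pair):
    return build_kmer_index(study_pair.donor, 15)


@pytest.fixture(scope="session")
def tiny_pair():
    """Two 40 kb chromosomes fused into one recipient chromosome; no indels."""
    spec = GenomeSpec(2, [40_000, 40_000], seed=3)
    params = EvolutionParams(
        substitution_rate=0.0845,
        indel_rate=0.0,
        specific_insertion_count=10,
        specific_insertion_length_range=(400, 2000),
        fusion_plan=make_fusion_plan(["chrH01", "chrH02"], 1),
        seed=4,
    )
    return make_species_pair(spec, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_genome(rng, names_lengths) -> Genome:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return Genome(
        {n: bases[rng.integers(0, 4, size=ln)].tobytes().decode() for n, ln in names_lengths}
    )
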