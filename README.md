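# alienscan

Tracing whole-chromosome introgression from a wild donor species into a
crop recipient. The package implements the computational core of an alien
addition line (AAL) breeding workflow for the *Cucumis* system — a
12-chromosome wild donor (such as *C. hystrix*) crossed into 7-chromosome
cultivated cucumber — but every stage is generic over a pair of FASTA
genomes and a FASTQ read set:

1. **Whole-genome alignment** (`alienscan.wga`): a self-contained
   seed–chain–extend aligner. Canonical *k*-mer anchors (default *k* = 21),
   co-linear gap-bounded chaining by dynamic programming, banded global
   extension with edlib, splitting at structural indels, and a greedy
   one-to-one filter so no base of either genome is covered twice. Percent
   identity is 100·matches/columns with gap columns in the denominator.
2. **Chromosome-specific sequences** (`alienscan.specificity`): the
   unaligned complement of the donor against the recipient (donor sequence
   with no recipient counterpart), then a uniqueness screen that realigns
   every candidate to the whole donor genome and keeps it only if every
   non-self hit (local score ≥ 30) lies on its own chromosome. Markers are
   chosen evenly along each chromosome (default: three per chromosome,
   length > 400 bp).
3. **AAL detection** (`alienscan.introgression`): resequencing reads are
   subsampled to ~2× depth and best-hit aligned to the donor; a read is
   called donor-origin iff its best hit has alignment length > 145 bp *and*
   identity > 99%. Donor-origin read starts are counted in 1 Mb windows
   advanced by 10 kb, and a donor chromosome is called present when a
   majority of windows carry a sustained (contiguous) signal of at least a
   quarter of the expected per-window read count.
4. **Summaries** (`alienscan.compstats`): aligned totals and fractions per
   genome, identity distributions with length-weighted medians, and
   per-identity-interval length statistics.
5. **Synthetic study generator** (`alienscan.synthetic`): simulates the
   whole data structure with known truth — an ancestor genome, a recipient
   derived by substitutions (default 8.45%, giving ~91.5% alignment
   identity), small indels and 12→7 chromosome fusions, a donor carrying
   planted donor-only insertions that share no 21-mer with the recipient,
   and 150 bp read pairs at 2× depth with 0.5% error.

## Worked example

```python
from alienscan import (make_species_pair, align_genomes, find_specific_sequences,
                       select_markers, simulate_aal_reads, detect_alien_chromosomes,
                       ReadSimParams, ClassificationParams)

pair = make_species_pair(seed=1)          # 12x500 kb donor, 7-chrom recipient
segments = align_genomes(pair.donor, pair.recipient)
specific = find_specific_sequences(pair.donor, segments, min_length=400)
markers = select_markers(specific, pair.donor.lengths(), per_chromosome=3)
print(len(specific), len(markers))        # -> 199 36

reads, _ = simulate_aal_reads(pair.recipient, pair.donor, {"chrH06", "chrH09"},
                              ReadSimParams(seed=7))
report, profiles, hits = detect_alien_chromosomes(
    pair.donor, reads, ClassificationParams(),
    sampled_genome_size=pair.recipient.total_length
    + len(pair.donor["chrH06"]) + len(pair.donor["chrH09"]))
print(sorted(report.called))              # -> ['chrH06', 'chrH09']
```

The first two numbers say that 199 donor intervals longer than 400 bp
survived both the complement and the uniqueness screen (the simulation
planted 200), and that marker selection returned exactly 3 × 12 = 36 evenly
spaced markers. The final line shows the detector recovering exactly the
two alien chromosomes the simulated line carries.

The same stages are available from a shell:

```bash
alienscan run-all --outdir demo --seed 1
alienscan detect --donor demo/donor.fa --reads demo/AAL01.fq \
    --depth 2 --window 1000000 --step 10000 --out-json calls.json
```

## Layout

```
src/alienscan/
  genome.py        sequence container + 2-bit encoding
  synthetic.py     study simulator (genomes, fusions, insertions, reads)
  coords.py        interval algebra and coordinate lifting
  wga.py           k-mer index, anchors, chains, extension, read best hits
  specificity.py   complement, uniqueness screen, marker selection
  introgression.py read classification, window profiles, presence calls
  compstats.py     alignment summary statistics
  io.py            FASTA/FASTQ/BED/PAF/bedGraph/TSV/JSON
  pipeline.py      config + end-to-end driver
  cli.py           `alienscan` subcommands
```

See `docs/methods.md` for the models, parameter choices, and limitations.
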