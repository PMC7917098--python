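# Methods

## Problem and scope

An alien addition line (AAL) carries one or more whole chromosomes of a
related donor species on top of the recipient's own complement. Verifying
*which* donor chromosomes a line received needs two computational assets:
donor sequences that occur nowhere in the recipient and on exactly one
donor chromosome (PCR marker targets), and a read-classification scheme
that can tell donor-derived reads from recipient reads despite the two
genomes being ~91.5% identical in their alignable regions. This package
implements both, plus the pairwise whole-genome alignment they depend on
and a simulator that generates the entire data structure with known truth.

## Whole-genome alignment

Seed–chain–extend with these components:

* **Canonical k-mer index.** Every k-mer is stored under the lexicographic
  minimum of itself and its reverse complement, so one index serves both
  strands. Default k = 21 for genome–genome anchoring and k = 15 for read
  seeding: at desk scale (≈6×10⁶ bp per genome) the expected number of
  random 21-mer collisions between two unrelated genomes is ≈
  (6·10⁶)²/4²¹ ≈ 8, i.e. negligible, while at 8.45% divergence roughly
  (1−0.0845)²¹ ≈ 16% of positions still anchor, one anchor every ~6 bp.
  K-mers containing non-ACGT symbols are skipped; k-mers occurring more
  than 100 times in the target are excluded from seeding (not from the
  uniqueness screen) to bound runtime on repeats.
* **Chaining.** Within each (target chromosome, query chromosome, strand)
  group, anchors sorted by target position are chained by dynamic
  programming: a predecessor must advance on both genomes and leave a gap
  of at most `max_gap` (default 1000 bp) on each. The DP maximises anchor
  count; chains are peeled off best-first and chains with fewer than
  `min_anchors` (default 3) are dropped. The backward predecessor scan
  terminates at the gap bound, so the DP is effectively linear-time on
  collinear anchor sets; the inner loop is numba-compiled.
* **Structural split before extension.** Consecutive anchors whose target
  and query gaps differ by ≥ `split_gap` (default 50 bp) imply a net indel
  of at least that size between two exact matches; the chain is cut there
  *before* alignment. This matters: an edit-distance-optimal alignment of
  a genome-private insertion against unrelated sequence scatters the gap
  into many short runs interleaved with chance matches (observed: a 706 bp
  insertion became ~200 gap runs, the longest 39 bp), so a cigar-level gap
  scan cannot recover it. Anchors are exact matches, so the anchor-level
  signal is unambiguous.
* **Extension.** Each chain part is aligned across its full span
  (including inter-anchor gaps) with edlib (Needleman–Wunsch, full path).
  The optional `band` caps the edit distance; if exceeded, extension falls
  back to per-anchor stitching with mismatch counting and the segments are
  flagged. The cigar is additionally split at any remaining gap run ≥
  `split_gap`, and edge gap runs are trimmed.
* **Scoring and identity.** Match +1, mismatch −1, gap open −2, gap
  extension −1 per column (a gap run of length L costs L + 2). Identity is
  100·matches/columns **with gap columns in the denominator** — stated
  explicitly because alignment tools disagree and the choice moves the
  number. All coordinates are 0-based half-open; strand '−' means the
  query interval aligns reverse-complemented, reported in forward query
  coordinates.
* **One-to-one filter.** Greedy by descending score (ties: longer
  alignment, then target chromosome, then start); a segment is kept iff it
  overlaps no kept segment on either genome. The output provably covers no
  base twice on either side.

## Chromosome-specific sequences and markers

* **Complement.** Aligned donor intervals are merged per chromosome and
  complemented; pieces < 28 bp are dropped by default (the floor is the
  smallest interval worth reporting, configurable). For recovery
  statistics and marker work the floor is 400 bp — marker-grade length —
  because sub-marker fragments at alignment boundaries carry no
  information about donor-only content.
* **Uniqueness screen.** Every candidate is re-seeded against the full
  donor index (no repeat suppression), seed hits are clustered by
  diagonal, each non-self cluster is extended with edlib and scored
  locally (best-scoring sub-path under the package scoring). A hit
  "overlaps the own locus" if its target span intersects the candidate
  interval by ≥ 1 bp on the same chromosome; such hits are ignored. The
  candidate survives iff every remaining hit with score ≥ 30 lies on its
  own chromosome — same-chromosome duplications are allowed and counted.
  The score-30 bar plays the role of a BLAST E-value cutoff: for this
  scoring the best random local score between a candidate and a
  desk-scale genome is ~15–20, so 30 is comfortably above noise yet any
  real duplication (tens of matching bases) clears it.
* **Marker selection.** Candidates longer than 400 bp are eligible. Each
  chromosome is divided into `per_chromosome` equal bins; for each bin
  center the nearest not-yet-chosen candidate midpoint is taken (ties to
  the longer interval). Chromosomes with fewer eligible candidates than
  bins yield fewer markers, with a warning. "Evenly distributed" admits
  many concretizations; nearest-to-bin-center is ours.

## Read classification and chromosome calls

* Reads are subsampled without replacement to round(depth·G/L) reads
  (G = size of the genome the line was sequenced from, L = read length;
  mates count independently).
* Best-hit placement: every second read k-mer (k = 15) votes for a
  (chromosome, strand, diagonal) locus; the best-voted locus is refined
  gaplessly and trimmed to the best-scoring local window (Kadane over
  per-column scores). Hits with score < 30 are discarded. The gapless
  refinement is exact under the simulator's substitution-only error model;
  real indel-bearing reads would lose a little identity at this step,
  which is conservative for the 99% filter. A single-read
  `align_read` entry point exposes the same path.
* A read is donor-origin iff aligned length > 145 bp **and** identity >
  99% (both strict, so a 145 bp or 99.0% hit fails). At ≥ 8% genome
  divergence recipient reads sit near 91.5% identity, ~25 standard
  deviations below the bar; with 0.5% sequencing error a true donor read
  passes unless it carries ≥ 2 errors that trimming cannot remove
  (measured pass rate ≈ 0.83), so the two read populations are fully
  separated.
* Donor-origin read starts are counted in windows of 1 Mb advanced by
  10 kb, grid anchored at 0; final truncated windows are kept and flagged.
* **Call rule** (all three constants are config keys): a window is
  supported when its count ≥ 0.25 × expected, where expected =
  depth·(effective window span)/read length — the *effective* span, so a
  window clipped by the chromosome end is judged against what it could
  have contained. A chromosome is present when ≥ 50% of windows are
  supported *and* the longest contiguous supported run covers ≥ 50% of
  windows. The run condition encodes "continuous pattern": a whole-
  chromosome addition supports essentially every window, while scattered
  false positives cannot form long runs. Effective-span scaling is what
  makes the rule well defined when the window exceeds the chromosome
  length (as it does at desk scale: 0.5 Mb chromosomes, 1 Mb window).

## The simulator

What it emulates: a 12-chromosome donor (12 × 500 kb by default, GC 0.35
≈ cucurbit genomes), a recipient derived from the same ancestor by
uniform substitutions (default rate 0.0845 — chosen so one-branch
divergence reproduces the ~91.5% alignable identity of the real species
pair), geometric indels (default rate 10⁻³/site, mean 3 bp), and five
pairwise chromosome fusions (some members inverted) reducing 12
chromosomes to 7. The donor additionally receives 200 insertions of
0.4–5 kb, rejection-sampled to share no 21-mer with the recipient —
the stand-in for species-specific sequence. Reads are 150 bp pairs at 2×
depth with 0.5% uniform substitution error, drawn uniformly from the
recipient plus any added donor chromosomes. All divergence sits on the
recipient branch (the donor *is* the ancestor plus insertions), which
makes the identity calibration a one-parameter relationship:
identity ≈ 100·(1−rate).

Truth tables record the ortholog block map (donor ↔ recipient
coordinates lifted across indels and fusions), the final coordinates of
every planted insertion, the set of added chromosomes per line, and the
true source of every read. Every operation takes an explicit seed and is
deterministic given it.

What it does **not** model — and hence what passing tests do not show
about real data: transposon families and segmental duplications (real
"specific" sequence is repeat-rich; the uniqueness screen is exercised
here only by planted duplicates), heterozygosity, GC/coverage bias,
indel sequencing errors, quality scores, and any rearrangement history
beyond clean fusions. Absolute counts from the real genomes
(tens of thousands of specific sequences, megabases of species-specific
content) are therefore not reproduced, only the procedure's behaviour.

## Numerical choices and degenerate inputs

* Identity denominators include gap columns; length-weighted means are
  the headline statistic (unweighted also reported) since per-segment
  means over-weight short segments.
* Tie-breaks are total orders everywhere (score, then length, then
  chromosome name, then coordinate), so reruns are byte-identical.
* Problem sizes: study simulations use 12 × 500 kb genomes, the identity
  calibration 6 × 200 kb, and oracle-equivalence checks 10–80 kb toy
  genomes — sizes at which every brute-force oracle is exhaustive while
  each statistic (identity sampled over ~10⁶ columns, specificity over
  10⁵ reads) has sampling noise far below its tolerance.
* Degenerate inputs: empty read sets, empty candidate sets, chromosomes
  shorter than the window, chromosomes with fewer candidates than marker
  bins, and reads with no seed match all return empty results or warnings
  rather than raising; invalid parameters (rates outside [0,1], window <
  step, fusion plans not covering the karyotype) raise before any compute.

## Known limitations

* The read aligner assumes uniform read length per batch and
  substitution-dominated error; it is not a general-purpose mapper.
* The one-to-one filter is greedy, not an optimal interval scheduling —
  deliberate, because the greedy rule is simple to state, deterministic,
  and its output is what downstream statistics are defined on.
* `screen_chromosome_uniqueness` requires seed hits (an exact 15-mer) to
  notice a duplication; a duplication diverged far enough to lack any
  shared 15-mer over a ≥ 30-score alignment could slip through. At the
  score threshold this needs a contrived mutation pattern, but it is the
  screen's blind spot.
* Sub-chromosomal introgression segments are out of scope: the caller
  decides whole-chromosome presence only.
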