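# Methods

`linkco` detects meiotic crossovers (COs) in *bulk* DNA of recombinant
genomes — pooled F2 plants, or pollen of an F1 hybrid — from linked-read
sequencing, without genotyping any individual. This note describes the
model behind each stage, the defaults and why they are what they are,
what the synthetic pools do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Molecule reconstruction

Linked-read libraries attach a shared barcode to the short reads derived
from one long DNA molecule (tens of kb). Reads with the same barcode
aligned to the same chromosome are chained into a molecule while the gap
between the running chain end and the next alignment start is at most
`max_gap` (default 25 kb); for intervals this sweep is exactly
single-linkage clustering at the gap threshold, which the test suite
verifies against a brute-force union-find oracle. Chains spanning less
than `min_len` (default 1 kb) are discarded. Coordinates are 1-based
inclusive everywhere inside the package; BED files are converted at the
I/O boundary. One deliberate convention: a marker whose 1-based position
equals a co-linear block's BED end value is treated as *outside* the
block, i.e. markers are kept only strictly inside the half-open block in
BED coordinate numbers.

Because a barcode is shared by a small number of molecules, two
molecules from different genomes that happen to align near each other
can fuse into a chimera that mimics a recombinant molecule. The chimera
filter removes molecules with `length >= 65 kb`, `n_reads >= 55`, or any
marker with read support for **both** parental alleles (`min_allele_support`
reads each, default 1). The kept set therefore satisfies the strict
inequalities (shorter than 65 kb, fewer than 55 reads). These thresholds
are empirical library-scale choices and are exposed in the configuration
rather than derived.

## Genotyping and crossover calls

Markers are biallelic SNPs between the two parental genomes, restricted
to co-linear (non-rearranged) regions; markers inside rearrangements are
false-positive hotspots and are removed before genotyping. A molecule's
genotype vector holds, per covered marker, the consensus parental allele
(markers showing only non-parental bases, or both parental alleles, are
omitted). Classification follows the run structure of the vector:

* zero switches and at least `min_markers_per_cluster` markers →
  **non-recombinant**;
* exactly one switch, with each run containing at least
  `min_markers_per_cluster` markers (default 2) and spanning at least
  `min_cluster_span` bp (default 1 kb) → **recombinant**; the CO
  breakpoint interval runs from the last marker of the first run to the
  first marker of the second, and its width is the breakpoint
  resolution;
* anything else (empty vectors, two or more switches — which includes
  double COs and most chimeras — or a run failing the criteria) →
  **undetermined**.

The run criteria defaults are conservative; they are configurable
because the precise values are a filtering policy, not a property of the
model. An exhaustive enumeration oracle (all allele strings up to length
8) pins the classification rule in the tests.

Calls can additionally be required to reproduce against the second
parental assembly (`intersect_dual_reference`): a call survives if a
call with the same barcode in the other-reference set overlaps it in
marker-index space. Marker IDs are the shared coordinate system, so no
liftover is needed, and calls on different chromosomes can never match.

Redundant calls of the same CO are merged into distinct sites by
single-linkage over intersecting breakpoint intervals; a site's interval
is the intersection of its members (the union when a chained cluster has
no common intersection), with member counts recorded. In small genomes
independent COs coincide by chance — `expected_overlap_fraction` gives a
Monte-Carlo estimate of that rate (intervals of the breakpoint
resolution placed uniformly; the definition is declared, not claimed
canonical) — so distinct-site counts are a lower bound on independent
events.

Benchmark scoring counts a call as a true positive when its interval
intersects at least one benchmark interval (optional ± padding, default
0); recall is the fraction of benchmark COs hit at least once.
Percentages are rounded to one decimal, half away from zero.

## Landscapes and pool comparison

CO landscapes use 1 Mb windows sliding in 50 kb steps, starting at
position 1 (the terminal window is truncated at the chromosome end; the
exact grid registration is a convention). A CO is assigned to windows by
its breakpoint-interval midpoint, a non-recombinant molecule by its
molecule midpoint. The window frequency is `f = n / t_i`, normalising by
the chromosome's total CO count `t_i`, so landscapes from libraries of
different depths are comparable; on a non-overlapping tiling the `f` of
a chromosome sums to 1. Landscape similarity is genome-wide Pearson
correlation on the shared grid.

Two pools are compared per window with two-sided Fisher's exact tests on
(recombinant, non-recombinant) counts against each of two replicate
pools; a window is flagged only when both p-values fall below alpha
(default 0.05). No multiple-testing correction is applied — requiring
concordance across both replicates plays that role. Flagged windows that
touch or overlap on the grid merge into candidate difference regions.

## Relative recombination frequency (C^M)

The fraction of recombinant molecules depends on molecule length and
coverage, so pools are compared only after matching their molecule
characteristics. Jointly over all pools, molecules are binned by length
(1 kb bins); each pool is sampled down to the per-bin minimum across
pools, then `floor(0.8 * count)` molecules are retained per bin, and
finally molecules with length ≥ 30 kb or ≥ 24 reads are removed. After
matching, `C^M = 1e6 * recombinant molecules / molecules`. The whole
procedure is repeated 50 times (sub-seeds `seed + replicate`); a pool is
summarised by the replicate mean μ and the 95% half-width
`s = t_{0.975, n-1} * sigma / sqrt(n)` (2.0096·σ/√50 at the default
count; σ is the sample standard deviation — the population/sample choice
is a convention, the sample form is used). Two pools differ
significantly when their intervals do not overlap. Thinning counts are
floored; molecules are genotyped and classified once (both operations
are deterministic per molecule) and each replicate re-counts crossovers
on its own subsampled set.

A caveat this package makes explicit: the interval above quantifies
*subsampling* noise only. Two independently constructed libraries from
the same population additionally differ by binomial sampling of which
molecules carry a CO, which is roughly `sqrt(2/E)` in relative terms for
`E` eligible CO molecules per library — at any library size about five
times the interval width when pools of similar depth are matched
pairwise (random per-bin retention ≈ 0.8). Concordance between
same-population libraries is therefore only the expected outcome when
the joint matching is *deep*: matching several pools together, with the
most limiting pool driving per-bin retention far below 1, widens σ until
the intervals dominate library-level noise. The acceptance checks follow
that design (two same-population libraries plus a small anchor pool
matched jointly). `C^M` is relative: converting it to cM/Mb would
require a molecule-detection-efficiency calibration that is out of
scope.

## Feature association

CO midpoints are assigned to genomic categories by a decision list
(first match wins), by default TE → promoter → gene start → gene end →
gene body → intergenic, where the promoter is the 1,000 bp upstream of
the transcription start site and gene start/end are the first/last
200 bp of the gene, all strand-aware. The order is configurable because
precedence among overlapping annotations is a policy choice; a TE
superfamily variant reuses the same machinery with one category per
superfamily. Enrichment/depletion per category is tested by permutation:
observed category proportions against those of `n_sets` (default 1,000)
random sets of `set_size` (default 3,000) midpoints placed uniformly in
the non-heterochromatic genome. The two-sided empirical p-value uses the
add-one rule `p = (2·min(k_ge, k_le) + 1) / (n_sets + 1)`, capped at 1,
so it is never exactly zero and is bounded below by `1/(n_sets+1)`.
GC association is windowed Pearson correlation (GC fraction computed
from the reference FASTA over unambiguous bases). Methylation of an
interval is `M = Σ N_met / Σ N` over the cytosine sites it covers;
CO-interval and random-interval levels are compared with a Welch
two-sample t-test, skipping (and counting) intervals without covered
sites.

## The synthetic pools

The simulator generates what the pipeline consumes, with known truth:

* **Genomes.** Each of `n_genomes` recombinants is one haploid parental
  mosaic (gamete) or two independent mosaics (F2). Each mosaic receives
  `Poisson(rate/2 × chromosome share)` COs, `rate` being the per-diploid
  CO rate (default 8.3 per genome, the F2 average in a Col-0 × Ler
  cross), placed uniformly or from a user density track so landscape
  recovery can be tested.
* **Molecules.** Lengths are shifted-exponential with mean 45 kb and
  minimum 1 kb (fragmentation's standard model; a lognormal alternative
  is available), positions uniform, genome/haplotype uniform per
  molecule. Each barcode carries `1 + Poisson(molecules_per_barcode_mean
  − 1)` molecules, so a mean of 1 gives exactly one molecule per barcode
  and larger means create the collision chimeras that drive false
  positives.
* **Reads.** Each molecule is covered by `max(1, Poisson(21))` read
  pairs of 151 bp at uniform offsets; a pair is emitted as one
  contiguous 302 bp alignment (insert geometry, base-level errors and
  quality scores are deliberately not modelled). Marker observations are
  the haplotype's parental allele, flipped to the other allele with
  probability `genotyping_error_rate`.

All randomness flows from one seed through a single generator; the same
seed reproduces a pool byte for byte. What the generator does *not*
emulate: reference/alignment bias, structural rearrangements between the
parents (all simulated markers are co-linear), size selection of the
input DNA, chromosome-scale CO interference, and gene conversion.
Passing tests therefore demonstrate the correctness and calibration of
the *pipeline* under its stated model, not robustness to those
real-data effects — on real data the co-linear marker filter and
dual-reference intersection carry that burden.

## Problem sizes in the tests and acceptance script

Desk-scale runs use 2–20 Mb genomes with 10⁴–2×10⁵ molecules per
library. Two sizing choices matter scientifically:

* The 2×-rate recovery check uses a 20 Mb chromosome: at 5 Mb the
  default 8.3 COs/genome already puts ~1.7 COs/Mb on a haplotype, so
  doubling the rate saturates per-molecule detection (a molecule carries
  ≥ 2 COs often enough to be classified undetermined or to hide a
  switch) and the measured μ ratio centres near 1.75 rather than 2. At
  20 Mb — and a fortiori on a real 135 Mb genome — detection is linear.
* Same-population concordance uses the joint-matching design with an
  anchor pool, for the variance reasons given above.

Generator defaults (molecule length, read-pair count, CO rate, barcode
load, thresholds) are never adjusted per test.

## Known limitations

* Molecule recovery merges co-barcoded molecules closer than `max_gap`
  on the same chromosome; the filters remove most but not all chimeras,
  and the residual false positives scatter roughly uniformly, diluting
  rather than distorting landscapes.
* Distinct-site deduplication cannot distinguish coincident independent
  COs from re-detections; member counts and the overlap Monte-Carlo are
  the tools for reasoning about that.
* The C^M interval understates between-library variance for shallow
  pairwise matching (see above).
* `benchmark_compare` uses plain interval intersection; whether padding
  should be allowed around benchmark intervals is a user decision
  (default 0).
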