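# Methods

This note documents the models and procedures implemented in
`digestax`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## Pairwise identity

All threshold decisions (novelty ranking, deduplication, taxonomy
inheritance, placeholder clustering, high-identity coverage) rest on
one identity definition:

> identity = 100 × matches / alignment columns over the aligned span
> of an optimal **query-in-target semi-global** alignment.

The shorter sequence of a pair (the query) must be aligned in full;
the longer sequence's terminal overhangs are gap-free and excluded
from the span. Internal gaps count as non-match columns. Two IUPAC
codes count as a match when their nucleotide sets intersect — the same
permissive rule used for degenerate primers, so an `N` in a reference
never penalises a comparison.

Scoring is match +1, mismatch −1, linear gap −2, computed by a
vectorised Needleman–Wunsch variant (the in-row dependency of the
linear-gap recurrence is resolved with a running-maximum transform).
Determinism is guaranteed by a fixed traceback preference
(diagonal > up > left), a fixed start-cell rule (maximum score on the
last row, rightmost on ties), and canonical ordering of the input pair
(by length, then lexicographically), which also makes the reported
identity exactly symmetric.

*Why query-in-target rather than free end gaps on both sequences:*
with both ends of both sequences free, the optimal alignment of two
**unrelated** sequences is a short chance overlap of their termini —
a handful of consecutive matches scores higher than the long noisy
full alignment and reports a spurious 100 % identity. Requiring the
query to be covered removes that artifact while preserving the
property that a read fully contained in a longer reference scores
100 %. This mirrors how global-mapping tools report query identity.

## Novelty ranking and placeholder taxonomy

A query's novelty rank is the most inclusive rank whose identity
threshold its best database hit fails (strict `<`; a hit at exactly
94.5 % is *not* genus-novel). Defaults are the classical per-rank 16S
thresholds: phylum 75.0, class 78.5, order 82.0, family 86.5, genus
94.5, species 98.7 %. Novelty summaries are cumulative: a sequence
below the genus threshold is counted in the genus row *and* the
species row.

Taxonomy assignment inherits the nearest neighbour's name rank by
rank while the identity meets that rank's threshold (the kingdom is
always inherited); from the first failing rank downward, placeholder
names `midas_<rank-letter>_<integer>` are minted. Placeholders are
reused through greedy star clustering per rank: the first minting
query becomes the cluster centroid, and a later query reuses the name
iff its identity to the centroid reaches the rank threshold, scanning
clusters in creation order. Numbering is therefore a deterministic
function of query input order — rerunning the same inputs reproduces
identical names byte for byte. The registry can be initialised from an
existing database so new numbers continue past the largest existing
placeholder index.

Deduplication during a database merge collapses an incoming sequence
iff it has equal length and position-wise IUPAC-compatible bases with
an already-retained record (exactly the condition for 100 % identity
at equal length). A shorter sequence contained in a longer one is
*not* collapsed — containment is reported as a warning, because
"non-redundant" collections conventionally keep distinct-length
variants.

## Bootstrap k-mer classifier

The classifier follows the published SINTAX scheme: the query's unique
8-mers are indexed; each of 100 bootstrap iterations draws 32 of them
with replacement and votes for the reference sharing the most drawn
8-mers (ties fall back to the lexicographically smallest accession, a
determinism choice). Both strands are searched; the orientation whose
best reference shares more 8-mers overall wins before bootstrapping.
Per-rank confidence is the fraction of bootstraps whose winner carries
the predicted lineage *prefix* down to that rank, which makes
confidence non-increasing with depth by construction; ranks below the
0.8 cutoff are blanked. k = 8, 32 draws, 100 bootstraps and the cutoff
are all constructor parameters. k-mers containing ambiguity codes are
ignored on both sides.

## Amplicon evaluation

Evaluation operates per sample on a samples × ASVs count table:

* samples under 10,000 reads are discarded;
* the rare biosphere is masked per sample (a feature is kept in a
  sample iff its relative abundance there is ≥ 0.01 %; the same
  feature may be kept in one sample and masked in another);
* high-identity coverage is the percentage of a sample's retained
  ASVs whose nearest reference is ≥ 99 % identical — ASVs weighted
  equally, not by abundance, so the measure is invariant to read
  depth;
* classification rates are the percentage of retained ASVs with a
  non-blank name at the requested rank.

Samples with zero retained ASVs yield missing values, never silent
zeros.

## Core and CRAT profiling

Within a metadata group (substrate × temperature by default), a taxon
is *abundant* in a sample when above 0.1 % relative abundance;
occupancy is the fraction of the group's samples where it is abundant.
Categories use strict comparisons: strict core > 0.8 occupancy,
general > 0.5, loose > 0.2, else CRAT if the taxon exceeds 1 % in at
least one sample, else other. Taxa sitting exactly on an occupancy
boundary are flagged in the output, since the strict inequality
decides their category. Taxa observed in none of a group's samples are
omitted from that group's assignments.

The most-wanted list takes each taxon's highest category across all
groups and primer sets (strict > general > loose > CRAT > other),
drops taxa that are "other" everywhere, and reports the first group
achieving the best category as provenance. Shared-core counts use
exclusive UpSet semantics: every core taxon is counted in exactly one
intersection pattern, so pattern counts sum to the union size.
Per-category accumulated abundance sums each member taxon's mean
relative abundance across the group's samples; features unnamed at the
aggregation rank are pooled as "unclassified", and the six category
totals sum to 100 %.

Replicate samples are treated as independent samples by default (the
generator links them via a `replicate_of` metadata column for
workflows that prefer per-digester averaging).

## Primer scoring

A primer is scored at every ungapped template offset plus every
single-gap variant within the primer span (one unpaired primer base,
or one skipped template base between two primer bases), on both
template strands. The overall weighted score (OWS) of the best site is
a weighted error sum with defaults: non-3' mismatch 0.4, 3' mismatch
1.0, non-3' gap 1.0, 3' gap 3.0, with the 3' region spanning the last
5 primer bases. These weights follow the published Primer Prospector
scheme and are fully configurable; every coverage report embeds the
weight configuration used. Categories: perfect (OWS = 0), partial
(0 < OWS ≤ 1), poor (OWS > 1). Gap search is limited to single-gap
variants — the dominant indel case — keeping the scan exhaustive
within that space (a gapped variant replaces an ungapped site only
when strictly better, and cannot when the ungapped best is already
at or below the cheapest gap weight).

Pair coverage is the percentage of a taxon's references with perfect
hits for *both* primers; a reverse-only mode exists for reference sets
whose 5' ends were themselves created with the forward primer.
Amplicon extraction returns the inter-primer region oriented 5'→3'
(0-based half-open coordinates), requiring perfect sites by default,
and reports which site was missing otherwise.

## Diversity statistics

* **Rarefaction** draws without replacement (multivariate
  hypergeometric) to a common depth, default 10,000 reads; shallower
  samples are excluded and listed. Rarefaction feeds alpha diversity
  only; Bray–Curtis uses relative abundances of full samples.
* **Alpha diversity**: observed richness and inverse Simpson
  (1 / Σ pᵢ²).
* **Bray–Curtis**: d(a,b) = 1 − 2·Σ min(aᵢ,bᵢ) / Σ (aᵢ+bᵢ), typically
  on genus-aggregated relative abundances; features unnamed at the
  rank can be dropped or pooled.
* **PCoA**: classical metric scaling (double-centred squared
  distances, symmetric eigendecomposition). Axes are ordered by
  eigenvalue; explained variance is relative to the sum of positive
  eigenvalues; negative eigenvalues (Bray–Curtis is a semimetric) are
  reported, never corrected. Axis signs are fixed by making the
  largest-magnitude loading positive.
* **PERMANOVA**: one-factor (marginal) distance-based partition —
  SS_total = Σ_{i<j} d²ᵢⱼ / n, SS_within summed per group,
  pseudo-F = (SS_among/(a−1)) / (SS_within/(n−a)), R² =
  SS_among/SS_total. The permutation p-value uses the
  (1 + #{F* ≥ F}) / (1 + n_permutations) estimator (unbiased, never
  zero), default 999 permutations, vectorised over permutations. For
  tiny designs an exact mode enumerates every distinct label
  arrangement and reports the exact tail fraction. Sequential
  (type-I/II) multi-factor partitioning is deliberately out of scope;
  each factor is tested in isolation.

## Synthetic data

The generators are pure functions of (spec, seed) and define the
conditions under which the pipeline is tested:

* `simulate_reference_phylogeny` grows a rank tree from random root
  sequences (default 1400 nt); each child mutates its parent by half
  the rank divergence, so siblings differ by approximately the full
  divergence. Default divergences place sibling identities midway
  between adjacent rank thresholds (e.g. sibling species ≈ 96.6 %,
  sibling genera ≈ 90.5 %), so every threshold decision is exercised
  away from its boundary.
* `mutate_to_identity` plants an exact Hamming identity: round((100 −
  target)/100 × length) distinct positions, never silent. The aligned
  identity can drift slightly above the planted value at low targets
  (the optimal alignment exploits chance compatibilities), which is
  why planted-recovery checks keep one percentage point of clearance
  from each threshold.
* `simulate_survey` plants, per group, taxa at occupancies safely
  inside each category band (strict 85 %, general 65 %, loose 35 % of
  samples; CRAT in a single sample at ~2.5 %; rare taxa below the
  0.01 % filter), with log-normal abundance noise and multinomial
  counts at a fixed depth (default 50,000 reads — deep enough that a
  planted 0.5 % taxon essentially never drops below the 0.1 %
  abundance cut by sampling noise). Background taxa fill the remaining
  mass in every sample, which means background taxa are themselves
  core within their group: in fully synthetic communities the
  core + CRAT accumulated abundance is 100 % by construction, unlike
  real surveys where rare and unclassified fractions remain.
* `simulate_primer_templates` embeds both primer binding sites at
  recorded offsets with the requested number and 3'/non-3' placement
  of mismatches, realising degenerate positions to concrete bases and
  forcing mismatches outside the primer's IUPAC set.

What passing these tests shows: the thresholds, counting rules and
statistics are implemented correctly against ground truth. What it
does not show: robustness to chimeras, indel-rich sequencing error,
primer-biased abundance distortion, or compositional effects of real
communities — none of which the generators emulate (substitution-only
mutation, no read-level error model).

## Numerical and degenerate-input conventions

* All ties broken deterministically (lexicographic accessions,
  smallest offsets, creation order), so identical inputs + seed give
  byte-identical outputs everywhere, including TSV files.
* Identity comparisons against thresholds use the exact computed
  float; equality tolerances (1e-9) appear only where two
  independently computed identities are compared with each other.
* Division-by-zero cases are typed: a zero-total sample is an error
  naming the sample; a sample with no retained ASVs is a missing
  value; a taxa-inventory rank where every name is new reports NaN
  ("undefined"), not an exception.
* Percentages are rounded only at the reporting edge (novelty to two
  decimals, inventory increase to one), never inside computations.

## Problem sizes

Default test and acceptance workloads are sized for a laptop-class
single core: reference sets of 16–37 full-length records, ASV pools of
~20 reads, surveys of 40–60 samples × ~130 taxa at depth 50,000,
PERMANOVA with 999 permutations, and 500-replicate null calibrations —
the full test suite runs in well under a minute of pure computation
per heavy check. All stages scale linearly in the number of pairwise
comparisons; nearest-neighbour search is exact (no heuristic
prefilter), which is the right trade-off at database sizes where the
all-pairs scan is still cheap.

## Known limitations

* Exact nearest-neighbour search is quadratic; expanding databases of
  10⁵ references would need a k-mer prescreen (not implemented —
  out of scope at the tested sizes).
* The greedy placeholder clustering is order-dependent by design
  (reproducibility over cluster optimality); a different input order
  can yield a different, equally valid clustering.
* The classifier's confidence calibration inherits SINTAX's behaviour:
  a query far from every reference can still classify confidently if a
  single reference dominates its k-mer overlap.
* Bray–Curtis is a semimetric; the triangle inequality is neither
  guaranteed nor asserted.
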