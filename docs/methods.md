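# Methods

This note records the statistical model behind each component, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the simulation-based validation does and does not
demonstrate.

## Insert-size model

A mate pair's **insert size** is its outer distance on the reference:
`max(end_fwd, end_rev) − min(start_fwd, start_rev)`. The outer distance is
the standard summary for long-insert libraries and is monotone in the
underlying fragment length.

The consistency bounds *(I_min, I_max)* are **nearest-rank percentiles** —
the `ceil(p·n)`-th order statistics at p = 0.005 and 0.995 by default. The
nearest-rank definition is deterministic and integer-valued, avoiding the
interpolation ambiguity between the many percentile conventions; the unit
tests pin it against an independent smallest-rank oracle for every n up to
500. Users can override the bounds, in which case the histogram is still
computed and reported.

**Orientation.** A pair's signature is (strand of forward-role read,
strand of reverse-role read, which role maps upstream) — a 2×2×2
enumeration. The library's expected signature is inferred as the majority
among intra-chromosomal pairs whose outer distance is at most 10× the
median (the gross cap keeps obviously discordant pairs from voting), and
can be forced per platform from the CLI. A fragment sequenced off the
opposite strand of the duplex produces the *mirror* signature — both
strands flipped, upstream role swapped — which is physically the same
library molecule, so the expected signature and its mirror both classify
as consistent. This also makes pairs mapping entirely inside an inverted
segment (locally colinear, reverse-complemented) consistent, as they should
be: only junction-spanning pairs carry variant evidence.

**Classification order.** Inconsistent reasons are assigned in the fixed
order inter-chromosomal → orientation → too close / too far, so reason
counts partition the inconsistent set deterministically.

**Clonal dedup** collapses pairs with identical (chrom, start, strand) on
both sides to the representative with the smallest pair id. The operation
is idempotent and order-independent; whether the percentile bounds are
computed before or after dedup is not externally constrained — this
implementation computes the model on the pairs as given and the caller
dedups internally before classification.

## The caller

Inconsistent pairs are bucketed by canonically ordered chromosome pair
(sequence-dictionary order when a SAM header is available, lexicographic
otherwise) with side A the 5'-ward side, then split by oriented strand
pair. The signature used for clustering is the canonical strand pair
(strand_A, strand_B), under which mirror-form pairs from the same junction
coincide — splitting them would halve the support of every real junction
in duplex data.

**Coarse clustering** is a greedy sweep in (start_A, start_B) order on a
grid of window size `w` (default `2·I_max`; any `w > I_max` is valid — the
doubling leaves slack before refinement): a pair joins the first open
cluster whose side-A and side-B start footprints are both within `w`, and
a cluster closes once the sweep passes it by more than `w` on side A. The
sweep is linear-time and deliberately permissive; over-merging is corrected
by refinement.

**Refinement** is single-linkage agglomerative clustering under the
Chebyshev distance `d(p,q) = max(|Δstart_A|, |Δstart_B|)`, cut at
`refine_cut` (default `I_max`). The rationale: two fragments spanning the
same physical junction must begin within one insert length of each other on
both sides. The scipy dendrogram cut equals the connected components of
the threshold graph `d ≤ refine_cut`; the test suite verifies this
equivalence against a brute-force union-find oracle on hundreds of random
buckets, and the composition is invariant to input order and batch
decomposition.

**Support filtering.** Reported support is the cluster size; *effective
support* is the size after a greedy thinning in which a member is redundant
iff **both** its side-A and side-B read starts lie strictly within 50 bp of
a previously kept member's (scan order: start_A, start_B, pair id). Read
diversity on either side therefore counts as independent evidence — a
conservative guard against PCR stacking that does not discard genuine
distinct fragments. The default mode applies the 3-pair minimum to the
thinned count; a `veto` mode instead thresholds raw support but rejects
clusters with no end diversity at all, for users who read the 50 bp rule as
a cluster-level veto. Defaults: `min_support = 3`, `min_end_spread = 50`.

**Variant classes.** Different chromosomes → translocation; strand pair
differing from the expected oriented strands → inversion; expected strands
with footprint-midpoint span above `I_max` → deletion, below `I_min` →
insertion. Pair consistency is judged on the pair's *outer distance* while
the cluster span is a *footprint-midpoint* distance; the two differ by
about a read length, so clusters of borderline range-discordant pairs can
have spans that fall back inside `[I_min, I_max]`. Such clusters are
resolved toward the nearer range edge (deletion at or above the midrange)
rather than treated as an error, since they arise on perfectly ordinary
data.

## Breakpoint set algebra

Breakpoints `B = chrA:[b1,e1]–chrB:[b2,e2]` and `B′` overlap iff they join
the same canonical chromosome pair and, on each side,
`min(|b−b′|, |e−e′|, |b−e′|, |e−b′|) ≤ I_max`, where `I_max` is the larger
of the two experiments' maximum insert sizes. The predicate is symmetric
and reflexive but **not transitive**; set operations evaluate it per
element of the left-hand set and never chain overlaps (a dedicated test
constructs a three-breakpoint chain to pin this down). The interval index
used for speed is a prefilter only — expanded-footprint intersection is a
strict superset of the endpoint-distance predicate (nested footprints can
intersect while every endpoint distance is large) — so every candidate is
re-checked with the exact formula and indexed results equal the all-pairs
evaluation.

Variant class is ignored by the overlap predicate (the formula is
class-blind); gene proximity in reports uses the gap between the gene
interval and either footprint, `≤ 2000 bp` by default with 0 for direct
overlap. Somatic triage labels a tumour breakpoint germline-like iff it
overlaps any breakpoint of any panel set; with no panels everything is
putatively somatic. Benchmark curves count, per support threshold, the
retained calls (a surrogate for the unknown false-positive rate) and the
truth breakpoints overlapped by at least one retained call; both counts are
non-increasing in the threshold by construction.

## Enrichment permutation test

Each breakpoint contributes the midpoints of its two footprints; windows of
± `radius` (default 50,000 bp — wide relative to insert-scale footprints,
so the midpoint approximation is immaterial) are merged when both sides sit
on one chromosome and the windows overlap, and clipped to chromosome
bounds. The observed statistic counts (feature, window) incidences with
multiplicity by default — a feature near two windows counts twice, keeping
the statistic additive over breakpoints — with a `unique` mode counting
distinct features.

**Null model.** What "expected by chance" randomizes was an open choice;
this implementation re-places each window uniformly at random on its own
chromosome (preserving per-chromosome window counts and widths) while
keeping the feature track fixed. Keeping the track fixed preserves its
spatial clustering, which is the dominant source of spurious enrichment;
per-chromosome placement preserves chromosome-scale composition. The
fold is `observed / mean(null)` and the p-values use the add-one rule
`p = (1 + #{null ≥ obs}) / (n_perm + 1)` (and `≤` for depletion), so p is
never 0 and floors at `1/(n_perm+1)`; with the default `n_perm = 1000` the
floor is ~0.001, giving resolution well below 0.05 at desk-scale runtime.
Both tails are always reported because depletion (e.g. of repressive
marks) is as interpretable as enrichment. Enrichment is computed per
variant class, plus a pooled "all" slice used by the matrix.

Matrix cells are seeded from (seed, track index) only, so samples holding
identical breakpoints produce identical columns regardless of label.
Discriminating-feature selection compares group fold vectors per track with
a two-sided Mann-Whitney rank-sum (default) or t-test at `alpha = 0.05`,
optionally requiring the higher/lower group-mean ratio to reach a
fold-change threshold such as 1.25; the t-test refuses single-sample
groups (undefined variance), the rank-sum warns.

Known limitation: the null is not GC- or mappability-matched; on real
genomes, features and breakpoints both correlated with such covariates can
show enrichment the permutation cannot explain away.

## Simulator

The simulator works at mapping-coordinate level — no sequence, no aligner.
A donor haplotype is a list of reference segments per chromosome: deletions
remove a segment, inversions flip one, insertions interpose an unmappable
novel segment, translocations add a derived fusion chromosome
`chrA[0,posA) + chrB[posB,end)` while leaving the source chromosomes
intact (one junction per fusion; fusion length counts toward donor genome
size). Fragment lengths are Normal(5000, 300) truncated at ±4 sd — the
0.5–99.5 percentile range then sits inside the 4–6 kb band typical of
long-insert libraries — and fragments are placed uniformly on the variant
haplotype with probability `tumor_fraction`, otherwise on the unmodified
reference. Reads are the first and last `read_len` bp (default 50) of the
fragment; a fragment whose read would straddle a junction or land in novel
sequence is resampled, mimicking reads that would fail unique mapping, so
every emitted read maps contiguously. Clonal duplicates are appended per
pair with probability `clonal_rate`; chimeric noise pairs join two uniform
random loci. Truth records one junction per deletion/insertion/fusion and
two per inversion (one per edge, with distinct strand signatures), each
with its realized non-clonal spanning-pair ids.

What the simulator does **not** model: sequencing error, mappability and
GC structure, copy-number changes, micro-homology or split reads, and
real libraries' chimera-rate structure. Passing the validation studies
therefore demonstrates the correctness of the algorithms under the stated
fragment process, not calling accuracy on real genomes.

## Validation studies (`matesv.validation`, `scripts/acceptance.py`)

Problem sizes were chosen to exercise every code path at desk scale: the
standard study plants 50 variants (14 deletions, 14 insertions, 14
inversions, 8 translocations; intra-chromosomal events 20–40 kb, insertions
2.5–3.5 kb so spanning pairs remain mappable and unambiguously too-close)
on a 20 Mb, 8-chromosome genome, with pair count set for 10× clone
coverage of the donor haplotype and 5% clonal duplicates.

Recovery is scored with the caller's insert bounds overridden to the true
truncation range of the simulated fragment distribution. This isolates the
clustering machinery from percentile-tail effects: with estimated bounds,
exactly ~1% of ordinary pairs are range-discordant *by construction of the
percentile definition*, and at genome-scale pair counts those tail pairs
occasionally form chance clusters of three. The percentile machinery is
validated separately (closed-form fixture; ≥98.5% within-bounds coverage on
simulated data, reported by the acceptance script from the same dataset).

The subclonal study reruns the same design at `tumor_fraction = 0.3`
across ten seeds and checks two things: (i) the called junctions are
*exactly* those whose own non-clonal spanning pairs, after dedup and the
50 bp thinning, still number ≥ 3 — an independent per-junction computation
bypassing the clustering; and (ii) the pooled recovery fraction lies within
the 99% envelope of the per-junction Poisson expectation
`P(Poisson(λ_j) ≥ 3)` with
`λ_j = tumor_fraction · n_pairs · w_j / G_donor`, where
`w_j = insert_mean − 2·read_len` minus the novel-sequence length for
insertion junctions (a fragment spans a junction only when both reads
clear it). The expectation ignores the small thinning loss (two spanning
pairs colliding within 50 bp on both sides is a ~0.2% event per pair
pair), which is far inside the envelope.

Enrichment calibration draws breakpoints and features independently and
uniformly over a 2×10 Mb genome, 200 replicates at `n_perm = 500`, and
compares the rejection count at nominal 0.05 to the exact binomial 99%
envelope around the achievable level `floor(0.05·501)/501 ≈ 0.0499`
(observed and null window centers are drawn from the same uniform law, so
the permutation p-value is exactly discrete-uniform by exchangeability).
Power is checked with features planted 1–2 kb from breakpoint midpoints.
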