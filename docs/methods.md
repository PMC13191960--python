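# Methods

This note documents the models implemented in `hicsv`, the assumptions they
make, the defaults and why, what the synthetic generators do and do not
emulate, and the design choices taken where the problem was genuinely open.

## Hi-C evidence framework

### Model

A complex SV that amplifies DNA leaves two distinct signatures in a
balanced Hi-C contact map:

* **ecDNA** — the amplified DNA circularizes and detaches. Its internal
  contacts are abundant (many copies of a small circle ligating to
  themselves), but contacts between the event region and its former
  chromosomal neighborhood do not grow with copy number. After matrix
  balancing (which equalizes bin marginals and therefore divides the
  event's rows by their inflated coverage) the event↔flank "projection"
  contacts drop *below* the local background.
* **BFB / linear amplification** — the extra copies stay on the
  chromosome, so event↔flank contact scales together with event coverage
  and the projection signature is absent; BFB additionally concentrates
  contact at its fold-back junction.

The framework tests exactly this contrast. Events are stratified into four
categories by segment/chromosome count. For categories 1–2 (cis), each
segment is compared against two equal-length unamplified flanks
immediately up- and downstream: the decisive comparison is event-projection
values (event bin × flank bin) versus flank-projection values (upstream bin
× downstream bin), two-sided Wilcoxon rank-sum. For categories 3–4 (trans),
the decisive comparison is intra-cSV cross-chromosome contacts versus
non-overlapping flank-flank contacts between the same chromosome pair.
P-values are BH-adjusted *within* an event across its segments (cis) or
chromosome pairs (trans); the event is supported when at least one decisive
comparison has adjusted p < α = 0.05 **and** the median difference points
in the class-expected direction (event-lower for cis, event-higher for
trans). Sidedness is not dictated by the biology alone, so the test is
two-sided with the direction recorded and enforced at the decision stage;
this also halves the effective false-support rate under the null.

### Distance-decay neutralization

Cis contact frequency decays roughly as a power law in genomic separation.
The event-projection and flank-projection sets occupy overlapping but not
identical separation ranges, so raw values would differ under the null for
distance reasons alone. With `distance_matching` on (default), both
projection sets are (a) divided by the chromosome-wide mean balanced
contact at their separation (observed/expected, standard Hi-C practice) and
(b) restricted to the intersection of the two sets' separation ranges.
Restriction alone is not sufficient: the two sets weight separations
differently within the common range, and under a power-law decay that
residual mixture difference is detectable by a rank test at realistic pair
counts. O/E normalization removes the dependence entirely; the package's
null calibration (false support ≤ α over ≥ 500 simulated null events)
holds with both mechanisms active.

### Flanks, masks, testability

Flank construction walks outward from the segment, skipping bins that are
masked (zero coverage / unmappable) or belong to *any* amplified segment of
any event in the sample, extending farther out rather than shrinking — this
preserves "unamplified, equal length" as closely as the neighborhood
allows. Flanks truncated at chromosome ends are flagged. A comparison with
fewer than `min_pairs_per_set = 10` values in either set is *untestable*
(reported with its reason), not a failure; an event with no testable
comparison gets `supported = None`, distinct from a negative call. The
support decision is recomputable from the stored per-comparison results
alone.

### Balancing

`iterative_correction` is plain ICE: alternately scale rows/columns by the
square root of their relative marginal until all unmasked marginals agree
within `tol = 1e-6` (relative); bins with zero marginal are masked rather
than treated as observed zeros. The bias vector is stored; balancing is
idempotent within tolerance, and non-convergence after `max_iter = 200`
yields a result flagged unbalanced plus a warning.

## Statistical primitives

Implemented in `hicsv.stats` with scipy used only for reference
distributions (normal, χ², F, hypergeometric pmf):

* **Wilcoxon rank-sum** — exact p by enumeration of all rank assignments
  when the combined sample is ≤ 12 with no ties (tiny projection sets can
  occur); otherwise normal approximation with midranks, tie-corrected
  variance, and continuity correction. The statistic is the Mann-Whitney U
  of the first sample.
* **Benjamini–Hochberg** — classic step-up with monotonicity enforcement,
  order-preserving.
* **Fisher exact 2×2** — two-sided p = sum of hypergeometric masses ≤ the
  observed table's mass (fixed margins); degenerate margins give p = 1.
* **Kruskal–Wallis** — tie-corrected H, p from χ²(k−1).
* **Nested F** — extra-sum-of-squares test of adding a 0/1 ecDNA indicator
  to an intercept+CN OLS model: F = (SSE_r − SSE_f)/(SSE_f/(n−3)). A
  perfect full fit with residual reduced-model error is reported as
  (∞, p = 0) so noise-free synthetic cases remain representable; a perfect
  reduced fit gives (0, 1). Collinear designs raise an error naming the
  collinearity.

## Chromothripsis caller

A window of 2.5 Mb positioned at 10 kb steps. Counts per window: inversion
breakpoints with **both** breakends inside the window, deletion breakpoints
likewise, and adjacent copy-number segment boundaries with |ΔCN| > 0.5
inside the window. A window is called when all of (≥ 15 inversions, ≥ 15
switches, ≥ 10 deletions) hold; a chromosome is positive if any window is
called, and overlapping called windows merge into regions. The 0.5-copy
switch magnitude separates adjacent integer CN states at typical purities;
requiring both breakends inside the window avoids double-counting an SV
whose ends straddle window borders (windows overlap heavily anyway). SV
type is taken from the input when present, else inferred from strand
orientation (+/− DEL, −/+ DUP, same-strand INV, inter-chromosomal TRA).

## Copy-number annotation

Gene-level CN is the mean of overlapping segment CNs weighted by the bp
each segment covers of the transcript span. When segments only partially
tile the gene, weights renormalize over *covered* bp — total-length
weighting would deflate CN at assembly gaps through no fault of the
segmentation. Status thresholds are strict inequalities relative to tumor
ploidy (biallelic loss < 0.5 absolute takes precedence; autosome gain
> 1.95×, loss < 0.5×; single-copy sex chromosome gain > 0.8×, loss
< 0.3×); values exactly at a threshold are the non-call branch.
Event-weighted CN is the segment-length-weighted mean over an event.

## Convergence scoring

Two measures per cross-sample event pair sharing a locus: interval Jaccard
over merged footprints, and a breakpoint Jaccard index where junctions
match iff chromosome pair, strand pair, and both positions within
`tol_bp = 100` (typical short-read breakpoint precision) — matching is
greedy one-to-one by total distance with a smaller-coordinate tie-break.
Verdicts: `shared` at breakpoint Jaccard ≥ 0.25, `independent` when the
footprints overlap but breakpoint Jaccard ≤ 0.05, else `indeterminate`.
The cutoffs are surfaced in the API; they separate the two generator
regimes (identical junctions vs junctions ≥ 5 kb apart) by a wide margin.

## Enrichment permutation test

The observed statistic is the number of query intervals overlapping ≥ 1
peak. Each permutation re-places every query interval uniformly at random
over the mask-free space of its own chromosome (exact gap-sampling over
feasible start positions — every placement preserves length and chromosome
and cannot touch the exclusion mask). Empirical
p = (1 + #{null ≥ observed})/(n_perm + 1), deterministic per seed. Interval
placements are independent of one another; inter-interval spacing is not
preserved. Annotation positivity is a separate rule — ≥ 100 bp overlap
(inclusive) with any peak, per event over all its segments — while the
permutation statistic uses any-overlap, mirroring the distinction between
annotation and randomization conventions in region-overlap practice.

The calibration benchmark draws queries and peaks independently and checks
the empirical p is approximately uniform. Its default dataset geometry
(100 queries of 5 kb, 1,400 peaks of 2 kb on a 20 Mb chromosome) puts the
per-query hit probability near 0.4 so the count statistic spreads over many
values; with a near-degenerate count distribution the empirical p is
heavily discretized (conservative) and uniformity cannot be resolved.

## Expression model

Per gene: samples carry log2(TPM+1) expression, continuous weighted CN, and
an ecDNA indicator (1 iff the gene span intersects any ecDNA-class segment
of that sample; any overlap counts). The scan runs the nested F test per
gene and BH-adjusts across tested genes; genes failing preconditions
(n < 4, a single ecDNA group, collinearity) are reported untested with the
reason. CN enters as a continuous covariate; a categorical status covariate
can be emulated by passing status codes in its place.

## Phylogeny

Sample distance is the Hamming count over binary deleterious-mutation
profiles — the natural complement of annotating branches by shared
mutations, and exactly additive on infinite-sites clonal data. NJ follows
the classic Q-criterion with deterministic lexicographic tie-breaks,
standard branch-length formulas, and negative lengths clamped to zero with
a warning; on any additive matrix it reproduces topology and path lengths
exactly. An optional all-zero germline pseudo-sample provides the outgroup;
the returned tree is rerooted on the germline edge (default on, since
clonal trees are conventionally drawn rooted). Trees are scikit-bio
`TreeNode` objects serialized as Newick.

## Synthetic generators

All generators are pure functions of (parameters, seed). The Hi-C
generator draws Poisson counts around

    e_ij = B (|i−j|+1)^(−α) m_i m_j   (cis),   e_ij = B τ m_i m_j   (trans)

with m = ρ·cn/ψ + (1−ρ) the purity-mixed chromosomal multiplier
(ρ purity, ψ ploidy). Defaults: α = 1 (standard empirical cis decay),
B = 200 (tens of counts at short range, single digits at megabase range —
the regime of a tumor biopsy Hi-C library at 10 kb bins), τ = 0.05,
ψ = 2, ρ = 0.7 (a typical metastatic biopsy). ecDNA adds
ρ(A−1)·B·decay only to pairs with both bins inside the event (A is the
amplification factor: at ρ = 1 the intra-event mean is exactly A×
baseline); BFB instead raises the chromosomal multiplier of its bins and
multiplies a fold-back hotspot block (factor 4, ±3 bins) at its 3′
junction. Benchmark scenarios use one 2.2 Mb chromosome (220 bins) with a
16-bin event for cis and two 1.2 Mb chromosomes with 12-bin segments for
trans — large enough for full flanks and hundreds of contact pairs per
set, small enough that a 500-replicate calibration runs in seconds.

What the generator does **not** emulate: restriction-fragment and GC/
mappability biases (balancing is still exercised, but the bias vector it
removes is coverage-driven), TADs/compartments/loops, subclonal CN
heterogeneity, translocation-induced neo-contacts outside the event, and
read-level artifacts. Passing calibration and power tests therefore show
the statistical machinery behaves correctly under the stated generative
model, not that real-library bias structure is handled beyond what ICE and
O/E normalization remove.

The chromothripsis generator places exactly the requested breakpoint and
oscillation counts (1 kb minimum spacing, |ΔCN| = 1 oscillations) inside a
region; the cohort generator gives every sample an amplification of the
same locus, with listed groups sharing identical boundaries/junctions and
all others drawn ≥ 5 kb apart; the expression generator draws CN with a
heavier tail in ecDNA-positive samples (deliberate confounding so the
nested test is genuinely exercised); the mutation generator assigns each
branch of a given tree its own variant set (perfect phylogeny).

## Numerical and interface choices

* Internal coordinates are 0-based half-open everywhere; the PURPLE-like
  TSV dialect (1-based inclusive) converts at the I/O boundary only.
* Contact matrices store the upper triangle in text (bins + pixels tables);
  construction mirrors it and masks zero-coverage bins. Cooler input is not
  supported; the text pair is the interchange format.
* Writers emit full-precision `repr` floats so write→read round-trips are
  exact.
* Ties in NJ's Q-matrix, in breakpoint matching, and in rank assignment all
  break deterministically; every stochastic component takes an explicit
  seed, and the end-to-end pipeline is byte-identical under a fixed seed.
* `run_all` demo scale: 6 cis + 3 trans Hi-C candidates (alternating true
  and null), one chromothriptic and one sub-threshold chromosome, a
  4-sample convergence cohort, a 6-gene expression scan at n = 60, and a
  6-leaf phylogeny — chosen to exercise every decision branch in well under
  a minute.

## Known limitations

* The Hi-C test assumes one candidate event list per sample is complete;
  an unlisted neighboring amplification would contaminate flanks.
* Trans evidence needs stored trans pixels for the chromosome pair;
  sparse trans coverage makes events untestable rather than unsupported.
* The BFB fold-back hotspot is a coarse stand-in for true fold-back
  junction geometry; the framework only relies on BFB *lacking* the ecDNA
  projection signature.
* Breakpoint Jaccard ignores copy-number of junctions and cycle structure;
  two rearrangements sharing all junctions but differing in amplicon
  topology score as identical.
* The expression model is a two-covariate OLS; it does not model
  library-size or batch structure and expects expression already
  normalized to log2(TPM+1).
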