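# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter for
reproducibility.

## Objects and vectorization

A correlation matrix is accepted when it is symmetric within 1e-8, has a
unit diagonal within 1e-8, and has entries in [−1, 1] (overshoots up to
1e-12 are clamped as float round-trip noise; larger ones are errors).
Positive semidefiniteness is checked against a relative tolerance
(smallest eigenvalue ≥ −1e-8·q) and reported as a warning unless strict
validation is requested, because sample correlation matrices that have
passed through text serialization routinely pick up eigenvalues a few ulps
below zero.

**Snake ordering.** The canonical ordering concatenates the superdiagonal
bands k = 1…q−1, walking odd bands top-to-bottom and even bands
bottom-to-top. For repeated-measures matrices band k collects the lag-k
correlations, so the ordering preserves an interpretable temporal/spatial
structure; it also makes band truncation (`--max-lag`, for systems with
finite memory whose matrices are ribbons around the diagonal) a contiguous
prefix of the vector. A row-major upper-triangle ordering is provided as
an alternative; any fixed ordering applied consistently across a
collection induces the same Euclidean geometry, and a test verifies that
cluster labels are invariant to the choice. The exact serpentine path
(start corner, alternation) is a declared convention, not a canonical
standard.

**Dragons.** Dragon 1 = [snake | means | variances] computed from a
variables × repeats data matrix (variances are unbiased, divisor n−1,
throughout the package). Dragon 2 = [snake | network summaries], where the
summary block is a fixed four-field set: mean off-diagonal |r| (no
threshold), hub count, characteristic path length, and mean degree, the
last three on the graph with an edge wherever |r| ≥ τ (default τ = 0.25).
Hubs are nodes with degree > mean + 2 SD of the degree sequence
(population SD: the degree sequence is the full population of interest,
not a sample). Path length averages shortest paths over *connected* pairs
and reports the connected fraction separately; an empty graph yields NaN.
A small deterministic summary set was preferred over a configurable menu
so that dragon-2 vectors are comparable across runs. Dragon 3 concatenates
per-site snakes in recipe order; dragon 4 concatenates arbitrary named
blocks.

**Scaling.** Each coordinate is centered by its reference mean (whole
cohort by default, or a designated control subset). The default
`per-segment` policy divides every coordinate in a segment by the square
root of the segment's *mean* per-coordinate variance: one scale per
segment equalizes segments' influence while preserving the relative
magnitudes — hence the correlation structure — inside a segment.
Per-coordinate z-scoring is available as an explicit alternative for users
who prefer every coordinate on unit variance. After per-segment scaling
the mean per-coordinate variance in each segment is exactly 1 (tested at
1e-10). Snakes clustered alone are not scaled: correlations already share
the [−1, 1] scale.

**PCA.** Components are retained up to 90% cumulative explained variance
by default (a conventional cutoff; the choice is exposed). With
`variance-explained` weighting, each retained score is multiplied by its
component's explained-variance fraction, shrinking the influence of minor
components instead of truncating them abruptly.

## Matrix-distance baselines

Random skewers draws skewers with iid uniform[−1, 1] entries, normalized
to unit length (standard practice; Pearson correlation of the responses
makes the normalization immaterial, which is why sources rarely state it).
100 skewers per pair by default. In all-pairs mode each unordered pair
(i, j), i < j, gets its own generator keyed (seed, i, j), so the distance
matrix is exactly symmetric and independent of evaluation order.

The T statistic sums |A_ij − B_ij| over the upper off-diagonal triangle —
each unordered pair once; summing the full matrix would merely double
every distance.

S1 is implemented as the operationalization

    S1(A, B) = Σ_k ( |λ_k^A − e_k^Aᵀ B e_k^A| + |λ_k^B − e_k^Bᵀ A e_k^B| )
               / (tr A + tr B),

the total mismatch between each matrix's eigenvalues and the variance its
eigenvectors explain in the other matrix, trace-normalized. It is
symmetric, non-negative, and zero iff each eigenbasis explains the other's
variance exactly as its own. The originally published S1 is defined in a
separate source not reproduced here; this package's S1 should be cited as
the formula above.

## Clustering engine

Consensus clustering follows the resampling scheme: each of 1,000
resamples selects ⌈0.8N⌉ objects, k-means partitions the subset for every
k in 2…8, and the consensus value for a pair is co-cluster count over
co-sample count. Subsets are *distinct* objects by default: duplicated
objects inside one k-means run would distort centroids, and the co-sample
denominator is only well-defined for distinct membership. A
`with_replacement` flag implements literal resampling with replacement,
collapsing duplicates for counting. Pairs never co-sampled (probability
≈ (1 − 0.64)^1000 per pair at the defaults, i.e. negligible) are imputed
with the global mean consensus under a logged warning.

Reproducibility protocol: resample r uses `default_rng([seed, r])`, which
draws the subset first and then one k-means seed per scanned k in
ascending order. Replay tests reconstruct the counts independently from
this protocol.

Final labels per k cut a Ward tree built on 1 − consensus. Ward's
variance interpretation is heuristic on a probability-derived
dissimilarity; it is used because a Ward-capable hierarchical tool on
consensus distances is the procedure being emulated, and average linkage
is available by flag. The Calinski–Harabasz criterion is evaluated on the
vectors that were actually clustered (post scaling/PCA when those were
applied) — the criterion must see the geometry the algorithm saw — and the
chosen k maximizes it, the smallest k winning ties. k-means uses k-means++
seeding with 10 restarts per subset. Merge ties in the hierarchical step
are resolved by the linkage implementation's fixed scan order;
deterministic for a given input, but no particular tie rule is promised.

## Noise simulator

A prototype matrix is used as the covariance of a zero-mean multivariate
normal (the mean is irrelevant to correlations); a q × n draw's sample
correlation matrix is one noisy replicate. Draws go through an
eigenfactor of the prototype; eigenvalues in [−1e-6, 0) are clipped to
zero with diagonal renormalization, anything lower is rejected as
invalid. For n < q the replicate is rank-deficient — expected and legal;
the noisiest benchmark setting is n = 3 with q = 36. n is derived from
the q/n ratio by rounding to the nearest integer with a floor of 2, and
both are reported.

The SNR between two classes is the Euclidean distance of the snake-
ensemble centroids over the pooled RMS within-class deviation,
sqrt((SS₁ + SS₂)/(M₁ + M₂)); both numerator and denominator are under
square roots, fixing an ambiguity that arises when the formula is typeset
without explicit radicals. Zero within-class spread yields +inf with a
warning.

**Prototype pair generator.** Each prototype is a convex combination
w·(block structure) + (1−w)·(shared dense background) with w = 0.8. The
block structure is a factor construction — node i loads √ρ_i on its
community's factor, ρ_i ~ U(0.7, 0.95) — giving within-community
correlations √(ρ_i ρ_j) and zero between; one class has 4 communities,
the other 2, with the second class's community boundaries rotated by 4
nodes so the layouts are misaligned rather than nested. The background is
a full-rank Wishart-type correlation matrix shared by both classes,
playing the role of the diffuse correlation structure two classes of real
matrices have in common; because it is shared it adds realism (a full
eigenvalue spectrum, nonzero background correlations) without adding
separation. Convex combinations of unit-diagonal PSD matrices are valid
correlation matrices, so the construction needs no repair. When a target
SNR floor is requested, a pilot simulation (10 matrices per class at
q/n = 4) checks the pair and regenerates up to a bounded number of
attempts; the defaults above clear a 1.2 floor at q = 36 across seeds.

What the simulator does *not* emulate: real connectivity matrices' spatial
autocorrelation, global signal structure, negative-correlation blocks,
and measurement artifacts; class differences that are diffuse rather than
community-based. Passing benchmarks therefore demonstrate correctness of
the machinery and the direction of noise effects, not performance on any
particular real data set. Notably, because the synthetic class difference
is a low-dimensional community rearrangement, eigenstructure statistics
(RS, S1) are *stronger* baselines here than on typical real matrix pairs,
and the observed error-free regime begins slightly above the SNR floor
(realized SNR ≈ 1.3) rather than exactly at it.

**Benchmark.** Per grid point, 20 matrices per class are simulated, the
ensemble SNR recorded, and all 40 objects clustered into k = 2 (the
benchmark's classes are known to be two) by six routes: RS/T/S1 distances
with Ward hierarchical clustering, and snake vectors with Ward, k-means,
and consensus clustering. Misclassification is scored under the best
bijection between predicted and true labels (Hungarian assignment), so it
is invariant to label permutations; with 40 balanced objects its chance
level is ≈ 0.44, not 0.5, because the best bijection absorbs part of the
random fluctuation. Each grid cell is seeded as (seed, cell index) and
failed cells are recorded as NaN rather than aborting the grid. Default
consensus depth inside the benchmark is 200 resamples (k = 2 only), a
deliberate reduction from the standalone default of 1,000 chosen to keep
a full grid affordable; the standalone default is used where the
consensus-versus-alternatives comparison itself is the question.

## Statistical evaluation

Covariate characterization routes categorical variables to chi-square,
and continuous variables to one-way ANOVA when every cluster passes a
Shapiro–Wilk normality screen at α = 0.05 (clusters with fewer than 3
observations are not screened), otherwise to Kruskal–Wallis. The screen
operationalizes "use ANOVA for normal data" with a concrete, seeded
check. All raw p-values are jointly Benjamini–Hochberg adjusted.

Element-wise cluster comparison uses Welch's t per off-diagonal element
(per-element variances across subjects are not assumed equal), BH across
all q(q−1)/2 elements; elements with zero range in both clusters are
skipped. Subnetwork block differences average off-diagonal elements with
one endpoint in each block (each unordered element pair once; within-block
cells use the block's upper triangle); the relative difference
R = (c₂ − c₁)/c₁ is flagged undefined when c₁ = 0, and the element-count-
weighted recombination of block means reproduces the global off-diagonal
mean difference exactly (tested at 1e-12).

Shannon diversity SI = −Σ r_i ln r_i with 0·ln 0 = 0; normalized SI =
SI/ln R for R ≥ 2 and undefined for a single taxon (where SI = 0).

## Problem sizes in the test suite

The simulation-backed tests run at q = 36 with 20 matrices per class —
the scale the methods are designed for — with 200 replicates for
noise-profile estimates, 20 independent benchmark runs for trend
assertions at the noisiest grid point (1,000-resample consensus there,
200 elsewhere), and 5 runs for null controls. These sizes give stable
means for the quantities asserted while keeping the default suite in the
low minutes.

## Known limitations

- S1 is an operationalization of a verbally defined statistic; agreement
  with the original publication's numbers is not guaranteed.
- Consensus-tree cutting can undershoot the requested k when consensus
  values tie heavily (e.g. ideal separation); an average-linkage merge-down
  repair then forces exactly k clusters.
- Network summaries are unweighted; no small-worldness, modularity, or
  weighted path lengths.
- The simulator's two-class benchmark fixes k = 2; model selection is
  exercised separately through the Calinski scan.
- Imaging, OTU/BIOM, and database formats are out of scope; inputs are
  delimited text.
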