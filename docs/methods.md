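# Methods

## The wTO score

The adjacency is the pairwise correlation matrix (Pearson by default;
Spearman = Pearson on average-rank-transformed rows, average ranks for
ties) with the diagonal forced to zero. The wTO of a pair augments the
direct correlation with the summed agreement of the two nodes'
correlation profiles:

    ω_ij = ( Σ_{u=1..N} a_iu a_uj + a_ij ) / ( min(k_i, k_j) + 1 − |a_ij| ),
    k_i = Σ_j |a_ij|.

The numerator sum deliberately includes u = i and u = j; with a zero
diagonal those terms vanish, so no exclusion logic exists. The
numerator is accumulated in double precision as the matrix product
A·A restricted to the reported rows/columns. Provable properties, all
enforced by tests: |ω| ≤ 1; the unsigned variant (|a| fed into the same
formula) lies in [0, 1] and dominates |ω_signed| pairwise; permuting
node labels permutes the output; the subset of interest only restricts
which pairs are reported, never the sums.

The denominator min(k_i, k_j) + 1 − |a_ij| is nonnegative and reaches
zero only when two nodes connect solely to each other with |a| = 1;
there we return ω = a_ij, the continuity limit.

The diagnostic self-overlap ω_ii = Σ_u a_iu² / (k_i + 1) uses the
absolute-value strength k_i in the denominator (the form consistent
with deriving it from the pair formula with a zero diagonal; for
nonnegative adjacencies the readings coincide). It is never emitted in
edge lists.

Zero-variance rows have undefined correlations that would poison every
sum, so they are dropped with a logged warning at read time; a
zero-variance row surviving to the correlation step is a hard error
naming the node.

## Resampling significance

The null/empirical distribution is built by recomputing the full
adjacency + wTO pipeline on each resampled matrix.

**Bootstrap.** Columns (samples) are drawn with replacement. The
reported p is the instability fraction P(|ω* − ω̂| ≥ δ), the estimated
probability that a resampled weight leaves the δ band around the
observed weight (δ default 0.2 — a band much wider than the resampling
noise of a stable link). This is a *stability* measure, not a
classical null p-value: it is small when the link weight is
reproducible under resampling. The raw fraction can be 0 at the
resample resolution; the assembled significance table floors it at
1/n so that p ∈ (0, 1] and downstream Fisher combination never takes
log 0.

**Blocked bootstrap.** For time series without replicates, overlapping
moving blocks of `lag` consecutive columns are drawn with replacement,
concatenated, and truncated to the original length; within-block
temporal order is preserved, so autocorrelation up to the block length
survives resampling. lag = 1 degenerates to the plain bootstrap.
`suggest_lag` picks the block length as the median over rows of the
largest lag whose autocorrelation exceeds the 95% white-noise band
1.96/√S (minimum 1); the partial autocorrelation function would be a
defensible alternative rule.

**Reshuffle.** Node labels are permuted independently within each
sample, preserving each sample's value distribution while destroying
all inter-node dependence. The two-sided permutation p uses the
add-one correction, p = (1 + #{|ω*| ≥ |ω̂|}) / (n + 1), which is never
exactly zero and finite-sample valid. On independent data these
p-values are approximately uniform (tested by KS statistic and the
fraction below 0.05).

Both the signed and the unsigned channel get p-values and adjusted
p-values; multiple-testing adjustment is Benjamini–Hochberg by default
(Bonferroni and Holm available) via statsmodels. Quantile thresholds at
0.1%, 2.5%, 10%, 90%, 97.5% and 99.9% are reported for the pooled
resampled distribution and the real wTO distribution, using type-7
(linear-interpolation) quantiles — a convention fixed for
bit-reproducibility.

**Determinism and parallelism.** Each resample draws its RNG from a
child SeedSequence spawned from the master seed by resample index, so
the output is bit-identical for any worker count and any scheduling.

## Consensus network

Input networks are edge tables (node1, node2, weight, p). Nodes absent
from any network are removed first — a consensus cannot be computed
for factors not measured everywhere. A pair missing from a subset of
networks while both endpoints are present is zero-filled (ω = 0,
p = 1) by default, consistent with treating insignificant links as
zero weight; a flag drops such pairs instead. The consensus weight is

    Ω_ij = Σ_k α_ij^k ω_ij^k,   α_ij^k = |ω_ij^k| / Σ_k |ω_ij^k|,

a convex combination: min_k ω ≤ Ω ≤ max_k ω, weighted toward the
larger magnitudes, with sign conflicts shrinking |Ω| strictly. When
all inputs are zero, Ω = 0 and the α are reported as zeros. Sign
conflicts are *shrunk*, not removed; the explicit |Ω| threshold
operation realizes removal when wanted. P-values combine by Fisher's
method, X = −2 Σ ln p ~ χ²(2k); combined p-values are not re-adjusted
for multiple testing by default (a flag applies BH).

## Network post-processing

Filtering keeps links with |weight| ≥ w_min and p ≤ p_max (ties kept;
idempotent and monotone). Community detection offers nine igraph
algorithms (walktrap, optimal, spinglass, edge_betweenness,
fast_greedy, infomap, louvain, label_prop, leading_eigen), all run on
|weight| because modularity-style objectives require nonnegative
weights; the sign survives as a link attribute. Spinglass and the
edge-betweenness dendrogram require connected graphs, so they run per
connected component. Cluster ids are contiguous integers from 0;
stochastic methods are seeded. Export writes the edge-table dialect or
GraphML with weight, sign, p-value, cluster and node-class attributes;
a GraphML round trip reproduces the graph exactly.

## Synthetic data

The generators emulate the two study designs the method targets.
`make_block_expression` draws multivariate normals with a
block-structured correlation matrix (planted modules; equicorrelation
ρ_w within, ρ_b between; PSD-checked before Cholesky, with the
offending eigenvalue reported otherwise) and can negate a fraction of
node profiles to plant genuinely negative correlations.
`make_ar1_series` produces stationary AR(1) rows (variance
1/(1 − φ²)), optionally cross-correlated through the same block
structure, for the blocked-bootstrap pathway. What these fixtures do
*not* emulate: heavy tails, count noise and library-size effects of
real RNA-seq, compositionality of relative-abundance data, or
nonstationary seasonal structure. Passing tests therefore demonstrate
correctness of the algorithms and calibration under Gaussian
conditions, not robustness to those real-data features (Spearman mode
is the built-in mitigation for monotone non-Gaussianity).

Default study conditions used by the tests and the acceptance script:
two blocks of 30 nodes at ρ_w = 0.7, ρ_b = 0, 100 samples (power and
module recovery); 30 independent nodes × 50 samples with 200
permutations (type-I error); AR(1) with φ = 0.8, 200 time points,
block length 5, 500 replicates (blocked bootstrap); 500 nodes × 100
samples with 100 bootstraps (runtime smoke). These sizes keep every
check at desk scale while leaving the measured effects far from the
pass thresholds.

## Numerical conventions

Correlations are clipped to [−1, 1] and symmetrized before the
diagonal is zeroed. Edge endpoints are stored lexicographically sorted
everywhere, preventing silent A–B / B–A duplication across networks.
Numeric output uses 12 significant digits. Every output directory
receives a provenance record (config, seed, package version, input
checksums).

## Known limitations

- The bootstrap p is a stability fraction, not a frequentist error
  rate; calibrations that apply to the permutation p do not transfer.
- Dense algebra throughout: memory scales as N² (the method is
  inherently dense — every pair is correlated).
- The δ band is on the wTO scale and does not adapt to sample size;
  for very small S a resample can be degenerate (a single column drawn
  S times), which is handled by deterministic redraw from the same
  stream.
- Clustering on |weight| discards sign information at the partition
  stage; a signed-modularity method would treat anti-correlated
  modules differently.
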