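# Methods

`persnet` compares collections of weighted gene coexpression networks
(WGCNs) without choosing an edge threshold.  Each expression matrix becomes
a weighted network; the network's multiscale connectivity is summarized by
persistent homology; networks are compared by the bottleneck distance
between their persistence diagrams; and the resulting distance matrix is
clustered.  This note records the model, the numerical choices, and what the
synthetic benchmark does and does not demonstrate.

## From expression matrix to network

Given a genes × samples matrix, the genes with the largest spread are
retained (top *k* by variance by default, `keep=400` on real microarray
data; IQR is available for heavy-tailed data).  Genes with zero spread are
excluded before ranking because a constant profile has no defined
correlation.  The similarity between two retained genes is the absolute
Pearson correlation |r| of their profiles, so strong negative coexpression
counts as similarity; the network dissimilarity is d = 1 − |r|, mapping
maximal coexpression to distance 0 and independence to distance 1.

The 1 − |r| transform is the canonical WGCN dissimilarity; the alternative
sqrt(1 − r²) (chordal) transform is not used.  d need not satisfy the
triangle inequality, and no metric repair is attempted: the Rips filtration
below is well defined for any symmetric nonnegative matrix.  Rows containing
missing values are dropped at load time with a logged count; no imputation
is performed.

## Persistent homology of the filtration

The Vietoris–Rips (clique) filtration of d is used: at scale ε the complex
contains every vertex, every edge with d ≤ ε, and every triangle whose three
edges are present.  Because the complex is determined by its edges, the
filtration value of a higher simplex is the maximum of its edge values.
Simplices are ordered by (value, dimension, lexicographic vertex tuple),
which places faces before cofaces and makes the computation deterministic.

Homology is computed over GF(2) by the standard left-to-right boundary
matrix reduction with lowest-one pairing, processed from high to low
dimension with the clearing (twist) optimization.  Columns are Python
integers used as bitsets, so column additions are single XOR operations.
Only dimensions 0 (connected components) and 1 (loops) are reported;
triangles are enumerated solely to kill loops.  Pairs with equal birth and
death are discarded — they never affect any diagram distance.  The one
component that survives to the end of the filtration is kept as a flagged
essential pair; if the filtration is truncated below the largest edge value,
unkilled loops likewise appear as essential dimension-1 pairs.

For dimension 0 alone there is a much cheaper route: every vertex is born at
0 and components only merge, so the finite deaths are exactly the minimum
spanning tree edge weights (Kruskal order).  `h0_via_mst` implements this in
O(n² log n) with a union–find, and is the default path whenever loops are
not requested.  The two paths are cross-checked against each other in the
test suite on random matrices.

Practical sizes: the triangle count grows as n³/6 (n = 400 genes gives
about 10.6 million triangles), so dimension-1 analysis of large networks
should either restrict the gene count (n ≤ 150 is comfortable) or lower the
filtration cap `max_value` below its default of 1.0 (the natural maximum of
a 1 − |r| network).  Dimension-0 analysis via the MST runs in seconds at any
realistic gene count.  Filtration values are kept as exact input floats; no
binning of thresholds is performed.

## Distances between diagrams

The bottleneck distance is the minimax cost over augmented bijections
between two diagrams: points may be matched to each other (L∞ cost in the
birth–death plane) or to their diagonal projections (cost half their
persistence), so diagrams of different sizes are comparable.  The optimum is
always attained at one of the finitely many candidate costs — the pairwise
L∞ distances plus the diagonal costs — so the implementation binary-searches
the sorted candidate set, deciding feasibility at each candidate by maximum
bipartite matching on the augmented graph.  The result is exact: no floating
tolerance enters, and the returned value is always an element of the
candidate set.  The q-Wasserstein distance replaces the max by a sum of q-th
powers and is solved exactly as a square linear assignment problem on the
point sets padded with diagonal slots, with the same L∞ ground metric; the
bottleneck distance is its q → ∞ limit and never exceeds any d_q.

Essential pairs are excluded from distance computation.  Every
connected-at-1 network carries exactly one essential component, so matching
essential to essential adds a constant zero and no discriminative
information; this exclusion is an assumption, documented here, about how
infinite classes should be treated.

Tests validate both distances against brute-force enumeration over all
augmented bijections on diagrams with up to four points, together with the
metric axioms and the d_B ≤ d_q ordering.

## Clustering and choosing the number of clusters

The pairwise bottleneck distances between all networks (dimension 0 by
default; dimension 1 by flag) form the input to Ward's agglomerative
clustering in the ward.D2 dialect — input distances are treated as
Euclidean-like and squared inside the Lance–Williams recurrence — as
implemented by scipy.  Ward linkage is monotone, so merge heights never
decrease.

The cluster count is scored by K-means on a classical multidimensional
scaling embedding of the distance matrix (double-centered squared distances,
eigendecomposition, positive-eigenvalue axes retained; negative axes —
bottleneck matrices are rarely exactly Euclidean — are dropped with a logged
warning, and the Gram-matrix error of the embedding equals exactly the
energy of the dropped eigenvalues).  For each k in 1..k_max, K-means runs
with seeded greedy farthest-point initializations (25 restarts by default,
plus one init derived from the previous k's solution so the WSS curve is
nonincreasing), and the within-sum-of-squares WSS_k is scored by

    BIC(k) = n · ln(WSS_k / n) + k · ln(n).

Two readings of this curve are reported.  `k_bic` is the raw argmin.  With
few networks per cluster the argmin is unreliable: splitting a handful of
points essentially always reduces WSS by more than the factor
exp(−ln(n)/n) that the penalty can absorb (about 14% at n = 20), so the
curve keeps drifting downward after the true cluster count regardless of
how well separated the clusters are.  BIC curves of this type are therefore
conventionally read at their elbow, and `k_elbow` — the k of maximum
positive curvature (largest second difference) — is the package's selection
rule (`k_selected`), with the argmin used only when the grid is too short to
define a curvature.  On the synthetic benchmark below, the BIC drop at the
true k = 4 is 47–77 units while no later step gains more than 8, so the
elbow is unambiguous; ties in either rule break toward smaller k.

## The synthetic benchmark

The generator emulates a study of several stress groups, each contributing
several replicate experiments.  A group's template partitions the genes
into coexpression modules and assigns each gene a sign; a replicate draws
one latent factor per module and sets

    x_g = s_g · a · f_{m(g)} + ε_g,    ε_g ~ N(0, σ²) i.i.d.,

so genes of one module reach |r| = a²/(a² + σ²) in the large-sample limit
(0.9 at the defaults a = 0.9, σ = 0.3) while cross-module genes are
uncorrelated.  Defaults: 4 groups × 5 replicates, 200 genes × 40 samples.

Two design points deserve emphasis.

*Groups differ in module count.*  A topological summary of an unlabeled
network is invariant under gene permutation, so two groups that differ only
in *which* genes are coassigned — same module count, same loading — produce
statistically exchangeable dissimilarity matrices and are provably
indistinguishable by any label-free method; direct measurement confirmed
within-group and between-group bottleneck distances of 0.115 vs 0.116 under
that design.  Groups must therefore differ in permutation-invariant
structure, and the count of long-lived components is exactly the feature
0-dimensional persistence detects.  Group g is partitioned into
`n_modules + g · module_count_step` modules (5, 7, 9, 11 at the defaults),
emulating stress responses that engage characteristically different numbers
of coexpression modules.  Each missing or extra long-lived component costs
half its persistence in the bottleneck metric — a large, stable separation
(≈ 0.4 at the defaults) between any two groups.

*Finite-sample orthogonalization.*  At 40 samples the sample correlation
between two nominally independent factors has standard deviation
1/√40 ≈ 0.16, and these chance alignments — not the template — then dictate
when modules merge in the filtration: replicates of one group scattered by
up to 0.27 in bottleneck distance, the same order as the between-group
signal.  The generator therefore orthonormalizes the factor matrix across
samples (QR), making factor sample correlations exactly zero, and projects
each gene's noise vector orthogonal to the factor span (rescaled to keep its
norm), so a spurious cross-module gene correlation can arise only from
noise–noise interaction (sd ≈ σ²/(a² + σ²)/√n ≈ 0.016).  With these
controls, replicates of a group stay within ≈ 0.1–0.2 of each other while
distinct groups sit ≈ 0.4 apart, and the full workflow recovers the four
groups exactly (adjusted Rand index 1.0, selected k = 4) on every seed
tested.

What the benchmark does *not* show: the factor model produces clean block
correlation with Gaussian noise and controlled module counts, not the
platform artifacts, batch effects, heavy-tailed noise, or overlapping
module membership of real microarray data.  Passing it demonstrates that
the pipeline's stages are correct and that the method detects genuine
topological differences between networks; it does not certify performance
on any particular real data set, where group differences may be subtler
than a module-count contrast.

Per-replicate random streams are derived from
(seed, stream, group, replicate) tuples, so any subset of the study is
reproducible independently and two runs with the same configuration are
bitwise identical.

## Packaged study manifest

`persnet.data/table1.tsv` transcribes the metadata of the 38 Arabidopsis
pathogen-stress microarray experiments (GEO accessions, stress group,
stress) on which this kind of analysis was designed: 6 PTI, 6 bacteria, 16
induced resistance, and 10 fungi experiments.  Entry 18 (GSE5513) is
recorded with stress "Induced resistance (PTI)": its stress group is set to
PTI, consistent with the published per-group totals and with the narrative
placement of that experiment among the PTI networks, although the original
table column reads "Induced resistance"; this is the one place where the
transcription departs from the table's group column.  The accessions are
metadata only — the package performs no GEO retrieval or normalization, and
real-data runs require user-supplied normalized expression matrices.

## Known limitations

- Dimension-1 analysis is cubic in gene count; large networks need a gene
  cap or a filtration cap.
- The bottleneck feasibility test builds the full augmented bipartite graph
  ((|A|+|B|)² candidate edges); diagrams beyond a few thousand points would
  need the geometric-neighbor optimizations of specialized libraries.
- Classical MDS is only one way to bridge a non-Euclidean distance matrix to
  K-means; the embedding is an explicit assumption of the k-selection step
  (Ward clustering itself uses the distances directly).
- The elbow reading of the BIC curve requires k_max at least two beyond the
  true cluster count to be detectable.
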