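# Methods

## The problem

Given per-subject fMRI activation (each voxel's BOLD time course averaged
over time) and a group label per subject (e.g. patients vs controls), we
want a voxel-level *information map*: which contiguous sets of voxels
jointly discriminate the groups. The classical searchlight slides a
fixed-radius sphere over the volume and assigns each sphere's
discriminability to its center voxel; its radius and shape are tuning
parameters, and informative irregular subregions get smeared or split.
`icsearch` instead grows a data-driven cluster from every voxel, with no
shape or size parameter: voxels are admitted while they raise the cluster's
discriminability and removed when they become redundant.

## Relevance: spectral trace ratio

Subjects are nodes of two label-derived affinity graphs. With n subjects
and class sizes n_l the Fisher affinities are

    S_b[i,j] = 1/n - 1/n_l  (i, j in the same class l, incl. i = j)
               1/n          otherwise
    S_w[i,j] = 1/n_l        (same class), 0 otherwise

Degrees are row sums, so D_b = 0 and D_w = I, giving Laplacians
L_b = -S_b and L_w = I - S_w. Both are projections (hence PSD): for a
voxel row x (1 x n), x L_b x' is its between-class scatter and x L_w x' its
within-class scatter. The relevance of a voxel set IC with selection matrix
W is the trace ratio

    S(IC) = tr(W' X L_b X' W) / tr(W' X L_w X' W)
          = (sum of b_i over IC) / (sum of w_i over IC),

where b_i, w_i are the per-voxel quadratic forms. The second equality
(additivity of the trace) is what makes the search cheap: b and w are
computed once, and every candidate evaluation afterwards is two sums and a
division. A dense reference implementation materializes W and is used as an
oracle in the tests.

A literal reading of the degree matrix as "diag of S" would make the
Laplacians indefinite and break the Fisher interpretation; row-sum degrees
are the standard graph-Laplacian construction and are what we use.

Voxels are standardized (zero mean, unit variance across subjects) before
scoring by default — the trace ratio is per-voxel scale sensitive — and the
toggle is exposed. If a cluster's within-class scatter sum falls below
1e-12 its score is reported as +inf with a warning; this arises only on
pathological (constant) input.

Without labels, the same machinery runs in Laplacian-score mode: S_w is a
symmetrized k-nearest-neighbor graph over subjects with heat-kernel weights
(defaults k = 5, width = median pairwise distance), S_b the complete graph
at 1/n.

## Admission and the expand/prune loop

A candidate voxel is admitted iff adding it strictly increases the cluster
score. Since (B + b)/(W + w) > B/W iff b/w > B/W, each expansion admits
exactly the adjacent voxels whose individual ratio exceeds the current
cluster score; all passers of a layer are admitted jointly, which also
strictly increases the joint score (mediant inequality). Ties (dif = 0)
reject, so scores increase strictly with every expansion and the search
terminates without any size parameter.

Pruning scores every unprotected member by J = mean mutual information with
the rest of the cluster, estimated on quantile-binned values (default 8
equal-frequency bins, natural log). The member with the largest J (ties:
lowest linear index) is removed iff removal does not decrease the cluster
score; pruning stops the first time the designated candidate fails that
gate. We read the stopping rule this way (rather than skipping to the
next-J member) as the literal greedy procedure; it is also the more
conservative of the two readings.

Anti-loop bookkeeping uses one-phase windows: voxels admitted by expansion
k are protected during prune k only; voxels removed by prune k are excluded
from expansion k+1 only. The origin voxel is protected permanently, which
preserves the "cluster originating at v" identity the per-voxel output map
needs. Pruning may disconnect a cluster; the set is kept and flagged.
A hard cap of 4p phases per origin exists as a safety bound; strict score
increase makes it unreachable in practice and the tests assert it.

Determinism: the search contains no randomness; all ties break by the
geometric linear index (lexicographic (i,j,k) order of in-space voxels).
Seeds govern only data generation and cross-validation folds.

## Memoization

The spectral terms b, w are computed once before the origin loop. Pairwise
MI values are filled into a sparse table keyed by the (lower, higher) voxel
pair the first time the search needs them and shared across all origins;
bin codes per voxel are likewise computed once. Because the search only
ever compares members of analytically formed local clusters, most pairs are
never requested and computed pairs concentrate near spatially adjacent
voxels (asserted in the tests). The non-memoized path recomputes MI from
the same canonical pair order, so memoized and non-memoized runs are
bit-identical, not merely close.

## Neighborhoods and the searchlight baseline

Connectivity is configurable (6/18/26); the default is 26, the most
inclusive standard voxel neighborhood, since "immediate neighbor" admits
several conventions. The searchlight baseline assigns each voxel the
trace-ratio score of the in-space voxels within Euclidean distance r
(sphere truncated at the mask boundary) — the same relevance measure as the
cluster search, so comparisons isolate the search strategy. The L1 baseline
fits an L1-penalized logistic model (penalty weight alpha on the mean loss,
default 0.001; sklearn C = 1/(n alpha)) and scores voxels by |coefficient|.

## Reported information

The search heuristic (trace ratio) is unbounded, so reported cluster
*information* is the stratified 5-fold cross-validated AUC of a linear SVM
restricted to the cluster's voxels: it has the 0.5 chance anchor that the
above-chance (> 0.5, strict) and top-k (default 50) selection rules need.
For unbiased estimates — e.g. null calibration — clusters must be
discovered on subjects disjoint from those used to score them; the package
provides `holdout_information` for split protocols, and the calibration
tests score clusters on an independent replication draw of the same
generator, which keeps the full-sample CV estimator (AUC sd ~0.04 at
n = 200) without the selection-bias inflation we measured (~0.74 mean null
AUC when scoring on the discovery sample, ~0.5 on a replication draw).

## Synthetic data

Each subject is a voxels x T matrix of N(0, baseline_sd^2) noise. Spatial
correlation is induced by mixing each voxel's series with the mean of its
6-neighbors' series, renormalized to unit variance; the mixing weight is
solved in closed form so interior adjacent pairs reach the target
correlation rho (default 0.3, a realistic adjacent-voxel value). The
construction has a ceiling of rho = 1/sqrt(6) ~ 0.408 — beyond it the
generator raises rather than silently under-correlating. Condition-locked
patterns add amplitude x envelope(t) x baseline_sd to the planted voxels of
class-1 subjects, where the envelope is a peak-normalized double-gamma
hemodynamic-response-shaped curve sampled at T points (default T = 120
spanning a 32 s response); time series are then averaged per voxel. With
the defaults, a 1.0 SD amplitude yields a per-voxel effect of about 1.4
averaged-noise SDs. An `amplitude = 0` spec is the matched null. Defaults
follow the study conditions: 1,000 subjects split evenly, and search-space
presets of 100 / 500 / 10,000 / ~30,000 voxels.

Atrophy is simulated by scaling the case group's values inside a mask by
(1 - fraction); because this acts multiplicatively, detection experiments
give the generator a nonzero baseline mean (we use 1.0) so atrophy shifts
group means rather than only variances. The generator does not model
physiological noise, drift, motion, or site effects, so passing tests show
correctness of the machinery and qualitative behavior under idealized
noise — not performance on real scanner data.

## Evaluation protocols and problem sizes used

Detection experiments use each method's native unit at matched k: the union
of the top-50 clusters (by relevance) for the cluster search, the union of
the top-50 spheres for the searchlight, and the nonzero-coefficient voxels
for L1; TPR/FPR/FNR are computed against the planted mask and method
orderings are asserted by one-sided sign tests across seeds, not as fixed
numbers. Planted-pattern recovery is summarized by best-match Jaccard (the
maximum Jaccard between any discovered cluster and the truth set), the
standard planted-structure recovery metric.

Test-suite problem sizes: recovery uses a 10x10x10 grid, 100+100 subjects,
a 27-voxel block at 1.0 SD, 20 seeds; null calibration uses the same
generator at amplitude 0 with 50 seeds and information estimated on 20
sampled origins per seed against a replication draw; atrophy uses a 7x7x7
grid, 30+30 subjects, 25% atrophy on a 27-voxel mask, 20 seeds;
memoization-neutrality runs both engines on a 5x5x5 grid with 30 subjects.
`scripts/acceptance.py` recomputes the same quantities at 3 seeds per
experiment.

## Known limitations

- Group-level only: per-subject maps are out of scope, as is any use of
  temporal dynamics beyond the time average.
- The MI estimator is plug-in histogram MI on quantile bins (default 8);
  it needs at least 2 x bins subjects and is biased upward at small n, which
  matters only for the absolute J values, not the rankings the pruner uses.
- Neighbor-mean mixing cannot produce adjacent correlations above ~0.41.
- The greedy expand/prune search is not exhaustive; it reduces but does not
  eliminate local optima.
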