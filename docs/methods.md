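# Methods

## Data model

The substrate is a rectangular connectivity table: rows are source areas,
columns are injected target areas, and each cell holds an ordinal input
strength from the vocabulary {0, 16, 33, 67, 100} (absent / weak /
moderate / medium / strong). Rows may include sources (temporal, insular)
that are not themselves targets. In canonical mode the vocabulary is
enforced strictly; permissive mode accepts any value in [0, 100] so that
jittered synthetic matrices remain loadable.

Self-connections: a target's own row is part of its column vector and
carries a structural 0. For square matrices `column_distances` offers an
`exclude_self` mode that drops the two rows named after each pair of
targets being compared, so the self-connection convention cannot influence
the distances; the default keeps all rows, which treats rectangular and
square matrices uniformly. Cluster-level mean inputs always exclude
source == target cells, since the diagonal is a convention rather than an
observation — this also makes within-cluster means directly comparable to
the generator's planted block means.

The packaged area registry reconstructs the 55-area parcellation of the
macaque parieto-frontal system (18 parietal areas — 9 SPL + 9 IPL — and 37
frontal areas) with each area's lobe, subdivision and reference cluster.
The published sources never enumerate the 37 frontal areas in a single
list, so the registry is a reconstruction from the parcellation
description; in particular the rostral and intermediate sectors of area
12r are carried as a single entry to match the stated area count. The
registry drives fixture generation and target subsetting only; any
user-supplied registry CSV can replace it.

## Tree search

Candidate topologies come from agglomerative clustering
(`scipy.cluster.hierarchy.linkage`) of the Euclidean distances between
target columns. The linkage rule defaults to average linkage —  the
standard choice for profile distances in connectivity parcellation and
stable in merge order — with complete, single and Ward available. Exact
distance ties are resolved by scipy's internal deterministic order; under
row bootstrapping ties have probability ~0, so no additional tie-breaking
layer is imposed.

The bootstrap resamples entire rows of the table with replacement
(columns untouched), recomputes column distances on each resample and
builds one topology per resample, plus one from the original table. With
the default 10,000 replicates the candidate ensemble holds 10,001 fitted
trees. Bootstrapping here is a topology *proposal* mechanism — a way out
of the local minima of direct tree fitting — not an inference procedure:
every candidate is scored against the original, unsampled data.

Per-replicate randomness derives from
`SeedSequence(entropy=seed, spawn_key=(i,))`, so each replicate has an
independent substream and results are identical regardless of evaluation
order.

## Branch-length fitting and the fit statistic

For a fixed rooted topology, each non-root node (leaf or internal)
contributes one edge, identified by the clade below it. The leaf-pair ×
edge incidence matrix A has a 1 where an edge separates a pair, and branch
lengths solve the nonnegatively constrained least squares problem
`min ‖A·x − d‖², x ≥ 0` via `scipy.optimize.nnls`. Edges fitted to exactly
zero are reported, not pruned, so the topology's clade set is preserved.

The fit statistic is the log-likelihood under iid Gaussian residuals on
the m = n(n−1)/2 leaf-pair distances with plug-in MLE variance:

    ℓ = −(m/2) (ln 2πσ̂² + 1),   σ̂² = max(SSE/m, 10⁻¹²)

The variance floor keeps ℓ finite on exactly additive data; below the
floor trees are tied and ordered by generation order (original-data tree
first). Because ℓ is a strictly decreasing function of SSE above the
floor, tree rankings coincide with least-squares rankings; a fixed-σ
Gaussian model would permute nothing. Only the root's position is
non-identifiable from leaf-to-leaf distances (the two root-child edges
trade off); NNLS returns one valid solution and all reported quantities
(SSE, ℓ, path distances) are invariant to that indeterminacy.

Duplicate topologies in the ensemble are retained as distinct entries:
consensus occurrence counts among the best k trees are multiplicities, so
deduplication would change the statistics. Fits are memoised by clade-set
identity internally, which is what keeps the 10,001-tree default run on a
55-area matrix in the low minutes on one CPU.

## Consensus

The k = 100 best trees by log-likelihood feed the consensus. Two rules:

- **majority**: keep clades occurring in more than k/2 trees (always
  pairwise compatible);
- **greedy** (default, extended majority): scan clades by decreasing
  count — ties broken toward larger clades, then lexicographic member
  order — keeping each clade compatible (nested or disjoint) with
  everything already kept.

Greedy is the default because observed support values in this kind of
analysis fall well below half (clusters retained with 29–48 occurrences
out of 100), which strict majority would discard; the greedy clade set is
always a superset of the majority set. Clade identity ignores branch
lengths. The retained clades nest into a possibly multifurcating topology
whose Newick export carries occurrence counts as node support values.

To compare a consensus against a reference partition at a given
granularity, `cut_tree_partition` repeatedly splits the frontier block
with the most leaves (ties: block containing the alphabetically first
leaf) until k blocks exist. This is a deterministic heuristic: the
primary recovery check is whether each reference cluster occurs as a
retained clade, with the cut-based adjusted Rand index as a secondary,
granularity-matched score.

## Input profiles and entropy

For a receiving cluster R and projecting cluster P, the mean input is the
arithmetic mean of all (source ∈ P, target ∈ R) cells, zeros included and
self pairs excluded. The entropy of R's input distribution is
H = −Σ pᵢ ln pᵢ (nats) over the normalised mean inputs, by default
*including* R's own local input — local connectivity is part of the input
budget, and with C clusters the distribution then ranges over C inputs —
with an exclude-self option and an area-level mode (fractions over
individual source areas) also available. H is bounded by ln(number of
inputs), attained exactly at uniformity; a point mass gives 0.

A documented discrepancy: evaluating the entropy formula on the seven
printed pmSPL mean-input values gives 1.708 nats, not the 1.92 nats the
figure reports for that cluster; the figure's profile evidently spans all
11 cluster-level inputs (including self and minor inputs not printed in
the text). The package freezes 1.708 as the oracle value for the
seven-input vector and treats the 11-input mode as the default
definition.

## Synthetic planted-partition generator

The generator emulates the statistical structure the analysis assumes,
not the tracing experiment. Its key design decision is *profile
coherence*: for every (source area, receiving cluster) pair a single
two-point mixture of the adjacent vocabulary levels bracketing the block
mean is drawn and written into all member columns. At `flip_rate = 0`,
areas of the same cluster therefore have near-identical input profiles —
exactly the "areas sharing inputs cluster together" premise — while
clusters differ through their block means and independent draws. An
earlier variant that drew each cell independently (coupling reciprocal
pairs instead) produced matrices whose planted partition was *not*
recoverable even at zero noise, because same-cluster columns carried
independent mixture noise of the same magnitude as the between-cluster
signal; profile coherence is what the clustering model actually assumes.

Noise and asymmetry:

- `flip_rate` (default 0): per-cell probability of resampling the level
  uniformly from the vocabulary — the ordinal analogue of measurement
  noise. Recovery degrades monotonically in expectation as it grows.
- `asymmetry` (default 0.3): per reciprocal pair, the probability that one
  member (chosen at random) moves one vocabulary step, making reciprocal
  connections "often of different strength". The step direction is drawn
  with probabilities inversely proportional to the step sizes, so the
  perturbation is mean-preserving away from the vocabulary boundaries.
  Reciprocity itself lives at the block level: both directions of a
  cluster pair carry positive, generally unequal, means.

Block means are exactly representable as mixtures of adjacent levels for
any target in [0, 100]; infeasible means are rejected. The
`macaque_fixture` modes (parietal 18 areas / 5 clusters, frontal 37 /
6, intrinsic SPL–IPL 18 / 5 with MIP reassigned to pmSPL and PEa to aSPL,
full 55 / 11) use the published between-cluster mean-input values as block
means where printed, a local (within-cluster) mean of 50 — the strongest
mean input observed in the published analysis — and a weak background of 5
elsewhere.

What passing tests on these fixtures do **not** show: the generator has no
missing data, no curation error, no per-study strength-calibration bias,
and its noise is iid across cells — real literature-curated matrices
violate all four. Recovery results on fixtures certify the pipeline's
correctness and its behaviour under controlled noise, not the robustness
of any particular anatomical conclusion.

## Problem sizes and defaults

Defaults reproduce the published workflow: `n_bootstrap = 10000`,
`k_best = 100`, average linkage, greedy consensus, entropy in nats with
self-input included. The test and driver runs use reduced bootstrap
depths (100–2,000) chosen so that occurrence counts are stable to a few
percent while the full suite stays fast; the acceptance script runs the
parietal fixture at the full 10,000-bootstrap default and the larger
frontal/SPL–IPL fixtures at 2,000.

## Known limitations

- The consensus cut used to derive a flat partition is a heuristic; when
  planted clusters differ greatly in size the cut can stop at a different
  antichain even though every planted clade is retained in the consensus.
- The Gaussian likelihood treats the m leaf-pair distances as independent
  observations, which they are not (they share the n underlying columns);
  ℓ is a ranking statistic here, not a calibrated model likelihood.
- Ordinal strengths are treated as interval-scaled quantities by the
  Euclidean distance and the means, inheriting the semi-quantitative
  character of the underlying scale.
- Exact distance ties (possible on tiny hand-made matrices) resolve by
  scipy's internal merge order rather than a label-lexicographic rule.
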