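# Methods

## Overview

`kdconn` implements a graph-theoretic analysis of functional-connectivity
networks built from node × time signal matrices (for example resting-state
fMRI voxel or ROI time series). The pipeline is:

1. Pearson correlation between every pair of node time series.
2. Binarization at a fixed **link density**: the subject-dependent
   absolute-correlation threshold is chosen so that exactly
   M = ⌊d·N(N−1)/2⌋ edges are retained for density d.
3. Global graph metrics (clustering, global efficiency, modularity,
   small-worldness) normalized against random-graph ensembles.
4. The **degree rank-order disruption index k_D**: with x the per-node mean
   degree of a designated reference cohort and y the difference between a
   subject's nodal degrees and x, k_D is the slope of the OLS fit
   y = k_D·x + b over all N nodes. k_D = 0 means the subject preserves the
   reference degree rank order; k_D → −1 means hubs have lost and peripheral
   nodes have gained connections until the rank order is fully random.
5. Consensus community detection (Louvain with resolution γ, repeated runs,
   thresholded co-assignment matrix), NMI partition similarity, and
   module-allegiance maps against a baseline partition.
6. Cohort orchestration: group summaries, k_D–covariate correlations, and a
   per-node permutation contrast with Benjamini–Hochberg FDR.

Because the method is defined on generic correlation networks, everything is
validated on synthetic cohorts with *planted* disruption of known magnitude,
so each stage has a quantitative ground truth.

## Graph construction

- **Pearson only.** The correlation estimator is fixed to Pearson; node
  series with zero variance are an error (masking belongs upstream).
- **Absolute-value thresholding.** Edges are the M node pairs with the
  largest |r|; strong negative correlations also create edges.
- **floor, not round,** for M: deterministic and never exceeding the nominal
  density. A 1e−9 guard absorbs binary float representation of d·N(N−1)/2
  without changing any exact rational floor.
- **Ties at the cut** are broken by lexicographic node-pair order, so graph
  construction is bit-reproducible.
- **Nestedness.** A density sweep ranks pairs once, so the edge set at a
  lower density is always a subset of the edge set at a higher one.
- Connectivity is *reported* (component count), never enforced.
- Retained correlations are not additionally filtered by a p-value; the
  density cut is the only selection rule.

## Graph metrics

- Local clustering follows the Watts–Strogatz definition; nodes with degree
  < 2 contribute 0. Global efficiency is the mean of 1/d(i,j) over distinct
  pairs, with disconnected pairs contributing 0. Both are computed through
  networkx and are verified in the test suite against exhaustive
  triangle-counting and Floyd–Warshall oracles on small random graphs
  (agreement to 1e−12).
- Modularity Q(γ) = (1/2M) Σ_ij [A_ij − γ k_i k_j/2M] δ(c_i,c_j) is
  implemented directly (per-module accumulation); γ = 1 recovers standard
  Newman–Girvan modularity.
- **Random references.** The default null is an ensemble of 25 Erdős–Rényi
  graphs with identical N and M. A degree-preserving null (Maslov–Sneppen
  double-edge swaps, 10·M swaps per realization) is also available; graphs
  whose degree sequence admits no swaps raise an error. Small-worldness is
  (C_G/C_rand)/(E_rand/E_G), with ratio > 2 flagged as the small-world
  regime.

## The disruption index and its variants

- The regression is **unweighted OLS over nodes**; heteroscedasticity across
  degree bins is deliberately ignored, matching the source formulation of
  the hub-disruption index. All nodes enter the regression, including
  zero-degree nodes.
- If the difference vector is exactly constant (e.g. the reference cohort
  regressed on its own mean map), the slope is returned as exactly 0 rather
  than going through the numerical fit.
- **Group k_D** is computed on the group mean degree profile (the default);
  the mean of per-subject slopes is exposed separately
  (`kd.mean_subject_kd`).
- The reference map is always an explicit argument — off-site controls,
  time-matched shams, or any designated cohort — never a global default.
- **k_D′ (node deletion)** drops nodes from the regression only; degrees are
  not recomputed on a pruned graph.
- **k_D″ (random subsets)** draws uniform node subsets (default 5000
  permutations) and summarizes the subset slopes by median and IQR. For a
  *globally* disrupted subject the subset median tracks the full-network
  k_D; localized effects would decouple the two.
- **Noise robustness.** White Gaussian noise is mixed into each z-scored
  node series as z((1−p)·z(signal) + p·z(wgn)) at levels 0.2…1.0 in steps of
  0.2, with level 0 prepended as baseline. Re-z-scoring keeps correlation
  magnitudes comparable across levels: the population effect of mixing is a
  uniform shrinkage of all correlations by (1−p)²/((1−p)²+p²), which
  preserves the |r| ranking, so k_D should be flat in p until sampling noise
  dominates and then collapse toward −1 at p = 1.

## Community analysis

- The Louvain engine is `networkx.community.louvain_communities` with the
  resolution parameter and a seeded sweep order; partitions are
  canonicalized (labels renumbered by first appearance) so label choices
  never leak into comparisons.
- **Consensus**: 100 repetitions by default; the co-assignment frequency
  matrix is thresholded at 0.9 (strictly above) and pairs surviving the
  threshold are closed into modules by connected components — the minimal
  closure of the pairwise "same module" relation. Singleton modules are
  allowed.
- **NMI** uses the arithmetic normalization 2I/(H₁+H₂) (scikit-learn).
  Entropy-zero edge cases: two single-module partitions → 1; single- vs
  multi-module → 0.
- **Parameter sweep**: densities 10–50% in steps of 10% × γ 1–2 in steps of
  0.25 by default (`kdconn communities --sweep`); each cell is scored by the
  mean NMI of its consensus partition with its 4-neighborhood and the argmax
  is selected, ties broken toward the lowest density, then the lowest γ. The
  second, anatomical criterion used in human studies (named resting-state
  systems) is a judgment call outside this package: the selected cell is
  reported, not validated against anatomy. The pipeline default operating
  point is density 10%, γ = 1.5.
- **Allegiance**: "same modular membership" across independently labeled
  partitions requires a label correspondence; we use optimal one-to-one
  maximum-overlap matching (linear assignment on the confusion matrix). It
  is deterministic, symmetric in module count, and reduces to the identity
  when the partitions agree. Nodes in unmatched subject modules score 0 and
  contribute to no baseline module in ROI profiles.

## Synthetic cohorts and planted disruption

The generator emulates only the *statistical* structure the analysis
assumes; it has no hemodynamic forward model, no spatial/volumetric
structure, and no parcellation geometry. What passing tests show is that the
estimators recover planted parameters under block-Gaussian assumptions — not
that real fMRI satisfies those assumptions.

- **Latent structure**: block correlation matrix with `r_within` inside
  modules and `r_between` across, unit diagonal, PSD-checked at
  construction. Default: 150 nodes, 6 modules of sizes 40/35/25/20/18/12,
  r_within = 0.5, r_between = 0.1, 300 timepoints. The *unequal* module
  sizes matter: at fixed density, nodes in larger modules have more
  strongly-correlated partners and hence higher degree, giving the cohort a
  shared hub hierarchy with genuinely positive reference-map variance. With
  equal module sizes the reference degree map is nearly flat and the
  regression slope is dominated by sampling noise.
- **Subject variability** is Gaussian jitter (sd 0.02) on the latent
  off-diagonal correlations, projected back to the nearest PSD correlation
  matrix (eigenvalue clipping + diagonal renormalization). The
  distributional form of inter-subject variability is our choice — nothing
  in the method constrains it — and module membership itself is never
  jittered.
- **Degree-mix disruption**: d′ = (1−λ)d + λπ(d) with π a uniform random
  permutation. Since E[cov(π(d), d)] → 0, the expected slope of (d′−d) on d
  is −λ exactly, giving a closed-form oracle for parameter recovery
  (verified at λ ∈ {0.1, 0.2, 0.3, 0.5}, N = 1000, 100 subjects, tolerance
  0.05).
- **Edge-rewire disruption**: a fraction λ of edges is detached with
  probability proportional to summed endpoint degrees (hubs lose first) and
  reattached uniformly among non-edges, conserving N, M, and simplicity.
  This has no closed-form slope but erodes rank order monotonically, which
  is what the end-to-end test asserts (strict decrease of group k_D across
  λ ∈ {0, 0.25, 0.5}).

## Cohort pipeline

- All randomness flows from one top-level seed through
  `numpy.random.SeedSequence`-derived sub-seeds (per subject, per
  repetition), so partial reruns are reproducible and full reruns are
  bit-identical.
- Subjects with differing node counts are rejected, not masked; a common
  node set is upstream preprocessing.
- Group inference is a per-node **permutation test** of mean degree
  differences (add-one p-values, floor 1/(n_perm+1)) followed by
  Benjamini–Hochberg FDR across nodes. This is a deliberate desk-scale
  substitute for covariate-adjusted ANCOVA and spatial cluster-corrected
  voxelwise inference, which are data-specific and out of scope; the two are
  not equivalent. Under a two-cohort global null the mean fraction of
  q < 0.05 nodes stays below 0.05 (verified over 50 replicates).
- Note on power at fixed density: thresholding makes nodal degrees compete
  (the edge budget is fixed), so between-subject degree variance of
  graph-derived profiles is large and spatially correlated; small planted
  mean shifts are better detected on degree profiles with independent noise,
  which is how the screening machinery itself is validated.

## Problem sizes used in validation

Simulation sizes were chosen as the smallest that leave clear air between
signal and Monte-Carlo noise: cohorts of 20 subjects at N = 150 nodes and
T = 300 timepoints for graph-level checks; N = 500–1000 node degree vectors
with 100–200 planted-disruption draws for slope recovery; 4-block
stochastic block models (N = 100, p_in = 0.5, p_out = 0.02, 50 runs × 100
consensus repetitions) for community recovery; 50 replicate two-cohort nulls
for FDR calibration.

## Known limitations

- Binarized graphs only; no weighted metrics, betweenness, rich-club, or
  characteristic path length.
- The Louvain internals are delegated to networkx, so per-pass monotonicity
  of Q is not instrumented; instead the tests assert that returned
  partitions beat trivial and random partitions in Q(γ).
- The generator's Gaussianity means correlation estimates are well behaved;
  heavy-tailed or nonstationary signals may degrade graph stability in ways
  the tests do not probe.
- No NIfTI/volumetric I/O, multi-site harmonization, or longitudinal
  modeling.
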